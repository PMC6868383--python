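"""Shrake-Rupley solvent-accessible surface area and relative carbonyl exposure.

The SASA of an atom is estimated by placing a deterministic quasi-uniform
point grid (golden-spiral construction) on its solvent-expanded sphere of
radius ``r_i + probe`` and counting the fraction of points that fall outside
every other atom's expanded sphere:

    SASA_i = (accessible fraction) * 4 * pi * (r_i + probe)^2

The relative carbonyl exposure of a conformer is the summed SASA of the
ester-carbonyl group divided by a normalization constant.  The default
constant is 48.4 A^2 — the maximum carbonyl SASA observed across the
reference aminoacylated-trinucleotide simulations — giving a value in [0, 1];
a "dataset-max" mode instead derives the constant as the maximum over the
ensembles of the current run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import BONDI_RADII, Ensemble, select

__all__ = [
    "RadiiTable",
    "ExposureSeries",
    "DEFAULT_NORMALIZATION",
    "sphere_points",
    "shrake_rupley",
    "carbonyl_exposure",
    "carbonyl_exposure_many",
    "exposure_histogram",
]

#: Reference normalization constant for relative carbonyl exposure (A^2).
DEFAULT_NORMALIZATION = 48.4


@dataclass(frozen=True)
class RadiiTable:
    """Van-der-Waals radii (A) by element with per-atom-name overrides.

    ``probe_radius`` defaults to 1.4 A (water probe) and ``n_sphere_points``
    to 196 grid points per sphere.
    """

    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    overrides: Mapping[str, float] = field(default_factory=dict)
    probe_radius: float = 1.4
    n_sphere_points: int = 196

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be > 0")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")

    def resolve(self, atom_name: str, element: str) -> float:
        if atom_name in self.overrides:
            return self.overrides[atom_name]
        return self.radii.get(element.upper(), 1.70)

    def for_ensemble(self, ensemble: Ensemble) -> np.ndarray:
        return np.array(
            [self.resolve(a.atom_name, a.element) for a in ensemble.topology.atoms]
        )


@dataclass
class ExposureSeries:
    """Per-frame carbonyl SASA (A^2) and its normalized relative exposure.

    ``n_exceeding_unity`` counts frames whose relative exposure exceeds 1
    under a fixed normalization constant; such values are reported as-is and
    flagged, never clipped.
    """

    carbonyl_sasa: np.ndarray
    relative_exposure: np.ndarray
    normalization_constant: float
    n_exceeding_unity: int = 0

    @property
    def mean_relative_exposure(self) -> float:
        return float(self.relative_exposure.mean())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors via the golden-spiral lattice."""
    if n < 12:
        raise ValueError(f"need at least 12 sphere points, got {n}")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    frame: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 196,
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom SASA (A^2) of one conformation.

    Parameters
    ----------
    frame : (n_atoms, 3) array
        Heavy-atom coordinates in angstrom.
    radii : (n_atoms,) array
        Van-der-Waals radius of each atom.
    subset : sequence of int, optional
        Compute SASA only for these atom indices (all atoms still occlude).
        Returns an array aligned with ``subset`` when given, else per atom.
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError(f"frame must be (n_atoms, 3), got {frame.shape}")
    if radii.shape != (frame.shape[0],):
        raise ValueError("radii must resolve one radius per atom")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite coordinates")
    grid = sphere_points(n_points)
    expanded = radii + probe_radius
    targets = np.arange(frame.shape[0]) if subset is None else np.asarray(subset, int)
    areas = np.empty(targets.size, dtype=float)
    diff = frame - frame[:, None]  # (i, j, 3): frame[j] - frame[i] at [i, j]
    dist = np.linalg.norm(diff, axis=-1)
    for out, i in enumerate(targets):
        # only spheres that can intersect atom i's expanded sphere occlude it
        neighbors = np.where((dist[i] < expanded[i] + expanded) & (dist[i] > 0))[0]
        points = frame[i] + expanded[i] * grid
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= (
                ((points - frame[j]) ** 2).sum(axis=1) > expanded[j] ** 2
            )
        areas[out] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def carbonyl_exposure(
    ensemble: Ensemble,
    radii: RadiiTable | None = None,
    normalization: float | str = DEFAULT_NORMALIZATION,
) -> ExposureSeries:
    """Per-frame carbonyl-group SASA and relative exposure for one ensemble.

    ``normalization`` is a positive constant in A^2, or ``"dataset-max"`` to
    normalize by this ensemble's own maximum (use
    :func:`carbonyl_exposure_many` for a shared dataset-wide constant).
    """
    radii = radii or RadiiTable()
    group = select(ensemble, "carbonyl")
    if not group:
        raise ValueError("carbonyl group is empty; cannot compute exposure")
    atom_radii = radii.for_ensemble(ensemble)
    sasa = np.array(
        [
            shrake_rupley(
                frame, atom_radii, radii.probe_radius, radii.n_sphere_points, subset=group
            ).sum()
            for frame in ensemble.coords
        ]
    )
    if normalization == "dataset-max":
        constant = float(sasa.max())
        if constant <= 0:
            raise ValueError("dataset-max normalization is zero (carbonyl fully buried)")
    else:
        constant = float(normalization)
        if constant <= 0:
            raise ValueError(f"normalization must be > 0, got {constant}")
    rel = sasa / constant
    return ExposureSeries(
        carbonyl_sasa=sasa,
        relative_exposure=rel,
        normalization_constant=constant,
        n_exceeding_unity=int((rel > 1.0).sum()),
    )


def carbonyl_exposure_many(
    ensembles: Sequence[Ensemble],
    radii: RadiiTable | None = None,
    normalization: float | str = DEFAULT_NORMALIZATION,
) -> list[ExposureSeries]:
    """Exposure series for several ensembles under one shared constant.

    With ``"dataset-max"`` the constant is the maximum carbonyl SASA across
    all ensembles, so the dataset-wide maximum relative exposure is exactly 1.
    """
    radii = radii or RadiiTable()
    raw = [carbonyl_exposure(e, radii, normalization=1.0) for e in ensembles]
    if normalization == "dataset-max":
        constant = max(s.carbonyl_sasa.max() for s in raw)
    else:
        constant = float(normalization)
        if constant <= 0:
            raise ValueError(f"normalization must be > 0, got {constant}")
    out = []
    for s in raw:
        rel = s.carbonyl_sasa / constant
        out.append(
            ExposureSeries(
                carbonyl_sasa=s.carbonyl_sasa,
                relative_exposure=rel,
                normalization_constant=float(constant),
                n_exceeding_unity=int((rel > 1.0).sum()),
            )
        )
    return out


def exposure_histogram(
    series: Iterable[ExposureSeries], bin_width: float
) -> np.ndarray:
    """Pooled normalized exposure histogram over [0, 1].

    Returns a structured (n_bins, 3) array of rows (bin_lo, bin_hi, frequency)
    with frequencies summing to 1.  Values above 1 are pooled into the top bin.
    """
    if not (0 < bin_width <= 1):
        raise ValueError(f"bin_width must be in (0, 1], got {bin_width}")
    values = np.concatenate([np.asarray(s.relative_exposure) for s in series])
    if values.size == 0:
        raise ValueError("no exposure values supplied")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    idx = np.minimum((values / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    freq = counts / counts.sum()
    return np.column_stack([edges[:-1], edges[1:], freq])
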