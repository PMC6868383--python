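"""Conformational-state analysis: greedy RMSD clustering, two-reference state
assignment, occupancy fractions, the conformational-preference statistic and
coordinate PCA.

The clustering follows the greedy scheme of Daura et al. (the "GROMOS
method"): among all unassigned frames, the one with the most neighbors within
the RMSD cutoff becomes a cluster center; it and its neighbors are removed
and the step repeats.  The default cutoff for master-ensemble clustering is a
stringent 0.5 A on backbone atoms; individual conformers are subsequently
assigned to the top two cluster centers ("collapsed" / "extended") with a
1.5 A backbone-RMSD shell, everything else being labelled "other".

The conformational preference is -ln(f_collapsed / f_extended), a free-energy
proxy for the collapsed/extended balance; it is positive when the extended
state dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Ensemble
from .geometry import kabsch_superpose, rmsd_matrix

__all__ = [
    "Cluster",
    "ClusterResult",
    "StateAssignment",
    "PCAResult",
    "gromos_cluster",
    "assign_states",
    "state_fractions",
    "conformational_preference",
    "pca",
    "DEFAULT_CLUSTER_CUTOFF",
    "DEFAULT_ASSIGN_CUTOFF",
]

DEFAULT_CLUSTER_CUTOFF = 0.5  # A, cluster perimeter on backbone RMSD
DEFAULT_ASSIGN_CUTOFF = 1.5  # A, state-membership shell around a center

STATES = ("collapsed", "extended", "other")


@dataclass(frozen=True)
class Cluster:
    """One cluster: the greedy center, its members, and the middle structure.

    ``center_frame`` is the max-neighbor frame that seeded the cluster during
    the greedy iteration; ``middle_frame`` is the member with the smallest
    mean RMSD to all members (the representative structure reported by the
    standard clustering tools, and the reference used for state assignment).
    """

    center_frame: int
    member_frames: tuple[int, ...]
    middle_frame: int

    @property
    def size(self) -> int:
        return len(self.member_frames)


@dataclass
class ClusterResult:
    """Greedy-clustering partition, ordered by decreasing cluster size."""

    clusters: list[Cluster]
    cutoff: float

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def labels(self, n_frames: int) -> np.ndarray:
        out = np.full(n_frames, -1, dtype=int)
        for rank, cluster in enumerate(self.clusters):
            out[list(cluster.member_frames)] = rank
        return out


@dataclass
class StateAssignment:
    """Per-frame collapsed/extended/other labels and derived statistics."""

    labels: np.ndarray  # array of strings in STATES
    rmsd_to_collapsed: np.ndarray
    rmsd_to_extended: np.ndarray
    assignment_cutoff: float

    @property
    def fractions(self) -> tuple[float, float, float]:
        return state_fractions(self.labels)

    @property
    def f_collapsed(self) -> float:
        return self.fractions[0]

    @property
    def f_extended(self) -> float:
        return self.fractions[1]

    @property
    def f_other(self) -> float:
        return self.fractions[2]

    @property
    def preference(self) -> float:
        """-ln(f_collapsed/f_extended); NaN (flagged undefined) if a state is empty."""
        return conformational_preference(self.f_collapsed, self.f_extended)

    @property
    def preference_defined(self) -> bool:
        return self.f_collapsed > 0 and self.f_extended > 0


@dataclass
class PCAResult:
    """Coordinate PCA of an atom selection: eigenvalues in A^2, descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, aligned with eigenvalues
    projections: np.ndarray  # (n_frames, 2) projections on components 1-2
    mean_coords: np.ndarray


def gromos_cluster(
    ensemble: Ensemble,
    atoms: list[int] | np.ndarray,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> ClusterResult:
    """Greedy neighbor-count clustering of an ensemble on an atom selection.

    Deterministic tie-break: equal neighbor counts go to the lowest frame
    index.  Output clusters are sorted by decreasing size, ties by ascending
    center frame index.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if ensemble.n_frames < 2:
        raise ValueError("clustering requires at least 2 frames")
    matrix = rmsd_matrix(ensemble, atoms)
    n = matrix.shape[0]
    within = matrix <= cutoff  # includes self
    alive = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while alive.any():
        counts = (within & alive).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[center] & alive)[0]
        middle = int(members[np.argmin(matrix[np.ix_(members, members)].mean(axis=1))])
        clusters.append(
            Cluster(
                center_frame=center,
                member_frames=tuple(int(m) for m in members),
                middle_frame=middle,
            )
        )
        alive[members] = False
    clusters.sort(key=lambda c: (-c.size, c.center_frame))
    return ClusterResult(clusters=clusters, cutoff=cutoff)


def assign_states(
    ensemble: Ensemble,
    collapsed_ref: np.ndarray,
    extended_ref: np.ndarray,
    atoms: list[int] | np.ndarray,
    cutoff: float = DEFAULT_ASSIGN_CUTOFF,
) -> StateAssignment:
    """Label every frame collapsed / extended / other by RMSD to two references.

    A frame within ``cutoff`` of exactly one reference takes that label; a
    frame within the cutoff of both takes the nearer center, with an exact
    tie resolved to collapsed (the dominant state); all remaining frames are
    "other".  References are (n_sel, 3) coordinate arrays ordered like the
    atom selection.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    atoms = np.asarray(atoms, dtype=int)
    collapsed_ref = np.asarray(collapsed_ref, dtype=float)
    extended_ref = np.asarray(extended_ref, dtype=float)
    if collapsed_ref.shape != (atoms.size, 3) or extended_ref.shape != (atoms.size, 3):
        raise ValueError(
            "reference coordinates must match the atom selection "
            f"({atoms.size} atoms); got {collapsed_ref.shape} and {extended_ref.shape}"
        )
    sel = ensemble.coords[:, atoms, :]
    d_col = np.array([kabsch_superpose(collapsed_ref, f).rmsd for f in sel])
    d_ext = np.array([kabsch_superpose(extended_ref, f).rmsd for f in sel])
    labels = np.full(ensemble.n_frames, "other", dtype=object)
    in_col = d_col <= cutoff
    in_ext = d_ext <= cutoff
    labels[in_col & ~in_ext] = "collapsed"
    labels[in_ext & ~in_col] = "extended"
    both = in_col & in_ext
    labels[both & (d_col <= d_ext)] = "collapsed"  # exact tie -> collapsed
    labels[both & (d_ext < d_col)] = "extended"
    return StateAssignment(
        labels=np.asarray(labels, dtype=object),
        rmsd_to_collapsed=d_col,
        rmsd_to_extended=d_ext,
        assignment_cutoff=cutoff,
    )


def state_fractions(labels: np.ndarray | list[str]) -> tuple[float, float, float]:
    """Empirical (f_collapsed, f_extended, f_other) frequencies."""
    labels = np.asarray(labels, dtype=object)
    if labels.size < 1:
        raise ValueError("need at least one label")
    n = labels.size
    return tuple(float((labels == s).sum()) / n for s in STATES)  # type: ignore[return-value]


def conformational_preference(f_collapsed: float, f_extended: float) -> float:
    """Free-energy-like preference statistic -ln(f_collapsed / f_extended).

    Positive when the extended state dominates.  If either occupancy is zero
    the statistic is undefined and NaN is returned (flagged, never a
    pseudo-counted value); downstream statistics drop such rows.
    """
    if f_collapsed < 0 or f_extended < 0 or f_collapsed > 1 or f_extended > 1:
        raise ValueError("occupancies must lie in [0, 1]")
    if f_collapsed == 0 or f_extended == 0:
        return float("nan")
    return float(-np.log(f_collapsed / f_extended))


def pca(ensemble: Ensemble, atoms: list[int] | np.ndarray) -> PCAResult:
    """PCA of the x, y, z coordinates of an atom selection.

    Each frame is Kabsch-fitted to the ensemble-mean structure (one fitting
    round, then the mean is recomputed once) before the 3m x 3m coordinate
    covariance is diagonalised.  Projections onto components 1 and 2 are
    returned per frame.
    """
    if ensemble.n_frames < 3:
        raise ValueError("PCA requires at least 3 frames")
    atoms = np.asarray(atoms, dtype=int)
    sel = ensemble.coords[:, atoms, :]
    mean = sel.mean(axis=0)
    fitted = np.array([kabsch_superpose(mean, f).apply(f) for f in sel])
    mean = fitted.mean(axis=0)
    flat = (fitted - mean).reshape(ensemble.n_frames, -1)
    cov = flat.T @ flat / ensemble.n_frames
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    projections = flat @ eigenvectors[:, :2]
    return PCAResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
        mean_coords=mean,
    )
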