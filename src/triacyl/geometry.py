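"""Rigid-body superposition, RMSD and center-of-geometry primitives.

Kabsch superposition is SVD-based with determinant sign correction so that
only proper rotations (no reflections) are returned; neither COG nor RMSD is
mass-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Ensemble

__all__ = [
    "Superposition",
    "center_of_geometry",
    "kabsch_superpose",
    "rmsd",
    "rmsd_matrix",
    "MAX_RMSD_MATRIX_FRAMES",
]

#: Hard cap on the frame count accepted by :func:`rmsd_matrix` (O(n^2) cost);
#: subsample larger ensembles first.
MAX_RMSD_MATRIX_FRAMES = 20_000


@dataclass(frozen=True)
class Superposition:
    """Optimal proper rotation + translation of a mobile set onto a reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def center_of_geometry(coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError(f"expected a non-empty (n, 3) array, got shape {coords.shape}")
    return coords.mean(axis=0)


def kabsch_superpose(ref: np.ndarray, mov: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``mov`` onto ``ref``.

    Returns the proper rotation R and translation t minimising
    ``|| (mov @ R.T + t) - ref ||``, together with the post-fit RMSD.
    Reflections are excluded by SVD sign correction; degenerate (e.g.
    collinear) point sets still yield the sign-corrected SVD solution.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"ref and mov must share an (n, 3) shape, got {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"superposition requires n >= 3 atoms, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(diag) @ u.T
    residual = mov_c @ rotation.T - ref_c
    value = float(np.sqrt((residual**2).sum() / n))
    translation = ref.mean(axis=0) - rotation @ mov.mean(axis=0)
    return Superposition(rotation=rotation, translation=translation, rmsd=value)


def rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Minimum RMSD between two conformations under proper rigid motion."""
    return kabsch_superpose(ref, mov).rmsd


def _pairwise_block(a_cent: np.ndarray, sq_norms: np.ndarray, rows: np.ndarray,
                    cols: np.ndarray, n_atoms: int) -> np.ndarray:
    """Kabsch RMSD for all (rows x cols) frame pairs via batched 3x3 SVD."""
    h = np.einsum("iak,jal->ijkl", a_cent[rows], a_cent[cols], optimize=True)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    # det(H) < 0 => optimal proper rotation flips the sign of the smallest
    # singular value in the trace term
    corr = np.where(det < 0, -1.0, 1.0)
    trace = s[..., 0] + s[..., 1] + corr * s[..., 2]
    msd = (sq_norms[rows][:, None] + sq_norms[cols][None, :] - 2.0 * trace) / n_atoms
    return np.sqrt(np.clip(msd, 0.0, None))


def rmsd_matrix(ensemble: Ensemble, atoms: list[int] | np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch RMSDs over the given atom selection."""
    n = ensemble.n_frames
    if n < 2:
        raise ValueError("rmsd_matrix requires at least 2 frames")
    if n > MAX_RMSD_MATRIX_FRAMES:
        raise ValueError(
            f"{n} frames exceed the pairwise-RMSD cap of {MAX_RMSD_MATRIX_FRAMES}; "
            "subsample the ensemble first"
        )
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size < 3:
        raise ValueError("atom selection must contain at least 3 atoms")
    sel = ensemble.coords[:, atoms, :]
    cent = sel - sel.mean(axis=1, keepdims=True)
    sq_norms = (cent**2).sum(axis=(1, 2))
    matrix = np.zeros((n, n), dtype=float)
    block = max(1, 4_000_000 // max(n, 1))
    all_cols = np.arange(n)
    for start in range(0, n, block):
        rows = np.arange(start, min(start + block, n))
        matrix[rows] = _pairwise_block(cent, sq_norms, rows, all_cols, atoms.size)
    matrix = 0.5 * (matrix + matrix.T)  # enforce exact symmetry
    np.fill_diagonal(matrix, 0.0)
    return matrix
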