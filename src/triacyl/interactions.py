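"""Center-of-geometry distance criteria for stacking and sidechain contacts.

Two bases are counted as stacked in a frame when their COG distance is
strictly below 5 A; the amino-acid sidechain is in contact with a base below
8 A.  Frequencies are averages of these per-frame indicators over an
ensemble.  Distances are plain Euclidean COG distances over the heavy atoms
of the configured groups, without periodic imaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Ensemble, select

__all__ = [
    "ContactProfile",
    "STACK_CUTOFF",
    "CONTACT_CUTOFF",
    "cog_distance_series",
    "contact_frequency",
    "contact_profile",
]

STACK_CUTOFF = 5.0  # A, base-base COG
CONTACT_CUTOFF = 8.0  # A, sidechain-base COG

#: Column order used by the system table and every TSV export.
PROFILE_COLUMNS = (
    "sc_b1", "sc_b2", "sc_b3", "stack12", "stack23", "stack13", "sc_b1_and_b2",
)


@dataclass
class ContactProfile:
    """Per-ensemble interaction frequencies (fractions of frames).

    Sidechain fields are None for free trinucleotides (not applicable).
    ``sc_b1_and_b2`` counts frames where the sidechain is simultaneously
    within the contact cutoff of base 1 and base 2.
    """

    freq_sc_b1: float | None
    freq_sc_b2: float | None
    freq_sc_b3: float | None
    freq_stack12: float
    freq_stack23: float
    freq_stack13: float
    freq_sc_b1_and_b2: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sc_b1": self.freq_sc_b1,
            "sc_b2": self.freq_sc_b2,
            "sc_b3": self.freq_sc_b3,
            "stack12": self.freq_stack12,
            "stack23": self.freq_stack23,
            "stack13": self.freq_stack13,
            "sc_b1_and_b2": self.freq_sc_b1_and_b2,
        }


def cog_distance_series(ensemble: Ensemble, group_a: str, group_b: str) -> np.ndarray:
    """Per-frame Euclidean distance between the COGs of two named groups."""
    idx_a = select(ensemble, group_a)
    idx_b = select(ensemble, group_b)
    if not idx_a or not idx_b:
        empty = group_a if not idx_a else group_b
        raise ValueError(f"group {empty!r} is empty; cannot compute a COG distance")
    cog_a = ensemble.coords[:, idx_a, :].mean(axis=1)
    cog_b = ensemble.coords[:, idx_b, :].mean(axis=1)
    return np.linalg.norm(cog_a - cog_b, axis=1)


def contact_frequency(distances: np.ndarray, cutoff: float) -> float:
    """Fraction of frames with distance strictly below the cutoff."""
    distances = np.asarray(distances, dtype=float)
    if distances.size < 1:
        raise ValueError("need at least one frame")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    return float((distances < cutoff).mean())


def contact_profile(
    ensemble: Ensemble,
    stack_cutoff: float = STACK_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> ContactProfile:
    """All seven interaction frequencies of one ensemble.

    For free trinucleotides (no sidechain) the stacking frequencies are
    computed and the sidechain fields are returned as None.
    """
    stack12 = contact_frequency(cog_distance_series(ensemble, "base1", "base2"), stack_cutoff)
    stack23 = contact_frequency(cog_distance_series(ensemble, "base2", "base3"), stack_cutoff)
    stack13 = contact_frequency(cog_distance_series(ensemble, "base1", "base3"), stack_cutoff)
    if not ensemble.topology.system.is_aminoacylated:
        return ContactProfile(None, None, None, stack12, stack23, stack13, None)
    d1 = cog_distance_series(ensemble, "sidechain", "base1")
    d2 = cog_distance_series(ensemble, "sidechain", "base2")
    d3 = cog_distance_series(ensemble, "sidechain", "base3")
    return ContactProfile(
        freq_sc_b1=contact_frequency(d1, contact_cutoff),
        freq_sc_b2=contact_frequency(d2, contact_cutoff),
        freq_sc_b3=contact_frequency(d3, contact_cutoff),
        freq_stack12=stack12,
        freq_stack23=stack23,
        freq_stack13=stack13,
        freq_sc_b1_and_b2=float(((d1 < contact_cutoff) & (d2 < contact_cutoff)).mean()),
    )
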