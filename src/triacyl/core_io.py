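"""Conformer-ensemble containers and multi-model PDB input/output.

An :class:`Ensemble` is an ordered set of conformers (frames x atoms x 3, in
angstroms) bound to a :class:`Topology` that carries per-atom metadata and the
named atom groups (``nuc_backbone``, ``aa_backbone``, ``base1/2/3``,
``sidechain``, ``carbonyl``) that drive every geometric stage downstream.

Units are angstroms throughout (PDB native); frame indices are 0-based in
memory and MODEL numbers 1-based on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "SystemDescriptor",
    "Topology",
    "Ensemble",
    "REQUIRED_GROUPS",
    "NUC_BACKBONE_ATOMS",
    "AA_BACKBONE_ATOMS",
    "CARBONYL_ATOMS",
    "default_groups",
    "read_multimodel_pdb",
    "write_ensemble",
    "select",
    "subsample",
]

#: Atom names forming the ribose-phosphate backbone of one nucleotide
#: (used "as present": a 5'-terminal residue may lack the phosphate atoms).
NUC_BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "O2'", "C1'", "O4'",
)
#: Amino-acid backbone atom names.
AA_BACKBONE_ATOMS = ("N", "CA", "C")
#: Default ester-carbonyl group: the carbonyl carbon and its oxygen.
CARBONYL_ATOMS = ("C", "O")

REQUIRED_GROUPS = (
    "nuc_backbone", "aa_backbone", "base1", "base2", "base3", "sidechain", "carbonyl",
)

#: Bondi van-der-Waals radii by element (angstrom); heavy-atom calibrated.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70

_RNA_RESIDUES = frozenset({"A", "C", "G", "U"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, 1-based residue index/name and vdW radius (A)."""

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass(frozen=True)
class SystemDescriptor:
    """Identity of one simulated system.

    Parameters
    ----------
    triplet : str
        Three-letter RNA sequence over {A, C, G, U}.
    amino_acid : str or None
        Three-letter amino-acid code of the esterified residue, or None for a
        free (non-aminoacylated) trinucleotide.
    attachment : {"2p", "3p", "free"}
        Ester attachment at the 2'- or 3'-hydroxyl of the terminal ribose,
        or "free" when no amino acid is attached.
    chirality : {"L", "D", "none"}
    """

    triplet: str
    amino_acid: str | None = None
    attachment: str = "free"
    chirality: str = "none"

    def __post_init__(self) -> None:
        if len(self.triplet) != 3 or any(b not in _RNA_RESIDUES for b in self.triplet):
            raise ValueError(f"triplet must be 3 letters over A/C/G/U, got {self.triplet!r}")
        if self.attachment not in ("2p", "3p", "free"):
            raise ValueError(f"attachment must be 2p, 3p or free, got {self.attachment!r}")
        free = self.attachment == "free"
        if free != (self.amino_acid is None) or free != (self.chirality == "none"):
            raise ValueError(
                "attachment='free' requires amino_acid=None and chirality='none' "
                "(and vice versa); got "
                f"attachment={self.attachment!r}, amino_acid={self.amino_acid!r}, "
                f"chirality={self.chirality!r}"
            )
        if not free and self.chirality not in ("L", "D"):
            raise ValueError(f"chirality must be L or D, got {self.chirality!r}")

    @property
    def is_aminoacylated(self) -> bool:
        return self.attachment != "free"

    def key(self) -> tuple:
        return (self.triplet, self.amino_acid, self.attachment, self.chirality)

    def label(self) -> str:
        if not self.is_aminoacylated:
            return self.triplet
        return f"{self.triplet}-{self.attachment}-{self.chirality}-{self.amino_acid}"


@dataclass
class Topology:
    """Atom metadata plus named atom groups for one molecular system."""

    atoms: list[AtomRecord]
    groups: dict[str, list[int]]
    system: SystemDescriptor

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for name, idx in self.groups.items():
            bad = [i for i in idx if not (0 <= i < n)]
            if bad:
                raise ValueError(f"group {name!r} has out-of-range atom indices {bad}")
        missing = [g for g in REQUIRED_GROUPS if g not in self.groups]
        if missing:
            raise ValueError(f"topology is missing required groups: {missing}")
        if "cluster_backbone" not in self.groups:
            # nucleotide + amino-acid backbone for aminoacylated systems,
            # nucleotide backbone only for free trinucleotides
            cb = list(self.groups["nuc_backbone"])
            if self.system.is_aminoacylated:
                cb = sorted(set(cb) | set(self.groups["aa_backbone"]))
            self.groups["cluster_backbone"] = cb

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """Conformer ensemble: coordinates (n_frames, n_atoms, 3) in angstrom.

    ``frame_stride`` is the time per stored frame in arbitrary units; it is
    metadata only and never enters any computation.
    """

    topology: Topology
    coords: np.ndarray
    frame_stride: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def default_groups(
    atoms: Sequence[AtomRecord], system: SystemDescriptor
) -> dict[str, list[int]]:
    """Build the default group map from atom naming conventions.

    Residues 1-3 are the nucleotides; any further residue is the amino acid.
    Per nucleotide, backbone atoms follow :data:`NUC_BACKBONE_ATOMS` (as
    present) and every other heavy atom belongs to the base.  For the amino
    acid, N/CA/C form the backbone, C and O the ester carbonyl, and the
    remaining heavy atoms the sidechain.  Hydrogens are excluded everywhere.
    """
    groups: dict[str, list[int]] = {g: [] for g in REQUIRED_GROUPS}
    nuc_bb = set(NUC_BACKBONE_ATOMS)
    for i, atom in enumerate(atoms):
        if atom.element == "H":
            continue
        if atom.residue_name in _RNA_RESIDUES and atom.residue_index <= 3:
            if atom.atom_name in nuc_bb:
                groups["nuc_backbone"].append(i)
            else:
                groups[f"base{atom.residue_index}"].append(i)
        else:  # amino-acid residue
            if atom.atom_name in AA_BACKBONE_ATOMS:
                groups["aa_backbone"].append(i)
            if atom.atom_name in CARBONYL_ATOMS:
                groups["carbonyl"].append(i)
            if atom.atom_name not in AA_BACKBONE_ATOMS + ("O",):
                groups["sidechain"].append(i)
    return groups


def _resolve_group_config(
    atoms: Sequence[AtomRecord], group_config: Mapping[str, Sequence]
) -> dict[str, list[int]]:
    """Resolve (residue_index, atom_name) pairs to atom indices."""
    lookup = {(a.residue_index, a.atom_name): i for i, a in enumerate(atoms)}
    groups: dict[str, list[int]] = {}
    for name, members in group_config.items():
        idx, unresolved = [], []
        for member in members:
            res_idx, atom_name = int(member[0]), str(member[1])
            key = (res_idx, atom_name)
            if key in lookup:
                idx.append(lookup[key])
            else:
                unresolved.append(key)
        if unresolved:
            raise ValueError(
                f"group {name!r} references atoms not present in the structure: {unresolved}"
            )
        groups[name] = idx
    return groups


def read_multimodel_pdb(
    path: str | Path,
    group_config: Mapping[str, Sequence] | None = None,
    system: SystemDescriptor | None = None,
    radius_overrides: Mapping[str, float] | None = None,
    frame_stride: float = 1.0,
) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One frame per MODEL record, in file order; a file without MODEL records
    yields a single frame.  ``group_config`` maps group names to lists of
    (residue_index, atom_name) pairs and overrides the name-based defaults.
    Atoms without a configured radius get the Bondi element default.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(
            f"{path}: inconsistent atom records across MODEL blocks ({exc})"
        ) from exc
    if isinstance(stack, struc.AtomArray):  # single unlabelled model
        stack = struc.stack([stack])

    overrides = dict(radius_overrides or {})
    atoms: list[AtomRecord] = []
    for k in range(stack.array_length()):
        name = str(stack.atom_name[k])
        element = str(stack.element[k]).strip().upper() or _element_of(name)
        radius = overrides.get(name, BONDI_RADII.get(element, _DEFAULT_RADIUS))
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_index=int(stack.res_id[k]),
                residue_name=str(stack.res_name[k]).strip(),
                vdw_radius=radius,
            )
        )

    if system is None:
        system = _infer_system(atoms)
    if group_config is not None:
        groups = dict(default_groups(atoms, system))
        groups.update(_resolve_group_config(atoms, group_config))
    else:
        groups = default_groups(atoms, system)
    topology = Topology(atoms=atoms, groups=groups, system=system)
    coords = np.asarray(stack.coord, dtype=float)
    return Ensemble(topology=topology, coords=coords, frame_stride=frame_stride)


def _infer_system(atoms: Sequence[AtomRecord]) -> SystemDescriptor:
    """Best-effort descriptor from residue naming (triplet + presence of aa)."""
    by_res: dict[int, str] = {}
    for a in atoms:
        by_res.setdefault(a.residue_index, a.residue_name)
    nuc = [by_res[i] for i in sorted(by_res) if by_res[i] in _RNA_RESIDUES]
    aa = [by_res[i] for i in sorted(by_res) if by_res[i] not in _RNA_RESIDUES]
    triplet = "".join(nuc[:3]) if len(nuc) >= 3 else "AAA"
    if aa:
        return SystemDescriptor(triplet, aa[0], "3p", "L")
    return SystemDescriptor(triplet)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a standards-conformant multi-model PDB file."""
    n_atoms = ensemble.n_atoms
    atoms = ensemble.topology.atoms
    array = struc.AtomArray(n_atoms)
    array.coord = ensemble.coords[0]
    array.chain_id = np.array(
        ["A" if a.residue_index <= 3 else "B" for a in atoms]
    )
    array.res_id = np.array([a.residue_index for a in atoms], dtype=int)
    array.res_name = np.array([a.residue_name for a in atoms])
    array.atom_name = np.array([a.atom_name for a in atoms])
    array.element = np.array([a.element for a in atoms])
    array.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = ensemble.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select(ensemble: Ensemble, group: str) -> list[int]:
    """Return the atom-index list of a named group, in stable configured order."""
    groups = ensemble.topology.groups
    if group not in groups:
        raise KeyError(
            f"unknown group {group!r}; available groups: {sorted(groups)}"
        )
    return list(groups[group])


def subsample(ensemble: Ensemble, stride: int) -> Ensemble:
    """Keep frames 0, stride, 2*stride, ...; scales frame_stride metadata."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return replace(
        ensemble,
        coords=ensemble.coords[::stride].copy(),
        frame_stride=ensemble.frame_stride * stride,
    )
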