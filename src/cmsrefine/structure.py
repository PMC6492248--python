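"""Structure I/O and rigid-body geometry for two-chain-group complexes.

A docked protein-protein complex is represented as a flat, ordered list of
atoms partitioned into a *receptor* chain group and a *ligand* chain group.
All downstream geometry (contact maps, CAPRI metrics, model averaging) is
expressed in terms of this partition.

PDB reading/writing is delegated to Biopython (``Bio.PDB``); only the first
model of a multi-model file is read, the first alternate location of a
disordered atom is kept, and HETATM records are excluded unless requested.
Residues are keyed by ``(chain_id, residue_index, insertion_code)`` using
author numbering throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "Ensemble",
    "ResidueKey",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "apply_transform",
    "rmsd",
]

#: (chain_id, author residue number, insertion code) -- the universal residue key.
ResidueKey = tuple[str, int, str]


@dataclass(eq=False)
class AtomRecord:
    """A single atom with author numbering and Cartesian coordinates in Å."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.insertion_code)


class ComplexStructure:
    """Atoms of a receptor/ligand complex with a chain-group partition.

    Parameters
    ----------
    atoms
        Ordered atom records (file order). Atom serial numbers are implicit:
        atom ``i`` has serial ``i + 1``.
    receptor_chains, ligand_chains
        Disjoint, non-empty chain-id sets; every atom must belong to exactly
        one of the two groups and each group must contribute at least one
        Cα atom.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        receptor_chains: Iterable[str],
        ligand_chains: Iterable[str],
        label: str = "",
    ) -> None:
        self.atoms = list(atoms)
        self.receptor_chains = frozenset(receptor_chains)
        self.ligand_chains = frozenset(ligand_chains)
        self.label = label
        self._validate()
        self._coords: np.ndarray | None = None

    def _validate(self) -> None:
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("receptor_chains and ligand_chains must both be non-empty")
        overlap = self.receptor_chains & self.ligand_chains
        if overlap:
            raise ValueError(f"chains assigned to both groups: {sorted(overlap)}")
        if not self.atoms:
            raise ValueError("structure has no atoms")
        known = self.receptor_chains | self.ligand_chains
        stray = {a.chain_id for a in self.atoms} - known
        if stray:
            raise ValueError(f"atoms in chains outside both groups: {sorted(stray)}")
        for group in ("receptor", "ligand"):
            if not any(a.atom_name == "CA" and a.chain_id in self.group_chains(group) for a in self.atoms):
                raise ValueError(f"no Cα atoms in {group} group")

    # -- selection helpers -------------------------------------------------

    def group_chains(self, group: str) -> frozenset[str]:
        if group == "receptor":
            return self.receptor_chains
        if group == "ligand":
            return self.ligand_chains
        raise ValueError(f"unknown group {group!r}")

    def group_of(self, chain_id: str) -> str:
        if chain_id in self.receptor_chains:
            return "receptor"
        if chain_id in self.ligand_chains:
            return "ligand"
        raise KeyError(chain_id)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a fresh copy each call is avoided)."""
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def atom_indices(self, group: str | None = None, heavy_only: bool = False) -> np.ndarray:
        chains = None if group is None else self.group_chains(group)
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (chains is None or a.chain_id in chains)
            and not (heavy_only and a.element.upper() == "H")
        ]
        return np.asarray(idx, dtype=int)

    def ca_table(self, group: str) -> tuple[list[ResidueKey], np.ndarray]:
        """Ordered residue keys and coordinates of the group's Cα atoms."""
        keys, xyz = [], []
        chains = self.group_chains(group)
        for a in self.atoms:
            if a.atom_name == "CA" and a.chain_id in chains:
                keys.append(a.residue_key)
                xyz.append(a.position)
        return keys, np.asarray(xyz, dtype=float)

    def residue_keys(self) -> set[ResidueKey]:
        return {a.residue_key for a in self.atoms}

    # -- geometry ----------------------------------------------------------

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "ComplexStructure":
        """Copy of the structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return ComplexStructure(atoms, self.receptor_chains, self.ligand_chains,
                                self.label if label is None else label)

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None,
                    group: str | None = None) -> "ComplexStructure":
        """Apply a rigid transform to the whole complex or to one chain group."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        coords = self.coords.copy()
        idx = slice(None) if group is None else self.atom_indices(group)
        coords[idx] = coords[idx] @ R.T + t
        return self.with_coords(coords)


@dataclass
class Ensemble:
    """Docked solutions of one target sharing identical Cα residue topology."""

    members: list[ComplexStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")
        ref_keys = self._ca_keyset(self.members[0])
        for i, m in enumerate(self.members[1:], start=1):
            if self._ca_keyset(m) != ref_keys:
                raise ValueError(f"ensemble member {i} has a different Cα residue topology")

    @staticmethod
    def _ca_keyset(s: ComplexStructure) -> frozenset:
        rk, _ = s.ca_table("receptor")
        lk, _ = s.ca_table("ligand")
        return frozenset(("R",) + k for k in rk) | frozenset(("L",) + k for k in lk)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _parse_chain_set(spec: str | Iterable[str]) -> frozenset[str]:
    if isinstance(spec, str):
        return frozenset(c.strip() for c in spec.split(",") if c.strip())
    return frozenset(spec)


def read_pdb(
    path: str | Path,
    receptor_chains: str | Iterable[str],
    ligand_chains: str | Iterable[str],
    include_hetatm: bool = False,
    label: str | None = None,
) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Only the first MODEL is read; for disordered atoms the first alternate
    location encountered is kept. Chains outside the two groups are dropped.

    Raises
    ------
    ValueError
        If a requested chain is absent (the message lists the chains that
        *are* present) or a group ends up without Cα atoms.
    """
    receptor = _parse_chain_set(receptor_chains)
    ligand = _parse_chain_set(ligand_chains)
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure("s", str(path))
    model = next(bio.get_models())  # first model only

    available = [c.id for c in model]
    missing = (receptor | ligand) - set(available)
    if missing:
        raise ValueError(
            f"chain(s) {sorted(missing)} not found in {path}; available chains: {sorted(available)}"
        )

    atoms: list[AtomRecord] = []
    for chain in model:
        if chain.id not in receptor | ligand:
            continue
        for residue in chain:
            hetfield, resseq, icode = residue.id
            if hetfield.strip() and not include_hetatm:
                continue
            seen: set[str] = set()
            for atom in residue.get_unpacked_list():
                if atom.get_name() in seen:
                    continue  # first altloc only
                seen.add(atom.get_name())
                element = (atom.element or atom.get_name()[0]).strip()
                atoms.append(
                    AtomRecord(
                        chain_id=chain.id,
                        residue_index=int(resseq),
                        residue_name=residue.get_resname(),
                        atom_name=atom.get_name(),
                        element=element,
                        position=np.asarray(atom.get_coord(), dtype=float),
                        insertion_code=icode.strip(),
                    )
                )
    return ComplexStructure(atoms, receptor, ligand, label=label or Path(path).stem)


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write standard ATOM records; round-trips coordinates at PDB precision."""
    builder = StructureBuilder()
    builder.init_structure(structure.label or "complex")
    builder.init_model(0)
    builder.init_seg("    ")
    current_chain = None
    current_res: tuple | None = None
    serial = 1
    for a in structure.atoms:
        if a.chain_id != current_chain:
            builder.init_chain(a.chain_id)
            current_chain = a.chain_id
            current_res = None
        res_id = (a.residue_index, a.insertion_code or " ")
        if res_id != current_res:
            builder.init_residue(a.residue_name, " ", a.residue_index, a.insertion_code or " ")
            current_res = res_id
        name = a.atom_name
        fullname = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
        builder.init_atom(name, a.position.astype(np.float32), 0.0, 1.0, " ",
                          fullname, serial, element=a.element.upper())
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired point sets, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def apply_transform(points: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` row-wise."""
    return np.asarray(points, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` in the
    least-squares sense, with a proper rotation (det = +1).

    Raises
    ------
    ValueError
        For fewer than 3 points or a rank-deficient (collinear/coincident)
        configuration, where the rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point sets must have equal shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    A = mobile - cm
    B = target - ct
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], float(np.abs(A).max()), float(np.abs(B).max()), 1e-12)
    if S[1] <= 1e-9 * scale:
        raise ValueError("degenerate (collinear or coincident) point configuration; rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    fitted = apply_transform(mobile, R, t)
    return R, t, rmsd(fitted, target)
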