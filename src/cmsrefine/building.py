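"""AZRANK-style model building: select, superpose, average, relax.

The final refined model is built from the ``n`` best-scored trajectory
snapshots (default 14, pooled over replicas, frames spaced 50 ps apart):
each selected snapshot is rigidly superposed onto the best-scored one via
receptor Cα atoms, the equivalent atomic coordinates are arithmetically
averaged, and the average is relaxed by steepest descent to resolve
non-physical artefacts of averaging (e.g. atom overlaps).

The relaxation potential is a deliberately lightweight surrogate whose only
contract is clash resolution with minimal displacement:

* a harmonic tether of every atom to its averaged position,
* a soft-sphere repulsion between non-bonded heavy-atom pairs closer than
  2.8 Å, and
* flat-bottom restraints on "bonded" distances (consecutive Cα along a
  chain, and each atom to its residue's Cα) taken from the best-scored
  snapshot.

Steepest descent with a backtracking step size never accepts an energy
increase, and the returned structure never has more heavy-atom clashes
(non-bonded pairs < 2.0 Å) than the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .scoring import ScoreTable
from .structure import ComplexStructure, apply_transform, kabsch_superpose, rmsd

__all__ = [
    "BuildConfig",
    "select_snapshots",
    "average_structure",
    "relax",
    "clash_count",
    "build_model",
]

CLASH_CUTOFF = 2.0       # Å, non-bonded heavy-atom pair below this = clash
REPULSION_RADIUS = 2.8   # Å, soft-sphere onset
TETHER_K = 2.0           # kJ/mol/Å^2
REPULSION_K = 100.0      # kJ/mol/Å^2
BOND_K = 20.0            # kJ/mol/Å^2
BOND_FLAT = 0.2          # Å, flat-bottom half width


@dataclass
class BuildConfig:
    n_snapshots: int = 14
    snapshot_spacing: float = 50.0  # ps
    relax_steps: int = 500
    relax_step_size: float = 0.05   # Å, initial max per-atom displacement
    selection: str = "external"     # "external" (ZRANK-style) or "cs"
    force_tolerance: float = 1.0    # kJ/mol/Å, max-force convergence threshold

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.snapshot_spacing <= 0:
            raise ValueError("snapshot_spacing must be positive")
        if self.selection not in ("external", "cs"):
            raise ValueError(f"unknown selection score {self.selection!r}")


def select_snapshots(table: ScoreTable, config: BuildConfig) -> list[int]:
    """Indices of the top-n records by the selection score, best first.

    Default selection is the external (ZRANK-style) score — the recommended
    generic choice; ``selection="cs"`` ranks by CS_alpha instead. Snapshots
    are pooled across replicas; ties break by (time, replica).
    """
    if len(table) < config.n_snapshots:
        raise ValueError(
            f"need {config.n_snapshots} snapshots, table has {len(table)}")
    by = "zrank" if config.selection == "external" else "cs"
    return table.ranked_indices(by=by)[: config.n_snapshots]


def _check_topology(snapshots: Sequence[ComplexStructure]) -> None:
    ref = snapshots[0]
    sig = [(a.chain_id, a.residue_index, a.insertion_code, a.atom_name) for a in ref.atoms]
    for k, s in enumerate(snapshots[1:], start=1):
        other = [(a.chain_id, a.residue_index, a.insertion_code, a.atom_name) for a in s.atoms]
        if other != sig:
            for i, (x, y) in enumerate(zip(sig, other)):
                if x != y:
                    raise ValueError(
                        f"snapshot {k} topology mismatch at atom {i}: {y} != {x}")
            raise ValueError(f"snapshot {k} has {len(other)} atoms, expected {len(sig)}")


def average_structure(snapshots: Sequence[ComplexStructure],
                      reference_index: int = 0) -> ComplexStructure:
    """Per-atom mean of snapshots after receptor-Cα superposition.

    Every snapshot is superposed onto ``snapshots[reference_index]`` using
    receptor Cα atoms (the receptor frame is the assessment reference frame),
    then all atoms present are averaged arithmetically. The result is
    independent of the order of the non-reference members.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    _check_topology(snapshots)
    ref = snapshots[reference_index]
    _, ref_rec = ref.ca_table("receptor")
    total = np.zeros((len(ref.atoms), 3))
    for s in snapshots:
        _, rec = s.ca_table("receptor")
        if s is ref or np.allclose(rec, ref_rec):
            coords = s.coords
        else:
            R, t, _ = kabsch_superpose(rec, ref_rec)
            coords = apply_transform(s.coords, R, t)
        total += coords
    return ref.with_coords(total / len(snapshots), label=f"avg_of_{len(snapshots)}")


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def _bonded_pairs(structure: ComplexStructure) -> np.ndarray:
    """(i, j) index pairs treated as bonded: chain-consecutive Cα and atom-Cα."""
    pairs: list[tuple[int, int]] = []
    ca_of_res: dict[tuple, int] = {}
    for i, a in enumerate(structure.atoms):
        if a.atom_name == "CA":
            ca_of_res[a.residue_key] = i
    prev_ca: dict[str, tuple[int, int]] = {}  # chain -> (residue_index, atom idx)
    for key, idx in ca_of_res.items():
        chain, resi, _ = key
        if chain in prev_ca and resi == prev_ca[chain][0] + 1:
            pairs.append((prev_ca[chain][1], idx))
        prev_ca[chain] = (resi, idx)
    for i, a in enumerate(structure.atoms):
        if a.atom_name != "CA" and a.residue_key in ca_of_res:
            pairs.append((ca_of_res[a.residue_key], i))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def _excluded_mask(structure: ComplexStructure, heavy: np.ndarray) -> np.ndarray:
    """Pairs within the same or adjacent residue of one chain are non-clashing."""
    keys = [structure.atoms[i].residue_key for i in heavy]
    chains = np.array([k[0] for k in keys])
    resis = np.array([k[1] for k in keys])
    same_chain = chains[:, None] == chains[None, :]
    near = np.abs(resis[:, None] - resis[None, :]) <= 1
    return same_chain & near


def clash_count(structure: ComplexStructure, cutoff: float = CLASH_CUTOFF) -> int:
    """Number of non-bonded heavy-atom pairs closer than ``cutoff``."""
    heavy = structure.atom_indices(heavy_only=True)
    xyz = structure.coords[heavy]
    dmat = cdist(xyz, xyz)
    excl = _excluded_mask(structure, heavy)
    iu = np.triu_indices(len(heavy), k=1)
    close = (dmat[iu] < cutoff) & ~excl[iu]
    return int(close.sum())


def _relax_energy_gradient(x: np.ndarray, x0: np.ndarray, heavy: np.ndarray,
                           excl: np.ndarray, bonds: np.ndarray,
                           bond_ref: np.ndarray) -> tuple[float, np.ndarray]:
    grad = np.zeros_like(x)

    diff = x - x0
    energy = TETHER_K * float((diff**2).sum())
    grad += 2.0 * TETHER_K * diff

    hx = x[heavy]
    dmat = cdist(hx, hx)
    np.fill_diagonal(dmat, np.inf)
    viol = (dmat < REPULSION_RADIUS) & ~excl
    ii, jj = np.nonzero(np.triu(viol, k=1))
    if ii.size:
        d = dmat[ii, jj]
        pen = REPULSION_RADIUS - d
        energy += REPULSION_K * float((pen**2).sum())
        unit = (hx[ii] - hx[jj]) / np.maximum(d, 1e-6)[:, None]
        g = (-2.0 * REPULSION_K * pen)[:, None] * unit
        np.add.at(grad, heavy[ii], g)
        np.add.at(grad, heavy[jj], -g)

    if bonds.size:
        bi, bj = bonds[:, 0], bonds[:, 1]
        vec = x[bi] - x[bj]
        d = np.linalg.norm(vec, axis=1)
        excess = np.abs(d - bond_ref) - BOND_FLAT
        active = excess > 0
        if active.any():
            sgn = np.sign(d - bond_ref)[active]
            e = excess[active]
            energy += BOND_K * float((e**2).sum())
            unit = vec[active] / np.maximum(d[active], 1e-6)[:, None]
            g = (2.0 * BOND_K * e * sgn)[:, None] * unit
            np.add.at(grad, bi[active], g)
            np.add.at(grad, bj[active], -g)

    return energy, grad


def relax(structure: ComplexStructure, config: BuildConfig | None = None,
          bond_reference: ComplexStructure | None = None) -> tuple[ComplexStructure, dict]:
    """Steepest-descent relaxation of an averaged model.

    ``bond_reference`` supplies the bonded reference distances (defaults to
    the input itself; the builder passes the best-scored snapshot). Returns
    the relaxed structure and an info dict with the energy trace and pre/post
    clash counts. The clash count never increases; if the minimizer cannot
    improve it the input is returned unchanged.
    """
    config = config or BuildConfig()
    ref = bond_reference or structure
    bonds = _bonded_pairs(structure)
    ref_coords = ref.coords
    bond_ref = (np.linalg.norm(ref_coords[bonds[:, 0]] - ref_coords[bonds[:, 1]], axis=1)
                if bonds.size else np.empty(0))
    heavy = structure.atom_indices(heavy_only=True)
    excl = _excluded_mask(structure, heavy)

    x0 = structure.coords.copy()
    x = x0.copy()
    energy, grad = _relax_energy_gradient(x, x0, heavy, excl, bonds, bond_ref)
    best_x, best_e = x.copy(), energy
    step = config.relax_step_size
    energies = [energy]
    n_accepted = 0
    for _ in range(config.relax_steps):
        max_force = float(np.abs(grad).max())
        if max_force < config.force_tolerance:
            break
        direction = -grad / max_force  # max per-atom component displacement = step
        accepted = False
        for _ in range(12):
            trial = x + step * direction
            e_trial, g_trial = _relax_energy_gradient(trial, x0, heavy, excl, bonds, bond_ref)
            if e_trial < energy:
                x, energy, grad = trial, e_trial, g_trial
                step = min(step * 1.2, 1.0)
                accepted = True
                n_accepted += 1
                break
            step *= 0.5
        if not accepted:
            break
        energies.append(energy)
        if energy < best_e:
            best_e, best_x = energy, x.copy()

    relaxed = structure.with_coords(best_x, label=structure.label)
    pre = clash_count(structure)
    post = clash_count(relaxed)
    if post > pre:  # contract: never make clashes worse
        warnings.warn("relaxation did not reduce clashes; returning input structure")
        relaxed, post = structure, pre
    info = {
        "steps_accepted": n_accepted,
        "initial_energy": energies[0],
        "final_energy": best_e,
        "energy_trace": energies,
        "clashes_before": pre,
        "clashes_after": post,
        "displacement_rmsd": rmsd(best_x, x0),
    }
    return relaxed, info


def build_model(table: ScoreTable, config: BuildConfig | None = None) -> tuple[ComplexStructure, dict]:
    """Full build: select top-n snapshots, superpose, average, relax.

    Every record selected must carry its snapshot structure. The report lists
    the chosen snapshot ids and scores plus pre/post clash counts.
    """
    config = config or BuildConfig()
    chosen = select_snapshots(table, config)
    snapshots = []
    for i in chosen:
        rec = table.records[i]
        if rec.structure is None:
            raise ValueError(f"record {rec.snapshot_id} has no structure attached")
        snapshots.append(rec.structure)
    averaged = average_structure(snapshots, reference_index=0)
    model, relax_info = relax(averaged, config, bond_reference=snapshots[0])
    report = {
        "n_snapshots": len(chosen),
        "snapshot_ids": [table.records[i].snapshot_id for i in chosen],
        "selection_scores": [float(table.records[i].external_score) if config.selection == "external"
                             else float(table.cs[i]) for i in chosen],
        "clashes_before": relax_info["clashes_before"],
        "clashes_after": relax_info["clashes_after"],
        "displacement_rmsd": relax_info["displacement_rmsd"],
    }
    return model, report
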