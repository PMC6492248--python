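"""CAPRI-style model quality assessment: FNAT, LRMSD, IRMSD, and classes.

* FNAT — fraction of the reference structure's interface residue contacts
  (receptor residue x ligand residue, any heavy-atom pair < 5 Å) that are
  reproduced by the model. Only reference-defined contacts count, so FNAT
  is in [0, 1] regardless of spurious model contacts.
* LRMSD — Cα RMSD over the ligand after optimally superposing the model's
  receptor Cα atoms onto the reference receptor.
* IRMSD — Cα RMSD over the interface residues, where the interface is
  defined on the *reference* (residues with any cross-interface heavy-atom
  pair < 10 Å) and the interface Cα sets are themselves optimally superposed
  before measuring.

Model and reference residues are matched by (chain, residue number,
insertion code) identity; hydrogens are excluded from all contact criteria
so models with and without protons assess identically.

Quality classes use the standard CAPRI assessment thresholds (the community
criteria; evaluated from high downward):

    high        fnat >= 0.5 and (lrmsd <= 1.0 or irmsd <= 1.0)
    medium      fnat >= 0.3 and (lrmsd <= 5.0 or irmsd <= 2.0)
    acceptable  fnat >= 0.1 and (lrmsd <= 10.0 or irmsd <= 4.0)
    incorrect   otherwise
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .structure import ComplexStructure, ResidueKey, apply_transform, kabsch_superpose, rmsd

__all__ = [
    "QualityReport",
    "fnat",
    "lrmsd",
    "irmsd",
    "classify",
    "assess",
    "delta_report",
    "residue_contacts",
    "interface_residues",
]

FNAT_CONTACT_CUTOFF = 5.0    # Å, any heavy atom, strict "<"
INTERFACE_CUTOFF = 10.0      # Å, any heavy atom, strict "<" (IRMSD interface)

CAPRI_CLASSES = ("incorrect", "acceptable", "medium", "high")


@dataclass
class QualityReport:
    fnat: float
    lrmsd: float
    irmsd: float
    capri_class: str
    deltas: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat must lie in [0, 1]")
        if self.lrmsd < 0 or self.irmsd < 0:
            raise ValueError("RMSD values must be non-negative")
        if self.capri_class not in CAPRI_CLASSES:
            raise ValueError(f"unknown CAPRI class {self.capri_class!r}")


def _group_heavy(structure: ComplexStructure, group: str) -> tuple[np.ndarray, list[ResidueKey]]:
    idx = structure.atom_indices(group, heavy_only=True)
    keys = [structure.atoms[i].residue_key for i in idx]
    return structure.coords[idx], keys


def residue_contacts(structure: ComplexStructure, cutoff: float) -> set[tuple[ResidueKey, ResidueKey]]:
    """Receptor x ligand residue pairs with any heavy-atom distance < cutoff."""
    rxyz, rkeys = _group_heavy(structure, "receptor")
    lxyz, lkeys = _group_heavy(structure, "ligand")
    dmat = cdist(rxyz, lxyz)
    pairs = set()
    for i, j in zip(*np.nonzero(dmat < cutoff)):
        pairs.add((rkeys[i], lkeys[j]))
    return pairs


def interface_residues(structure: ComplexStructure, cutoff: float = INTERFACE_CUTOFF) -> set[ResidueKey]:
    """Residues (both sides) participating in any cross-interface contact."""
    residues: set[ResidueKey] = set()
    for rkey, lkey in residue_contacts(structure, cutoff):
        residues.add(rkey)
        residues.add(lkey)
    return residues


def _check_mappable(model: ComplexStructure, needed: Iterable[ResidueKey], what: str) -> None:
    have = model.residue_keys()
    missing = sorted(k for k in needed if k not in have)
    if missing:
        raise KeyError(f"{what}: reference residues unmappable in model: {missing}")


def fnat(model: ComplexStructure, reference: ComplexStructure) -> float:
    """Fraction of reference interface contacts reproduced by the model."""
    native = residue_contacts(reference, FNAT_CONTACT_CUTOFF)
    if not native:
        raise ValueError("reference structure has no interface contacts (< 5 Å)")
    needed = {k for pair in native for k in pair}
    _check_mappable(model, needed, "fnat")
    modeled = residue_contacts(model, FNAT_CONTACT_CUTOFF)
    return len(native & modeled) / len(native)


def _matched_ca(model: ComplexStructure, reference: ComplexStructure, group: str,
                restrict: set[ResidueKey] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinate pair (model, reference) over the reference's residues."""
    ref_keys, ref_xyz = reference.ca_table(group)
    mod_keys, mod_xyz = model.ca_table(group)
    mod_pos = {k: mod_xyz[i] for i, k in enumerate(mod_keys)}
    keep = [i for i, k in enumerate(ref_keys)
            if restrict is None or k in restrict]
    missing = [ref_keys[i] for i in keep if ref_keys[i] not in mod_pos]
    if missing:
        raise KeyError(f"model lacks Cα for reference residues: {missing}")
    m = np.array([mod_pos[ref_keys[i]] for i in keep])
    r = ref_xyz[keep]
    return m, r


def lrmsd(model: ComplexStructure, reference: ComplexStructure) -> float:
    """Ligand Cα RMSD after receptor-Cα superposition onto the reference."""
    mod_rec, ref_rec = _matched_ca(model, reference, "receptor")
    mod_lig, ref_lig = _matched_ca(model, reference, "ligand")
    R, t, _ = kabsch_superpose(mod_rec, ref_rec)
    return rmsd(apply_transform(mod_lig, R, t), ref_lig)


def irmsd(model: ComplexStructure, reference: ComplexStructure) -> float:
    """Cα RMSD over reference-defined interface residues after fitting them."""
    iface = interface_residues(reference, INTERFACE_CUTOFF)
    if not iface:
        raise ValueError("reference structure has an empty interface (< 10 Å)")
    mod_r, ref_r = _matched_ca(model, reference, "receptor", restrict=iface)
    mod_l, ref_l = _matched_ca(model, reference, "ligand", restrict=iface)
    mod = np.vstack([mod_r, mod_l])
    ref = np.vstack([ref_r, ref_l])
    _, _, fitted_rmsd = kabsch_superpose(mod, ref)
    return fitted_rmsd


def classify(fnat_value: float, lrmsd_value: float, irmsd_value: float) -> str:
    """CAPRI class from the three metrics; evaluated from high downward."""
    if fnat_value >= 0.5 and (lrmsd_value <= 1.0 or irmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (lrmsd_value <= 5.0 or irmsd_value <= 2.0):
        return "medium"
    if fnat_value >= 0.1 and (lrmsd_value <= 10.0 or irmsd_value <= 4.0):
        return "acceptable"
    return "incorrect"


def assess(model: ComplexStructure, reference: ComplexStructure,
           start: "QualityReport | None" = None) -> QualityReport:
    """Full quality report of ``model`` against ``reference``.

    If ``start`` (the starting model's report against the same reference) is
    given, the report carries delta metrics (negative ΔRMSD = improvement).
    """
    f = fnat(model, reference)
    l = lrmsd(model, reference)
    i = irmsd(model, reference)
    report = QualityReport(fnat=f, lrmsd=l, irmsd=i, capri_class=classify(f, l, i))
    if start is not None:
        report.deltas = delta_report(report, start)
    return report


def delta_report(refined: QualityReport, start: QualityReport) -> dict[str, float]:
    """Changes relative to the starting model (ΔFNAT > 0 and ΔRMSD < 0 improve)."""
    d = {
        "delta_fnat": refined.fnat - start.fnat,
        "delta_lrmsd": refined.lrmsd - start.lrmsd,
        "delta_irmsd": refined.irmsd - start.irmsd,
    }
    d["improved_fnat"] = d["delta_fnat"] > 0
    d["improved_lrmsd"] = d["delta_lrmsd"] < 0
    d["improved_irmsd"] = d["delta_irmsd"] < 0
    return d
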