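"""Interface contact map and the contact-map-space (CMS) collective variable.

The interface contact map ``CM_if`` is the set of receptor-ligand residue
pairs whose Cα-Cα distance falls strictly below a cutoff (8 Å by default) in
at least one member of a docked ensemble. Each contact carries a reference
distance ``r0`` pooled over the supporting members, and a support count.

The degree of formation of a contact at distance ``r`` is measured by the
rational switching function

    D(r) = (1 - x^n) / (1 - x^m),   x = r / r0,   n = 6, m = 10,

which is 1 at r = 0, strictly decreasing, and takes the removable-singularity
value n/m = 0.6 at r = r0. The scalar CMS collective variable of a structure
is the summed squared deviation of each contact's D value from the reference
value 0.6:

    CMS(R) = sum_gamma ( D_gamma(R) - 0.6 )^2

so a structure reproducing every reference contact distance exactly has
CMS = 0, and CMS grows as the interface deforms in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import ComplexStructure, Ensemble, ResidueKey

__all__ = [
    "Contact",
    "InterfaceContactMap",
    "detect_interface_contacts",
    "build_cmif",
    "switching_D",
    "cms_value",
    "export_plumed",
    "write_contact_map",
    "read_contact_map",
]

DEFAULT_CUTOFF = 8.0  # Å, Cα-Cα, strict "<"
N_EXPONENT = 6
M_EXPONENT = 10

#: |x - 1| below which the analytic limit n/m replaces the rational form,
#: avoiding catastrophic cancellation in (1 - x^n)/(1 - x^m).
SINGULARITY_GUARD = 1e-6


@dataclass(frozen=True)
class Contact:
    """A receptor-ligand residue pair with its reference distance."""

    receptor_residue: ResidueKey
    ligand_residue: ResidueKey
    r0: float
    support: int = 1

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("reference distance r0 must be positive")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class InterfaceContactMap:
    """``CM_if``: unique interface contacts plus the switching parameters."""

    contacts: list[Contact]
    cutoff: float = DEFAULT_CUTOFF
    n_exponent: int = N_EXPONENT
    m_exponent: int = M_EXPONENT

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (self.m_exponent > self.n_exponent > 0):
            raise ValueError("exponents must satisfy m > n > 0")
        keys = [(c.receptor_residue, c.ligand_residue) for c in self.contacts]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue-pair contacts")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def d_reference(self) -> float:
        """The reference switching value n/m (0.6 for the defaults)."""
        return self.n_exponent / self.m_exponent


def detect_interface_contacts(
    structure: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> dict[tuple[ResidueKey, ResidueKey], float]:
    """All receptor-Cα x ligand-Cα pairs strictly closer than ``cutoff``.

    Returns a mapping ``(receptor_key, ligand_key) -> distance``; may be empty.
    """
    rkeys, rxyz = structure.ca_table("receptor")
    lkeys, lxyz = structure.ca_table("ligand")
    dmat = cdist(rxyz, lxyz)
    out: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for i, j in zip(*np.nonzero(dmat < cutoff)):
        out[(rkeys[i], lkeys[j])] = float(dmat[i, j])
    return out


def build_cmif(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_CUTOFF,
    min_support: int = 1,
    pooling: str = "mean",
    n_exponent: int = N_EXPONENT,
    m_exponent: int = M_EXPONENT,
) -> InterfaceContactMap:
    """Build ``CM_if`` from a docked ensemble.

    The contact set is the union over members; ``r0`` pools the Cα distances
    of the members in which the pair is below the cutoff (``pooling``:
    ``"mean"`` (default), ``"median"``, or ``"centroid"`` = distance in the
    member closest to the ensemble-average Cα coordinates). Contacts seen in
    fewer than ``min_support`` members are dropped.
    """
    if pooling not in ("mean", "median", "centroid"):
        raise ValueError(f"unknown pooling {pooling!r}")

    per_pair: dict[tuple[ResidueKey, ResidueKey], list[float]] = {}
    per_member: list[dict[tuple[ResidueKey, ResidueKey], float]] = []
    for member in ensemble:
        found = detect_interface_contacts(member, cutoff)
        per_member.append(found)
        for pair, dist in found.items():
            per_pair.setdefault(pair, []).append(dist)

    if not per_pair:
        raise ValueError("no interface detected: no Cα pair below the cutoff in any member")

    centroid_idx = 0
    if pooling == "centroid" and len(ensemble.members) > 1:
        stacks = []
        for m in ensemble:
            _, rxyz = m.ca_table("receptor")
            _, lxyz = m.ca_table("ligand")
            stacks.append(np.vstack([rxyz, lxyz]))
        mean_xyz = np.mean(stacks, axis=0)
        centroid_idx = int(np.argmin([np.sum((s - mean_xyz) ** 2) for s in stacks]))

    contacts = []
    for pair, dists in sorted(per_pair.items()):
        if len(dists) < min_support:
            continue
        if pooling == "mean":
            r0 = float(np.mean(dists))
        elif pooling == "median":
            r0 = float(np.median(dists))
        else:
            r0 = per_member[centroid_idx].get(pair, float(np.mean(dists)))
        contacts.append(Contact(pair[0], pair[1], r0=r0, support=len(dists)))

    if not contacts:
        raise ValueError(f"no interface contact has support >= {min_support}")
    return InterfaceContactMap(contacts, cutoff=cutoff, n_exponent=n_exponent, m_exponent=m_exponent)


def switching_D(r, r0: float, n: int = N_EXPONENT, m: int = M_EXPONENT):
    """Rational switching function ``(1 - x^n)/(1 - x^m)`` with ``x = r/r0``.

    Accepts scalars or arrays. Within ``|x - 1| < 1e-6`` the analytic limit
    ``n/m`` is returned (removable singularity; 0.6 for the defaults).
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    scalar = np.isscalar(r)
    x = np.atleast_1d(np.asarray(r, dtype=float)) / r0
    if np.any(x < 0):
        raise ValueError("r must be non-negative")
    out = np.empty_like(x)
    near = np.abs(x - 1.0) < SINGULARITY_GUARD
    out[near] = n / m
    xs = x[~near]
    out[~near] = (1.0 - xs**n) / (1.0 - xs**m)
    return float(out[0]) if scalar else out


def _resolve_contact_distances(structure: ComplexStructure, cmap: InterfaceContactMap) -> np.ndarray:
    rkeys, rxyz = structure.ca_table("receptor")
    lkeys, lxyz = structure.ca_table("ligand")
    rpos = {k: rxyz[i] for i, k in enumerate(rkeys)}
    lpos = {k: lxyz[i] for i, k in enumerate(lkeys)}
    missing = [c for c in cmap.contacts
               if c.receptor_residue not in rpos or c.ligand_residue not in lpos]
    if missing:
        keys = [(c.receptor_residue, c.ligand_residue) for c in missing]
        raise KeyError(f"contact residues unresolvable in structure: {keys}")
    return np.array([
        np.linalg.norm(rpos[c.receptor_residue] - lpos[c.ligand_residue])
        for c in cmap.contacts
    ])


def cms_value(structure: ComplexStructure, cmap: InterfaceContactMap,
              d_reference: float | None = None) -> float:
    """Evaluate the scalar CMS collective variable of ``structure``.

    ``d_reference`` defaults to the constant n/m (0.6): with ``r = r0`` the
    switching function is pinned to 0.6, which makes the per-contact reference
    term constant across the map.
    """
    dists = _resolve_contact_distances(structure, cmap)
    d_ref = cmap.d_reference if d_reference is None else d_reference
    total = 0.0
    for c, r in zip(cmap.contacts, dists):
        d = switching_D(float(r), c.r0, cmap.n_exponent, cmap.m_exponent)
        total += (d - d_ref) ** 2
    return total


# ---------------------------------------------------------------------------
# Export / serialization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:g}"


def export_plumed(
    cmap: InterfaceContactMap,
    structure: ComplexStructure,
    sigma: float = 0.5,
    pace_ps: float = 2.0,
    initial_height: float = 5.0,
    bias_factor: float = 10.0,
    temperature: float = 300.0,
    md_timestep_ps: float = 0.002,
    label: str = "cms",
) -> str:
    """Emit a PLUMED2 input: CONTACTMAP CV (CMDIST mode) plus a METAD block.

    Each contact becomes an ``ATOMSk`` Cα serial pair with a RATIONAL switch
    (R_0 = r0 in nm, NN/MM exponents) and ``REFERENCEk`` = n/m, so the CV is
    exactly the summed squared deviation of Eq.-style contact formation. PACE
    is ``pace_ps`` converted to MD steps.
    """
    # Map residue key -> serial of its Cα (serial = 1-based atom order).
    serial_of: dict[ResidueKey, int] = {}
    for i, a in enumerate(structure.atoms):
        if a.atom_name == "CA":
            if a.residue_key in serial_of:
                raise ValueError(f"atom serial collision for residue {a.residue_key}")
            serial_of[a.residue_key] = i + 1

    lines = [f"{label}: CONTACTMAP ..."]
    for k, c in enumerate(cmap.contacts, start=1):
        try:
            sr = serial_of[c.receptor_residue]
            sl = serial_of[c.ligand_residue]
        except KeyError as exc:
            raise KeyError(f"contact residue {exc} has no Cα in structure") from exc
        r0_nm = c.r0 / 10.0  # PLUMED length unit is nm
        lines.append(
            f"  ATOMS{k}={sr},{sl} "
            f"SWITCH{k}={{RATIONAL R_0={_fmt(r0_nm)} NN={cmap.n_exponent} MM={cmap.m_exponent}}} "
            f"REFERENCE{k}={_fmt(cmap.d_reference)}"
        )
    lines.append("  CMDIST")
    lines.append("...")
    pace_steps = max(1, round(pace_ps / md_timestep_ps))
    lines.append(
        f"metad: METAD ARG={label} PACE={pace_steps} SIGMA={_fmt(sigma)} "
        f"HEIGHT={_fmt(initial_height)} BIASFACTOR={_fmt(bias_factor)} TEMP={_fmt(temperature)}"
    )
    lines.append(f"PRINT ARG={label},metad.bias STRIDE={pace_steps} FILE=COLVAR")
    return "\n".join(lines) + "\n"


def write_contact_map(cmap: InterfaceContactMap, path: str | Path) -> None:
    """Serialize as TSV with a comment header carrying cutoff/exponents."""
    rows = [
        {
            "receptor_chain": c.receptor_residue[0],
            "receptor_resid": f"{c.receptor_residue[1]}{c.receptor_residue[2]}",
            "ligand_chain": c.ligand_residue[0],
            "ligand_resid": f"{c.ligand_residue[1]}{c.ligand_residue[2]}",
            "r0": c.r0,
            "support": c.support,
        }
        for c in cmap.contacts
    ]
    with open(path, "w") as fh:
        fh.write(f"# cutoff={cmap.cutoff} n={cmap.n_exponent} m={cmap.m_exponent}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def _split_resid(text: str) -> tuple[int, str]:
    text = str(text)
    digits = ""
    for ch in text:
        if ch.isdigit() or (ch == "-" and not digits):
            digits += ch
        else:
            break
    return int(digits), text[len(digits):]


def read_contact_map(path: str | Path) -> InterfaceContactMap:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    contacts = []
    for _, row in df.iterrows():
        ri, ric = _split_resid(row["receptor_resid"])
        li, lic = _split_resid(row["ligand_resid"])
        contacts.append(
            Contact((str(row["receptor_chain"]), ri, ric), (str(row["ligand_chain"]), li, lic),
                    r0=float(row["r0"]), support=int(row["support"]))
        )
    return InterfaceContactMap(
        contacts,
        cutoff=float(meta.get("cutoff", DEFAULT_CUTOFF)),
        n_exponent=int(meta.get("n", N_EXPONENT)),
        m_exponent=int(meta.get("m", M_EXPONENT)),
    )
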