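"""Snapshot scoring: surrogate interface score, normalization, and CS_alpha.

Trajectory snapshots are scored two ways: an external interface score in the
ZRANK convention (lower = better; either supplied as a table or computed by
the built-in surrogate), and the free-energy value of the snapshot's CV read
off the reconstructed FES. Both are affinely normalized to [0, 1] with 1 =
best, and blended by a weighting factor alpha in [0, 1]:

    CS_alpha = alpha * ZRANK_eta + (1 - alpha) * FES_eta

so alpha = 1 ranks purely by the external score and alpha = 0 purely by the
free energy. Predicted ranks are the descending order of CS_alpha.

The surrogate interface score is a deliberately simple, fully documented
additive function (soft Lennard-Jones repulsion/attraction on heavy-atom
interface pairs, screened Coulomb on nitrogen/oxygen partial charges, and a
contact-count desolvation proxy). It is deterministic, rigid-invariant, and
rewards compact clash-free interfaces; it makes no claim to ZRANK's weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .metadynamics import FESProfile
from .structure import ComplexStructure

__all__ = [
    "SnapshotRecord",
    "ScoreTable",
    "surrogate_interface_score",
    "normalize_01",
    "cs_alpha",
    "attach_fes",
    "read_external_scores",
]

# Surrogate score weights (documented constants, arbitrary energy units).
LJ_EPSILON = 0.2      # depth of the soft Lennard-Jones well
LJ_RMIN = 3.6         # Å, pair distance at the LJ minimum
SOFT_CORE = 0.8       # Å, softening added in quadrature to avoid singularities
COULOMB_K = 5.0       # prefactor of the screened Coulomb term
SCREENING_LENGTH = 8.0  # Å, exponential screening length
DESOLVATION_WEIGHT = 0.05  # reward per heavy-atom contact pair < 5 Å
INTERFACE_CUTOFF = 10.0    # Å, pair list cutoff
WORST_SCORE = 1.0e6   # sentinel for structures with no interface

_PARTIAL_CHARGE = {"N": 0.4, "O": -0.4}


@dataclass
class SnapshotRecord:
    """One trajectory frame considered for scoring and model building."""

    replica: int
    time_ps: float
    cv_value: float = float("nan")
    external_score: float = float("nan")
    fes_energy: float = 0.0
    lrmsd: float | None = None
    structure: ComplexStructure | None = None

    def __post_init__(self) -> None:
        if self.time_ps < 0:
            raise ValueError("time must be non-negative")
        if self.fes_energy < 0:
            raise ValueError("fes_energy must be non-negative")

    @property
    def snapshot_id(self) -> tuple[int, float]:
        return (self.replica, self.time_ps)


def surrogate_interface_score(structure: ComplexStructure) -> float:
    """Deterministic stand-in interface score; lower = better.

    ``E = sum soft-LJ(r) + sum k q_i q_j exp(-r/lambda)/r_eff - w * n_close``
    over receptor-ligand heavy-atom pairs within 10 Å, with
    ``r_eff = sqrt(r^2 + 0.8^2)``; nitrogen/oxygen carry +/-0.4 partial
    charges. Overlapping atoms are strongly penalized, so clashed decoys
    always score worse than relaxed ones; the desolvation proxy rewards
    buried contact area via the count of pairs under 5 Å.

    Returns a large sentinel value (with a warning) when no heavy-atom pair
    falls within the 10 Å cutoff.
    """
    ridx = structure.atom_indices("receptor", heavy_only=True)
    lidx = structure.atom_indices("ligand", heavy_only=True)
    coords = structure.coords
    dmat = cdist(coords[ridx], coords[lidx])
    mask = dmat < INTERFACE_CUTOFF
    if not mask.any():
        warnings.warn("no interface atoms within 10 Å; returning worst-case score")
        return WORST_SCORE
    r = dmat[mask]
    r_eff = np.sqrt(r**2 + SOFT_CORE**2)
    ratio4 = (LJ_RMIN / r_eff) ** 4
    e_lj = LJ_EPSILON * (ratio4**2 - 2.0 * ratio4)

    q = np.array([_PARTIAL_CHARGE.get(a.element.upper(), 0.0) for a in structure.atoms])
    qq = np.outer(q[ridx], q[lidx])[mask]
    e_coul = COULOMB_K * qq * np.exp(-r / SCREENING_LENGTH) / r_eff

    n_close = int((r < 5.0).sum())
    return float(e_lj.sum() + e_coul.sum() - DESOLVATION_WEIGHT * n_close)


def normalize_01(values: Sequence[float], orientation: str = "lower_is_better") -> np.ndarray:
    """Affine map to [0, 1] with 1 = best under the stated orientation.

    A constant vector maps to all 0.5 (neutral value; keeps CS_alpha defined).
    """
    if orientation not in ("lower_is_better", "higher_is_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty vector")
    bad = np.nonzero(~np.isfinite(v))[0]
    if bad.size:
        raise ValueError(f"non-finite scores at indices {bad.tolist()}")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.full_like(v, 0.5)
    if orientation == "lower_is_better":
        return (vmax - v) / (vmax - vmin)
    return (v - vmin) / (vmax - vmin)


def cs_alpha(zrank_eta: Sequence[float], fes_eta: Sequence[float], alpha: float) -> np.ndarray:
    """Blend ``alpha * zrank_eta + (1 - alpha) * fes_eta`` elementwise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    z = np.asarray(zrank_eta, dtype=float)
    f = np.asarray(fes_eta, dtype=float)
    if z.shape != f.shape:
        raise ValueError("zrank_eta and fes_eta must have equal lengths")
    return alpha * z + (1.0 - alpha) * f


def attach_fes(records: list[SnapshotRecord], fes: FESProfile) -> list[SnapshotRecord]:
    """Set each record's ``fes_energy`` by interpolating F at its CV value.

    CV values outside the grid are clamped to the nearest edge; one warning
    reports how many records were clamped.
    """
    if fes.grid.size == 0:
        raise ValueError("empty FES")
    clamped = 0
    lo, hi = fes.grid[0], fes.grid[-1]
    for rec in records:
        if rec.cv_value < lo or rec.cv_value > hi:
            clamped += 1
        rec.fes_energy = float(fes.interpolate(rec.cv_value))
    if clamped:
        warnings.warn(f"{clamped} snapshot CV value(s) outside the FES grid were clamped")
    return records


def read_external_scores(path: str | Path) -> dict[tuple[int, float], float]:
    """Read a TSV of (replica, time_ps, score) supplied by a real scorer."""
    df = pd.read_csv(path, sep="\t")
    return {(int(r), float(t)): float(s)
            for r, t, s in zip(df["replica"], df["time_ps"], df["score"])}


class ScoreTable:
    """Per-snapshot scores with normalized components and CS_alpha.

    Normalization scope is per target over the pooled snapshots of all
    replicas (``normalize="pooled"``, the default, matching selection over
    runs 1-5) or within each replica (``normalize="per_replica"``).
    """

    COLUMNS = ["replica", "time_ps", "cv", "external_score", "fes_kjmol",
               "zrank_eta", "fes_eta", "cs_alpha"]

    def __init__(self, records: Sequence[SnapshotRecord], alpha: float = 0.49,
                 normalize: str = "pooled") -> None:
        if not records:
            raise ValueError("score table needs at least one record")
        if normalize not in ("pooled", "per_replica"):
            raise ValueError(f"unknown normalization scope {normalize!r}")
        self.records = list(records)
        self.alpha = float(alpha)
        self.normalize = normalize
        self._recompute()

    def _recompute(self) -> None:
        ext = np.array([r.external_score for r in self.records])
        fes = np.array([r.fes_energy for r in self.records])
        reps = np.array([r.replica for r in self.records])
        if self.normalize == "pooled":
            self.zrank_eta = normalize_01(ext, "lower_is_better")
            self.fes_eta = normalize_01(fes, "lower_is_better")
        else:
            self.zrank_eta = np.empty(len(ext))
            self.fes_eta = np.empty(len(ext))
            for rep in np.unique(reps):
                m = reps == rep
                self.zrank_eta[m] = normalize_01(ext[m], "lower_is_better")
                self.fes_eta[m] = normalize_01(fes[m], "lower_is_better")
        self.cs = cs_alpha(self.zrank_eta, self.fes_eta, self.alpha)

    def __len__(self) -> int:
        return len(self.records)

    def set_alpha(self, alpha: float) -> None:
        self.alpha = float(alpha)
        self.cs = cs_alpha(self.zrank_eta, self.fes_eta, alpha)

    def ranked_indices(self, by: str = "cs") -> list[int]:
        """Record indices in predicted-rank order (best first).

        ``by``: ``"cs"``, ``"zrank"`` or ``"fes"`` -- descending eta values,
        ties broken by (time, replica).
        """
        key = {"cs": self.cs, "zrank": self.zrank_eta, "fes": self.fes_eta}[by]
        order = sorted(
            range(len(self.records)),
            key=lambda i: (-key[i], self.records[i].time_ps, self.records[i].replica),
        )
        return order

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replica": [r.replica for r in self.records],
            "time_ps": [r.time_ps for r in self.records],
            "cv": [r.cv_value for r in self.records],
            "external_score": [r.external_score for r in self.records],
            "fes_kjmol": [r.fes_energy for r in self.records],
            "zrank_eta": self.zrank_eta,
            "fes_eta": self.fes_eta,
            "cs_alpha": self.cs,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
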