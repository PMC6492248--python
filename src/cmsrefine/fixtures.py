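"""Synthetic toy complexes, decoy ensembles, trajectories, and potentials.

Every stage of the refinement pipeline is testable without downloads through
the generators here:

* :func:`make_toy_complex` — a two-chain complex with ideal backbone spacing
  (Cα-Cα 3.8 Å) and a designed interface of at least 10 Cα contact pairs
  under 8 Å. Each residue carries a Cα plus N/O/CB pseudo heavy atoms so
  any-atom contact rules and the surrogate scorer exercise more than the
  Cα-only logic. Geometries: two parallel bead chains on a gentle arc
  (``"bead-chain"``, the default) or two packed α-helix-like coils
  (``"helix"``).
* :func:`make_decoy_ensemble` — graded rigid ligand perturbations of a truth
  complex emulating high / medium / acceptable / incorrect docked decoys,
  with ground-truth LRMSD per decoy.
* :func:`make_synthetic_trajectory` — a rigid-body Ornstein-Uhlenbeck walk
  of the ligand pose attracted toward the truth complex, standing in for
  refinement trajectories: frames drift down a binding funnel with tunable
  noise, so contact-map deviation falls while native-contact fraction rises.
* :func:`double_well` — a quartic double-well test potential with analytic
  minima and barrier for the metadynamics engine.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .scoring import SnapshotRecord
from .structure import AtomRecord, ComplexStructure, Ensemble, kabsch_superpose, rmsd

__all__ = [
    "FixtureSpec",
    "DoubleWell",
    "make_toy_complex",
    "make_decoy_ensemble",
    "make_synthetic_trajectory",
    "double_well",
    "DECOY_GRADES",
]

CA_SPACING = 3.8    # Å, consecutive Cα distance in both geometries
HELIX_RISE = 1.5    # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
BEAD_ARC_RADIUS = 150.0  # Å, gentle curvature so bead-chain Cα are not collinear
#: Distance between the two chain axes and side-chain bead length; chosen so
#: the truth complex is clash-free (closest heavy-atom pair >= ~3.4 Å) yet
#: contact-rich at both the Cα (< 8 Å) and any-atom (< 5 Å) criteria.
AXIS_SEPARATION = {"helix": 10.0, "bead-chain": 7.0}
SIDECHAIN_LENGTH = {"helix": 1.0, "bead-chain": 1.53}


@dataclass
class FixtureSpec:
    n_residues_receptor: int = 30
    n_residues_ligand: int = 24
    geometry: str = "bead-chain"  # or "helix"
    perturbation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (rot °, trans Å, jitter Å)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_residues_receptor, self.n_residues_ligand) < 5:
            raise ValueError("chains need at least 5 residues")
        if self.geometry not in ("helix", "bead-chain"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.perturbation[2] < 0:
            raise ValueError("jitter must be non-negative")


def _helix_ca(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cα positions and outward radial unit vectors of an ideal coil."""
    chord = math.sqrt(CA_SPACING**2 - HELIX_RISE**2)
    radius = chord / (2.0 * math.sin(math.radians(HELIX_TWIST) / 2.0))
    phi = np.radians(HELIX_TWIST) * np.arange(n)
    ca = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), HELIX_RISE * np.arange(n)])
    e_r = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    return ca, e_r


def _bead_ca(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Bead chain along z on a gentle arc (exact 3.8 Å spacing, not collinear)."""
    dtheta = 2.0 * math.asin(CA_SPACING / (2.0 * BEAD_ARC_RADIUS))
    theta = dtheta * (np.arange(n) - (n - 1) / 2.0)  # symmetric: chains stay parallel
    ca = np.column_stack([
        BEAD_ARC_RADIUS * (1.0 - np.cos(theta)),
        np.zeros(n),
        BEAD_ARC_RADIUS * np.sin(theta),
    ])
    e_r = np.column_stack([np.cos(theta), np.zeros(n), -np.sin(theta)])
    return ca, e_r


def _chain_atoms(chain_id: str, ca: np.ndarray, e_r: np.ndarray, sidechain: float,
                 start_resid: int = 1) -> list[AtomRecord]:
    n = len(ca)
    e_z = np.array([0.0, 0.0, 1.0])
    atoms = []
    for i in range(n):
        tangent = np.cross(e_z, e_r[i])
        offsets = {
            ("N", "N"): -0.65 * tangent + 1.25 * e_z,
            ("CA", "C"): np.zeros(3),
            ("CB", "C"): sidechain * e_r[i],
            ("O", "O"): 0.65 * tangent - 1.25 * e_z,
        }
        for (name, element), off in offsets.items():
            atoms.append(AtomRecord(chain_id=chain_id, residue_index=start_resid + i,
                                    residue_name="ALA", atom_name=name, element=element,
                                    position=ca[i] + off))
    return atoms


def _rigid_perturb_ligand(structure: ComplexStructure, rotation_deg: float,
                          translation: np.ndarray, jitter: float,
                          rng: np.random.Generator) -> ComplexStructure:
    """Rotate the ligand about its centroid (random axis), translate, jitter."""
    lidx = structure.atom_indices("ligand")
    coords = structure.coords.copy()
    lig = coords[lidx]
    centroid = lig.mean(axis=0)
    if rotation_deg:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(rotation_deg) * axis).as_matrix()
        lig = (lig - centroid) @ R.T + centroid
    lig = lig + translation
    if jitter > 0:
        lig = lig + rng.normal(scale=jitter, size=lig.shape)
    coords[lidx] = lig
    return structure.with_coords(coords)


def make_toy_complex(spec: FixtureSpec | None = None) -> ComplexStructure:
    """Build the deterministic two-chain toy complex described by ``spec``.

    Chain A is the receptor, chain B the ligand, packed side by side so that
    at least 10 Cα-Cα pairs fall under the 8 Å contact cutoff. A non-zero
    ``spec.perturbation`` additionally perturbs the ligand rigidly
    (rotation °, translation Å along a random direction, per-atom jitter Å).
    """
    spec = spec or FixtureSpec()
    builder = _helix_ca if spec.geometry == "helix" else _bead_ca
    rec_ca, rec_er = builder(spec.n_residues_receptor)
    lig_ca, lig_er = builder(spec.n_residues_ligand)

    sep = AXIS_SEPARATION[spec.geometry]
    # Center the ligand on the receptor's z-span, offset along +x; bead-chain
    # side groups of the ligand are flipped to face the receptor.
    z_shift = (rec_ca[0, 2] + rec_ca[-1, 2]) / 2.0 - (lig_ca[0, 2] + lig_ca[-1, 2]) / 2.0
    shift = np.array([sep, 0.0, z_shift])
    lig_ca = lig_ca + shift
    if spec.geometry == "bead-chain":
        lig_er = -lig_er

    side = SIDECHAIN_LENGTH[spec.geometry]
    atoms = _chain_atoms("A", rec_ca, rec_er, side) + _chain_atoms("B", lig_ca, lig_er, side)
    structure = ComplexStructure(atoms, {"A"}, {"B"}, label=f"toy_{spec.geometry}")

    rot_deg, trans_mag, jitter = spec.perturbation
    if rot_deg or trans_mag or jitter:
        rng = np.random.default_rng(spec.seed)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        structure = _rigid_perturb_ligand(structure, rot_deg, trans_mag * direction, jitter, rng)
    return structure


#: Grade -> (hinge end displacement Å, translation away from receptor Å,
#: per-atom jitter Å). Decoys are generated by rotating the ligand about the
#: receptor->ligand separation axis through its centroid, so its ends sweep
#: laterally (no interpenetration) and native contacts are lost from the
#: ends inward — the same mechanism that grades real near-native decoys.
#: The rotation angle is set so a chain end moves by the stated displacement,
#: making both the LRMSD and the surviving-contact fraction roughly
#: independent of chain length.
DECOY_GRADES: dict[str, tuple[float, float, float]] = {
    "high": (1.2, 0.1, 0.03),
    "medium": (4.0, 0.3, 0.08),
    "acceptable": (7.0, 0.4, 0.12),
    "incorrect": (25.0, 15.0, 0.2),
}

GRADE_ORDER = ("high", "medium", "acceptable", "incorrect")


def _ligand_lrmsd(structure: ComplexStructure, truth: ComplexStructure) -> float:
    """LRMSD for decoys sharing the truth's receptor coordinates exactly."""
    _, lig = structure.ca_table("ligand")
    _, lig0 = truth.ca_table("ligand")
    return rmsd(lig, lig0)


def make_decoy_ensemble(
    truth: ComplexStructure,
    n_decoys: int = 8,
    quality_grades: Sequence[str] = GRADE_ORDER,
    seed: int = 0,
) -> tuple[Ensemble, list[dict]]:
    """Graded rigid-ligand decoys of ``truth`` with a known LRMSD ladder.

    Decoys cycle through ``quality_grades`` (each grade appears at least
    once; ``n_decoys`` is raised to the grade count if smaller). The ligand
    is hinge-rotated about the separation axis through its centroid (random
    sign), pulled slightly away from the receptor, and jittered, with
    grade-specific magnitudes (:data:`DECOY_GRADES`). Returns the ensemble
    and a manifest of dicts ``{decoy_id, grade, lrmsd}`` with the true
    ligand-Cα LRMSD.
    """
    for g in quality_grades:
        if g not in DECOY_GRADES:
            raise ValueError(f"unknown grade {g!r}")
    n_decoys = max(n_decoys, len(quality_grades))
    rng = np.random.default_rng(seed)

    ridx = truth.atom_indices("receptor")
    lidx = truth.atom_indices("ligand")
    lig = truth.coords[lidx]
    centroid = lig.mean(axis=0)
    away = centroid - truth.coords[ridx].mean(axis=0)
    away /= np.linalg.norm(away)
    # Half-extent of the ligand perpendicular to the hinge axis.
    r_perp = lig - centroid
    r_perp = r_perp - np.outer(r_perp @ away, away)
    half_extent = float(np.linalg.norm(r_perp, axis=1).max())

    members, manifest = [], []
    for k in range(n_decoys):
        grade = quality_grades[k % len(quality_grades)]
        end_disp, t_away, jitter = DECOY_GRADES[grade]
        angle = end_disp / max(half_extent, 1.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        R = Rotation.from_rotvec(sign * angle * away).as_matrix()
        coords = truth.coords.copy()
        coords[lidx] = (lig - centroid) @ R.T + centroid + t_away * away
        decoy = truth.with_coords(coords)
        if jitter > 0:
            c2 = decoy.coords.copy()
            c2[lidx] += rng.normal(scale=jitter, size=(len(lidx), 3))
            decoy = decoy.with_coords(c2)
        decoy.label = f"decoy_{k:02d}_{grade}"
        members.append(decoy)
        manifest.append({"decoy_id": decoy.label, "grade": grade,
                         "lrmsd": _ligand_lrmsd(decoy, truth)})
    return Ensemble(members), manifest


def _pose_from_decoy(truth: ComplexStructure, start: ComplexStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid (rotvec, translation) of the start ligand relative to truth."""
    _, truth_lig = truth.ca_table("ligand")
    _, start_lig = start.ca_table("ligand")
    centroid = truth.coords[truth.atom_indices("ligand")].mean(axis=0)
    R, t, _ = kabsch_superpose(truth_lig, start_lig)
    w = Rotation.from_matrix(R).as_rotvec()
    d = R @ centroid + t - centroid
    return w, d, centroid


def make_synthetic_trajectory(
    truth: ComplexStructure,
    start: ComplexStructure,
    n_frames: int = 60,
    spacing_ps: float = 50.0,
    funnel_strength: float = 0.08,
    noise_translation: float = 0.25,
    noise_rotation_deg: float = 1.0,
    seed: int = 0,
    replica: int = 0,
) -> list[SnapshotRecord]:
    """Rigid-body OU walk of the ligand pose from ``start`` toward ``truth``.

    The pose (rotation vector, centroid translation) relative to the truth
    ligand decays by the factor ``1 - funnel_strength`` per frame (clamped to
    [0, 1]; 1 = pure attraction, 0 = free diffusion) plus Gaussian noise.
    Frame 0 is the rigid-body fit of the start pose (any non-rigid jitter of
    the start is not carried over); frames are spaced ``spacing_ps`` apart.
    Returns snapshot records with structures and ground-truth ligand-Cα
    LRMSD filled in; scores and CV values are left to the caller.
    """
    if not 0.0 <= funnel_strength <= 1.0:
        raise ValueError("funnel_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w, d, centroid = _pose_from_decoy(truth, start)
    lidx = truth.atom_indices("ligand")
    base = truth.coords
    decay = 1.0 - funnel_strength
    sigma_rot = math.radians(noise_rotation_deg)

    records = []
    for i in range(n_frames):
        if i > 0:
            w = decay * w + sigma_rot * rng.standard_normal(3)
            d = decay * d + noise_translation * rng.standard_normal(3)
        coords = base.copy()
        R = Rotation.from_rotvec(w).as_matrix()
        coords[lidx] = (base[lidx] - centroid) @ R.T + centroid + d
        frame = truth.with_coords(coords, label=f"frame_r{replica}_{i:03d}")
        records.append(SnapshotRecord(
            replica=replica,
            time_ps=i * spacing_ps,
            lrmsd=_ligand_lrmsd(frame, truth),
            structure=frame,
        ))
    return records


@dataclass
class DoubleWell:
    """Quartic double well ``U(s) = barrier * ((s/a)^2 - 1)^2``.

    Minima at ``s = -a, +a`` (U = 0), barrier top at ``s = 0``
    (U = barrier). ``a = minima_separation / 2``. The default separation of
    6 CV units keeps the metadynamics kernel width (0.5) small relative to
    the basin size, matching the regime of a production contact-map CV whose
    range spans many kernel widths.
    """

    barrier: float
    minima_separation: float = 6.0

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")
        if self.minima_separation <= 0:
            raise ValueError("minima separation must be positive")

    @property
    def a(self) -> float:
        return self.minima_separation / 2.0

    @property
    def minima(self) -> tuple[float, float]:
        return (-self.a, self.a)

    def potential(self, s: float) -> float:
        z = (s / self.a) ** 2 - 1.0
        return self.barrier * z * z

    def gradient(self, s: float) -> float:
        return 4.0 * self.barrier * s * ((s / self.a) ** 2 - 1.0) / self.a**2


def double_well(barrier: float, minima_separation: float = 4.0) -> DoubleWell:
    """Analytic quartic double-well test potential (see :class:`DoubleWell`)."""
    return DoubleWell(barrier=barrier, minima_separation=minima_separation)
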