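# Methods

This note documents the models, parameters and numerical choices behind
`cmsrefine`, and what the synthetic test bed does and does not demonstrate.

## Contact map space

A residue pair (one receptor residue, one ligand residue) is an interface
contact when the Cα–Cα distance is strictly below the cutoff (default 8 Å;
the boundary value is excluded because the criterion is "below"). Built
from an ensemble, CM_if is the union of the members' contact sets; each
contact stores a reference distance r₀ and a support count. r₀ pools the
distances of the supporting members — the members in which the pair is
below the cutoff — with the arithmetic mean by default (median and
centroid-member pooling are available; the mean is the least-committal
choice). `min_support` defaults to 1 (pure union): the ensemble is treated
as evidence of plausible contacts, not as a vote.

The switching function D(r) = (1 − xⁿ)/(1 − xᵐ), x = r/r₀, uses n = 6,
m = 10. At x = 1 both numerator and denominator vanish; the limit is n/m =
0.6, and evaluation within |x − 1| < 1e−6 returns that limit to avoid
catastrophic cancellation (relative error of the direct form grows as
1/|x − 1| toward the singularity). D is strictly decreasing for r > 0, 1 at
r = 0, and → 0 as r → ∞.

The CMS of a structure sums (D_γ − D_ref)² over CM_if. D_ref is the
constant 0.6: when a contact sits exactly at its reference distance the
switching value is pinned to 0.6, which makes the per-contact reference
term constant even though the reference is an ensemble rather than a
single structure. A custom D_ref can be supplied. Consequences used by the
tests: CMS = 0 iff every contact distance equals its r₀, and CMS is
invariant under rigid motion of the complex (it depends on internal
distances only).

## Well-tempered metadynamics engine

The bias is a sum of Gaussians V(s) = Σ h_k exp(−(s − c_k)²/2σ_k²).
Deposition follows the standard well-tempered rule

    h = h₀ · exp( −V(s)/(k_B ΔT) ),   ΔT = (γ − 1) T,

and the free energy estimate is F(s) = −(γ/(γ−1)) V(s), shifted so
min F = 0. γ = ∞ reproduces standard metadynamics (constant heights,
F = −V). Defaults mirror the production protocol: σ = 0.5, pace 2 ps,
h₀ = 5 kJ/mol, γ = 10, T = 300 K; k_B = 0.008314462618 kJ/(mol·K).

`reconstruct_fes` additionally offers the standard time-averaged estimator
(`average_from=f`): the instantaneous estimate −(γ/(γ−1))V_k(s) is averaged
over the bias states after the first fraction f of depositions. A single
final-bias estimate carries a ~k_BT ripple that decays only slowly; the
time average converges markedly faster and is what the quantitative
recovery test uses (f = 0.3). Because V_k is a partial sum, the average
reduces to one kernel summation with per-kernel weights
(K − max(j, k₀))/(K − k₀).

Kernel evaluation is exact summation (no grid cache) — at the scales used
here (≤ a few thousand kernels) this is both exact and fast.

### Surrogate sampler

Production sampling is explicit-solvent MD under PLUMED (inputs exported by
`export_plumed`; HILLS files are read back with `read_hills`). For testing,
an overdamped Langevin sampler evolves the scalar CV directly:

    s ← s − (U′(s) + V′(s))·Δt/ξ + N(0, 2 k_B T Δt/ξ),

with friction ξ (1/ps) and timestep Δt (ps), deterministic per seed.
Defaults: Δt = 0.002 ps (the conventional 2 fs MD timestep) and ξ = 1/ps.
Replicated runs (default five) use distinct seeds and fully independent
bias states; a mean FES across replicas can be formed, but scoring uses the
per-replica FES by default.

The quantitative test bed is a quartic double well
U(s) = B((s/a)² − 1)², minima at ±a, barrier B at s = 0. The default
minima separation is 6 CV units so that the σ = 0.5 kernels resolve the
basins (σ ≪ basin scale) — the regime of a production contact-map CV,
whose range spans many kernel widths; with much narrower wells the finite
kernel width alone leaves a ~1 kJ/mol systematic floor in the
reconstruction. The recovery benchmark (barrier 15 k_BT, 10⁶ steps) uses
ξ = 0.5/ps so the 2 ns-equivalent budget yields many well-to-well round
trips; recovery error is measured as the offset-aligned RMSE over the
well-sampled support (the 1–99 % quantile range of visited CV values —
the rare excursions beyond it are not converged and are excluded).

## Snapshot scoring

The external score follows the ZRANK convention (lower = better). The
built-in surrogate is an additive interface score over receptor–ligand
heavy-atom pairs within 10 Å:

* soft Lennard-Jones, ε = 0.2, r_min = 3.6 Å, softened with
  r_eff = √(r² + 0.8²) so overlaps are strongly but finitely penalized;
* screened Coulomb, prefactor 5.0, screening length 8 Å, partial charges
  +0.4/−0.4 on N/O;
* a desolvation proxy of −0.05 per heavy-atom pair under 5 Å (rewards
  buried contact area).

It is deterministic, rigid-invariant, ranks clashed poses worst and
contact-rich near-native poses best — the properties the pipeline needs —
and makes no claim to reproduce any particular empirical scoring function's
weights. Real scores are supplied as a TSV (replica, time_ps, score).

Normalization maps scores affinely to [0, 1] with 1 = best for both
components, so CS_α = α·ZRANK_η + (1 − α)·FES_η is "higher = better" and
predicted ranks are its descending order. A constant score vector maps to
0.5 everywhere (keeps CS_α defined with a neutral contribution). The
normalization scope is the pooled snapshots of all replicas of a target
(selection operates on the pooled set); per-replica scope is available.
FES energies attach to snapshots by linear interpolation of F at the
snapshot's CV value, clamping out-of-grid values to the nearest edge (with
a warning counting the clamps).

## Ranking error

Reference ranks order snapshots by ascending LRMSD to the reference
structure (rank 1 = best; ties broken by replica then time — documented,
deterministic). Predicted order is descending score with ties broken by
time then replica. For selection depth n, each target contributes the sum
of the capped reference ranks, rank(i) = min(i, max), of its top-n
predicted snapshots; summing over targets gives ε, normalized by

    ε_η = (ε − rank_min)/(rank_max − rank_min),
    rank_min = |TR|·n(n+1)/2,   rank_max = |TR|·(max+1)·n.

`max` defaults to 100. Note rank_max uses (max + 1) although the worst
capped rank is max, so ε_η < 1 strictly; the formula is implemented as
stated in its source and the slack is accepted. Perfect selection gives
ε_η = 0 exactly. The α × n sweep evaluates ε_η on a grid and reports, per
n, the smallest α attaining the minimum.

## Model building

The build takes the top-n snapshots (default n = 14, pooled over replicas,
frames spaced 50 ps). Selection defaults to the external score — the
recommended generic choice, robust across starting-model qualities — with
CS_α as an option for acceptable-quality workflows. Each selected snapshot
is rigidly superposed onto the best-scored one via receptor Cα atoms
before averaging: frames from independent runs share no common frame of
reference, and the receptor frame is also the assessment frame. All atoms
present in every snapshot are averaged arithmetically.

Averaging can create locally non-physical geometry, so the average is
relaxed by steepest descent on a deliberately lightweight potential whose
only contract is clash resolution with minimal displacement:

* harmonic tether of each atom to its averaged position (k = 2 kJ/mol/Å²),
* soft-sphere repulsion, k = 100 kJ/mol/Å², onset 2.8 Å, between
  non-bonded heavy-atom pairs (same/adjacent residues of a chain excluded),
* flat-bottom (±0.2 Å) restraints, k = 20 kJ/mol/Å², on bonded distances
  (chain-consecutive Cα and atom-to-Cα within a residue) taken from the
  best-scored snapshot.

Backtracking line search never accepts an energy increase; iteration stops
at the step cap (default 500) or when the maximum force component drops
below 1 kJ/mol/Å. The returned structure never has more heavy-atom clashes
(non-bonded pairs < 2.0 Å) than the input — if the minimizer cannot
improve, the input is returned with a warning.

## CAPRI assessment

* **FNAT**: fraction of the reference's interface residue contacts
  (any heavy-atom pair < 5 Å) present in the model. Only reference-defined
  contacts count.
* **LRMSD**: ligand Cα RMSD after least-squares superposition of the model
  receptor Cα onto the reference receptor.
* **IRMSD**: Cα RMSD over the reference-defined interface residues
  (any heavy-atom pair < 10 Å — note this wider interface cutoff is the
  protocol's stated variation from the blind-trial formulation), after
  superposing those interface Cα sets.

Hydrogens are excluded from every contact criterion so structures with and
without protons assess identically. Residues map between model and
reference by (chain, author residue number, insertion code) identity; no
alignment fallback. Class thresholds are the standard CAPRI criteria
(high: FNAT ≥ 0.5 ∧ (LRMSD ≤ 1 ∨ IRMSD ≤ 1); medium: FNAT ≥ 0.3 ∧
(LRMSD ≤ 5 ∨ IRMSD ≤ 2); acceptable: FNAT ≥ 0.1 ∧ (LRMSD ≤ 10 ∨
IRMSD ≤ 4); else incorrect), evaluated from high downward. These
thresholds are a documented choice; annotations that ship with external
decoy sets may disagree on borderline cases.

Rigid superposition uses the Kabsch SVD construction with a determinant
correction to enforce a proper rotation. Configurations whose second
singular value vanishes (collinear or coincident point sets) are rejected:
the rotation is not unique there.

## Synthetic fixtures — what they do and do not show

`make_toy_complex` builds a two-chain complex from ideal backbones (Cα–Cα
3.8 Å) with N/O/CB pseudo heavy atoms per residue, so any-atom contact
rules and the scorer exercise more than Cα logic. The default geometry is
two parallel bead chains on a gentle arc (radius 150 Å — exact 3.8 Å
spacing, non-collinear Cα so receptor superposition is well-posed), axis
separation 7 Å with side-chain beads facing the interface: a clash-free
complex with ~50 Cα contacts under 8 Å and ~42 native contacts under 5 Å.
A helix-pair geometry is available; its sparser interface (6 native
contacts) makes graded-FNAT statements coarse, so class-band guarantees
are stated for the default fixture.

Graded decoys hinge-rotate the ligand about the separation axis through
its centroid: the chain ends sweep laterally (no interpenetration) and
native contacts are lost from the ends inward, which grades FNAT smoothly
and nearly independently of chain length. Grade magnitudes
(end displacement 1.2 / 4.0 / 7.0 / 25 Å, plus small pull-away and jitter)
are sized so the four grades land in the high / medium / acceptable /
incorrect class bands for the default fixture.

Synthetic trajectories evolve the rigid ligand pose (rotation vector +
centroid translation relative to truth) by an Ornstein–Uhlenbeck update:
geometric decay toward the truth pose (funnel strength per frame ∈ [0, 1])
plus Gaussian noise (0.25 Å, 1° per frame by default). Along such a
trajectory the CMS falls while FNAT rises — the opposed drift the CV is
designed to produce — and the best-scored frames cluster near the truth.

These fixtures validate bookkeeping, geometry, estimators and the
selection/averaging logic. They are rigid-body caricatures: no backbone or
side-chain flexibility, no solvent, sequence or force-field realism, and a
funnel that is attractive by construction. Passing tests therefore
demonstrate the correctness of the machinery, not refinement performance
on real docked complexes, which depends on MD sampling and the external
scorer.

## Problem sizes in the test suite

The suite runs the pipeline at desk scale: 10⁶-step surrogate sampling for
the free-energy recovery benchmark (≈ 10 s), 2×10⁵-step paired runs for
the barrier-crossing comparison, 10-seed repetitions for the averaging and
end-to-end refinement benchmarks (3 replicas × 40 frames each), and
brute-force oracles over ~24-decoy sets. These sizes keep the full suite
around half a minute while leaving each statistical check comfortably
powered.
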