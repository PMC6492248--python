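"""Well-tempered bias math, FES reconstruction, and the surrogate sampler."""

import math

import numpy as np
import pytest

from cmsrefine import (
    BiasPotential,
    ToySystem,
    double_well,
    read_hills,
    reconstruct_fes,
    run_replicas,
    run_toy_sampler,
)
from cmsrefine.metadynamics import KB, Trajectory


def _harmonic(k=10.0):
    return ToySystem(potential=lambda s: 0.5 * k * s * s,
                     gradient=lambda s: k * s,
                     friction=1.0, temperature=300.0, timestep=0.002, seed=0)


class TestBiasEnergy:
    def test_empty_bias_is_zero(self):
        bias = BiasPotential()
        assert bias.bias_energy(1.7) == 0.0
        assert bias.bias_force(1.7) == 0.0

    def test_single_kernel_peak_value(self):
        bias = BiasPotential(sigma=0.5, initial_height=5.0)
        bias.deposit(0.0)
        assert bias.bias_energy(0.0) == pytest.approx(5.0)
        assert bias.bias_energy(0.5) == pytest.approx(5.0 * math.exp(-0.5))

    def test_hundred_random_kernels_match_direct_summation(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(-5, 5, size=100)
        bias = BiasPotential(sigma=0.5, bias_factor=math.inf)  # constant heights
        for c in centers:
            bias.deposit(float(c))
        s = rng.uniform(-6, 6, size=50)
        direct = np.array([
            sum(5.0 * math.exp(-((x - c) ** 2) / (2 * 0.5**2)) for c in centers) for x in s
        ])
        assert np.abs(bias.bias_energy(s) - direct).max() < 1e-10


class TestWellTemperedDeposition:
    def test_first_deposit_has_initial_height(self):
        bias = BiasPotential()
        assert bias.deposit(2.3) == pytest.approx(5.0)

    def test_second_deposit_damped_by_standard_rule(self):
        bias = BiasPotential(sigma=0.5, initial_height=5.0, bias_factor=10.0, temperature=300.0)
        bias.deposit(1.0)
        delta_T = 9.0 * 300.0
        expected = 5.0 * math.exp(-5.0 / (KB * delta_T))
        assert bias.deposit(1.0) == pytest.approx(expected, rel=1e-12)

    def test_infinite_bias_factor_keeps_heights_constant(self):
        bias = BiasPotential(bias_factor=math.inf)
        for _ in range(5):
            assert bias.deposit(0.0) == pytest.approx(5.0)

    def test_heights_non_increasing_at_revisited_point(self):
        bias = BiasPotential()
        heights = [bias.deposit(0.0) for _ in range(20)]
        assert all(b <= a for a, b in zip(heights, heights[1:]))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            BiasPotential(bias_factor=1.0)
        with pytest.raises(ValueError):
            BiasPotential(sigma=0.0)


class TestFesReconstruction:
    def test_single_kernel_gives_inverted_gaussian(self):
        bias = BiasPotential()
        bias.deposit(1.5)
        grid = np.linspace(-3, 3, 121)
        fes = reconstruct_fes(bias, grid)
        assert fes.free_energy.min() == 0.0
        assert grid[np.argmin(fes.free_energy)] == pytest.approx(1.5, abs=0.05)
        # far from the kernel F approaches the (shifted) maximum
        assert fes.free_energy[0] == pytest.approx(fes.free_energy.max(), rel=1e-3)

    def test_linearity_in_heights_before_shift(self):
        grid = np.linspace(-2, 2, 41)
        b1 = BiasPotential(bias_factor=math.inf)
        b2 = BiasPotential(bias_factor=math.inf, initial_height=10.0)
        for c in (0.0, 0.7, -0.4):
            b1.deposit(c)
            b2.deposit(c)
        assert np.allclose(2.0 * b1.bias_energy(grid), b2.bias_energy(grid), atol=1e-12)

    def test_empty_bias_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_fes(BiasPotential(), np.linspace(0, 1, 5))

    def test_well_tempered_prefactor(self):
        bias = BiasPotential(bias_factor=10.0)
        bias.deposit(0.0)
        grid = np.array([-1.0, 0.0, 1.0])
        fes = reconstruct_fes(bias, grid)
        v = bias.bias_energy(grid)
        expected = -(10.0 / 9.0) * v
        assert np.allclose(fes.free_energy, expected - expected.min(), atol=1e-12)


class TestToySampler:
    def test_zero_temperature_descends_to_minimum(self):
        system = ToySystem(potential=lambda s: 0.5 * 10 * (s - 1.0) ** 2,
                           gradient=lambda s: 10 * (s - 1.0),
                           friction=1.0, temperature=1e-12, timestep=0.002, seed=0)
        traj = run_toy_sampler(system, None, 5000, s0=3.0)
        assert traj.positions[-1] == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_reproduces_trajectory(self):
        dw = double_well(10.0)
        system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=42)
        bias_a = BiasPotential()
        bias_b = BiasPotential()
        ta = run_toy_sampler(system, bias_a, 20_000, s0=-3.0)
        tb = run_toy_sampler(system, bias_b, 20_000, s0=-3.0)
        assert np.array_equal(ta.positions, tb.positions)
        assert bias_a.n_kernels == bias_b.n_kernels

    @pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
    def test_divergence_raises(self):
        system = ToySystem(potential=lambda s: 0.5 * 1e8 * s * s,
                           gradient=lambda s: 1e8 * s,
                           friction=1.0, temperature=300.0, timestep=0.1, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            run_toy_sampler(system, None, 50_000, s0=1.0)

    def test_equilibrium_variance_in_harmonic_well(self):
        k = 10.0
        traj = run_toy_sampler(_harmonic(k), None, 1_000_000, s0=0.0, record_stride=10)
        var = float(np.var(traj.positions[1000:]))
        assert var == pytest.approx(KB * 300.0 / k, rel=0.10)

    def test_metadynamics_crosses_high_barrier_where_plain_langevin_cannot(self):
        barrier = 15 * KB * 300.0
        dw = double_well(barrier)
        a = dw.a
        biased_hits, plain_hits = [], []
        for seed in range(10):
            system = ToySystem(potential=dw.potential, gradient=dw.gradient,
                               friction=0.5, temperature=300.0, timestep=0.002, seed=seed)
            tb = run_toy_sampler(system, BiasPotential(), 200_000, s0=-a, record_stride=20)
            tp = run_toy_sampler(system, None, 200_000, s0=-a, record_stride=20)
            biased_hits.append(tb.positions.max() > a / 2)
            plain_hits.append(tp.positions.max() > a / 2)
        assert np.median(biased_hits) == 1.0          # both wells reached with bias
        assert sum(plain_hits) < sum(biased_hits)     # plain Langevin stays trapped


class TestReplicas:
    def test_default_replica_count_is_five(self):
        dw = double_well(5.0)
        system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=0)
        runs = run_replicas(system, BiasPotential(), n_steps=2000)
        assert len(runs) == 5
        assert [r.replica for r in runs] == list(range(5))

    def test_distinct_seeds_give_distinct_trajectories_with_separate_bias(self):
        dw = double_well(5.0)
        system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=3)
        runs = run_replicas(system, BiasPotential(), n_steps=5000, n_replicas=3)
        assert not np.array_equal(runs[0].positions, runs[1].positions)
        assert runs[0].bias is not runs[1].bias

    def test_duplicate_seeds_warn(self):
        dw = double_well(5.0)
        system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=0)
        with pytest.warns(UserWarning, match="duplicate"):
            run_replicas(system, BiasPotential(), n_steps=100, n_replicas=2, seeds=[1, 1])

    def test_concatenated_snapshot_count(self):
        dw = double_well(5.0)
        system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=0)
        runs = run_replicas(system, BiasPotential(), n_steps=1000, n_replicas=4,
                            record_stride=10)
        total = sum(len(r) for r in runs)
        assert total == 4 * (1000 // 10 + 1)


class TestHillsIO:
    def test_round_trip_through_hills_format(self, tmp_path):
        bias = BiasPotential(sigma=0.5, initial_height=5.0, bias_factor=10.0)
        rng = np.random.default_rng(1)
        for i, c in enumerate(rng.uniform(-2, 2, size=30)):
            bias.deposit(float(c), t=2.0 * (i + 1))
        path = tmp_path / "HILLS"
        lines = ["#! FIELDS time cms sigma_cms height biasf"]
        for k in bias.kernels:
            lines.append(f"{k.deposit_time:.3f} {k.center:.9f} {k.sigma:.3f} {k.height:.9f} 10")
        path.write_text("\n".join(lines) + "\n")
        back = read_hills(path)
        grid = np.linspace(-3, 3, 61)
        assert np.abs(back.bias_energy(grid) - bias.bias_energy(grid)).max() < 1e-6
        assert back.bias_factor == 10.0

    def test_rejects_non_hills_file(self, tmp_path):
        bad = tmp_path / "junk"
        bad.write_text("1 2 3\n")
        with pytest.raises(ValueError, match="HILLS"):
            read_hills(bad)


def test_bias_settings_config_round_trip(tmp_path):
    bias = BiasPotential(sigma=0.4, pace=1.0, initial_height=3.0, bias_factor=8.0,
                         temperature=310.0)
    path = tmp_path / "metad.cfg"
    bias.to_config(path)
    back = BiasPotential.from_config(path)
    for key in ("sigma", "pace", "initial_height", "bias_factor", "temperature"):
        assert getattr(back, key) == getattr(bias, key)


def test_trajectory_tsv_and_hdf5_round_trip(tmp_path):
    dw = double_well(5.0)
    system = ToySystem(potential=dw.potential, gradient=dw.gradient, seed=0)
    traj = run_toy_sampler(system, BiasPotential(), 2000, s0=-dw.a, record_stride=10)
    tsv = tmp_path / "traj.tsv"
    traj.to_tsv(tsv)
    back = Trajectory.from_tsv(tsv)
    assert np.allclose(back.positions, traj.positions)
    assert np.allclose(back.times, traj.times)
    h5 = tmp_path / "traj.h5"
    traj.to_hdf5(h5)
    import h5py

    with h5py.File(h5) as fh:
        assert np.allclose(fh["cv"][...], traj.positions)
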