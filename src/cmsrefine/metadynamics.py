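"""Well-tempered metadynamics on a scalar collective variable.

The bias is a sum of Gaussian kernels deposited along the CV at a fixed pace.
In the well-tempered scheme each new kernel's height is damped by the bias
already accumulated at the deposition point,

    h = h0 * exp( -V_bias(s) / (kB * dT) ),    dT = (gamma - 1) * T,

where ``gamma`` is the bias factor (the ratio of the CV temperature to the
system temperature). The free energy along the CV is estimated from the
converged bias as

    F(s) = -(gamma / (gamma - 1)) * V_bias(s),

shifted so its minimum is zero. ``gamma -> inf`` recovers standard
(untempered) metadynamics: constant heights and F = -V.

A desk-scale surrogate sampler is included: overdamped Langevin dynamics of
the scalar CV on an analytic potential, with kernels deposited every pace
interval. It exists to exercise and validate the bias/FES machinery without
any MD engine; production runs are driven through exported PLUMED inputs
(:func:`cmsrefine.contacts.export_plumed`), and PLUMED HILLS files can be
read back for FES reconstruction with :func:`read_hills`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KB",
    "GaussianKernel",
    "BiasPotential",
    "FESProfile",
    "ToySystem",
    "Trajectory",
    "reconstruct_fes",
    "run_toy_sampler",
    "run_replicas",
    "read_hills",
]

#: Boltzmann constant in kJ/(mol K).
KB = 0.008314462618


@dataclass(frozen=True)
class GaussianKernel:
    center: float
    sigma: float
    height: float
    deposit_time: float  # ps

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")


class BiasPotential:
    """Accumulated Gaussian bias with well-tempered deposition.

    Parameters
    ----------
    sigma : kernel width in CV units (default 0.5).
    pace : deposition interval in ps (default 2).
    initial_height : undamped kernel height in kJ/mol (default 5).
    bias_factor : well-tempered gamma > 1; ``math.inf`` gives standard
        metadynamics with constant heights.
    temperature : system temperature in K (default 300).
    """

    def __init__(
        self,
        sigma: float = 0.5,
        pace: float = 2.0,
        initial_height: float = 5.0,
        bias_factor: float = 10.0,
        temperature: float = 300.0,
    ) -> None:
        if not bias_factor > 1:
            raise ValueError("bias_factor must be > 1")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if sigma <= 0 or initial_height <= 0 or pace <= 0:
            raise ValueError("sigma, pace and initial_height must be positive")
        self.sigma = float(sigma)
        self.pace = float(pace)
        self.initial_height = float(initial_height)
        self.bias_factor = float(bias_factor)
        self.temperature = float(temperature)
        self._centers: list[float] = []
        self._sigmas: list[float] = []
        self._heights: list[float] = []
        self._times: list[float] = []

    # -- bookkeeping -------------------------------------------------------

    @property
    def kernels(self) -> list[GaussianKernel]:
        return [GaussianKernel(c, s, h, t)
                for c, s, h, t in zip(self._centers, self._sigmas, self._heights, self._times)]

    @property
    def n_kernels(self) -> int:
        return len(self._centers)

    @property
    def delta_T(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature

    def clone_settings(self) -> "BiasPotential":
        """Fresh, empty bias with the same deposition settings."""
        return BiasPotential(self.sigma, self.pace, self.initial_height,
                             self.bias_factor, self.temperature)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.asarray(self._centers), np.asarray(self._sigmas), np.asarray(self._heights))

    # -- evaluation --------------------------------------------------------

    def bias_energy(self, s):
        """V_bias(s) by exact kernel summation; scalar or array ``s``."""
        if not self._centers:
            return 0.0 if np.isscalar(s) else np.zeros_like(np.asarray(s, dtype=float))
        c, sig, h = self._arrays()
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        z = (s_arr[:, None] - c[None, :]) / sig[None, :]
        v = (h[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)
        return float(v[0]) if np.isscalar(s) else v.reshape(np.shape(s))

    def bias_force(self, s: float) -> float:
        """-dV_bias/ds at scalar ``s``."""
        if not self._centers:
            return 0.0
        c, sig, h = self._arrays()
        d = s - c
        g = h * np.exp(-0.5 * (d / sig) ** 2)
        return float((g * d / sig**2).sum())

    # -- deposition --------------------------------------------------------

    def next_height(self, s: float) -> float:
        """Well-tempered height of a kernel deposited now at ``s``."""
        if math.isinf(self.bias_factor):
            return self.initial_height
        return self.initial_height * math.exp(-self.bias_energy(s) / (KB * self.delta_T))

    def deposit(self, s: float, t: float = 0.0) -> float:
        """Deposit a kernel at CV value ``s`` (time ``t`` ps); returns its height."""
        h = self.next_height(s)
        self._centers.append(float(s))
        self._sigmas.append(self.sigma)
        self._heights.append(h)
        self._times.append(float(t))
        return h

    # -- flat key=value config block --------------------------------------

    def to_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in ("sigma", "pace", "initial_height", "bias_factor", "temperature"):
                fh.write(f"{key} = {getattr(self, key)}\n")

    @classmethod
    def from_config(cls, path: str | Path, **overrides) -> "BiasPotential":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = float(value)
        kv.update(overrides)
        return cls(**kv)


@dataclass
class FESProfile:
    """Free energy profile on a CV grid, minimum shifted to zero."""

    grid: np.ndarray
    free_energy: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.free_energy.shape:
            raise ValueError("grid and free_energy must be matching 1-D arrays")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        self.free_energy = self.free_energy - self.free_energy.min()

    def interpolate(self, s):
        """Linear interpolation of F at ``s``; out-of-grid values are clamped."""
        return np.interp(s, self.grid, self.free_energy)

    def local_minima(self) -> np.ndarray:
        """Grid values of strict interior local minima of F, plus basin edges."""
        f = self.free_energy
        interior = (f[1:-1] < f[:-2]) & (f[1:-1] <= f[2:])
        idx = np.nonzero(interior)[0] + 1
        return self.grid[idx]


def reconstruct_fes(bias: BiasPotential, grid: Sequence[float],
                    average_from: float | None = None) -> FESProfile:
    """Well-tempered FES estimate ``F = -(gamma/(gamma-1)) V_bias``, min at 0.

    With ``average_from=None`` (default) the estimator uses the final
    accumulated bias. ``average_from=f`` (0 <= f < 1) instead time-averages
    the estimator over the bias states after the first fraction ``f`` of
    depositions — the standard remedy for the residual ripple of a single
    instantaneous estimate, which converges markedly faster on long runs.
    The average over deposition indices k of the partial sums V_k reduces to
    one weighted kernel summation.
    """
    if bias.n_kernels == 0:
        raise ValueError("cannot reconstruct a FES from an empty bias")
    grid = np.asarray(grid, dtype=float)
    gamma = bias.bias_factor
    factor = 1.0 if math.isinf(gamma) else gamma / (gamma - 1.0)
    if average_from is None:
        v = bias.bias_energy(grid)
    else:
        if not 0.0 <= average_from < 1.0:
            raise ValueError("average_from must lie in [0, 1)")
        c, sig, h = bias._arrays()
        K = len(c)
        k0 = int(average_from * K)
        # Kernel j appears in V_k for k >= j; averaging V_k over k = k0..K-1
        # weights kernel j by the fraction of averaged states containing it.
        idx = np.arange(K)
        w = np.clip(K - np.maximum(idx, k0), 0, None) / (K - k0)
        g = np.exp(-0.5 * ((grid[:, None] - c[None, :]) / sig[None, :]) ** 2)
        v = (g * (h * w)[None, :]).sum(axis=1)
    return FESProfile(grid, -factor * v)


# ---------------------------------------------------------------------------
# Surrogate sampler
# ---------------------------------------------------------------------------

@dataclass
class ToySystem:
    """Overdamped scalar system: analytic potential + Langevin parameters.

    ``potential``/``gradient`` map the CV value to kJ/mol and kJ/mol per CV
    unit. ``friction`` (1/ps) sets the mobility ``dt/friction``; the noise
    variance per step is ``2 kB T dt / friction``.
    """

    potential: Callable[[float], float]
    gradient: Callable[[float], float]
    friction: float = 1.0
    temperature: float = 300.0
    timestep: float = 0.002  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")


@dataclass
class Trajectory:
    """Sampled (time, CV, bias energy) series plus the bias that produced it."""

    times: np.ndarray  # ps
    positions: np.ndarray
    bias_energies: np.ndarray
    bias: BiasPotential | None = None
    replica: int = 0

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ps": self.times, "cv": self.positions,
                      "bias_kjmol": self.bias_energies}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, replica: int = 0) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["time_ps"].to_numpy(), df["cv"].to_numpy(),
                   df["bias_kjmol"].to_numpy(), replica=replica)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ps", data=self.times)
            fh.create_dataset("cv", data=self.positions)
            fh.create_dataset("bias_kjmol", data=self.bias_energies)
            fh.attrs["replica"] = self.replica


def run_toy_sampler(
    system: ToySystem,
    bias: BiasPotential | None,
    n_steps: int,
    s0: float = 0.0,
    record_stride: int = 1,
) -> Trajectory:
    """Overdamped Langevin run with optional metadynamics deposition.

    The update rule is

        s <- s - (dU/ds + dV_bias/ds) * dt / friction + sqrt(2 kB T dt / friction) * xi

    with unit-normal ``xi``. Kernels are deposited every ``bias.pace`` ps.
    Deterministic for a given ``system.seed``. Raises if the coordinate
    leaves the finite range (too large a timestep).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(system.seed)
    dt = system.timestep
    mobility = dt / system.friction
    noise_scale = math.sqrt(2.0 * KB * system.temperature * mobility)
    pace_steps = max(1, round(bias.pace / dt)) if bias is not None else n_steps + 1

    n_rec = n_steps // record_stride + 1
    times = np.empty(n_rec)
    positions = np.empty(n_rec)
    bias_energies = np.empty(n_rec)

    s = float(s0)
    times[0], positions[0] = 0.0, s
    bias_energies[0] = bias.bias_energy(s) if bias is not None else 0.0
    rec = 1

    grad = system.gradient
    centers = np.empty(0)
    heights = np.empty(0)
    inv_sig2 = 1.0
    if bias is not None:
        c, sig, h = bias._arrays()
        centers, heights = c, h
        inv_sig2 = 1.0 / bias.sigma**2

    chunk = 10_000
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        xi = rng.standard_normal(m)
        for k in range(m):
            step += 1
            if bias is not None and step % pace_steps == 0:
                bias.deposit(s, t=step * dt)
                centers = np.asarray(bias._centers)
                heights = np.asarray(bias._heights)
            f = -grad(s)
            if centers.size:
                d = s - centers
                g = heights * np.exp(-0.5 * inv_sig2 * d * d)
                f += float((g * d).sum()) * inv_sig2
            s = s + f * mobility + noise_scale * xi[k]
            if step % record_stride == 0:
                times[rec] = step * dt
                positions[rec] = s
                if centers.size:
                    d = s - centers
                    bias_energies[rec] = float((heights * np.exp(-0.5 * inv_sig2 * d * d)).sum())
                else:
                    bias_energies[rec] = 0.0
                rec += 1
        if not math.isfinite(s):
            raise RuntimeError("sampler diverged; reduce timestep")

    return Trajectory(times[:rec], positions[:rec], bias_energies[:rec], bias=bias)


def run_replicas(
    system: ToySystem,
    bias_settings: BiasPotential,
    n_steps: int,
    n_replicas: int = 5,
    seeds: Sequence[int] | None = None,
    s0: float = 0.0,
    record_stride: int = 1,
) -> list[Trajectory]:
    """Independent replicated runs, each with its own bias state.

    Five replicas is the protocol default. ``seeds`` defaults to
    ``system.seed + replica index``; duplicate seeds only warn, since
    identical replicas are occasionally useful in testing.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if seeds is None:
        seeds = [system.seed + i for i in range(n_replicas)]
    if len(seeds) != n_replicas:
        raise ValueError("need one seed per replica")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate replica seeds; replicas will not be independent")
    out = []
    for i, seed in enumerate(seeds):
        replica_system = replace(system, seed=int(seed))
        traj = run_toy_sampler(replica_system, bias_settings.clone_settings(),
                               n_steps, s0=s0, record_stride=record_stride)
        traj.replica = i
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# PLUMED HILLS input
# ---------------------------------------------------------------------------

def read_hills(path: str | Path, temperature: float = 300.0) -> BiasPotential:
    """Read a PLUMED HILLS file (time, center, sigma, height[, biasf] columns).

    Column roles come from the ``#! FIELDS`` header: the first field is time,
    the second the kernel center, a ``sigma_*`` field the width, ``height``
    the deposited height, and ``biasf`` (if present) the bias factor. The
    returned bias replays the kernels as recorded, so
    :func:`reconstruct_fes` applies unchanged to real PLUMED output.
    """
    lines = Path(path).read_text().splitlines()
    fields: list[str] | None = None
    rows = []
    for line in lines:
        if line.startswith("#!"):
            tokens = line.split()
            if len(tokens) >= 3 and tokens[1] == "FIELDS":
                fields = tokens[2:]
            continue
        if line.strip():
            rows.append([float(tok) for tok in line.split()])
    if fields is None or not rows:
        raise ValueError(f"{path} is not a HILLS file (missing '#! FIELDS' header or data)")
    data = np.asarray(rows)
    col = {name: i for i, name in enumerate(fields)}
    time_i = col.get("time", 0)
    sigma_i = next((i for name, i in col.items() if name.startswith("sigma")), 2)
    height_i = col.get("height", 3)
    center_i = next(i for i in range(len(fields)) if i not in (time_i, sigma_i, height_i, col.get("biasf", -1)))

    bias_factor = float(data[0, col["biasf"]]) if "biasf" in col else math.inf
    if bias_factor <= 1:
        bias_factor = math.inf  # PLUMED writes biasf = -1 (or 1) for untempered runs
    pace = float(data[1, time_i] - data[0, time_i]) if len(data) > 1 else 1.0
    bias = BiasPotential(
        sigma=float(data[0, sigma_i]),
        pace=max(pace, 1e-9),
        initial_height=float(data[:, height_i].max()),
        bias_factor=bias_factor,
        temperature=temperature,
    )
    bias._centers = list(map(float, data[:, center_i]))
    bias._sigmas = list(map(float, data[:, sigma_i]))
    bias._heights = list(map(float, data[:, height_i]))
    bias._times = list(map(float, data[:, time_i]))
    return bias
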