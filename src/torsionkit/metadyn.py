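"""1-D well-tempered metadynamics on a torsional degree of freedom.

The sampler integrates overdamped (Brownian) Langevin dynamics on the
circle,

    dphi = -(1/xi) * dU/dphi * dt + sqrt(2 * kB*T * dt / xi) * dW,

whose stationary density is the Boltzmann distribution of U regardless of
the friction xi — which is all that matters here, since the sampler exists
to validate fitted torsion potentials by free-energy recovery, not to
reproduce kinetics.  Every ``pace`` steps a periodic Gaussian hill of width
sigma is deposited at the current position with the well-tempered height

    h_i = w0 * exp(-V_bias(c_i) / (kB * dT)),    dT = (gamma - 1) * T,

and the free energy is reconstructed from the accumulated bias as
F = -gamma/(gamma-1) * V_bias, min-shifted to zero.

Times are in ps-equivalents (default 2 fs step, friction 1 ps^-1-equivalent),
so the default pace of 1,000 steps deposits one hill per 2 ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import KB_KCAL, KJ_PER_KCAL, TWO_PI
from .model import DihedralSeries, TorsionProfile, series_gradient, wrap_angle
from . import _kernels

__all__ = [
    "MetaDConfig",
    "HillsLog",
    "SamplerTrajectory",
    "run_wtmetad",
    "bias_potential",
    "reconstruct_pmf",
    "averaged_pmf",
    "convergence_series",
    "torsion_occupancy_stats",
]


@dataclass
class MetaDConfig:
    """Sampler and bias settings.

    ``height_kj`` is the initial hill height w0 in kJ/mol (the unit hill
    heights are conventionally quoted in; converted to kcal/mol internally);
    sigma is the hill width in radians; ``biasfactor`` is gamma > 1.
    ``height_kj = 0`` runs plain unbiased Langevin dynamics.
    """

    height_kj: float = 0.1
    sigma: float = 0.05
    biasfactor: float = 15.0
    pace: int = 1000
    temperature: float = 300.0
    timestep: float = 0.002
    friction: float = 1.0
    n_steps: int = 1_000_000
    seed: int = 0
    x0: float = 0.0
    grid_size: int = 4096
    record_stride: int = 100

    def __post_init__(self):
        if self.height_kj < 0:
            raise ValueError("height_kj must be >= 0")
        if self.height_kj > 0 and self.biasfactor <= 1.0:
            raise ValueError("biasfactor must be > 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.height_kj > 0 and self.n_steps < self.pace:
            raise ValueError("n_steps must be >= pace")
        if self.timestep <= 0 or self.friction <= 0 or self.temperature <= 0:
            raise ValueError("timestep, friction and temperature must be positive")

    @property
    def height_kcal(self) -> float:
        return self.height_kj / KJ_PER_KCAL

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def delta_kT(self) -> float:
        """kB * dT with dT = (gamma - 1) * T, in kcal/mol."""
        return KB_KCAL * (self.biasfactor - 1.0) * self.temperature


@dataclass
class HillsLog:
    """Deposited bias history: times, centers, widths, post-tempering heights."""

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = self.times.size
        if not (self.centers.size == self.sigmas.size == self.heights.size == n):
            raise ValueError("hills columns must have equal length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("hill times must be strictly increasing")
        if n and (np.any(self.sigmas <= 0) or np.any(self.heights <= 0)):
            raise ValueError("sigmas and heights must be positive")

    def __len__(self):
        return self.times.size

    def upto(self, time: float) -> "HillsLog":
        """Sub-log of hills deposited at or before ``time``."""
        m = self.times <= time
        return HillsLog(self.times[m], self.centers[m], self.sigmas[m], self.heights[m])


@dataclass
class SamplerTrajectory:
    """Recorded walker positions and instantaneous bias energies."""

    times: np.ndarray
    positions: np.ndarray
    bias_energies: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.bias_energies = np.asarray(self.bias_energies, dtype=float)

    def __len__(self):
        return self.times.size


def _mix_seed(seed: int) -> np.uint64:
    """Python-side splitmix64 of the seed, so nearby seeds give far-apart keys."""
    x = (int(seed) + 0x9E3779B97F4A7C15) % (1 << 64)
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) % (1 << 64)
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) % (1 << 64)
    return np.uint64(x ^ (x >> 31))


def _tabulate_gradient(potential, grid_size: int) -> np.ndarray:
    """dU/dphi on the kernel's uniform periodic grid over [-pi, pi)."""
    xg = -np.pi + np.arange(grid_size) * (TWO_PI / grid_size)
    if isinstance(potential, DihedralSeries):
        return np.asarray(series_gradient(potential, xg), dtype=float)
    if isinstance(potential, TorsionProfile):
        a, e = potential.angles, potential.energies
        # periodicity check: linearly extrapolate the last interval across the
        # seam; a smooth periodic profile lands within the tolerance, a ramp
        # or otherwise non-periodic table does not
        gap = (a[0] + TWO_PI) - a[-1]
        slope = (e[-1] - e[-2]) / (a[-1] - a[-2])
        mismatch = abs((e[-1] + slope * gap) - e[0])
        tol = 1e-3 + 2.0 * np.max(np.abs(np.diff(e)))
        if mismatch > tol:
            raise ValueError(
                f"tabulated potential is not periodic: seam mismatch "
                f"{mismatch:.4g} kcal/mol exceeds tolerance {tol:.4g}")
        spline = CubicSpline(np.append(a, a[0] + TWO_PI), np.append(e, e[0]),
                             bc_type="periodic")
        return np.asarray(spline(np.where(xg < a[0], xg + TWO_PI, xg), 1), dtype=float)
    raise TypeError(f"potential must be DihedralSeries or TorsionProfile, "
                    f"got {type(potential).__name__}")


def run_wtmetad(potential, config: MetaDConfig):
    """Run WT-MetaD (or unbiased Langevin if ``height_kj == 0``).

    ``potential`` is a :class:`DihedralSeries` or a tabulated periodic
    :class:`TorsionProfile` (interpolated with a periodic cubic spline).
    Returns ``(SamplerTrajectory, HillsLog)``; both are bit-reproducible
    for a fixed seed.
    """
    du = _tabulate_gradient(potential, config.grid_size)
    n_images = int(6.0 * config.sigma // TWO_PI) + 1
    hill_t, centers, heights, rec_t, rec_x, rec_b = _kernels.run_kernel(
        du, config.n_steps, config.timestep, config.friction, config.kT,
        float(wrap_angle(config.x0)), config.pace, config.height_kcal,
        config.sigma, config.delta_kT if config.biasfactor > 1.0 else 1.0,
        _mix_seed(config.seed), config.record_stride, n_images)
    traj = SamplerTrajectory(rec_t, rec_x, rec_b)
    hills = HillsLog(hill_t, centers, np.full_like(centers, config.sigma), heights)
    return traj, hills


def bias_potential(hills: HillsLog, angles) -> np.ndarray:
    """Total deposited bias V(phi) at arbitrary query angles.

    Gaussians are truncated at 6 sigma and summed over periodic images,
    matching the deposition convention of the sampler.
    """
    phi = np.atleast_1d(np.asarray(angles, dtype=float))
    v = np.zeros_like(phi)
    if len(hills) == 0:
        return v
    n_images = int(6.0 * float(np.max(hills.sigmas)) // TWO_PI) + 1
    # chunk over hills to bound the broadcast size
    step = max(1, int(2_000_000 / max(phi.size, 1)))
    for lo in range(0, len(hills), step):
        c = hills.centers[lo:lo + step, None]
        s = hills.sigmas[lo:lo + step, None]
        h = hills.heights[lo:lo + step, None]
        d = wrap_angle(phi[None, :] - c)
        for m in range(-n_images + 1, n_images):
            dm = d + m * TWO_PI
            g = h * np.exp(-0.5 * (dm / s) ** 2)
            g[np.abs(dm) > 6.0 * s] = 0.0
            v += g.sum(axis=0)
    return v


def reconstruct_pmf(hills: HillsLog, gamma: float, grid) -> TorsionProfile:
    """Free energy from the bias: F = -gamma/(gamma-1) * V, min-shifted."""
    if gamma <= 1.0:
        raise ValueError("gamma must be > 1")
    if len(hills) == 0:
        raise ValueError("hills log is empty")
    grid = np.asarray(grid, dtype=float)
    F = -(gamma / (gamma - 1.0)) * bias_potential(hills, grid)
    return TorsionProfile(grid, F - F.min(), label="reconstructed")


def averaged_pmf(hills: HillsLog, gamma: float, grid,
                 from_fraction: float = 0.8, n_snapshots: int = 11) -> TorsionProfile:
    """Time-averaged free-energy estimate over the late, tempered regime.

    Averages :func:`reconstruct_pmf` snapshots at ``n_snapshots`` evenly
    spaced checkpoint times covering the last ``1 - from_fraction`` of the
    run, then min-shifts.  Once hills have shrunk into the tempered regime
    the instantaneous estimate fluctuates around the true profile, so the
    time average has a visibly smaller error than the final snapshot alone;
    this is the production estimator.
    """
    if not 0.0 <= from_fraction < 1.0:
        raise ValueError("from_fraction must be in [0, 1)")
    if len(hills) == 0:
        raise ValueError("hills log is empty")
    grid = np.asarray(grid, dtype=float)
    t0, t1 = hills.times[0], hills.times[-1]
    start = max(t0, t0 + from_fraction * (t1 - t0))
    checkpoints = np.linspace(start, t1, n_snapshots)
    acc = np.zeros_like(grid)
    for t in checkpoints:
        acc += reconstruct_pmf(hills.upto(t), gamma, grid).energies
    acc /= n_snapshots
    return TorsionProfile(grid, acc - acc.min(), label="reconstructed-averaged")


def convergence_series(hills: HillsLog, gamma: float, grid, checkpoints):
    """PMF reconstructed at each checkpoint time, with deviation from final.

    Returns a list of ``(time, TorsionProfile, max_abs_deviation)`` where the
    deviation is max over the grid of |F_t - F_final| after min-shifting
    both (reconstruct_pmf already min-shifts).
    """
    checkpoints = np.asarray(checkpoints, dtype=float)
    if len(hills) == 0:
        raise ValueError("hills log is empty")
    if np.any(checkpoints < hills.times[0]) or np.any(checkpoints > hills.times[-1]):
        raise ValueError("checkpoints must lie within the hills time range")
    final = reconstruct_pmf(hills, gamma, grid)
    out = []
    for t in checkpoints:
        prof = reconstruct_pmf(hills.upto(t), gamma, grid)
        dev = float(np.max(np.abs(prof.energies - final.energies)))
        out.append((float(t), prof, dev))
    return out


def torsion_occupancy_stats(traj: SamplerTrajectory, window):
    """Circular mean/std of the trajectory and time fraction inside ``window``.

    ``window = (lo, hi)`` in radians; a window with lo > hi wraps through
    the domain boundary.
    """
    from scipy.stats import circmean, circstd

    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x = traj.positions
    mean = float(circmean(x, high=math.pi, low=-math.pi))
    std = float(circstd(x, high=math.pi, low=-math.pi))
    lo, hi = window
    lo, hi = float(wrap_angle(lo)), float(wrap_angle(hi))
    if lo <= hi:
        frac = float(np.mean((x >= lo) & (x <= hi)))
    else:
        frac = float(np.mean((x >= lo) | (x <= hi)))
    return mean, std, frac
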