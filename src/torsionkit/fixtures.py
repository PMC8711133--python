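"""Deterministic synthetic inputs for every module.

These generators emulate the *shape* of the study inputs — a
benzamidine-like QM torsion scan (four equivalent minima at pi/4 + n*pi/2,
a ~4.5 kcal/mol planar barrier and a smaller perpendicular one) and 1-D
binding PMFs with a deep site minimum below a flat unbound plateau — so the
whole pipeline is testable without any external data.  Everything is a pure
function of its parameters and seed.  The benzamidine-like scan is a
synthetic stand-in for a real QM scan, not quantum-chemistry data.
"""

from __future__ import annotations

import numpy as np

from .binding import FreeEnergyProfile1D
from .model import DihedralSeries, DihedralTerm, TorsionProfile, evaluate_series

__all__ = [
    "paper_series",
    "make_scan",
    "benzamidine_like_series",
    "make_benzamidine_like_scan",
    "make_pmf",
    "make_hills",
]


def paper_series() -> DihedralSeries:
    """The published ad hoc benzamidine torsion correction.

    E(phi) = 2.4*(1 + cos(2*phi - pi)) + 1.0*(1 + cos(4*phi)) kcal/mol.
    """
    return DihedralSeries((DihedralTerm(2.4, 2, np.pi), DihedralTerm(1.0, 4, 0.0)))


def _uniform_grid(n_points: int) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_points, endpoint=False)


def make_scan(series: DihedralSeries, n_points: int = 72,
              noise_sd: float = 0.0, seed: int = 0,
              label: str = "synthetic-scan") -> TorsionProfile:
    """Evaluate a series on a uniform grid over [-pi, pi), plus i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` (kcal/mol)."""
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = _uniform_grid(n_points)
    energies = evaluate_series(series, grid)
    if noise_sd > 0:
        energies = energies + np.random.default_rng(seed).normal(0.0, noise_sd, n_points)
    return TorsionProfile(grid, energies, label=label)


def benzamidine_like_series(planar_barrier: float = 4.5,
                            perp_barrier: float = 2.5) -> DihedralSeries:
    """Cosine series with minima exactly at pi/4 + n*pi/2 (energy 0),
    maxima of height ``planar_barrier`` at 0 and pi and ``perp_barrier``
    at +/- pi/2.

    In cosine form  E = A*cos(2*phi) + B*cos(4*phi) + (A/3)*cos(6*phi) + C:
    stationarity at pi/4 fixes the n=6 coefficient to A/3, and the barrier
    conditions give A = 3*(planar - perp)/8, B = C = (planar + perp)/4.
    Three harmonics are the minimum: any series whose extrema sit exactly
    at pi/4 + n*pi/2 with only n in {4, 8, ...} has period pi/2 and hence
    equal planar and perpendicular barriers.
    """
    if planar_barrier <= 0 or perp_barrier <= 0:
        raise ValueError("barriers must be positive")
    if planar_barrier >= 5.0 * perp_barrier:
        # A >= B turns pi/2 into a minimum; outside the emulated regime
        raise ValueError("planar_barrier must be < 5 * perp_barrier")
    A = 3.0 * (planar_barrier - perp_barrier) / 8.0
    B = (planar_barrier + perp_barrier) / 4.0
    C = B
    terms = []
    offset = C
    for coef, n in ((A, 2), (B, 4), (A / 3.0, 6)):
        if coef >= 0:
            terms.append(DihedralTerm(coef, n, 0.0))
            offset -= coef
        else:
            terms.append(DihedralTerm(-coef, n, np.pi))
            offset += coef
    return DihedralSeries(tuple(terms), offset_c=offset)


def make_benzamidine_like_scan(planar_barrier: float = 4.5,
                               perp_barrier: float = 2.5,
                               n_points: int = 360,
                               noise_sd: float = 0.0,
                               seed: int = 0) -> TorsionProfile:
    """Synthetic QM-scan stand-in with the published barrier layout."""
    series = benzamidine_like_series(planar_barrier, perp_barrier)
    return make_scan(series, n_points=n_points, noise_sd=noise_sd, seed=seed,
                     label="benzamidine-like-synthetic")


def make_pmf(kind: str, **params) -> FreeEnergyProfile1D:
    """Synthetic 1-D binding PMFs.

    kinds:
      ``square_well``  — W = plateau - depth on [z0, z1], plateau elsewhere
                         (params: depth, z0=2, z1=4, plateau=0, z_max=30, n=601)
      ``harmonic``     — W = plateau - depth + 0.5*kappa*(z-z0)^2, capped at
                         plateau (params: kappa, depth, z0, plateau=0, ...)
      ``benzamidine_like`` — smooth deep site minimum plus two barrier bumps
                         on the approach, flat unbound plateau
                         (params: depth=12.5, z_min=3.0, width=0.8,
                          bump_height=1.0, z_max=30, n=601).  The default
                         depth is calibrated so that a 1 A-radius funnel
                         yields a standard binding free energy of about
                         -8.3 kcal/mol, the magnitude funnel-metadynamics
                         reports for benzamidine/trypsin.
    """
    z_max = float(params.pop("z_max", 30.0))
    n = int(params.pop("n", 601))
    plateau = float(params.pop("plateau", 0.0))
    z = np.linspace(0.0, z_max, n)

    if kind == "square_well":
        depth = float(params.pop("depth"))
        z0 = float(params.pop("z0", 2.0))
        z1 = float(params.pop("z1", 4.0))
        if depth < 0 or not (0 <= z0 < z1 <= z_max):
            raise ValueError("square well needs depth >= 0 and 0 <= z0 < z1 <= z_max")
        W = np.full_like(z, plateau)
        W[(z >= z0) & (z <= z1)] = plateau - depth
    elif kind == "harmonic":
        kappa = float(params.pop("kappa"))
        depth = float(params.pop("depth"))
        z0 = float(params.pop("z0", 3.0))
        if kappa <= 0 or depth <= 0:
            raise ValueError("harmonic well needs kappa > 0 and depth > 0")
        W = np.minimum(plateau, plateau - depth + 0.5 * kappa * (z - z0) ** 2)
    elif kind == "benzamidine_like":
        depth = float(params.pop("depth", 12.5))
        z_min = float(params.pop("z_min", 3.0))
        width = float(params.pop("width", 0.8))
        bump = float(params.pop("bump_height", 1.0))
        if depth <= 0 or width <= 0:
            raise ValueError("benzamidine-like PMF needs depth > 0 and width > 0")
        W = plateau - depth * np.exp(-0.5 * ((z - z_min) / width) ** 2)
        # intermediate barriers along the binding pathway
        W += bump * np.exp(-0.5 * ((z - (z_min + 4.0)) / 0.6) ** 2)
        W += 0.5 * bump * np.exp(-0.5 * ((z - (z_min + 7.0)) / 0.6) ** 2)
    else:
        raise ValueError(f"unknown PMF kind {kind!r}")
    if params:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(params)}")
    return FreeEnergyProfile1D(z, W)


def make_hills(n_hills: int = 100, sigma: float = 0.05,
               height: float = 0.02, dt: float = 2.0, seed: int = 0):
    """A synthetic hills log with uniform random centers (for I/O tests)."""
    from .metadyn import HillsLog

    rng = np.random.default_rng(seed)
    times = dt * np.arange(1, n_hills + 1)
    centers = rng.uniform(-np.pi, np.pi, n_hills)
    return HillsLog(times, centers, np.full(n_hills, sigma),
                    np.full(n_hills, height))
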