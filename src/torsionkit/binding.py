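"""Absolute binding free energy from a funnel-metadynamics PMF.

In funnel metadynamics the unbound ligand is confined to a cylinder of
radius R_cyl, which makes the binding constant computable from the 1-D
potential of mean force W(z) along the ligand-protein separation z:

    K_b = pi * R_cyl^2 * integral_site exp(-beta * [W(z) - W_ref]) dz

with beta = 1/(kB*T) and W_ref the PMF level in the flat unbound region.
The standard-state binding free energy follows as

    dG0 = -kB * T * ln(K_b * C0),

where C0 is the standard concentration (1 mol/L = one molecule per
1660.5389 A^3).  Internally z is in Angstrom and W in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import C0_VOLUME_A3, KB_KCAL

__all__ = [
    "FreeEnergyProfile1D",
    "FunnelGeometry",
    "WrefEstimate",
    "BindingResult",
    "estimate_wref",
    "compute_kb",
    "compute_dg0",
    "binding_report",
    "suggest_site_boundary",
]

#: Spread above which an unbound window is flagged as not flat (kcal/mol).
FLATNESS_TOL = 0.5


@dataclass
class FreeEnergyProfile1D:
    """W(z) on a strictly increasing distance grid (A, kcal/mol)."""

    z_grid: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.z_grid.shape != self.W.shape or self.z_grid.ndim != 1:
            raise ValueError("z_grid and W must be 1-D arrays of equal length")
        if self.z_grid.size < 4:
            raise ValueError("profile needs at least 4 points")
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if not (np.all(np.isfinite(self.z_grid)) and np.all(np.isfinite(self.W))):
            raise ValueError("profile values must be finite")

    def shifted(self, delta: float) -> "FreeEnergyProfile1D":
        return FreeEnergyProfile1D(self.z_grid.copy(), self.W + delta)


@dataclass(frozen=True)
class FunnelGeometry:
    """Cylinder radius and the site / unbound integration windows (A)."""

    R_cyl: float
    site_window: tuple
    unbound_window: tuple

    def __post_init__(self):
        if self.R_cyl <= 0:
            raise ValueError("R_cyl must be positive")
        s_lo, s_hi = self.site_window
        u_lo, u_hi = self.unbound_window
        if not (s_lo < s_hi and u_lo < u_hi):
            raise ValueError("windows must be (lo, hi) with lo < hi")
        if s_hi > u_lo:
            raise ValueError("site window must precede and not overlap the unbound window")


@dataclass(frozen=True)
class WrefEstimate:
    """Unbound-plateau PMF level with a flatness diagnostic."""

    value: float
    spread: float

    @property
    def plateau_not_flat(self) -> bool:
        return self.spread > FLATNESS_TOL

    def __float__(self):
        return self.value


@dataclass(frozen=True)
class BindingResult:
    K_b: float          # A^3
    W_ref: WrefEstimate  # kcal/mol
    dG0: float          # kcal/mol
    temperature: float  # K
    C0: float           # molecules / A^3
    funnel: FunnelGeometry


def _window_mask(z, window, min_points, what):
    lo, hi = window
    if lo < z[0] - 1e-9 or hi > z[-1] + 1e-9:
        raise ValueError(f"{what} window ({lo}, {hi}) outside grid span "
                         f"({z[0]}, {z[-1]})")
    mask = (z >= lo - 1e-12) & (z <= hi + 1e-12)
    if mask.sum() < min_points:
        raise ValueError(f"{what} window contains only {int(mask.sum())} grid "
                         f"points, need >= {min_points}")
    return mask


def estimate_wref(profile: FreeEnergyProfile1D, window) -> WrefEstimate:
    """Mean of W over the unbound window, with its max-min spread.

    A spread above 0.5 kcal/mol marks the plateau as not flat (the estimate
    is then window-position dependent and should be treated with care).
    """
    mask = _window_mask(profile.z_grid, window, 3, "unbound")
    w = profile.W[mask]
    return WrefEstimate(float(w.mean()), float(w.max() - w.min()))


def compute_kb(profile: FreeEnergyProfile1D, funnel: FunnelGeometry,
               temperature: float, refine: int = 1):
    """Binding constant K_b (A^3) by trapezoidal quadrature over the site.

    ``refine > 1`` subdivides each native grid interval that many times
    using a cubic-spline interpolant of W — useful on analytically smooth
    profiles; the native grid is the default since PMF grids are fine.
    Returns ``(K_b, WrefEstimate)``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    wref = estimate_wref(profile, funnel.unbound_window)
    beta = 1.0 / (KB_KCAL * temperature)
    mask = _window_mask(profile.z_grid, funnel.site_window, 2, "site")
    z = profile.z_grid[mask]
    w = profile.W[mask]
    if refine > 1:
        spline = CubicSpline(profile.z_grid, profile.W)
        zf = np.linspace(z[0], z[-1], (z.size - 1) * int(refine) + 1)
        z, w = zf, spline(zf)
    integrand = np.exp(-beta * (w - wref.value))
    integral = float(np.trapezoid(integrand, z))
    return math.pi * funnel.R_cyl ** 2 * integral, wref


def compute_dg0(K_b: float, temperature: float,
                C0: float = 1.0 / C0_VOLUME_A3) -> float:
    """Standard binding free energy dG0 = -kB*T*ln(K_b * C0), kcal/mol."""
    if K_b <= 0:
        raise ValueError("K_b must be positive")
    return -KB_KCAL * temperature * math.log(K_b * C0)


def binding_report(profile: FreeEnergyProfile1D, funnel: FunnelGeometry,
                   temperature: float = 300.0,
                   C0: float = 1.0 / C0_VOLUME_A3, refine: int = 1) -> BindingResult:
    """End-to-end K_b, W_ref and dG0 for one PMF and funnel geometry."""
    K_b, wref = compute_kb(profile, funnel, temperature, refine=refine)
    dg0 = compute_dg0(K_b, temperature, C0)
    return BindingResult(K_b=K_b, W_ref=wref, dG0=dg0,
                         temperature=temperature, C0=C0, funnel=funnel)


def suggest_site_boundary(profile: FreeEnergyProfile1D, window,
                          temperature: float = 300.0) -> float:
    """Heuristic site/bulk boundary: first z where W rises to within kB*T
    of the unbound plateau W_ref.

    Offered as a diagnostic only; the integration windows are always
    explicit user inputs.
    """
    wref = estimate_wref(profile, window)
    kT = KB_KCAL * temperature
    idx = np.nonzero(profile.W >= wref.value - kT)[0]
    below = np.nonzero(profile.W < wref.value - kT)[0]
    if below.size == 0:
        return float(profile.z_grid[0])
    first_after = idx[idx > below[0]]
    if first_after.size == 0:
        return float(profile.z_grid[-1])
    return float(profile.z_grid[first_after[0]])
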