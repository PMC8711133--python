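"""Periodic dihedral potentials and their extrema.

The force-field torsion energy is represented as a sum of Amber-style
cosine terms

    E(phi) = c + sum_i k_i * (1 + cos(n_i * phi - psi_i))

with amplitude k_i >= 0 (kcal/mol), integer periodicity n_i >= 1 and phase
psi_i (radians).  Angles live on the half-open periodic domain [-pi, pi).
Tabulated energy-vs-angle profiles (QM scans, MM baselines, reconstructed
free energies) are carried by :class:`TorsionProfile`, and
:func:`find_extrema` locates minima, maxima and barrier heights on such a
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import TWO_PI

__all__ = [
    "DihedralTerm",
    "DihedralSeries",
    "TorsionProfile",
    "ExtremaReport",
    "wrap_angle",
    "evaluate_series",
    "series_gradient",
    "series_profile",
    "find_extrema",
]


def wrap_angle(angle):
    """Wrap an angle (scalar or array) into the canonical domain [-pi, pi)."""
    return (np.asarray(angle) + np.pi) % TWO_PI - np.pi


@dataclass(frozen=True)
class DihedralTerm:
    """One cosine term ``k * (1 + cos(n*phi - psi))``."""

    amplitude_k: float
    periodicity_n: int
    phase_psi: float

    def __post_init__(self):
        if not math.isfinite(self.amplitude_k) or self.amplitude_k < 0:
            raise ValueError(f"amplitude_k must be finite and >= 0, got {self.amplitude_k}")
        if int(self.periodicity_n) != self.periodicity_n or self.periodicity_n < 1:
            raise ValueError(f"periodicity_n must be a positive integer, got {self.periodicity_n}")
        # canonicalize the phase into [0, 2*pi)
        object.__setattr__(self, "phase_psi", float(self.phase_psi) % TWO_PI)
        object.__setattr__(self, "periodicity_n", int(self.periodicity_n))
        object.__setattr__(self, "amplitude_k", float(self.amplitude_k))


@dataclass(frozen=True)
class DihedralSeries:
    """A sum of :class:`DihedralTerm` plus a constant offset (kcal/mol).

    The energy is invariant under permutation of the terms; the stored order
    is preserved for round-trip fidelity of parameter files.
    """

    terms: tuple
    offset_c: float = 0.0

    def __post_init__(self):
        terms = tuple(self.terms)
        if not terms:
            raise ValueError("DihedralSeries needs at least one term")
        for t in terms:
            if not isinstance(t, DihedralTerm):
                raise TypeError(f"terms must be DihedralTerm, got {type(t).__name__}")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "offset_c", float(self.offset_c))

    def __call__(self, angle):
        return evaluate_series(self, angle)

    def with_offset(self, offset_c: float) -> "DihedralSeries":
        return replace(self, offset_c=offset_c)

    def merged(self) -> "DihedralSeries":
        """Combine terms sharing (periodicity, phase); amplitudes add exactly.

        Terms are returned sorted by (n, psi).  Useful for comparing fits
        whose populations split one physical term across chromosome slots.
        """
        acc = {}
        for t in self.terms:
            key = (t.periodicity_n, round(t.phase_psi, 12))
            acc[key] = acc.get(key, 0.0) + t.amplitude_k
        terms = tuple(DihedralTerm(k, n, psi) for (n, psi), k in sorted(acc.items()))
        return DihedralSeries(terms, offset_c=self.offset_c)

    def canonical(self) -> "DihedralSeries":
        """Resolve each periodicity into a single term; energy is unchanged.

        Every term k*(1 + cos(n*phi - psi)) contributes the phasor
        (k*cos(psi), k*sin(psi)) at harmonic n; the resultant per n is one
        cosine of amplitude R = |sum| and phase atan2 of the sum, with the
        amplitude surplus (sum of k) - R folded into the offset.  Redundant
        representations (e.g. opposite-phase terms that partially cancel)
        map to the same canonical form.  Zero-resultant harmonics are
        dropped, keeping at least one term.
        """
        phasors = {}
        ksum = 0.0
        for t in self.terms:
            a, b = phasors.get(t.periodicity_n, (0.0, 0.0))
            phasors[t.periodicity_n] = (a + t.amplitude_k * math.cos(t.phase_psi),
                                        b + t.amplitude_k * math.sin(t.phase_psi))
            ksum += t.amplitude_k
        terms, rsum = [], 0.0
        for n, (a, b) in sorted(phasors.items()):
            r = math.hypot(a, b)
            if r > 1e-15:
                terms.append(DihedralTerm(r, n, math.atan2(b, a)))
                rsum += r
        if not terms:
            terms = [DihedralTerm(0.0, self.terms[0].periodicity_n, 0.0)]
        return DihedralSeries(tuple(terms), offset_c=self.offset_c + ksum - rsum)

    def amplitude_of(self, periodicity_n: int, phase_psi: float) -> float:
        """Total amplitude carried by the (n, psi) component (0 if absent)."""
        return sum(t.amplitude_k for t in self.terms
                   if t.periodicity_n == periodicity_n
                   and abs(wrap_angle(t.phase_psi - phase_psi)) < 1e-9)


@dataclass
class TorsionProfile:
    """Tabulated energy vs dihedral angle on one period of the circle.

    ``angles`` are strictly increasing radians within [-pi, pi); ``energies``
    are finite kcal/mol values of equal length (>= 4).
    """

    angles: np.ndarray
    energies: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.ndim != 1 or self.angles.shape != self.energies.shape:
            raise ValueError("angles and energies must be 1-D arrays of equal length")
        if self.angles.size < 4:
            raise ValueError("profile needs at least 4 points")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < -np.pi - 1e-12 or self.angles[-1] >= np.pi:
            raise ValueError("angles must lie within one period [-pi, pi)")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    def __len__(self):
        return self.angles.size

    def min_shifted(self) -> "TorsionProfile":
        """Return a copy with the global minimum shifted to zero."""
        return TorsionProfile(self.angles.copy(), self.energies - self.energies.min(),
                              label=self.label)


@dataclass
class ExtremaReport:
    """Minima, maxima and barriers of a periodic torsion profile.

    ``barriers`` holds one entry per (minimum, adjacent maximum) pair as
    ``(minimum_angle, maximum_angle, height)`` with height >= 0 in kcal/mol.
    ``grid_too_coarse`` flags profiles whose extrema are separated by fewer
    than two grid points, where the quadratic refinement is unreliable.
    """

    minima: list = field(default_factory=list)
    maxima: list = field(default_factory=list)
    barriers: list = field(default_factory=list)
    grid_too_coarse: bool = False

    @property
    def global_barrier(self) -> float:
        """Largest barrier height, 0.0 if the profile has no extrema."""
        return max((b[2] for b in self.barriers), default=0.0)

    def barrier_over(self, angle: float, tol: float = 0.3) -> float:
        """Largest barrier whose maximum lies within ``tol`` rad of ``angle``."""
        best = [b[2] for b in self.barriers
                if abs(wrap_angle(b[1] - angle)) <= tol]
        if not best:
            raise ValueError(f"no barrier maximum within {tol} rad of {angle}")
        return max(best)


def evaluate_series(series: DihedralSeries, angle):
    """Evaluate the cosine series at ``angle`` (any real; 2*pi-periodic).

    Accepts scalars or arrays and returns energies in kcal/mol.
    """
    phi = np.asarray(angle, dtype=float)
    out = np.full_like(phi, series.offset_c, dtype=float)
    for t in series.terms:
        out += t.amplitude_k * (1.0 + np.cos(t.periodicity_n * phi - t.phase_psi))
    if np.ndim(angle) == 0:
        return float(out)
    return out


def series_gradient(series: DihedralSeries, angle):
    """dE/dphi of the series, kcal/mol/rad."""
    phi = np.asarray(angle, dtype=float)
    out = np.zeros_like(phi, dtype=float)
    for t in series.terms:
        out -= t.amplitude_k * t.periodicity_n * np.sin(t.periodicity_n * phi - t.phase_psi)
    if np.ndim(angle) == 0:
        return float(out)
    return out


def series_profile(series: DihedralSeries, grid) -> TorsionProfile:
    """Tabulate the series on ``grid`` (strictly increasing, one period)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    return TorsionProfile(grid, evaluate_series(series, grid), label="model")


def _refine_quadratic(x0, x1, x2, y0, y1, y2):
    """Vertex of the parabola through three points; x unwrapped locally.

    Falls back to the middle point for degenerate (collinear) triplets.
    """
    # unwrap neighbours around x1 so the triplet is monotone in x
    a = x1 + wrap_angle(x0 - x1)
    c = x1 + wrap_angle(x2 - x1)
    denom = (a - x1) * (a - c) * (x1 - c)
    if denom == 0.0:
        return x1, y1
    # Lagrange quadratic coefficients
    A = (c * (y1 - y0) + x1 * (y0 - y2) + a * (y2 - y1)) / denom
    if A == 0.0:
        return x1, y1
    B = (c * c * (y0 - y1) + x1 * x1 * (y2 - y0) + a * a * (y1 - y2)) / denom
    xv = -B / (2.0 * A)
    # keep the refinement inside the bracketing interval
    if not (min(a, c) <= xv <= max(a, c)):
        return x1, y1
    C = y1 - A * x1 * x1 - B * x1
    return xv, A * xv * xv + B * xv + C


def find_extrema(profile: TorsionProfile) -> ExtremaReport:
    """Locate minima, maxima and barriers of a periodic profile.

    Extrema are detected by sign changes of the periodic finite difference
    and refined with a 3-point parabola.  For flat plateaus the leftmost
    grid point of the plateau is reported.  A constant profile yields an
    empty report.
    """
    x = profile.angles
    y = profile.energies
    n = x.size
    dy = np.roll(y, -1) - y  # dy[i] = y[i+1] - y[i], periodic

    if np.all(dy == 0.0):
        return ExtremaReport()

    # sign of the slope on each interval, carrying the last nonzero sign
    # backwards through plateaus so that the leftmost plateau point wins
    sgn = np.sign(dy)
    filled = sgn.copy()
    nz = np.nonzero(sgn)[0]
    # propagate the *next* nonzero sign into zero runs (scan right to left)
    nxt = sgn[nz[0]]
    for i in range(n - 1, -1, -1):
        if filled[i] == 0.0:
            filled[i] = nxt
        else:
            nxt = filled[i]

    minima, maxima = [], []
    for i in range(n):
        prev = filled[(i - 1) % n]
        cur = filled[i]
        if sgn[(i - 1) % n] == 0.0 and sgn[i] == 0.0:
            continue  # interior of a plateau
        if prev < 0 and cur > 0:
            kind = minima
        elif prev > 0 and cur < 0:
            kind = maxima
        else:
            continue
        if sgn[(i - 1) % n] == 0.0 or sgn[i] == 0.0:
            # plateau edge: report the leftmost grid point of the flat run
            j = i
            while sgn[(j - 1) % n] == 0.0 and j != (i + 1) % n:
                j = (j - 1) % n
            kind.append((float(x[j]), float(y[j])))
        else:
            xv, yv = _refine_quadratic(x[(i - 1) % n], x[i], x[(i + 1) % n],
                                       y[(i - 1) % n], y[i], y[(i + 1) % n])
            kind.append((float(wrap_angle(xv)), float(yv)))

    minima.sort()
    maxima.sort()

    report = ExtremaReport(minima=minima, maxima=maxima)
    if not minima or not maxima:
        return report

    # adjacency check: extrema closer than 2 grid points apart
    spacing = TWO_PI / n
    allx = sorted([m[0] for m in minima] + [m[0] for m in maxima])
    gaps = np.diff(allx + [allx[0] + TWO_PI])
    if np.any(gaps < 2 * spacing):
        report.grid_too_coarse = True

    # barriers: every maximum paired with its two circularly adjacent minima
    for mx_ang, mx_e in maxima:
        dists = wrap_angle(np.array([m[0] for m in minima]) - mx_ang)
        left_candidates = [(d, i) for i, d in enumerate(dists) if d < 0] or \
                          [(d - TWO_PI, i) for i, d in enumerate(dists)]
        right_candidates = [(d, i) for i, d in enumerate(dists) if d > 0] or \
                           [(d + TWO_PI, i) for i, d in enumerate(dists)]
        left = max(left_candidates)[1]
        right = min(right_candidates)[1]
        for mi in {left, right}:
            mn_ang, mn_e = minima[mi]
            report.barriers.append((mn_ang, float(mx_ang), float(mx_e - mn_e)))
    report.barriers.sort(key=lambda b: (b[1], b[0]))
    return report
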