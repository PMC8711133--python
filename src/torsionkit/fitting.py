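"""Fitting a dihedral cosine series to a torsion-scan target.

The target is the QM scan, optionally minus an MM baseline computed on the
same grid (both min-shifted first), so the fitted series is the torsion
*correction* the force field is missing.  Two fitters are provided:

* :func:`fit_least_squares` — for a fixed set of (periodicity, phase)
  basis functions the model is linear in the amplitudes, so the weighted
  normal equations give the global optimum.  This is the deterministic
  oracle.
* :func:`fit_series_ga` — a genetic algorithm over chromosomes of
  (amplitude, periodicity, phase) terms with tournament selection, uniform
  crossover, multi-scale Gaussian amplitude mutation and elitism, fully
  reproducible given a seed.  This mirrors how torsion corrections are
  fitted in practice when the basis is not known in advance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL, TWO_PI
from .model import (DihedralSeries, DihedralTerm, TorsionProfile,
                    evaluate_series, find_extrema, series_profile, wrap_angle)

__all__ = [
    "FitTarget",
    "GAConfig",
    "FitResult",
    "build_fit_target",
    "fit_least_squares",
    "fit_series_ga",
    "barrier_agreement",
]


@dataclass
class FitTarget:
    """Grid, target energies and per-point weights for a torsion fit."""

    grid: np.ndarray
    target_energies: np.ndarray
    weights: np.ndarray
    baseline_subtracted: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.target_energies = np.asarray(self.target_energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.grid.shape == self.target_energies.shape == self.weights.shape):
            raise ValueError("grid, target_energies and weights must have equal length")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    The search space is small (a handful of terms with discrete periodicity
    and phase), so a modest population and generation count converge; all
    values are exposed through the toolkit config file.
    """

    population_size: int = 64
    generations: int = 500
    mutation_rate: float = 0.2
    crossover_rate: float = 0.8
    allowed_periodicities: tuple = (1, 2, 3, 4, 5, 6)
    allowed_phases: tuple = (0.0, math.pi)
    amplitude_bounds: tuple = (0.0, 10.0)
    seed: int = 0
    max_terms: int = 4
    tournament_size: int = 3
    stall_generations: int = 50
    stall_tol: float = 1e-6

    def __post_init__(self):
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("rates must be probabilities in [0, 1]")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        lo, hi = self.amplitude_bounds
        if lo < 0 or lo > hi:
            raise ValueError("amplitude_bounds must satisfy 0 <= lo <= hi")
        if len(self.allowed_periodicities) == 0:
            raise ValueError("allowed_periodicities must not be empty")
        self.allowed_periodicities = tuple(sorted(int(n) for n in self.allowed_periodicities))
        if any(n < 1 for n in self.allowed_periodicities):
            raise ValueError("periodicities must be positive integers")
        self.allowed_phases = tuple(float(p) % TWO_PI for p in self.allowed_phases)


@dataclass
class FitResult:
    series: DihedralSeries
    rmse: float
    residuals: np.ndarray
    generations_run: int = 0
    converged: bool = True
    metadata: dict = field(default_factory=dict)


def build_fit_target(qm: TorsionProfile, mm_baseline: TorsionProfile | None = None,
                     weighting: str = "uniform", temperature: float = 300.0) -> FitTarget:
    """Build the fit target from a QM profile and an optional MM baseline.

    Both profiles are min-shifted to zero before the pointwise subtraction
    ``target = qm - mm_baseline``; with no baseline the target is the
    (min-shifted) QM profile itself.  ``weighting="boltzmann"`` assigns
    ``w_i = exp(-E_i / kT)`` on the QM energies, normalized to mean 1.
    """
    grid = qm.angles
    qm_e = qm.energies - qm.energies.min()
    if mm_baseline is not None:
        if len(mm_baseline) != len(qm):
            raise ValueError("QM and MM baseline grids differ in length")
        mism = np.nonzero(np.abs(mm_baseline.angles - grid) > 1e-6)[0]
        if mism.size:
            pts = ", ".join(f"{grid[i]:.6f}!={mm_baseline.angles[i]:.6f}" for i in mism[:8])
            raise ValueError(f"grid mismatch between QM and baseline at: {pts}")
        target = qm_e - (mm_baseline.energies - mm_baseline.energies.min())
    else:
        target = qm_e

    if weighting == "uniform":
        weights = np.ones_like(target)
    elif weighting == "boltzmann":
        w = np.exp(-qm_e / (KB_KCAL * temperature))
        weights = w / w.mean()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return FitTarget(grid, target, weights, baseline_subtracted=mm_baseline is not None)


def _design_matrix(grid, basis):
    """Columns ``1 + cos(n*phi - psi)`` for each (n, psi), plus the offset."""
    cols = [1.0 + np.cos(n * grid - psi) for n, psi in basis]
    cols.append(np.ones_like(grid))
    return np.column_stack(cols)


def _weighted_rmse(residuals, weights):
    return float(np.sqrt(np.sum(weights * residuals ** 2) / np.sum(weights)))


def fit_least_squares(target: FitTarget, basis) -> FitResult:
    """Exact weighted linear least squares for a fixed (n, psi) basis.

    Amplitudes may come out negative; a negative amplitude k is folded into
    the phase afterwards via ``k(1+cos(x)) = |k|(1+cos(x-pi)) + 2k`` so the
    returned series respects the k >= 0 invariant.
    """
    basis = [(int(n), float(psi) % TWO_PI) for n, psi in basis]
    if not basis:
        raise ValueError("basis must not be empty")
    if len(target.grid) < len(basis) + 1:
        raise ValueError("need at least len(basis)+1 grid points")
    A = _design_matrix(target.grid, basis)
    sw = np.sqrt(target.weights)
    Aw = A * sw[:, None]
    bw = target.target_energies * sw
    # rank check catches duplicate basis entries and the {(n,0),(n,pi)}+offset
    # collinearity before lstsq silently regularizes them away
    s = np.linalg.svd(Aw, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError(f"rank-deficient design for basis {basis}")
    coef, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
    amps, offset = coef[:-1], float(coef[-1])

    terms = []
    for (n, psi), k in zip(basis, amps):
        k = float(k)
        if k < 0:
            offset += 2.0 * k
            k, psi = -k, (psi + math.pi) % TWO_PI
        terms.append(DihedralTerm(k, n, psi))
    series = DihedralSeries(tuple(terms), offset_c=offset)
    residuals = evaluate_series(series, target.grid) - target.target_energies
    return FitResult(series, _weighted_rmse(residuals, target.weights), residuals,
                     metadata={"method": "least_squares", "basis": basis})


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------
# A chromosome is a fixed-length array of max_terms slots, each (k, n, psi);
# slots with k == 0 are dormant but still recombine.  The constant offset is
# not part of the chromosome: for given amplitudes the optimal offset is the
# weighted mean residual, computed in closed form inside the fitness.

_MUTATION_SCALES = np.array([0.5, 0.05, 0.005, 5e-4])


def _chrom_rmse(chrom, grid, target, weights, wsum):
    model = np.zeros_like(grid)
    for k, n, psi in chrom:
        if k != 0.0:
            model += k * (1.0 + np.cos(n * grid - psi))
    resid = target - model
    offset = float(np.sum(weights * resid) / wsum)
    resid = resid - offset
    return float(np.sqrt(np.sum(weights * resid ** 2) / wsum)), offset


def _random_chrom(rng, cfg):
    lo, hi = cfg.amplitude_bounds
    chrom = []
    for _ in range(cfg.max_terms):
        active = rng.random() < 0.7
        k = rng.uniform(lo, min(hi, lo + 5.0)) if active else 0.0
        n = int(rng.choice(cfg.allowed_periodicities))
        psi = float(rng.choice(cfg.allowed_phases))
        chrom.append((k, n, psi))
    return tuple(chrom)


def _mutate(chrom, rng, cfg):
    lo, hi = cfg.amplitude_bounds
    out = []
    for k, n, psi in chrom:
        if rng.random() < cfg.mutation_rate:
            scale = _MUTATION_SCALES[rng.integers(len(_MUTATION_SCALES))]
            k = float(np.clip(k + rng.normal(0.0, scale), lo, hi))
            if rng.random() < 0.25:  # structural move: new (n, psi)
                n = int(rng.choice(cfg.allowed_periodicities))
                psi = float(rng.choice(cfg.allowed_phases))
            if rng.random() < 0.05:  # pruning move: switch the slot off
                k = 0.0
        out.append((k, n, psi))
    return tuple(out)


def _crossover(a, b, rng, cfg):
    if rng.random() >= cfg.crossover_rate:
        return a, b
    mask = rng.random(cfg.max_terms) < 0.5
    child1 = tuple(a[i] if mask[i] else b[i] for i in range(cfg.max_terms))
    child2 = tuple(b[i] if mask[i] else a[i] for i in range(cfg.max_terms))
    return child1, child2


def _active_terms(chrom):
    return tuple((k, n, psi) for k, n, psi in chrom if k != 0.0)


def _tiebreak_key(chrom):
    active = _active_terms(chrom)
    return (len(active), tuple(sorted((n, psi) for _, n, psi in active)))


def fit_series_ga(target: FitTarget, config: GAConfig | None = None) -> FitResult:
    """Fit a dihedral series to the target by genetic algorithm.

    Fitness is the negative weighted RMSE (offset optimized in closed form
    per individual).  Tournament selection, uniform crossover, multi-scale
    Gaussian amplitude mutation, elitism of one; stops after the configured
    number of generations or once the best RMSE has improved by less than
    ``stall_tol`` for ``stall_generations`` consecutive generations.
    Bit-reproducible for a fixed seed.
    """
    cfg = config or GAConfig()
    if len(target.grid) < 8:
        raise ValueError("target needs at least 8 grid points")
    rng = np.random.default_rng(cfg.seed)
    grid, tgt, w = target.grid, target.target_energies, target.weights
    wsum = float(np.sum(w))

    pop = [_random_chrom(rng, cfg) for _ in range(cfg.population_size)]
    scores = [_chrom_rmse(c, grid, tgt, w, wsum) for c in pop]

    def better(i, j):
        # lower rmse wins; ties broken toward fewer terms, then lex (n, psi)
        if abs(scores[i][0] - scores[j][0]) > 1e-15:
            return i if scores[i][0] < scores[j][0] else j
        return i if _tiebreak_key(pop[i]) <= _tiebreak_key(pop[j]) else j

    best_idx = 0
    for i in range(1, len(pop)):
        best_idx = better(best_idx, i)
    best_chrom, best_score = pop[best_idx], scores[best_idx]
    stall, gen = 0, 0

    for gen in range(1, cfg.generations + 1):
        new_pop = [best_chrom]  # elitism of 1
        while len(new_pop) < cfg.population_size:
            idx = rng.integers(len(pop), size=cfg.tournament_size)
            p1 = min(idx, key=lambda i: (scores[i][0], _tiebreak_key(pop[i])))
            idx = rng.integers(len(pop), size=cfg.tournament_size)
            p2 = min(idx, key=lambda i: (scores[i][0], _tiebreak_key(pop[i])))
            c1, c2 = _crossover(pop[p1], pop[p2], rng, cfg)
            new_pop.append(_mutate(c1, rng, cfg))
            if len(new_pop) < cfg.population_size:
                new_pop.append(_mutate(c2, rng, cfg))
        pop = new_pop
        scores = [_chrom_rmse(c, grid, tgt, w, wsum) for c in pop]
        gen_best = 0
        for i in range(1, len(pop)):
            gen_best = better(gen_best, i)
        improvement = best_score[0] - scores[gen_best][0]
        if scores[gen_best][0] < best_score[0] or (
                scores[gen_best][0] == best_score[0]
                and _tiebreak_key(pop[gen_best]) < _tiebreak_key(best_chrom)):
            best_chrom, best_score = pop[gen_best], scores[gen_best]
        stall = stall + 1 if improvement < cfg.stall_tol else 0
        if stall >= cfg.stall_generations:
            break

    rmse, offset = best_score
    active = _active_terms(best_chrom)
    if active:
        terms = tuple(DihedralTerm(k, n, psi) for k, n, psi in active)
    else:  # zero target: keep a single dormant term to satisfy the invariant
        _, n, psi = best_chrom[0]
        terms = (DihedralTerm(0.0, n, psi),)
    # canonical form: one resultant cosine per periodicity, same energy
    series = DihedralSeries(terms, offset_c=offset).canonical()
    residuals = evaluate_series(series, grid) - tgt
    return FitResult(series, rmse, residuals, generations_run=gen,
                     converged=stall >= cfg.stall_generations or gen == cfg.generations,
                     metadata={"method": "ga", "seed": cfg.seed,
                               "baseline_subtracted": target.baseline_subtracted})


def best_two_term_ls(target: FitTarget, periodicities, phases) -> FitResult:
    """Exhaustive least squares over all 2-element (n, psi) bases.

    Rank-deficient pairs (e.g. {(n,0),(n,pi)}, which are collinear with the
    offset) are skipped.  Used as the optimality oracle for the GA.
    """
    pairs = [(n, p) for n in periodicities for p in phases]
    best = None
    for b in itertools.combinations(pairs, 2):
        try:
            res = fit_least_squares(target, list(b))
        except ValueError:
            continue
        if best is None or res.rmse < best.rmse:
            best = res
    if best is None:
        raise ValueError("no full-rank 2-term basis available")
    return best


def barrier_agreement(model: DihedralSeries, baseline: TorsionProfile | None,
                      reference: TorsionProfile) -> float:
    """Largest absolute barrier-height difference, model total vs reference.

    The model total profile is the fitted series evaluated on the reference
    grid plus the MM baseline (if one was subtracted during fitting).
    Barriers are paired by nearest maximum angle on the circle; differing
    extrema counts are an error because the pairing would be ambiguous.
    """
    grid = reference.angles
    total = evaluate_series(model, grid)
    if baseline is not None:
        if len(baseline) != len(reference) or np.any(
                np.abs(baseline.angles - grid) > 1e-6):
            raise ValueError("baseline grid must match the reference grid")
        total = total + baseline.energies
    model_profile = TorsionProfile(grid, total, label="model-total")

    rep_m = find_extrema(model_profile)
    rep_r = find_extrema(reference)
    if len(rep_m.maxima) != len(rep_r.maxima) or len(rep_m.minima) != len(rep_r.minima):
        raise ValueError(
            "differing numbers of extrema: model "
            f"{len(rep_m.minima)} min/{len(rep_m.maxima)} max "
            f"(minima {[round(a, 3) for a, _ in rep_m.minima]}, "
            f"maxima {[round(a, 3) for a, _ in rep_m.maxima]}) vs reference "
            f"{len(rep_r.minima)} min/{len(rep_r.maxima)} max "
            f"(minima {[round(a, 3) for a, _ in rep_r.minima]}, "
            f"maxima {[round(a, 3) for a, _ in rep_r.maxima]})")

    worst = 0.0
    for mn_ang, mx_ang, height in rep_r.barriers:
        # nearest model maximum on the circle
        dists = [abs(wrap_angle(bm[1] - mx_ang)) for bm in rep_m.barriers]
        j = int(np.argmin(dists))
        worst = max(worst, abs(rep_m.barriers[j][2] - height))
    return worst
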