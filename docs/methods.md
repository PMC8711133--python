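# Methods

## The problem

Small-molecule force fields assign torsion parameters by atom-type analogy,
which fails for ligands with partially conjugated groups: for benzamidine,
general-purpose libraries underestimate the rotation barrier between the
amidine group and the phenyl ring by several kcal/mol, letting simulations
visit the planar conformation far too often and distorting binding
free-energy landscapes. The remedy is to refit the torsion term against a
quantum-mechanical (QM) dihedral scan, validate the new parameters by an
enhanced-sampling run on the torsion itself, and check the downstream
observable — the absolute binding free energy from a funnel-metadynamics
potential of mean force (PMF). `torsionkit` implements that workflow for
1-D torsion profiles and 1-D binding PMFs; it does not run QM or all-atom
MD itself.

## Torsion model

The force-field torsion energy is the Amber cosine series

    E(phi) = c + sum_i k_i (1 + cos(n_i phi - psi_i)),

with amplitudes `k_i >= 0` (kcal/mol), integer periodicities `n_i >= 1` and
phases `psi_i` in `[0, 2pi)`. Angles are radians on the half-open periodic
domain `[-pi, pi)`; energies are kcal/mol internally (kJ/mol, hartree and
degree dialects are converted at the I/O boundary: 4.184 kJ/kcal,
627.509474 kcal/hartree). The reference benzamidine correction is the
two-term series `2.4 (1 + cos(2 phi - pi)) + 1.0 (1 + cos(4 phi))`.

A series is not uniquely parameterized: terms sharing a periodicity add as
phasors (`k cos(n phi - psi) = k cos psi cos n phi + k sin psi sin n phi`),
so `DihedralSeries.canonical()` resolves each harmonic into one resultant
cosine, folding the amplitude surplus into the constant offset. All
amplitude comparisons in the test suite are made on canonical forms.

Extrema of tabulated profiles are located by sign change of the periodic
finite difference and refined with a 3-point parabola — deterministic, no
smoothing parameter, and accurate to `O(h^2)` in the grid spacing (the
suite checks 1e-3 rad / 1e-4 kcal/mol agreement against a 200,000-point
brute-force scan for series with up to 4 terms and n <= 6). Flat plateaus
report their leftmost grid point; profiles whose extrema are separated by
fewer than two grid points carry a `grid_too_coarse` flag instead of a
silent wrong answer. Barrier heights are differences (maximum energy minus
circularly adjacent minimum energy), hence invariant under any constant
shift of the profile.

## Fit target and fitters

The fit target is the QM scan minus an optional MM baseline evaluated on
the same grid (both min-shifted to zero first), so the fitted series is
the torsion *correction* missing from the force field. Whether a baseline
should be subtracted at all is left to the user — both modes are supported
and recorded in the result metadata — because either convention is
defensible: fitting the raw QM profile folds the molecule's non-bonded 1-4
interactions into the torsion term, while subtracting an MM baseline
isolates the pure dihedral correction. Relatedly, the reference two-term
series above has its largest maximum at `±pi/2` while the QM-like profile
has it at the planar angle 0: the printed dihedral term evidently acts *on
top of* non-bonded contributions, and nothing in this package assumes the
dihedral term alone reproduces the QM curve. Weighting is uniform by
default; Boltzmann weighting `w_i = exp(-E_i/kT)` at T = 300 K (normalized
to mean 1) is available to emphasize minima.

Two fitters share this target:

* **Weighted linear least squares** (`fit_least_squares`): for fixed
  `(n, psi)` basis functions the model is linear in the amplitudes, so the
  normal equations give the global optimum. A singular-value check rejects
  rank-deficient designs — duplicate basis entries, and the less obvious
  `{(n, 0), (n, pi)}` pair whose columns sum to a constant and are
  collinear with the offset. Negative amplitudes are folded into the phase
  (`k(1+cos x) = |k|(1+cos(x-pi)) + 2k`) so the returned series respects
  `k >= 0`. This is the deterministic oracle the stochastic fitter is
  measured against.

* **Genetic algorithm** (`fit_series_ga`): chromosomes are `max_terms = 4`
  slots of `(k, n, psi)` with `n` and `psi` drawn from configured discrete
  sets (defaults: n in {1..6}, psi in {0, pi}, preserving the phi -> -phi
  symmetry of the molecule; continuous phases are a config flag away).
  Fitness is negative weighted RMSE with the offset solved in closed form
  per individual. Tournament selection (size 3), uniform crossover (rate
  0.8), elitism of one, and a multi-scale Gaussian amplitude mutation
  (rate 0.2; kick widths 0.5, 0.05, 5e-3, 5e-4 kcal/mol chosen uniformly,
  plus low-probability structural moves that reassign `(n, psi)` or switch
  a slot off). The multi-scale kick is what lets a plain GA refine
  amplitudes to within 1e-3 kcal/mol of the least-squares optimum without
  any gradient step. Population 64, up to 500 generations, early stop
  after 50 generations with < 1e-6 kcal/mol improvement; ties break toward
  fewer terms, then lexicographic `(n, psi)`. Runs are bit-reproducible
  given the seed.

Fit quality is summarized by `barrier_agreement`: the model-total profile
(series plus baseline, if any) and the reference are both sent through the
extrema analysis, barriers are paired by nearest maximum angle on the
circle, and the largest absolute height difference is returned. The
0.5 kcal/mol bar used in the acceptance suite is the quality level at
which a refitted topology is considered to reproduce its QM target.

## Validation sampler

Fitted potentials are validated the same way refitted topologies are
validated in practice: a well-tempered metadynamics (WT-MetaD) run on the
torsion, checking that the reconstructed free energy returns the input
potential. The dynamics is overdamped Langevin on the circle,

    d phi = -(1/xi) U'(phi) dt + sqrt(2 kB T dt / xi) dW,

integrated by Euler-Maruyama. Overdamped dynamics was chosen over inertial
MD deliberately: for a single periodic coordinate the stationary density
is the Boltzmann distribution of U regardless of friction, and the
sampler's purpose is free-energy recovery, not kinetics. Defaults are a
2 fs-equivalent timestep (0.002 ps), friction 1 ps^-1-equivalent and
T = 300 K; with the default deposition pace of 1,000 steps one hill lands
every 2 ps, so 5e7 steps correspond to the 100 ns horizon over which such
torsion runs converge.

Bias deposition follows the well-tempered rule: every `pace` steps a
periodic Gaussian of width sigma is added at the current position with
height `h_i = w0 exp(-V(c_i) / (kB dT))`, `dT = (gamma - 1) T`. Default
bias settings mirror the validation protocol: initial height 0.1 kJ/mol
(0.0239 kcal/mol), sigma 0.05 rad, biasfactor gamma = 15, pace 1,000.
Heights are stored post-tempering, and `V(c_i)` is computed as the *exact*
sum over prior hills (Gaussians truncated at 6 sigma, ~1e-8 tail error,
summed over periodic images), so the tempering identity is recomputable
from the hills log alone to 1e-9 — the suite checks this. The force on the
walker, by contrast, interpolates the bias linearly from a 4,096-point
periodic grid updated once per deposition; at sigma = 0.05 rad a hill
spans ~33 grid points, making the interpolation error negligible against
the thermal noise while keeping the inner loop O(1) per step (the loop is
numba-compiled; 5e7 steps run in ~30 s on one core).

Per-step noise is counter-based: step `i` hashes `(seed, i)` through
splitmix64 and Box-Muller. Depositions therefore consume no randomness and
changing the pace never perturbs the noise stream; identical seeds give
bit-identical trajectories and hills.

Free energies follow from `F = -gamma/(gamma-1) V`, min-shifted. Two
estimators are provided: `reconstruct_pmf` (the final-bias formula above)
and `averaged_pmf`, which averages reconstruction snapshots over the last
20% of the run. Once hills have shrunk into the tempered regime the
instantaneous estimate fluctuates around the true profile, so the time
average is the production estimator: on the 4.5 kcal/mol double well at
the default settings the final snapshot recovers the well to ~0.15-0.35
kcal/mol depending on seed, the tail average to ~0.18-0.24.
`convergence_series` reports the checkpointed deviation-from-final curve
used to judge convergence. Tabulated (non-analytic) potentials are
interpolated with a periodic cubic spline after a seam check: the last
interval is linearly extrapolated across the periodic boundary and a
mismatch beyond `1e-3 + 2 max|dE|` kcal/mol is rejected as non-periodic.

The unbiased integrator is itself validated against a quadrature Boltzmann
density via a chi-square test (24 bins, samples subsampled every 10,000
steps — about ten within-well relaxation times — so counts are effectively
independent). A calibrated test at alpha = 0.01 rejects ~1% of seeds by
construction; the acceptance script therefore reports the median p-value
of three replicas.

## Binding free energy

Funnel metadynamics confines the unbound ligand to a cylinder of radius
`R_cyl`, which makes the binding constant a 1-D integral over the PMF
W(z) along the ligand-protein separation:

    K_b  = pi R_cyl^2  integral_site  exp(-beta [W(z) - W_ref]) dz
    dG0  = -kB T ln(K_b C0)

with `kB = 0.0019872041 kcal mol^-1 K^-1` and the standard concentration
`C0 = 1 mol/L = 1/1660.5389 A^-3`. `W_ref` is defined here as the mean of
W over an explicit, user-supplied unbound window — the definition is a
genuine free choice, and an explicit window makes the estimator auditable;
a max-min spread above 0.5 kcal/mol flags the plateau as not flat. The
site window is likewise always explicit; a heuristic boundary (first z
where W rises to within kB T of W_ref) is offered as a diagnostic but
never applied silently. Quadrature is trapezoidal on the native grid (PMF
grids are already fine); an optional cubic-spline refinement exists for
analytically smooth fixtures, where the suite verifies the square-well and
harmonic-well closed forms to 1e-6 and the flat-well volume `pi R^2 L` to
1e-9. Exact identities — dG0 depends on W only through W - W_ref, and
`d dG0 / d ln R_cyl^2 = -kB T` — are tested directly.

## Synthetic fixtures

All inputs are generated in-package; nothing is downloaded and no file is
claimed to be QM or simulation data.

* **Benzamidine-like scan**: a smooth periodic profile with four
  equivalent minima exactly at `pi/4 + n pi/2` (energy 0), a 4.5 kcal/mol
  planar barrier and a 2.5 kcal/mol perpendicular barrier — the published
  barrier layout. Hitting those extremum positions and two *unequal*
  barriers requires three harmonics: in the form
  `A cos 2phi + B cos 4phi + (A/3) cos 6phi + C`, stationarity at `pi/4`
  fixes the n = 6 coefficient to A/3, and the barrier conditions give
  `A = 3(planar - perp)/8`, `B = C = (planar + perp)/4`. (Any series
  stationary at `pi/4 + n pi/2` using only n in {4, 8, ...} has period
  pi/2 and hence equal barriers — two terms cannot do it.)
* **Noisy scans**: a series evaluated on a uniform grid plus i.i.d.
  Gaussian noise of chosen standard deviation, seeded.
* **Binding PMFs**: square well and truncated harmonic well (closed-form
  K_b for quadrature tests), and a benzamidine-like PMF — a Gaussian site
  minimum at z = 3 A (width 0.8 A) below a flat plateau, with two smaller
  barrier bumps on the approach path emulating the staged binding
  pathway. Its default depth of 12.5 kcal/mol is calibrated so that a
  1 A-radius funnel yields dG0 ~ -8.3 kcal/mol, the magnitude
  funnel-metadynamics reports for benzamidine/trypsin; the PMF minimum is
  necessarily deeper than |dG0| because the standard-state volume term is
  entropically unfavourable.

What these fixtures deliberately do not emulate: QM electronic effects
(the scan is an analytic cosine curve, not a quantum calculation),
coupling of the torsion to other degrees of freedom, solvent, and the 2-D
(distance, orientation) structure of real funnel-metadynamics surfaces.
Passing tests therefore demonstrate that the fitting, sampling and
integration machinery is correct at the published operating point — not
that any specific molecule is well parameterized.

## Numerical choices and degenerate inputs

* Periodic wrapping is always to `[-pi, pi)`, half-open, everywhere.
* Duplicate scan angles after wrapping (within 1e-9 rad) are an error, as
  are non-finite energies and decreasing hill times.
* frcmod DIHE records write PK with 3 decimals and phases with 1 decimal
  (degrees) — enough to round-trip the reference parameters exactly;
  multi-term dihedrals use the negative-PN continuation convention and a
  chain left dangling at the end of a block is an error. GROMACS export
  writes function-type-9 lines with `%.10g` precision so amplitudes
  survive a round trip to 1e-9.
* A constant torsion profile yields an empty extrema report, not an error.
* Problem sizes used by the test suite and the acceptance script: 120-720
  point scan grids, 5e7-step metadynamics runs (50,000 hills), 1.2e7-step
  unbiased runs, 601-30,001 point PMF grids.

## Known limitations

* One torsion at a time; no coupled multi-dimensional torsion surfaces,
  improper dihedrals, or Ryckaert-Bellemans conversion beyond the
  type-9 export.
* The sampler is 1-D overdamped Langevin: free energies are faithful,
  kinetics (rates, transition times) are not meaningful and are not
  exposed.
* `binding_free_energy` post-processes an existing PMF; it does not run
  funnel metadynamics, and published benzamidine/trypsin numbers are not
  reproducible from in-package inputs because the original R_cyl, window
  choices and trajectories are not part of any printed table.
* Bond-angle parameter adjustment (sometimes bundled with torsion refits)
  is out of scope.
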