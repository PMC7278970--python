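# Methods

## Model and assumptions

The package implements a target-theory survival model for photon
irradiation. Dose deposition is assumed homogeneous over the nucleus, so
DSB induction is a Poisson process with a dose-proportional mean,
`alpha_dsb * dose * dna_content`. The critical targets are giant-loop
chromatin domains; the genome is treated as an exact tiling of
`dna_content / loop_size` identical loops, and breaks land on loops
uniformly and independently. No spatial structure within a loop, repair
kinetics, cell-cycle stage, or track structure is modelled. Lesion
classification is purely combinatorial (one break = isolated, two or more
= complex), and lesions act independently on survival through the two
per-lesion kill probabilities `k_idsb` and `k_cdsb`.

The direct/indirect split is a yield-level bookkeeping device: a fixed
fraction `fr_dir` of the induction rate is attributed to direct energy
deposition and held invariant under both DMSO and oxygenation; all
chemistry acts multiplicatively on the remainder. Consequently the hypoxic
scavenged yield requires `hrf < 1/fr_dir` (= 5 at the default 20%), or the
indirect part would be negative; this is enforced as a hard error rather
than clipped, because a negative indirect yield signals inconsistent
inputs, and all fitted HRFs (2.85–2.94) sit well inside the bound.

## Sampling and the closed-form oracle

Damage realizations are drawn exactly as the model states them: a Poisson
total followed by uniform placement over loops. The batch sampler used by
the Monte Carlo estimator draws the same distribution but counts loop
occupancy by sorting all (cell, loop) break assignments at once, which is
O(breaks log breaks) rather than O(cells × loops); single-tally and batch
paths are statistically identical and both seed-reproducible through
`numpy.random.default_rng`.

Because per-loop counts are i.i.d. Poisson(mu), the expected survival
factorizes over loops and has an exact closed form (per-loop factor raised
to the number of loops, evaluated in log space with `expm1` guarding the
small-mu regime). This closed form serves two roles: an independent oracle
against which the Monte Carlo estimator is tested, and the deterministic
predictor used by all fits.

## Fitting workflow

The stages mirror the standard derivation order for this model family and
each stage consumes the previous stage's output frozen:

1. `fit_lethality` on normoxic, zero-DMSO curves (at least three distinct
   doses; both parameters bounded to [0, 1]);
2. `fit_hrf` on hypoxic, zero-DMSO curves, lethality fixed, one-dimensional
   and bounded to [1, 1/fr_dir);
3. `fit_fdmso_points`: one free scaling factor per measured DMSO
   concentration, bounded to [0, 1], lethality (and HRF for hypoxic data)
   fixed;
4. `fit_fdmso_curve`: least squares of `exp(-a c**b)` through those points,
   a and b positive.

The objective is least squares on `ln S` — survival spans decades, and
multiplicative errors are the norm for clonogenic assays — inverse-variance
weighted when every record carries an uncertainty (absolute uncertainties
are converted to log-domain sigmas as `u/S`). The optimizer is bounded
local search (L-BFGS-B, or bounded Brent for scalar stages) from a fixed
documented start (`k_idsb=1e-2, k_cdsb=0.5, hrf=2, f=0.5, a=1, b=0.5`),
preceded for the lethality stage by a coarse grid pre-scan because the two
kill probabilities trade off along a ridge at intermediate doses; ties
break toward the lowest objective, then lexicographically smallest
parameters. Fitting always uses the closed-form predictor, never the Monte
Carlo estimate, so repeated fits on identical data are bit-identical.

Reported uncertainties come from the local quadratic approximation of the
objective at the optimum (numerical Hessian; Gauss–Newton `J^T J` for the
curve stage) scaled by the residual variance when the fit is unweighted.
They are approximate by construction and are reported as NaN when the
optimum sits on a bound or the curvature is not positive definite.
Boundary optima are flagged (`at_boundary`), not raised: degenerate data
(e.g. all survivors) legitimately drive parameters to a bound. The bounded
Brent stages snap to a bound when the boundary value fits at least as well,
since the optimizer itself stops ~1e-5 short of its bracket.

## Numerical choices

- `f_dmso(0)` is defined as exactly 1 (`0**b := 0` for `b > 0`, the
  continuous limit).
- Loop-count divisibility is checked to 1e-9 relative; oxygen is given in
  percent and DMSO in molar everywhere, with units baked into table column
  names (`dose_Gy`, `dmso_M`) and never converted implicitly.
- Default Monte Carlo sample count is 10^4 per estimate (10^5 in the
  oracle-agreement tests); all stochastic APIs take an explicit seed with a
  documented default, so every published number is reproducible.
- The low-damage limit `-ln S -> k_idsb * <N>` holds to 1% only once the
  complex-lesion term `k_cdsb*mu/(2*k_idsb)` is small; for CHO-like
  parameters that means per-loop means around 1e-4, the regime the test
  uses.

## Synthetic data

The generator emulates the design of the clonogenic experiments this model
family is fitted to: dose levels of a few Gy up to the steep part of the
curve (default 2/4/8 Gy), DMSO from zero to molar-scale, normoxic plus
(when an HRF is supplied) hypoxic arms. Each replicate is the closed-form
mean times multiplicative lognormal noise (default sigma_ln = 0.05, the
relative-error scale typical of colony counts), truncated at 1; the
truncation bias is negligible at that sigma for S <= 0.5. Records carry an
absolute uncertainty of `sigma_ln * S`, i.e. a relative error equal to the
generating sigma, so the weighted log-domain objective sees homoscedastic
residuals. What the generator does *not* emulate: plating-efficiency and
colony-counting (Poisson) statistics, dose-rate effects, inter-experiment
batch effects, or any deviation of real survival curves from this model
family — passing round-trip tests therefore demonstrates correctness of
the implementation and identifiability of the parameters under the model's
own assumptions, not validity of the model for real cells.

## Design choices on open points

- The population surviving fraction is the arithmetic mean of per-cell S,
  not the survival of the mean tally.
- `fr_dir` lives on the scavenger model and is cell-line independent; it is
  treated as dose-independent at all doses.
- Cell lines without a fitted HRF (V79) fall back to the anoxic value of
  the oxygen parametrization when a hypoxic prediction is requested, the
  parametrization's stated purpose.
- Registry uncertainties for the fitted lethality parameters are stored for
  reference only; their original derivation is not reproduced here.

## Problem sizes

Default test and acceptance workloads: 10^5 Monte Carlo cells per
oracle-agreement check (18 condition cells), 10^5 draws for the occupancy
check, and 50 replicate noisy datasets (8 doses × 3 replicates, two oxygen
arms) for the recovery study. These sizes put all statistical checks at
3-standard-error resolution while keeping the whole suite around half a
minute on one CPU.

## Known limitations

Single-scavenger (DMSO) chemistry only; no LET dependence of the direct
fraction; no modelling of the steeper high-concentration DSB-yield decline
some pulsed-field data show; lethality parameters are assumed invariant
under oxygenation and scavenging, so any drug interaction with repair is
out of scope.
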