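# Methods

This note records the models implemented in `climtop`, the choices made
where the design was genuinely open, and what the synthetic test-bed does
and does not establish about behaviour on real trial data.

## Top-height equations

Both species use the sigmoid-ratio site-index form

    HT(SI, t) = SI * (1 + exp(u(50))) / (1 + exp(u(t)))
    u(t) = c1 + c2 * g(t) + c3 * s(SI) + c4 * sqrt(50)

with age transform `g(t) = sqrt(ln(1 + t²))` and site-index transform
`s = (ln SI)²` for white spruce, and `g(t) = sqrt(ln(1 + t))`, `s = ln SI`
for lodgepole pine. The two forms are kept exactly as published for each
species; no harmonisation is attempted. Note that the fourth constant
multiplies `sqrt(50)` in both numerator and denominator, so it only
shifts the exponent and is algebraically absorbable into `c1`; it is
retained for compatibility with the four-constant parameterisation.
`HT(SI, 50) = SI` holds identically for any constants.

**Constants.** The regionally fitted constants are not public data that
this package can ship. The bundled file
(`src/climtop/data/species_params_synthetic.yaml`) is a synthetic
calibration solved so that, at SI 18 m, height is ≈ 0.3 m at age 3,
≈ 8 m (spruce, age 16) / ≈ 12.6 m (pine, age 32) at the common age, and
the curve is strictly increasing in age over 1–80 years and in SI over
the full inversion bracket. Every algebraic test (identity at 50,
round trips, telescoping, curve equivalence) is constant-agnostic;
loading rejects any parameter set that violates strict monotonicity in
either argument.

**Inversion.** Brent's method on SI ∈ [0.05, 80] m with xtol 1e-10.
Monotonicity in SI is validated at load, so the root is unique; a height
outside the bracket's image raises "height outside representable range".
Age semantics are total age from germination throughout; no
breast-height-age correction is implemented.

## Trial preparation

Unhealthy trees (dead, crooked, browsed, diseased — an input column, not
diagnosed from measurements) are removed first. Population top height at
each site is the block-adjusted population mean from a linear mixed model
with population as a fixed effect (cell-mean coding) and block as a
random intercept, fitted per site × measurement age — the simplest
reading of an "at each age and at each site" analysis. If REML fails or
returns adjusted means outside the data spread (a degenerate solution
that near-zero variance components occasionally produce), the model falls
back to an OLS population + block fit with block effects averaged out; in
a balanced design both routes equal the raw means.

One measurement age per site is used — the age nearest the species'
common age (16 yr spruce, 32 yr pine), ties resolved toward the older age
because later measurements integrate more growth signal. Heights are
converted to the common age through the site-index curve (invert at the
measured age, evaluate at the common age); heights measured at the common
age pass through unchanged.

## Climate handling

The registry holds the 22 annual variables (AHM … TD) in a canonical
order; degree-day variables relative to 18 °C are excluded as lacking
direct biological interpretation. Highly correlated pairs (|r| > 0.9 —
absolute value, the conservative reading) are pruned separately for
provenance normals and site climates by repeatedly removing the variable
in the largest number of offending pairs, ties resolved toward the later
registry position; the rule is deterministic and idempotent. Site climate
enters the response function as the mean over the plantation's life so
far (planting year through age *i*); for projection runs a log-age
regression `v(i) = c0 + c1 ln i` smooths that path (flag `smooth`,
default off for fitting-era reconstructions).

## Response-function fitting and selection

The published five-term exponent has no intercept; the multi-variable
generalisation here adds linear and quadratic terms per variable and all
provenance × site cross terms (no within-side interactions), and includes
an intercept by default — without one, zero-valued climate inputs would
force a 1 m prediction. Screening fits are OLS on `ln(height)`:
deterministic and cheap enough for the full candidate enumeration
(hundreds of thousands of models at realistic pool sizes). R² is
reported on the original height scale from back-transformed predictions
(all heights identical → R² defined as 0); AIC from the log-scale
Gaussian likelihood. Cross-validation folds are assigned by a seeded
shuffle keyed to a stable observation identifier (site, population), so
every statistic is invariant to row order; CV refits use the screening
route. The final minimum-RMSEP model (ties: higher EF, then enumeration
order) is optionally re-estimated by Gauss–Newton nonlinear least squares
on the original scale (additive error), initialised at the screening
estimates, with fallback to them on non-convergence. Fitting the
original-scale error model for every candidate would be the purist
alternative; the screening/refinement split trades that for tractability
and is the package's main numerical deviation from a literal reading of
the error form.

## Curve assembly

For each age *i* in 1..A (default A = 80): predict the common-age height
under (provenance normals, site climate averaged to age *i*), invert to
`SI_i`, and add the age-*i* increment of the `SI_i` static curve to the
running height; the age-1 height comes from the `SI_1` curve. Constant
climate telescopes to the static curve exactly (asserted to 1e-9 in the
tests — the defining oracle). A falling `SI_i` path could in principle
produce a negative increment; increments are floored at zero with a
logged warning to preserve cumulative-growth semantics (with validated
monotone constants the static increment itself is always positive, so the
floor guards only pathological parameter files).

## Deployment

Grids are supplied (or synthesised) as point tables; each point's own
normals define its local population. `si_dif` compares a scenario
against replaying the normals as a constant series; `si_opt`/`si_imp`
come from scanning candidate provenance climates (default: 100 points
sampled with a fixed seed from the in-range grid, configurable) and
taking the argmax of age-50 height, ties toward the first candidate.
Sites whose optimal SI strictly exceeds 25 m (configurable) are flagged —
not deleted — as extrapolation beyond the trial climate envelope.

## Synthetic test-bed

The generators emulate the structure of real trial series: randomized
complete blocks (zero-sum additive block effects within a site), row
plots, multiplicative lognormal tree noise (matching the log-scale
screening fit; the refinement path is exercised separately), Bernoulli
health flags, climate normals on linear spatial gradients with annual
noise and optional linear warming (defaults: 5% log noise, 0.15 m block
SD, 10% unhealthy rate, 17 sites × 40 populations at full scale; tests
and the acceptance script run smaller designs — e.g. 12 × 25 with 4
blocks of 4 trees — chosen to exercise every code path at interactive
runtimes). The ground-truth response function is log-quadratic in mean
annual temperature on both sides with a mild positive interaction,
giving ~10 m common-age heights and an interior provenance optimum.

What passing tests show: the pipeline is internally consistent
(noiseless data round-trip to the true coefficients at 1e-6; exhaustive
selection recovers the true variables in a majority of seeds at 5%
noise) and every closed-form identity holds. What they do not show:
performance under real genotype-by-environment structure — spatially
autocorrelated residuals, non-quadratic climate response, measurement-age
imbalance across decades, or climate-normal error — none of which the
generators emulate.

## Known limitations

- Only the top-height/site-index component of the growth-and-yield system
  is implemented; volume, density and diameter subsystems are out of scope.
- Climate values are consumed as tables; no downscaling or GCM-ensemble
  construction.
- The curve-level ten-fold validation against held-out measurement ages
  requires real multi-age trial data and is not reproduced on synthetics.
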