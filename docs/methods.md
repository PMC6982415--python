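# Methods

## The model and the testing problem

`medperm` tests for mediation in the standard two-regression formulation.
With exposure `X`, mediator `M`, outcome `Y` and covariates `C`:

    E[Y | X, C, M] = γ0 + γ1 X + γ2'C + γ3 M
    E[M | X, C]    = α0 + α1 X + α2'C

The indirect effect of `X` on `Y` through `M` is the product `α1·γ3`, and the
null hypothesis of no mediation is `H0: α1·γ3 = 0`.  This null is *composite*:
it holds when `α1 = 0`, when `γ3 = 0`, or when both are zero, and the three
configurations give the product estimator very different sampling behaviour.
Because the product of two approximately normal coefficient estimates is not
normal — and badly so in small samples — inference here is resampling-based
throughout; no standard errors or Sobel-type Wald tests are computed anywhere
in the package.

Covariates are the reason the permutation schemes need care.  Mediation
analysis assumes no unmeasured confounding, so `C` must stay in the models;
permuting raw `Y` or raw `X` would destroy the `C` associations along with the
one under test and turn the procedure into a global test.  The permutable
units are therefore model *residuals*.

## The three permutation procedures

All three tests share one mechanical core.  Residual vectors `e_Y` and `e_M`
are permuted `n_perm` times; each permutation is added back onto fitted
values, `Y* = Ŷ + e_Y*` and `M* = M̂ + e_M*`; and the full models are refit
with the starred vectors as responses, yielding per-permutation draws of
`α1*`, `γ3*` and `α1*·γ3*`.  The procedures differ in which fits supply
`Ŷ, e_Y, M̂, e_M` and in the decision rule:

* **IERM** (indirect effect under reduced models, Freedman–Lane).  Residuals
  come from the reduced fits `Y ~ X + C` and `M ~ C` — the models with the
  coefficient under test removed — so permutation happens under
  `α1 = γ3 = 0` while covariate associations are preserved.  Two-sided
  p-value: the proportion of permuted `|α1*·γ3*|` at or above the observed
  `|α1·γ3|` (ties count as exceedances).  Reject when `p ≤ α`.
* **PSRM** (permutation supremum test under reduced models).  Same
  permutation stream as IERM — one loop produces all three starred statistics
  per draw — but each of `α1·γ3`, `α1`, `γ3` gets its own two-sided p-value
  and the null is rejected only when all three fall at or below `α`
  (an intersection–union construction); the operative p-value is the
  supremum of the three.  Requiring the component coefficients to be
  individually significant is what protects the type I error under the
  composite null's one-coefficient-zero configurations, where IERM's
  permutation null (both coefficients zero) is the wrong reference
  distribution and IERM inflates badly.
* **IEFM** (indirect effect under full models, ter Braak; the comparison
  standard).  Residuals and fitted values come from the *full* fits, so the
  permuted products scatter around the observed estimate rather than zero.
  The (α/2, 1−α/2) percentiles of the draws form confidence bounds and the
  null is rejected when 0 lies outside.  No p-value is produced.

### The refit rule

The procedure descriptions this package implements say the full models are
refit "replacing Y and M with Y* and M*".  Read literally, that would put the
permuted `M*` into the outcome model's *design matrix*.  We implement the
Freedman–Lane / ter Braak convention instead: starred vectors are responses
only, and the outcome design keeps the original mediator column.  The two
readings are nearly indistinguishable for the reduced-model tests, but for
IEFM the literal reading detaches the permuted `γ3*` draws from `γ̂3`,
centres every product draw at zero, and drives power to zero — behaviour
incompatible with the published operating characteristics of the method.
Under the response-only rule this implementation reproduces the reference
type I error and power tables for all three tests (see `tests/` and
`scripts/acceptance.py`).

### Permutation details

* `e_Y` and `e_M` are permuted **independently** by default (two separate
  draws per iteration).  The source descriptions never say whether the same
  permutation is applied to both vectors; independent draws break all
  associations under the null most completely.  A `scheme="joint"` option
  applies one shared permutation; measured rejection rates differ only within
  Monte-Carlo noise.
* p-values use the literal proportion `b / n_perm` ("the proportion of values
  in the distribution ..."), so `p = 0` is attainable.  A `smoothed=True`
  option gives the guaranteed-valid `(b+1)/(n_perm+1)` variant.
* Magnitude ties are detected with a relative tolerance of 1e-12 so that a
  permutation which exactly reproduces the observed statistic (the identity)
  always counts as an exceedance regardless of refit roundoff.
* `exact=True` enumerates all permutations — the full Cartesian product of
  the two enumerations under the independent scheme — and is admitted up to
  `factorial(n) ≤ 720` (n ≤ 6).
* Percentile bounds (IEFM and all bootstrap intervals) use the nearest-order-
  statistic quantile, index `ceil(q·B)`, with no interpolation: bounds are
  always actual draws and decisions are exact functions of the resampling
  distribution.
* Refits are vectorized: one QR decomposition of the shared predictor block
  `(1, X, C)` gives every `α1*` by a triangular solve over all `M*` columns
  and every `γ3*` by the Frisch–Waugh identity.  A test verifies equality
  with literal per-permutation OLS refits to 1e-10.

## Bootstrap comparators

Three case-resampling bootstrap tests are provided for comparison: rows of
`(x, c, m, y)` are resampled jointly with replacement and both models refit
per resample (batched QR).  Intervals: percentile (PB); bias-corrected (BCB)
with `z0 = Φ⁻¹(#{draws < observed}/B)` and levels `Φ(2z0 + z_q)`; and BCa
(BCAB) with jackknife acceleration `a = Σd³ / (6 (Σd²)^{3/2})`,
`d_i = mean(θ̂₋) − θ̂₋ᵢ`, and levels `Φ(z0 + (z0+z_q)/(1 − a(z0+z_q)))`.
Draw counts default to 10,000 to parallel `n_perm`.  Ties between a draw and
the observed estimate do not count toward `z0` (strict `<`); resamples whose
designs are numerically rank deficient are redrawn with a cap of `100·n_boot`
attempts.

## The data generator and condition catalogue

Simulated data are standard multivariate normals: `V = Z Lᵀ` with `Z` an
`n×4` i.i.d. N(0,1) matrix and `L` the lower Cholesky factor of a 4×4
correlation matrix over `(X, C, M, Y)`.  Columns have mean 0 and variance 1,
so population regression coefficients follow from the correlation matrix by
the normal equations (`implied_coefficients`); the generator emulates exactly
the evaluation conditions of the reference study and nothing more.  What it
deliberately does **not** emulate: non-normal marginals, heteroscedastic or
dependent errors, discrete exposures or outcomes, exposure–mediator
interactions, multiple mediators or covariate sets beyond one standardized
`C`.  Passing tests therefore certify behaviour under clean multivariate
normality; they say nothing about robustness beyond it.

The condition catalogue crosses three covariate scenarios (`a`: `C`
associated with `Y` only; `b`: `C` confounds `X–Y`; `c`: `C` confounds
`M–Y`), two confounder strengths (correlation 0.15 "weak", 0.6 "strong"),
and four hypothesis families.  Null families fix `α1 = 0` (via `ρ_XM = 0`)
and/or `γ3 = 0`; alternatives vary `ρ_XM, ρ_MY` over {0.15, 0.3, 0.6}; all
other correlations sit at the strength value.  Two generation details are
worth recording:

* `γ3 = 0` with `α1 ≠ 0` is unattainable on the correlation grid while the
  direct `X–Y` correlation is held at the strength value (the implied `γ3`
  is provably nonzero for any grid `ρ_MY`), so null-3 conditions set
  `ρ_XY = ρ_MY = 0`.  With that rule plus the two filters below, the
  catalogue contains exactly 13/8/6 null and 18/18/15 alternative conditions
  for scenarios a/b/c.
* Candidates are dropped when the matrix is not positive definite.  Validity
  of a user-supplied matrix is judged at smallest eigenvalue > 1e-10, but the
  catalogue applies a stricter screen of 5e-3: one strong scenario-c corner
  has smallest eigenvalue 0.0011 — numerically almost singular — and is
  excluded as a study condition.  A hypothesis-consistency filter also drops
  candidates whose implied `(α1, γ3)` do not realize the declared family.

## The Monte-Carlo harness

`run_study` estimates a rejection rate by generating fresh data per replicate
and recording binary decisions.  Seeds derive from
`(master seed, condition key CRC, method, replicate index)` through
`numpy.random.SeedSequence`, so every cell and every replicate is
independently recomputable and results are identical for any execution order.
Rates outside the Wald band `nominal ± z_{0.975}·sqrt(nominal(1−nominal)/R)`
are flagged (at `nominal = 0.05`, `R = 1000` the band is (0.036, 0.064) to
three decimals); flags use unrounded bounds.  Replicates failing with a
degenerate-resampling error are excluded and counted, keeping rates ratios of
observed decisions.

Default scales mirror the reference study (1,000 replicates × 10,000
permutations, α = 0.05).  The test suite and the acceptance script run at a
desk scale — 500 and 1,000 replicates respectively, 2,000 permutations or
bootstrap draws per replicate — chosen as the package's own
accuracy/turnaround trade-off; at these scales every rejection-rate check
carries a tolerance of three binomial standard errors at the replicate count
used.

## Known limitations

* Continuous variables and OLS only; no GLM/binary-outcome mediation.
* Single-mediator model; no exposure–mediator interaction terms.
* The IERM is implemented for completeness and comparison; its type I error
  is grossly inflated whenever exactly one of `α1, γ3` is zero (its
  permutation null assumes both are), and it should not be used for
  inference.  PSRM is the recommended test.
* BCB/BCAB inflate type I error in small samples; they are comparators, not
  recommendations.
* Exact enumeration is limited to n ≤ 6 by the factorial cap; above that the
  tests are approximate with `O(n_perm^{-1/2})` p-value noise.
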