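# medperm

Permutation and bootstrap tests of the mediated indirect effect, built for
small samples with covariate adjustment.

## The problem

Mediation analysis asks whether an exposure `X` affects an outcome `Y`
through an intermediate variable `M`.  In the regression formulation

    E[Y | X, C, M] = γ0 + γ1 X + γ2'C + γ3 M
    E[M | X, C]    = α0 + α1 X + α2'C

the indirect effect is the product `α1·γ3`, and the null hypothesis of no
mediation, `H0: α1·γ3 = 0`, is composite — it holds when either coefficient
is zero.  The product of two coefficient estimates is far from normal in
small samples, so Wald/Sobel tests behave poorly and resampling is the
standard recourse.  Covariates `C` (required by the no-unmeasured-confounding
assumption) rule out naive permutation of raw `X` or `Y`; the permutable
units must be model residuals.

`medperm` implements:

* **PSRM** — the permutation supremum test under reduced models (the
  recommended test): Freedman–Lane permutation of reduced-model residuals,
  with the composite null rejected only when the indirect effect *and* both
  component coefficients are individually significant; the reported p-value
  is the supremum of the three.
* **IERM** — the plain permutation test of the indirect effect under reduced
  models (included for comparison; its type I error inflates badly when
  exactly one coefficient is zero).
* **IEFM** — the comparison-standard ter Braak test under full models, with
  a percentile confidence-bound decision.
* **PB / BCB / BCAB** — percentile, bias-corrected and BCa case-resampling
  bootstrap tests of the indirect effect.
* A multivariate-normal simulator over 4×4 correlation structures for
  `(X, C, M, Y)`, the evaluation-condition catalogue (covariate scenarios ×
  confounder strengths × null/alternative families), implied population
  coefficients, and a seeded Monte-Carlo harness for type I error and power
  studies with Wald-band exceedance flags.

See `docs/methods.md` for the procedures in full detail.

## Worked example

Simulate one dataset of n = 30 from a condition where `C` weakly confounds
the `X–Y` relationship (those correlations 0.15) and a strong mediated chain
is present (`ρ_XM = ρ_MY = 0.6`), then test it:

```python
from medperm import (CorrelationCondition, PermutationConfig, generate,
                     implied_coefficients, psrm_test)

cond = CorrelationCondition.from_correlations(
    rho_xc=0.15, rho_xy=0.15, rho_cy=0.15, rho_xm=0.6, rho_my=0.6)
coef = implied_coefficients(cond)
print(round(coef.alpha1, 4), round(coef.gamma3, 4))
# 0.6138 0.8259          <- population coefficients implied by the structure

data = generate(cond, n=30, seed=7)
res = psrm_test(data, PermutationConfig(n_perm=10_000, seed=7))
print(round(res.estimate, 3), res.p_value, res.reject)
# 0.793 0.0007 True
```

The estimated indirect effect is 0.793 (population value
0.6138 × 0.8259 ≈ 0.507; n = 30 is noisy).  The supremum p-value 0.0007 is
the largest of the three component p-values (indirect effect 0.0007, `α1`
0.0007, `γ3` 0.0); all fall below 0.05, so mediation is declared.

The same analysis runs from the shell on your own delimited data:

```sh
medperm test --data study.csv --x framing --m anxiety --y attitude \
             --c age --c income --method psrm --nperm 10000 --seed 1
```

and rejection-rate studies over the built-in condition catalogue:

```sh
medperm simulate --scenario b --strength strong --hypothesis null2 \
                 --method psrm --method iefm --n 30 --reps 1000 --seed 1 --out rates.csv
medperm coefficients --scenario b --hypothesis alt
```

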