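"""Residual-permutation tests of the mediated indirect effect.

Three procedures are implemented, differing in which model supplies the
residuals that are permuted and in the decision rule:

* **IERM** — indirect effect under *reduced* models (Freedman–Lane style).
  Residuals come from the reduced regressions Y ~ X + C and M ~ C, i.e. the
  fits with the coefficient under test removed, so permutation happens under
  the null while associations with the covariates are preserved.  The p-value
  is the two-sided permutation p of ``alpha1 * gamma3``.

* **PSRM** — permutation supremum test under reduced models.  Same permutation
  stream as IERM, but three statistics are tracked per permutation
  (``alpha1* * gamma3*``, ``alpha1*``, ``gamma3*``) and the composite null
  ``alpha1 * gamma3 = 0`` is rejected only when all three two-sided p-values
  fall at or below the level; the operative p-value is their supremum.  This
  is an intersection-union construction targeting the composite null, which
  is what keeps the type I error controlled when exactly one coefficient is
  zero.

* **IEFM** — indirect effect under *full* models (ter Braak style), the
  comparison standard.  Full-model residuals are permuted, the permuted
  refits give an empirical distribution of ``alpha1* * gamma3*``, and the
  decision is interval-based: reject when 0 lies outside the central
  ``1 - alpha`` percentile band of the draws.  No p-value is produced.

In every procedure each permutation adds the permuted residuals back onto the
appropriate fitted values, ``Y* = Yhat + e_Y*`` and ``M* = Mhat + e_M*``, and
the full models are refit with the starred vectors as the *responses*:
``M*`` on (1, X, C) gives ``alpha1*`` and ``Y*`` on (1, X, C, M) gives
``gamma3*``.  The designs are those of the original full models — in
particular the outcome design keeps the original mediator column — which is
the Freedman–Lane / ter Braak construction: permutation perturbs what the
model is asked to explain, not the explanatory variables.  (Substituting
``M*`` into the outcome design as well would detach the permuted ``gamma3*``
draws from the observed ``gamma3`` and collapse the IEFM interval decision;
it is not what the reference procedures do.)

Because the designs are fixed across permutations, one QR decomposition of
the shared predictor block (1, X, C) yields every permuted coefficient at
once: ``alpha1*`` by a triangular solve over all ``M*`` columns, ``gamma3*``
by the Frisch–Waugh identity (slope of residualized ``Y*`` on residualized
``M``).  A test verifies this equals literal per-column refits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy.linalg import solve_triangular

from .models import MediationData, FittedMediation, fit_mediation
from .results import TestResult

__all__ = [
    "PermutationConfig",
    "TestResult",
    "two_sided_perm_pvalue",
    "nearest_quantile",
    "ierm_test",
    "psrm_test",
    "iefm_test",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings shared by the three permutation tests.

    Parameters
    ----------
    n_perm : int
        Number of permutations (ignored when ``exact`` is set).
    alpha : float
        Significance level in (0, 1).
    seed : int or None
        Seed for the permutation stream; ``None`` draws fresh entropy.
    exact : bool
        Enumerate all permutations instead of sampling.  Requires
        ``factorial(n) <= enumeration_cap``.
    scheme : {"independent", "joint"}
        Whether e_Y and e_M receive independent permutations per iteration
        (default) or share the same one.
    smoothed : bool
        Use the (b + 1) / (n_perm + 1) p-value instead of the plain
        proportion b / n_perm.
    enumeration_cap : int
        Largest factorial(n) admitted in exact mode.
    """

    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int | None = None
    exact: bool = False
    scheme: str = "independent"
    smoothed: bool = False
    enumeration_cap: int = 720

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scheme not in ("independent", "joint"):
            raise ValueError("scheme must be 'independent' or 'joint'")


#: relative slack when detecting magnitude ties between a draw and the
#: observed statistic, so refit roundoff cannot drop an exact tie (e.g. the
#: identity permutation reproducing the observed estimate)
TIE_RTOL = 1e-12


def two_sided_perm_pvalue(observed: float, null_draws, smoothed: bool = False) -> float:
    """Two-sided permutation p-value of ``observed`` against ``null_draws``.

    The proportion of draws whose absolute value is greater than or equal to
    ``|observed|``; ties count as exceedances and are detected with relative
    tolerance ``TIE_RTOL``.  With ``smoothed`` the add-one variant
    (b + 1) / (B + 1) is returned instead.
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("null_draws must be nonempty")
    b = int(np.count_nonzero(np.abs(draws) >= abs(observed) * (1 - TIE_RTOL)))
    if smoothed:
        return (b + 1) / (draws.size + 1)
    return b / draws.size


def nearest_quantile(draws, q: float) -> float:
    """Inverse-empirical-CDF quantile: the ceil(q*B)-th order statistic.

    No interpolation — the bound is always one of the draws, so interval
    decisions are exact functions of the resampling distribution.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    b = draws.size
    k = min(max(int(math.ceil(q * b)), 1), b)
    return float(draws[k - 1])


def _permutation_matrices(ey, em, cfg: PermutationConfig, n: int):
    """Columns of permuted residual vectors (n, B) for e_Y and e_M."""
    if cfg.exact:
        nfact = math.factorial(n)
        if nfact > cfg.enumeration_cap:
            raise ValueError(
                f"exact enumeration needs factorial(n) <= {cfg.enumeration_cap}, "
                f"got {nfact} for n = {n}"
            )
        perms = np.array(list(_iter_permutations(range(n))))
        ey_all = ey[perms]  # (n!, n)
        em_all = em[perms]
        if cfg.scheme == "joint":
            return ey_all.T, em_all.T
        # independent scheme: full Cartesian product of the two enumerations
        ey_mat = np.repeat(ey_all, nfact, axis=0).T
        em_mat = np.tile(em_all, (nfact, 1)).T
        return ey_mat, em_mat
    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "joint":
        idx = rng.permuted(np.tile(np.arange(n), (cfg.n_perm, 1)), axis=1)
        return ey[idx].T, em[idx].T
    ey_mat = rng.permuted(np.tile(ey, (cfg.n_perm, 1)), axis=1).T
    em_mat = rng.permuted(np.tile(em, (cfg.n_perm, 1)), axis=1).T
    return ey_mat, em_mat


def _permuted_coefficients(data: MediationData, cfg: PermutationConfig, under: str):
    """Observed fits plus the per-permutation (alpha1*, gamma3*) draws.

    ``under`` selects which models supply the fitted values and residuals that
    are recombined: "reduced" (IERM / PSRM) or "full" (IEFM).
    """
    fits = fit_mediation(data, with_reduced=(under == "reduced"))
    if under == "reduced":
        yhat, ey = fits.outcome_reduced.fitted, fits.outcome_reduced.residuals
        mhat, em = fits.mediator_reduced.fitted, fits.mediator_reduced.residuals
    elif under == "full":
        yhat, ey = fits.outcome_full.fitted, fits.outcome_full.residuals
        mhat, em = fits.mediator_full.fitted, fits.mediator_full.residuals
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"unknown model family {under!r}")

    n = data.n
    ey_mat, em_mat = _permutation_matrices(ey, em, cfg, n)
    ystar = yhat[:, None] + ey_mat
    mstar = mhat[:, None] + em_mat

    # Shared predictor block of both full models: (1, X, C).
    w = np.column_stack([np.ones(n), data.x, data.c])
    q, r = np.linalg.qr(w)
    # alpha1*: X coefficient of M* ~ (1, X, C), all columns at once.
    alpha1 = solve_triangular(r, q.T @ mstar)[1]
    # gamma3*: Frisch-Waugh - slope of Y* on the original M, both residualized
    # on (1, X, C); the outcome design is unchanged across permutations.
    qm = data.m - q @ (q.T @ data.m)
    denom = float(qm @ qm)
    if denom <= 0:
        raise np.linalg.LinAlgError(
            "the mediator lies in the span of (intercept, X, C); the outcome "
            "model coefficient gamma3 is not identified"
        )
    ry = ystar - q @ (q.T @ ystar)
    gamma3 = (qm @ ry) / denom
    return fits, alpha1, gamma3


def ierm_test(data: MediationData, cfg: PermutationConfig) -> TestResult:
    """Permutation test of the indirect effect under reduced models.

    Reduced-model residuals are permuted, the full models refit per
    permutation, and the two-sided p-value of the observed
    ``alpha1 * gamma3`` computed against the permuted products.
    """
    fits, alpha1, gamma3 = _permuted_coefficients(data, cfg, under="reduced")
    draws = alpha1 * gamma3
    p = two_sided_perm_pvalue(fits.indirect, draws, smoothed=cfg.smoothed)
    return TestResult(
        method="IERM",
        estimate=fits.indirect,
        p_value=p,
        alpha=cfg.alpha,
        reject=p <= cfg.alpha,
        n_resamples=draws.size,
        seed=cfg.seed,
    )


def psrm_test(data: MediationData, cfg: PermutationConfig) -> TestResult:
    """Permutation supremum test under reduced models.

    One permutation stream yields, per permutation, the refit ``alpha1*``,
    ``gamma3*`` and their product.  Each observed quantity gets a two-sided
    permutation p-value; the null is rejected only when all three are at or
    below ``alpha``, and the reported p-value is their supremum.
    """
    fits, alpha1, gamma3 = _permuted_coefficients(data, cfg, under="reduced")
    p_ie = two_sided_perm_pvalue(fits.indirect, alpha1 * gamma3, smoothed=cfg.smoothed)
    p_a = two_sided_perm_pvalue(fits.alpha1, alpha1, smoothed=cfg.smoothed)
    p_g = two_sided_perm_pvalue(fits.gamma3, gamma3, smoothed=cfg.smoothed)
    p_sup = max(p_ie, p_a, p_g)
    return TestResult(
        method="PSRM",
        estimate=fits.indirect,
        p_value=p_sup,
        component_p_alpha=p_a,
        component_p_gamma=p_g,
        alpha=cfg.alpha,
        reject=p_sup <= cfg.alpha,
        n_resamples=alpha1.size,
        seed=cfg.seed,
    )


def iefm_test(data: MediationData, cfg: PermutationConfig) -> TestResult:
    """Permutation test of the indirect effect under full models.

    Full-model residuals are permuted and the (alpha/2, 1 - alpha/2)
    percentiles of the permuted ``alpha1* * gamma3*`` draws form confidence
    bounds; the null is rejected when 0 is not contained within them.
    """
    fits, alpha1, gamma3 = _permuted_coefficients(data, cfg, under="full")
    draws = np.sort(alpha1 * gamma3)
    lo = nearest_quantile(draws, cfg.alpha / 2)
    hi = nearest_quantile(draws, 1 - cfg.alpha / 2)
    return TestResult(
        method="IEFM",
        estimate=fits.indirect,
        ci_lower=lo,
        ci_upper=hi,
        alpha=cfg.alpha,
        reject=not (lo <= 0 <= hi),
        n_resamples=draws.size,
        seed=cfg.seed,
    )
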