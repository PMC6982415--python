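"""Case-resampling bootstrap tests of the indirect effect (PB, BCB, BCAB).

These are the standard comparators for small-sample mediation inference:
rows of (x, c, m, y) are resampled jointly with replacement, the two mediation
regressions are refit on each resample, and the resampled products
``alpha1* * gamma3*`` form the bootstrap distribution.  Three interval
constructions are offered:

* percentile (PB): plain (alpha/2, 1 - alpha/2) empirical percentiles;
* bias-corrected (BCB): percentile levels shifted by the median-bias term
  ``z0 = Phi^{-1}(#{draws < observed} / B)``;
* bias-corrected accelerated (BCAB): additionally adjusted by the jackknife
  acceleration constant ``a`` (the skewness of the leave-one-out estimates).

Each test rejects ``H0: alpha1 * gamma3 = 0`` when 0 falls outside its
interval.  Quantiles use the same nearest-order-statistic definition as the
permutation module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .models import MediationData, fit_mediation
from .permutation import nearest_quantile
from .results import TestResult

__all__ = [
    "BootstrapConfig",
    "DegenerateBootstrapError",
    "bootstrap_indirect_draws",
    "pb_interval",
    "bc_interval",
    "bca_interval",
    "pb_test",
    "bcb_test",
    "bcab_test",
]


class DegenerateBootstrapError(RuntimeError):
    """Bootstrap distribution too degenerate for the requested interval."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: draw count, level, seed.

    ``n_boot`` defaults to 10,000 to parallel the permutation default.
    """

    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# relative tolerance on batched-QR diagonals for flagging degenerate resamples
_DIAG_RTOL = 1e-10


def _batched_indirect(data: MediationData, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indirect-effect estimates for each resample index row.

    Returns (draws, ok) where ``ok`` flags resamples whose designs were
    numerically full rank.  Both regressions are solved by batched QR.
    """
    x, m, y, c = data.x[idx], data.m[idx], data.y[idx], data.c[idx]
    ones = np.ones_like(x)
    wy = np.concatenate([ones[..., None], x[..., None], c, m[..., None]], axis=2)
    wm = np.concatenate([ones[..., None], x[..., None], c], axis=2)

    def solve(design, resp):
        q, r = np.linalg.qr(design)
        diag = np.abs(np.diagonal(r, axis1=1, axis2=2))
        ok = diag.min(axis=1) > _DIAG_RTOL * diag.max(axis=1)
        rhs = np.einsum("bnk,bn->bk", q, resp)
        # guard singular triangles so solve() does not blow up on bad rows
        r = np.where(ok[:, None, None], r, np.eye(r.shape[1]))
        coef = np.linalg.solve(r, rhs[..., None])[..., 0]
        return coef, ok

    coef_y, ok_y = solve(wy, y)
    coef_m, ok_m = solve(wm, m)
    return coef_m[:, 1] * coef_y[:, -1], ok_y & ok_m


def bootstrap_indirect_draws(data: MediationData, cfg: BootstrapConfig) -> np.ndarray:
    """``n_boot`` case-resampled draws of the indirect effect.

    Rank-deficient resamples (e.g. a resample that repeats one row) are
    redrawn, with a total attempt cap of ``100 * n_boot``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = data.n
    idx = rng.integers(0, n, size=(cfg.n_boot, n))
    draws, ok = _batched_indirect(data, idx)
    attempts = cfg.n_boot
    while not ok.all():
        bad = np.flatnonzero(~ok)
        attempts += bad.size
        if attempts > 100 * cfg.n_boot:
            raise DegenerateBootstrapError(
                "redraw cap exceeded: resamples are persistently rank deficient"
            )
        idx_bad = rng.integers(0, n, size=(bad.size, n))
        draws_bad, ok_bad = _batched_indirect(data, idx_bad)
        draws[bad] = draws_bad
        ok[bad] = ok_bad
    return draws


def pb_interval(draws, alpha: float) -> tuple[float, float]:
    """Percentile-bootstrap interval: (alpha/2, 1 - alpha/2) order statistics."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be nonempty")
    return nearest_quantile(draws, alpha / 2), nearest_quantile(draws, 1 - alpha / 2)


def _z0(draws: np.ndarray, observed: float) -> float:
    prop = np.count_nonzero(draws < observed) / draws.size
    if prop <= 0 or prop >= 1:
        raise DegenerateBootstrapError(
            "all bootstrap draws lie on one side of the observed estimate, so "
            "the bias-correction term z0 is undefined; increase n_boot"
        )
    return float(norm.ppf(prop))


def bc_interval(draws, observed: float, alpha: float) -> tuple[float, float]:
    """Bias-corrected bootstrap interval.

    Percentile levels are ``Phi(2 z0 + z_q)`` for q = alpha/2 and 1 - alpha/2,
    with ``z0`` the normal quantile of the fraction of draws strictly below
    the observed estimate (ties with the observed value do not count).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be nonempty")
    z0 = _z0(draws, observed)
    lo_level = float(norm.cdf(2 * z0 + norm.ppf(alpha / 2)))
    hi_level = float(norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2)))
    return nearest_quantile(draws, lo_level), nearest_quantile(draws, hi_level)


def jackknife_indirect(data: MediationData) -> np.ndarray:
    """Leave-one-out indirect-effect estimates (for the BCa acceleration)."""
    n = data.n
    out = np.empty(n)
    for i in range(n):
        keep = np.r_[0:i, i + 1 : n]
        out[i] = fit_mediation(data.take(keep)).indirect
    return out


def bca_interval(draws, observed: float, data: MediationData, alpha: float) -> tuple[float, float]:
    """Bias-corrected *accelerated* bootstrap interval.

    The acceleration ``a = sum(d^3) / (6 * sum(d^2)^{3/2})`` with
    ``d_i = mean(theta_-) - theta_-i`` over jackknife estimates; percentile
    levels are ``Phi(z0 + (z0 + z_q) / (1 - a (z0 + z_q)))``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be nonempty")
    if data.n < data.n_covariates + 5:
        raise ValueError("need n >= p + 5 so every leave-one-out fit is defined")
    z0 = _z0(draws, observed)
    theta = jackknife_indirect(data)
    d = theta.mean() - theta
    denom = (d @ d) ** 1.5
    if denom == 0:
        raise DegenerateBootstrapError(
            "jackknife estimates have zero variance; acceleration is undefined"
        )
    a = float((d**3).sum() / (6 * denom))
    levels = []
    for q in (alpha / 2, 1 - alpha / 2):
        zq = norm.ppf(q)
        levels.append(float(norm.cdf(z0 + (z0 + zq) / (1 - a * (z0 + zq)))))
    return nearest_quantile(draws, levels[0]), nearest_quantile(draws, levels[1])


def _interval_result(method: str, estimate: float, lo: float, hi: float,
                     cfg: BootstrapConfig, n_draws: int) -> TestResult:
    return TestResult(
        method=method,
        estimate=estimate,
        ci_lower=lo,
        ci_upper=hi,
        alpha=cfg.alpha,
        reject=not (lo <= 0 <= hi),
        n_resamples=n_draws,
        seed=cfg.seed,
    )


def _run(data: MediationData, cfg: BootstrapConfig, method: str) -> TestResult:
    observed = fit_mediation(data).indirect
    draws = bootstrap_indirect_draws(data, cfg)
    if method == "PB":
        lo, hi = pb_interval(draws, cfg.alpha)
    elif method == "BCB":
        lo, hi = bc_interval(draws, observed, cfg.alpha)
    else:
        lo, hi = bca_interval(draws, observed, data, cfg.alpha)
    return _interval_result(method, observed, lo, hi, cfg, draws.size)


def pb_test(data: MediationData, cfg: BootstrapConfig) -> TestResult:
    """Percentile-bootstrap test of the indirect effect."""
    return _run(data, cfg, "PB")


def bcb_test(data: MediationData, cfg: BootstrapConfig) -> TestResult:
    """Bias-corrected bootstrap test of the indirect effect."""
    return _run(data, cfg, "BCB")


def bcab_test(data: MediationData, cfg: BootstrapConfig) -> TestResult:
    """Bias-corrected accelerated bootstrap test of the indirect effect."""
    return _run(data, cfg, "BCAB")
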