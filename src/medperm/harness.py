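"""Replicate studies: type I error / power estimation over simulated conditions.

``run_study`` runs one test method on one correlation condition over many
independently generated replicate datasets and aggregates the binary
reject/accept decisions into a Monte-Carlo rejection-rate estimate.  Rates for
null conditions estimate the type I error; rates for alternative conditions
estimate power.  A rate is flagged when it falls outside the Wald interval
``nominal +/- z_0.975 * sqrt(nominal (1 - nominal) / R)`` — at the usual
nominal 0.05 and R = 1,000 replicates this is (0.036, 0.064) to three
decimals, the band within which a level-0.05 test's estimated rate should
fall absent a real deviation.

Seeding: every replicate's seeds derive deterministically from
(master seed, condition key, method, replicate index) via a CRC-keyed
``numpy.random.SeedSequence``, so any single cell — or single replicate — can
be recomputed independently and results do not depend on execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bootstrap import (
    BootstrapConfig,
    DegenerateBootstrapError,
    bcab_test,
    bcb_test,
    pb_test,
)
from .permutation import PermutationConfig, iefm_test, ierm_test, psrm_test
from .results import TestResult
from .simulate import CorrelationCondition, generate, implied_coefficients

__all__ = [
    "METHODS",
    "RejectionRateEstimate",
    "wald_bounds",
    "run_study",
    "run_single_test",
    "tabulate",
    "exceedance_summary",
]

_PERM_METHODS = {"ierm": ierm_test, "psrm": psrm_test, "iefm": iefm_test}
_BOOT_METHODS = {"pb": pb_test, "bcb": bcb_test, "bcab": bcab_test}

#: method label -> callable(data, cfg) -> TestResult
METHODS = {**_PERM_METHODS, **_BOOT_METHODS}


def wald_bounds(nominal: float, n_replicates: int) -> tuple[float, float]:
    """Wald interval for a rejection proportion around the nominal level."""
    if not 0 < nominal < 1:
        raise ValueError("nominal must lie in (0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    half = norm.ppf(0.975) * np.sqrt(nominal * (1 - nominal) / n_replicates)
    return nominal - half, nominal + half


@dataclass(frozen=True)
class RejectionRateEstimate:
    """One Monte-Carlo cell: rejection rate of one method on one condition."""

    condition: CorrelationCondition
    method: str
    sample_size: int
    n_replicates: int
    n_inner: int
    rejections: int
    n_excluded: int
    nominal: float
    master_seed: int
    rate: float
    exceeds_wald: bool

    def to_record(self) -> dict:
        coef = implied_coefficients(self.condition)
        rec = self.condition.to_dict()
        rec.update(
            alpha1=coef.alpha1,
            gamma3=coef.gamma3,
            method=self.method,
            n=self.sample_size,
            n_replicates=self.n_replicates,
            n_inner=self.n_inner,
            rejections=self.rejections,
            n_excluded=self.n_excluded,
            rate=self.rate,
            nominal=self.nominal,
            exceeds_wald=self.exceeds_wald,
            master_seed=self.master_seed,
        )
        return rec


def _replicate_seeds(master_seed: int, condition: CorrelationCondition,
                     method: str, replicate: int) -> tuple[int, int]:
    """(data seed, test seed) for one replicate; order-invariant and stable."""
    key = zlib.crc32(f"{condition.key()}|{method}".encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key, replicate])
    state = ss.generate_state(2)
    return int(state[0]) % 2**31, int(state[1]) % 2**31


def run_single_test(data, method: str, inner_count: int, nominal: float,
                    seed: int | None = None) -> TestResult:
    """Run one named method on one dataset (CLI / library entry point)."""
    if method in _PERM_METHODS:
        cfg = PermutationConfig(n_perm=inner_count, alpha=nominal, seed=seed)
        return _PERM_METHODS[method](data, cfg)
    if method in _BOOT_METHODS:
        cfg = BootstrapConfig(n_boot=inner_count, alpha=nominal, seed=seed)
        return _BOOT_METHODS[method](data, cfg)
    raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")


def run_study(
    condition: CorrelationCondition,
    method: str,
    n: int,
    n_replicates: int = 1000,
    inner_count: int = 10_000,
    nominal: float = 0.05,
    master_seed: int = 0,
    progress=None,
) -> RejectionRateEstimate:
    """Estimate the rejection rate of ``method`` on ``condition`` at size ``n``.

    Each replicate generates a fresh dataset from the condition and records
    the binary decision at level ``nominal``.  Replicates that fail with a
    degenerate-resampling error are excluded and counted, so the rate remains
    a ratio of observed decisions.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    if n_replicates < 1 or inner_count < 1:
        raise ValueError("n_replicates and inner_count must be >= 1")
    rejections = 0
    completed = 0
    excluded = 0
    for rep in range(n_replicates):
        data_seed, test_seed = _replicate_seeds(master_seed, condition, method, rep)
        data = generate(condition, n, seed=data_seed)
        try:
            result = run_single_test(data, method, inner_count, nominal, seed=test_seed)
        except DegenerateBootstrapError:
            excluded += 1
            continue
        completed += 1
        rejections += int(result.reject)
        if progress is not None:
            progress(rep)
    rate = rejections / completed if completed else float("nan")
    lo, hi = wald_bounds(nominal, completed) if completed else (np.nan, np.nan)
    return RejectionRateEstimate(
        condition=condition,
        method=method,
        sample_size=n,
        n_replicates=completed,
        n_inner=inner_count,
        rejections=rejections,
        n_excluded=excluded,
        nominal=nominal,
        master_seed=master_seed,
        rate=rate,
        exceeds_wald=bool(completed) and not (lo <= rate <= hi),
    )


def tabulate(estimates: list[RejectionRateEstimate]) -> pd.DataFrame:
    """Arrange estimates as a conditions-by-methods table.

    One row per condition (in the order first encountered), with the six
    correlations, the implied alpha1/gamma3, and per-method ``rate_*`` and
    ``exceeds_*`` columns — the layout of the published condition tables.
    All estimates must share a nominal level and replicate count.
    """
    if not estimates:
        return pd.DataFrame()
    nominals = {e.nominal for e in estimates}
    if len(nominals) > 1:
        raise ValueError(f"mixed nominal levels in one table: {sorted(nominals)}")
    reps = {e.n_replicates for e in estimates}
    if len(reps) > 1:
        raise ValueError(f"mixed replicate counts in one table: {sorted(reps)}")

    rows: dict[tuple, dict] = {}
    for est in estimates:
        k = (est.condition.key(), est.sample_size)
        if k not in rows:
            coef = implied_coefficients(est.condition)
            row = est.condition.to_dict()
            row.update(n=est.sample_size, alpha1=coef.alpha1, gamma3=coef.gamma3)
            rows[k] = row
        rows[k][f"rate_{est.method}"] = est.rate
        rows[k][f"exceeds_{est.method}"] = est.exceeds_wald
    return pd.DataFrame(list(rows.values()))


def exceedance_summary(estimates: list[RejectionRateEstimate]) -> pd.DataFrame:
    """Per-method count and share of conditions exceeding the Wald bounds."""
    frame = pd.DataFrame(
        [{"method": e.method, "exceeds": e.exceeds_wald} for e in estimates]
    )
    if frame.empty:
        return frame
    grouped = frame.groupby("method")["exceeds"].agg(["sum", "count"])
    grouped["share"] = grouped["sum"] / grouped["count"]
    return grouped.rename(columns={"sum": "n_exceeded", "count": "n_conditions"})
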