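"""Shared result record for permutation and bootstrap tests of the indirect effect."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test of ``H0: alpha1 * gamma3 = 0`` on one dataset.

    Which fields are populated depends on the method:

    * IERM  — ``p_value`` (two-sided permutation p of the indirect effect).
    * PSRM  — ``p_value`` is the supremum (maximum) of the indirect-effect p
      and the two component p-values ``component_p_alpha`` / ``component_p_gamma``.
    * IEFM, PB, BCB, BCAB — interval-based decisions: ``ci_lower``/``ci_upper``
      populated, no p-value; the null is rejected when 0 falls outside.
    """

    method: str
    estimate: float
    alpha: float
    reject: bool
    n_resamples: int
    p_value: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    component_p_alpha: float | None = None
    component_p_gamma: float | None = None
    seed: int | None = None

    def to_record(self) -> dict:
        """Flat dict suitable for one row of a CSV."""
        return {
            "method": self.method,
            "estimate": self.estimate,
            "p_value": self.p_value,
            "component_p_alpha": self.component_p_alpha,
            "component_p_gamma": self.component_p_gamma,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "alpha": self.alpha,
            "reject": self.reject,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }
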