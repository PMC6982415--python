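"""Correlation-structure data generation and the simulation condition catalogue.

A simulation condition is a 4x4 correlation matrix over the variables
(X, C, M, Y) — exposure, covariate, mediator, outcome — together with labels
for the covariate scenario, confounder strength and hypothesis family.
Datasets are drawn as standard multivariate normals: an n x 4 matrix of i.i.d.
N(0, 1) values is multiplied by the transposed lower Cholesky factor of the
correlation matrix, so every marginal has mean 0 and variance 1 and the
population correlation matrix is exactly ``rho``.

Because the variables are jointly standard normal, the population regression
coefficients of the two mediation models follow from ``rho`` by the normal
equations: ``alpha1`` is the X component of
``R[(X,C),(X,C)]^{-1} R[(X,C),M]`` and ``gamma3`` the M component of
``R[(X,C,M),(X,C,M)]^{-1} R[(X,C,M),Y]``.  These implied coefficients are what
the condition tables report next to each correlation row.

Covariate scenarios (strength s = 0.15 weak, 0.6 strong):

* ``a`` — C is a covariate of Y only: rho_XC = rho_CM = 0, rho_CY = s;
* ``b`` — C confounds X–Y: rho_XC = rho_CY = s, rho_CM = 0;
* ``c`` — C confounds M–Y: rho_CM = rho_CY = s, rho_XC = 0.

Hypothesis families for the composite null ``alpha1 * gamma3 = 0``:

* ``null1``: alpha1 = 0 and gamma3 = 0 (rho_XM = rho_MY = 0);
* ``null2``: alpha1 = 0, gamma3 != 0 (rho_XM = 0, rho_MY in {0.15, 0.3, 0.6});
* ``null3``: alpha1 != 0, gamma3 = 0 (rho_MY = 0 and rho_XY = 0,
  rho_XM in {0.15, 0.3, 0.6} — gamma3 = 0 is only attainable on the
  correlation grid when the direct X–Y correlation is also zero);
* ``alternative``: both nonzero (rho_XM, rho_MY in {0.15, 0.3, 0.6}^2).

All remaining correlations are held at the strength s.  Candidate matrices
that are not positive definite, or whose implied coefficients do not match the
declared hypothesis family, are dropped; the surviving grid has 13/8/6 null
and 18/18/15 alternative conditions for scenarios a/b/c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import MediationData

__all__ = [
    "VARIABLES",
    "CorrelationCondition",
    "ImpliedCoefficients",
    "generate",
    "implied_coefficients",
    "catalogue",
    "SCENARIOS",
    "STRENGTHS",
    "HYPOTHESES",
]

VARIABLES = ("X", "C", "M", "Y")
SCENARIOS = ("a", "b", "c")
STRENGTHS = ("weak", "strong")
HYPOTHESES = ("null1", "null2", "null3", "alternative")

_STRENGTH_VALUE = {"weak": 0.15, "strong": 0.6}
_VARIED = (0.15, 0.3, 0.6)

#: smallest admissible eigenvalue of a correlation matrix
PD_TOL = 1e-10

#: stricter near-singularity screen applied when enumerating the catalogue;
#: grid corners this close to singular are excluded as study conditions
CATALOGUE_PD_TOL = 5e-3

#: implied coefficients smaller than this count as exactly zero
_COEF_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationCondition:
    """One simulation condition: a correlation matrix over (X, C, M, Y) plus labels."""

    rho: np.ndarray
    scenario: str | None = None
    strength: str | None = None
    hypothesis: str | None = None

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (4, 4):
            raise ValueError(f"rho must be 4x4, got shape {rho.shape}")
        if not np.allclose(rho, rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
            raise ValueError("rho must have a unit diagonal")
        if np.any(np.abs(rho) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        w = np.linalg.eigvalsh(rho)
        if w[0] <= PD_TOL:
            raise ValueError(
                f"correlation matrix is not positive definite "
                f"(smallest eigenvalue {w[0]:.3e})"
            )
        rho = rho.copy()
        rho.flags.writeable = False
        object.__setattr__(self, "rho", rho)

    # named accessors in the fixed (X, C, M, Y) order
    @property
    def rho_xc(self) -> float:
        return float(self.rho[0, 1])

    @property
    def rho_xm(self) -> float:
        return float(self.rho[0, 2])

    @property
    def rho_xy(self) -> float:
        return float(self.rho[0, 3])

    @property
    def rho_cm(self) -> float:
        return float(self.rho[1, 2])

    @property
    def rho_cy(self) -> float:
        return float(self.rho[1, 3])

    @property
    def rho_my(self) -> float:
        return float(self.rho[2, 3])

    @classmethod
    def from_correlations(
        cls,
        rho_xc: float = 0.0,
        rho_xm: float = 0.0,
        rho_cm: float = 0.0,
        rho_xy: float = 0.0,
        rho_cy: float = 0.0,
        rho_my: float = 0.0,
        scenario: str | None = None,
        strength: str | None = None,
        hypothesis: str | None = None,
    ) -> "CorrelationCondition":
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = rho_xc
        rho[0, 2] = rho[2, 0] = rho_xm
        rho[0, 3] = rho[3, 0] = rho_xy
        rho[1, 2] = rho[2, 1] = rho_cm
        rho[1, 3] = rho[3, 1] = rho_cy
        rho[2, 3] = rho[3, 2] = rho_my
        return cls(rho=rho, scenario=scenario, strength=strength, hypothesis=hypothesis)

    def to_dict(self) -> dict:
        """Plain-text-serializable mapping (six correlations plus labels)."""
        return {
            "rho_xc": self.rho_xc,
            "rho_xm": self.rho_xm,
            "rho_cm": self.rho_cm,
            "rho_xy": self.rho_xy,
            "rho_cy": self.rho_cy,
            "rho_my": self.rho_my,
            "scenario": self.scenario,
            "strength": self.strength,
            "hypothesis": self.hypothesis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationCondition":
        return cls.from_correlations(**d)

    def key(self) -> str:
        """Stable identifier used for seed derivation and table ordering."""
        corr = ",".join(
            f"{v:g}"
            for v in (self.rho_xc, self.rho_xm, self.rho_cm,
                      self.rho_xy, self.rho_cy, self.rho_my)
        )
        return f"{self.scenario}|{self.strength}|{self.hypothesis}|{corr}"


@dataclass(frozen=True)
class ImpliedCoefficients:
    """Population regression coefficients implied by a correlation structure."""

    alpha1: float
    alpha2: float
    gamma1: float
    gamma2: float
    gamma3: float

    @property
    def indirect(self) -> float:
        return self.alpha1 * self.gamma3


def implied_coefficients(condition: CorrelationCondition) -> ImpliedCoefficients:
    """Solve the population normal equations for both mediation models.

    For standardized jointly normal variables the population OLS slopes of the
    regression of target t on predictor set S are ``R[S,S]^{-1} R[S,t]``.
    """
    rho = condition.rho
    # M ~ (X, C)
    beta_m = np.linalg.solve(rho[np.ix_([0, 1], [0, 1])], rho[[0, 1], 2])
    # Y ~ (X, C, M)
    beta_y = np.linalg.solve(rho[np.ix_([0, 1, 2], [0, 1, 2])], rho[[0, 1, 2], 3])
    return ImpliedCoefficients(
        alpha1=float(beta_m[0]),
        alpha2=float(beta_m[1]),
        gamma1=float(beta_y[0]),
        gamma2=float(beta_y[1]),
        gamma3=float(beta_y[2]),
    )


def generate(condition: CorrelationCondition, n: int, seed=None) -> MediationData:
    """Draw an n-sample of (X, C, M, Y) from the condition's correlation matrix.

    An n x 4 matrix ``Z`` of i.i.d. standard normals is multiplied by the
    transposed lower Cholesky factor of ``rho`` (``V = Z @ L.T``), giving
    mean-0, variance-1 columns with population correlation ``rho``.
    ``seed`` may be anything ``numpy.random.default_rng`` accepts.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    try:
        chol = np.linalg.cholesky(condition.rho)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        w = np.linalg.eigvalsh(condition.rho)
        raise ValueError(
            f"correlation matrix is not positive definite "
            f"(smallest eigenvalue {w[0]:.3e})"
        ) from exc
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, 4)) @ chol.T
    return MediationData(x=values[:, 0], m=values[:, 2], y=values[:, 3], c=values[:, 1:2])


def _scenario_base(scenario: str, s: float) -> dict:
    if scenario == "a":
        return {"rho_xc": 0.0, "rho_cm": 0.0, "rho_cy": s}
    if scenario == "b":
        return {"rho_xc": s, "rho_cm": 0.0, "rho_cy": s}
    if scenario == "c":
        return {"rho_xc": 0.0, "rho_cm": s, "rho_cy": s}
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def _candidates(scenario: str, strength: str, hypothesis: str):
    s = _STRENGTH_VALUE[strength]
    base = _scenario_base(scenario, s)
    if hypothesis == "null1":
        yield dict(base, rho_xm=0.0, rho_my=0.0, rho_xy=s)
    elif hypothesis == "null2":
        for my in _VARIED:
            yield dict(base, rho_xm=0.0, rho_my=my, rho_xy=s)
    elif hypothesis == "null3":
        # gamma3 = 0 is unreachable on the grid unless the direct X-Y
        # correlation is also zero, so null3 sets rho_XY = rho_MY = 0.
        for xm in _VARIED:
            yield dict(base, rho_xm=xm, rho_my=0.0, rho_xy=0.0)
    elif hypothesis == "alternative":
        for xm in _VARIED:
            for my in _VARIED:
                yield dict(base, rho_xm=xm, rho_my=my, rho_xy=s)
    else:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}"
        )


def _matches_hypothesis(coef: ImpliedCoefficients, hypothesis: str) -> bool:
    a_zero = abs(coef.alpha1) <= _COEF_ZERO_TOL
    g_zero = abs(coef.gamma3) <= _COEF_ZERO_TOL
    return {
        "null1": a_zero and g_zero,
        "null2": a_zero and not g_zero,
        "null3": not a_zero and g_zero,
        "alternative": not a_zero and not g_zero,
    }[hypothesis]


def catalogue(
    scenario: str | None = None,
    strength: str | None = None,
    hypothesis: str | None = None,
) -> list[CorrelationCondition]:
    """Enumerate the simulation conditions, optionally filtered by label.

    Candidates are generated from the scenario/strength/hypothesis grid and
    kept only when the correlation matrix is positive definite (with the
    stricter ``CATALOGUE_PD_TOL`` near-singularity screen) and the implied
    (alpha1, gamma3) pair actually realizes the declared hypothesis family.
    Ordering is scenario, then strength (weak before strong), then hypothesis,
    then the varied correlation(s) ascending — the row order of the condition
    tables.
    """
    scenarios = SCENARIOS if scenario is None else (scenario,)
    strengths = STRENGTHS if strength is None else (strength,)
    hypotheses = HYPOTHESES if hypothesis is None else (hypothesis,)
    out: list[CorrelationCondition] = []
    for sc in scenarios:
        for st in strengths:
            if st not in STRENGTHS:
                raise ValueError(f"unknown strength {st!r}; expected one of {STRENGTHS}")
            for hyp in hypotheses:
                for cand in _candidates(sc, st, hyp):
                    try:
                        cond = CorrelationCondition.from_correlations(
                            scenario=sc, strength=st, hypothesis=hyp, **cand
                        )
                    except ValueError:
                        continue  # not positive definite
                    if np.linalg.eigvalsh(cond.rho)[0] <= CATALOGUE_PD_TOL:
                        continue  # too close to singular for a study condition
                    if _matches_hypothesis(implied_coefficients(cond), hyp):
                        out.append(cond)
    return out
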