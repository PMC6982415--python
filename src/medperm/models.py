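"""Linear-model machinery for regression-based mediation analysis.

The mediation model is the classic product-of-coefficients formulation: with
exposure ``X``, mediator ``M``, outcome ``Y`` and covariates ``C``,

    Y = gamma0 + gamma1*X + gamma2'C + gamma3*M + e_Y        (outcome model)
    M = alpha0 + alpha1*X + alpha2'C + e_M                   (mediator model)

and the indirect effect of ``X`` on ``Y`` through ``M`` is the product
``alpha1 * gamma3``.  The resampling tests in :mod:`medperm.permutation` also
need the *reduced* forms of each model — the regression with the coefficient
under test removed (``Y`` on ``X, C``; ``M`` on ``C``) — whose residuals are
the permutable units.

Coefficient vectors are always ordered (intercept, X, C columns..., M) for the
outcome model and (intercept, X, C columns...) for the mediator model, so
``alpha1`` is ``mediator_full.coefficients[1]`` and ``gamma3`` is
``outcome_full.coefficients[-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CollinearityError",
    "MediationData",
    "LinearFit",
    "FittedMediation",
    "fit_linear",
    "fit_mediation",
    "indirect_effect",
]

#: relative tolerance on singular values used for rank detection
RANK_RTOL = 1e-8


class CollinearityError(np.linalg.LinAlgError):
    """Raised when a design matrix is rank deficient.

    ``column`` is the 0-based index of the first offending column of the
    intercept-augmented design (0 = intercept).
    """

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


def _as_vector(name: str, v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


@dataclass(frozen=True)
class MediationData:
    """Aligned exposure/mediator/outcome/covariate columns for one analysis.

    Parameters
    ----------
    x, m, y : array-like, length n
        Exposure, mediator and outcome.
    c : array-like, shape (n, p) with p >= 0
        Covariate matrix.  May be empty (no covariate adjustment).
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    c: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self):
        x = _as_vector("x", self.x)
        m = _as_vector("m", self.m)
        y = _as_vector("y", self.y)
        c = np.asarray(self.c, dtype=float)
        if c.size == 0:
            c = np.empty((len(x), 0))
        if c.ndim == 1:
            c = c[:, None]
        if c.ndim != 2:
            raise ValueError(f"c must be 2-dimensional, got shape {c.shape}")
        n = len(x)
        if not (len(m) == len(y) == c.shape[0] == n):
            raise ValueError(
                "x, m, y and c must have the same number of rows: "
                f"{len(x)}, {len(m)}, {len(y)}, {c.shape[0]}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("c contains missing or non-finite values")
        if n < c.shape[1] + 4:
            raise ValueError(
                f"n = {n} is too small to fit the outcome model with "
                f"{c.shape[1]} covariate(s); need n >= p + 4"
            )
        for name, col in (("x", x), ("m", m), ("y", y)):
            if np.ptp(col) == 0:
                raise ValueError(f"{name} has zero variance")
        for j in range(c.shape[1]):
            if np.ptp(c[:, j]) == 0:
                raise ValueError(f"covariate column {j} has zero variance")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "c", c)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_covariates(self) -> int:
        return self.c.shape[1]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, x: str, m: str, y: str, c: tuple[str, ...] = ()
    ) -> "MediationData":
        """Map named columns of a DataFrame onto the x/m/y/c roles."""
        missing = [col for col in (x, m, y, *c) if col not in frame.columns]
        if missing:
            raise KeyError(f"columns not found in table: {missing}")
        cmat = frame.loc[:, list(c)].to_numpy(dtype=float) if c else np.empty((len(frame), 0))
        return cls(
            x=frame[x].to_numpy(dtype=float),
            m=frame[m].to_numpy(dtype=float),
            y=frame[y].to_numpy(dtype=float),
            c=cmat,
        )

    def take(self, idx) -> "MediationData":
        """Row subset / resample (used by the jackknife and case bootstrap)."""
        idx = np.asarray(idx)
        return MediationData(x=self.x[idx], m=self.m[idx], y=self.y[idx], c=self.c[idx])


@dataclass(frozen=True)
class LinearFit:
    """Least-squares fit: coefficients (intercept first), fitted values, residuals."""

    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def _find_dependent_column(design: np.ndarray) -> int:
    """First column of ``design`` linearly dependent on the columns before it."""
    rank = 0
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1], tol=None, hermitian=False)
        if new_rank == rank:
            return j
        rank = new_rank
    return design.shape[1] - 1


def fit_linear(response, predictors) -> LinearFit:
    """OLS of ``response`` on an intercept plus ``predictors``.

    Solved with an SVD-based least-squares routine (stable under near
    collinearity); rank deficiency relative to tolerance ``RANK_RTOL`` raises
    :class:`CollinearityError` naming the offending design column.
    """
    y = _as_vector("response", response)
    X = np.asarray(predictors, dtype=float)
    if X.size == 0:
        X = np.empty((len(y), 0))
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError(
            f"length mismatch: response has {len(y)} rows, predictors {X.shape[0]}"
        )
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=RANK_RTOL)
    if rank < design.shape[1]:
        col = _find_dependent_column(design)
        label = "intercept" if col == 0 else f"predictor column {col - 1}"
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"first dependent column: {label}",
            column=col,
        )
    fitted = design @ coef
    return LinearFit(coefficients=coef, fitted=fitted, residuals=y - fitted)


@dataclass(frozen=True)
class FittedMediation:
    """Full (and optionally reduced) mediation fits plus the indirect effect.

    ``outcome_full``   : Y ~ 1 + X + C + M   (coefficients gamma)
    ``mediator_full``  : M ~ 1 + X + C       (coefficients alpha)
    ``outcome_reduced``: Y ~ 1 + X + C       (M removed)
    ``mediator_reduced``: M ~ 1 + C          (X removed)
    """

    outcome_full: LinearFit
    mediator_full: LinearFit
    outcome_reduced: LinearFit | None
    mediator_reduced: LinearFit | None
    indirect: float

    @property
    def alpha1(self) -> float:
        return float(self.mediator_full.coefficients[1])

    @property
    def gamma3(self) -> float:
        return float(self.outcome_full.coefficients[-1])


def fit_mediation(data: MediationData, with_reduced: bool = False) -> FittedMediation:
    """Fit the full mediation regressions (and reduced forms if requested)."""
    xc = np.column_stack([data.x, data.c])
    outcome_full = fit_linear(data.y, np.column_stack([xc, data.m]))
    mediator_full = fit_linear(data.m, xc)
    outcome_reduced = mediator_reduced = None
    if with_reduced:
        outcome_reduced = fit_linear(data.y, xc)
        mediator_reduced = fit_linear(data.m, data.c)
    fit = FittedMediation(
        outcome_full=outcome_full,
        mediator_full=mediator_full,
        outcome_reduced=outcome_reduced,
        mediator_reduced=mediator_reduced,
        indirect=float(mediator_full.coefficients[1] * outcome_full.coefficients[-1]),
    )
    return fit


def indirect_effect(fit: FittedMediation) -> float:
    """The product-of-coefficients indirect effect ``alpha1 * gamma3``."""
    return fit.alpha1 * fit.gamma3
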