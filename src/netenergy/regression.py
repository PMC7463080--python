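"""Minimal least-squares engine (one or two predictors) with diagnostics.

Coefficients are computed by SVD-based least squares on the augmented
design matrix (intercept column first). The coefficient of determination
uses the centred total sum of squares; the root mean squared error uses
residual degrees of freedom n - p - 1 (p = number of predictors), the
convention under which a log-scale fit of heat production on intake
reproduces published RMSE magnitudes. No p-values are computed: group
comparison inference is not part of the factorial estimation chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegreesOfFreedomError, RankError, ValidationError

#: Condition-number threshold above which predictors are declared collinear.
COND_MAX = 1e10


@dataclass(frozen=True)
class FitResult:
    """OLS fit: coefficients (intercept first), R^2, RMSE, sample size."""

    coefficients: tuple[float, ...]
    r2: float
    rmse: float
    n: int
    cond: float

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        """Slope of a single-predictor fit."""
        if len(self.coefficients) != 2:
            raise ValidationError(
                "slope is only defined for single-predictor fits"
            )
        return self.coefficients[1]


def ols(
    y: "np.typing.ArrayLike",
    X: "np.typing.ArrayLike",
    weights: "np.typing.ArrayLike | None" = None,
) -> FitResult:
    """(Weighted) ordinary least squares of y on one or more predictors.

    ``X`` is a vector (one predictor) or an (n, k) array of predictor
    columns; an intercept is always added. Optional ``weights`` are
    per-observation weights applied to the squared residuals.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValidationError(f"y has {y.shape[0]} rows but X has {n}")
    p = k + 1  # coefficients including intercept
    if n < p:
        raise DegreesOfFreedomError(
            f"need at least {p} observations for {k} predictor(s), got {n}"
        )

    A = np.column_stack([np.ones(n), X])
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != n or np.any(w < 0):
            raise ValidationError("weights must be non-negative, one per row")
        sw = np.sqrt(w)
        Aw, yw = A * sw[:, None], y * sw
    else:
        w = np.ones(n)
        Aw, yw = A, y

    cond = float(np.linalg.cond(Aw))
    if not np.isfinite(cond) or cond > COND_MAX:
        raise RankError(
            f"predictors are collinear (condition number {cond:.3g})"
        )

    beta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    resid = y - A @ beta
    ssr = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    dof = n - p
    rmse = float(np.sqrt(ssr / dof)) if dof > 0 else float("nan")
    return FitResult(
        coefficients=tuple(float(b) for b in beta),
        r2=r2, rmse=rmse, n=n, cond=cond,
    )


def x_intercept(fit: FitResult) -> float:
    """Where a single-predictor fitted line crosses zero response."""
    slope = fit.slope  # raises for multi-predictor fits
    if slope == 0:
        raise ValidationError("x-intercept undefined for zero slope")
    return -fit.intercept / slope
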