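"""Seasonal-curve smoothing and the continuous predictability index.

A penalized cubic B-spline regression of normalized area on day-of-year,
with the penalty weight chosen by generalized cross-validation (GCV), plays
the role of an additive model with one smooth term.  Predictability is the
reciprocal of the residual standard deviation (n-1 divisor):

    predictability = 1 / sd(residuals)

Two variants differ only in the normalizing mean: ``GAM_a`` uses the
balanced mean over all cloud-free observations, ``GAM_w`` the mean over wet
observations only (zeros stay in the regression unless ``fit_zeros=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import DegenerateFitError, EstimationError, InputError
from .timeseries import PondSeries, mean_area, normalize

#: Basis dimension: number of cubic B-spline basis functions.
DEFAULT_K = 8

_DEGREE = 3
_DOMAIN = (0.5, 366.5)  # covers every legal day-of-year
_LOG10_LAMBDA_GRID = np.linspace(-8.0, 8.0, 81)

# Residual SDs at or below this are round-off, not signal: on the normalized
# A' scale (values near 1) genuine residual spread is orders larger.
_DEGENERATE_SD = 1e-10


@dataclass
class SeasonalFit:
    """A fitted penalized-spline seasonal curve and its residuals."""

    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    gcv: float
    edf: float
    fitted: np.ndarray
    residuals: np.ndarray
    n_obs: int

    @property
    def degenerate(self) -> bool:
        """True when the fit is exact (residual variance at round-off level)."""
        return bool(np.std(self.residuals) <= _DEGENERATE_SD)

    def predict(self, day_of_year) -> np.ndarray:
        x = np.clip(np.asarray(day_of_year, dtype=np.float64), *_DOMAIN)
        return BSpline(self.knots, self.coefficients, _DEGREE)(x)


@dataclass(frozen=True)
class GamResult:
    variant: str
    p_gam: float
    sd_res: float
    fit: SeasonalFit
    mean_used: float


def _basis(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with k basis functions over the DOY domain."""
    lo, hi = _DOMAIN
    n_interior = k - _DEGREE - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)])
    design = BSpline.design_matrix(x, knots, _DEGREE).toarray()
    return design, knots


def _second_difference_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


def fit_seasonal_curve(points, k: int = DEFAULT_K, cyclic: bool = False) -> SeasonalFit:
    """Penalized least-squares cubic-spline fit of A' on day-of-year.

    The smoothing weight is picked by minimizing GCV over a fixed log-spaced
    grid, so the fit is deterministic for a given input.

    ``cyclic=True`` approximates a periodic smooth by replicating the data at
    +/- 365 days and fitting over the widened support; off by default.
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be (day_of_year, value) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.any((x < 1) | (x > 366)):
        raise InputError("day_of_year must lie in [1, 366]")
    if k < _DEGREE + 2:
        raise InputError(f"basis dimension k must be >= {_DEGREE + 2}")
    n = len(x)
    if len(np.unique(x)) < 2 * k:
        raise EstimationError(
            f"need at least {2 * k} distinct days for a k={k} basis, got {len(np.unique(x))}"
        )

    if cyclic:
        x_fit = np.concatenate([x - 365.0, x, x + 365.0])
        y_fit = np.concatenate([y, y, y])
        lo, hi = _DOMAIN
        n_interior = 3 * k - _DEGREE - 1
        interior = np.linspace(lo - 365, hi + 365, n_interior + 2)[1:-1]
        knots = np.concatenate(
            [[lo - 365] * (_DEGREE + 1), interior, [hi + 365] * (_DEGREE + 1)]
        )
        design_fit = BSpline.design_matrix(x_fit, knots, _DEGREE).toarray()
        design = BSpline.design_matrix(x, knots, _DEGREE).toarray()
    else:
        x_fit, y_fit = x, y
        design_fit, knots = _basis(x, k)
        design = design_fit

    n_fit = len(x_fit)
    penalty = _second_difference_penalty(design_fit.shape[1])
    bt_b = design_fit.T @ design_fit
    bt_y = design_fit.T @ y_fit

    best = None
    for lam in 10.0 ** _LOG10_LAMBDA_GRID:
        try:
            coef = np.linalg.solve(bt_b + lam * penalty, bt_y)
            hat_core = np.linalg.solve(bt_b + lam * penalty, bt_b)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(hat_core))
        rss = float(np.sum((y_fit - design_fit @ coef) ** 2))
        denom = max(n_fit - edf, 1e-8)
        gcv = n_fit * rss / denom**2
        if best is None or gcv < best[0] - 1e-15:
            best = (gcv, lam, coef, edf)
    if best is None:
        raise EstimationError("spline system singular at every smoothing weight")
    gcv, lam, coef, edf = best
    fitted = design @ coef
    return SeasonalFit(
        knots=knots,
        coefficients=coef,
        lam=lam,
        gcv=gcv,
        edf=edf,
        fitted=fitted,
        residuals=y - fitted,
        n_obs=n,
    )


def p_gam(fit: SeasonalFit) -> float:
    """Reciprocal residual standard deviation (n-1 divisor)."""
    if fit.n_obs < 3:
        raise EstimationError("need at least 3 observations for a residual SD")
    sd = float(np.std(fit.residuals, ddof=1))
    if sd <= _DEGENERATE_SD:
        raise DegenerateFitError(
            "zero residual variance: predictability is infinite, not a finite value"
        )
    return 1.0 / sd


def run_continuous_model(series: PondSeries, variant: str, k: int = DEFAULT_K,
                         cyclic: bool = False, fit_zeros: bool = True) -> GamResult:
    """Normalize, fit the seasonal curve, and score one pond.

    ``fit_zeros=False`` additionally drops dry observations from the
    regression for GAM_w (by default they are dropped only from the mean).
    """
    if variant not in ("GAM_a", "GAM_w"):
        raise InputError(f"unknown continuous model {variant!r}")
    exclude_zeros = variant == "GAM_w"
    mean = mean_area(series, exclude_zeros=exclude_zeros)
    points = normalize(series, mean)
    if exclude_zeros and not fit_zeros:
        points = [(d, v) for d, v in points if v > 0]
    fit = fit_seasonal_curve(points, k=k, cyclic=cyclic)
    sd = float(np.std(fit.residuals, ddof=1))
    return GamResult(
        variant=variant,
        p_gam=p_gam(fit),
        sd_res=sd,
        fit=fit,
        mean_used=mean,
    )
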