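"""The two analytical curves of the method, with linearity diagnostics.

Concentration curve
    peak area = slope * concentration + intercept, fit by ordinary least
    squares over the calibration levels of one molecular-weight standard
    (curves are fit per standard, because the response factor varies with MW).

Molecular-weight curve
    Kav = slope * ln(MW) + intercept over the MW standards, slope < 0 since
    larger molecules access less pore volume and elute earlier.  The inverse,
    MW = exp((Kav - intercept)/slope), converts observed retention into
    molecular weight for unknowns.

Fits are unweighted OLS (scipy.stats.linregress) with the usual simple-
regression diagnostics: R², adjusted R², Pearson r, residual standard
deviation and coefficient standard errors; Student t-tests check that the
slope differs from zero and that the intercept is compatible with zero
(the proportionality requirement for an interference-free method).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import (
    BelowBlankWarning,
    DomainError,
    ExtrapolationWarning,
    NonInvertibleError,
    SingularDesignError,
)

__all__ = [
    "LinearFit",
    "fit_concentration_curve",
    "fit_mw_curve",
    "t_test_coefficients",
    "predict_concentration",
    "kav_theoretical",
    "mw_from_kav",
]


@dataclass(frozen=True)
class LinearFit:
    """A simple linear regression y = slope*x + intercept with diagnostics.

    ``curve_kind`` is ``"concentration"`` (x = mg/L, y = peak area) or
    ``"molecular_weight"`` (x = ln MW, y = Kav).  ``x_min``/``x_max`` record
    the regressor range of the standards, in the regressor's own units, and
    drive extrapolation warnings.  ``adj_r2`` is NaN when n == 2 (no residual
    degrees of freedom).
    """

    slope: float
    intercept: float
    n: int
    r2: float
    adj_r2: float
    pearson_r: float
    residual_sd: float
    se_slope: float
    se_intercept: float
    curve_kind: str
    x_min: float
    x_max: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2)


def _ols(x, y, curve_kind: str, min_points: int) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < min_points:
        raise DomainError(f"need at least {min_points} points, got {n}")
    if np.ptp(x) == 0:
        raise SingularDesignError("all x values identical: design is singular")

    if n == 2:
        # exact interpolating line; no residual degrees of freedom
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return LinearFit(
            slope=float(slope), intercept=float(intercept), n=2,
            r2=1.0, adj_r2=math.nan, pearson_r=float(math.copysign(1.0, slope)),
            residual_sd=0.0, se_slope=math.nan, se_intercept=math.nan,
            curve_kind=curve_kind, x_min=float(x.min()), x_max=float(x.max()),
        )

    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    sse = float(np.dot(resid, resid))
    sst = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    adj_r2 = math.nan if n <= 2 else 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    residual_sd = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
        r2=float(min(max(r2, 0.0), 1.0)),
        adj_r2=adj_r2,
        pearson_r=float(res.rvalue),
        residual_sd=residual_sd,
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        curve_kind=curve_kind,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def fit_concentration_curve(points) -> LinearFit:
    """OLS line through (concentration mg/L, peak area) calibration points.

    ``points`` is a sequence of (concentration, area) pairs or a pair of
    arrays.  At least three points with at least two distinct concentrations
    are required.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        conc, area = arr[:, 0], arr[:, 1]
    elif arr.ndim == 2 and arr.shape[0] == 2:
        conc, area = arr[0], arr[1]
    else:
        raise DomainError("points must be (concentration, area) pairs")
    return _ols(conc, area, "concentration", min_points=3)


def fit_mw_curve(standards) -> LinearFit:
    """OLS line Kav = slope*ln(MW) + intercept through the MW standards.

    ``standards`` is a sequence of (average MW in Da, observed Kav) pairs.
    The natural logarithm of MW is the regressor; at least two standards with
    distinct MW are required.  A negative slope is expected (larger molecules
    elute earlier) but not enforced here — downstream DP slicing checks it.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("standards must be (mw_da, kav) pairs")
    mw, kav_obs = arr[:, 0], arr[:, 1]
    if np.any(mw <= 0):
        raise DomainError("molecular weights must be strictly positive")
    return _ols(np.log(mw), kav_obs, "molecular_weight", min_points=2)


def t_test_coefficients(fit: LinearFit):
    """Student t statistics and two-sided p-values for slope and intercept.

    t = coefficient / standard error with n − 2 degrees of freedom.  Used to
    check that the slope differs from zero (a real response) and that the
    intercept is compatible with zero (no systematic interference).  A zero
    standard error with a nonzero coefficient reports t = ±inf, p = 0.
    """
    if fit.n < 3:
        raise DomainError("t-tests need at least 3 points")
    df = fit.n - 2

    def one(coef, se):
        if se == 0:
            if coef == 0:
                return 0.0, 1.0
            return math.copysign(math.inf, coef), 0.0
        t = coef / se
        return t, float(2 * stats.t.sf(abs(t), df))

    t_s, p_s = one(fit.slope, fit.se_slope)
    t_i, p_i = one(fit.intercept, fit.se_intercept)
    return t_s, p_s, t_i, p_i


def predict_concentration(area: float, fit: LinearFit) -> float:
    """Invert the concentration curve: (area − intercept) / slope, mg/L.

    Negative results (response below the blank) are returned but flagged with
    :class:`BelowBlankWarning`.
    """
    if fit.curve_kind != "concentration":
        raise DomainError("fit is not a concentration curve")
    if fit.slope == 0:
        raise NonInvertibleError("zero slope: curve cannot be inverted")
    conc = (area - fit.intercept) / fit.slope
    if conc < 0:
        warnings.warn(
            f"predicted concentration {conc:.3g} mg/L is below the blank",
            BelowBlankWarning,
            stacklevel=2,
        )
    return float(conc)


def _check_mw_fit(fit: LinearFit) -> None:
    if fit.curve_kind != "molecular_weight":
        raise DomainError("fit is not a molecular-weight curve")
    if fit.slope == 0:
        raise NonInvertibleError("zero slope: MW curve cannot be inverted")


def kav_theoretical(mw, fit: LinearFit):
    """Theoretical Kav of a species of molecular weight ``mw`` (Da).

    Evaluating beyond the standards' MW range emits an
    :class:`ExtrapolationWarning` (the curve is only trusted between its
    calibration points).
    """
    _check_mw_fit(fit)
    mw_arr = np.asarray(mw, dtype=float)
    if np.any(mw_arr <= 0):
        raise DomainError("molecular weight must be strictly positive")
    ln_mw = np.log(mw_arr)
    if np.any(ln_mw < fit.x_min - 1e-12) or np.any(ln_mw > fit.x_max + 1e-12):
        warnings.warn(
            "molecular weight outside the calibrated standard range "
            f"[{math.exp(fit.x_min):.3g}, {math.exp(fit.x_max):.3g}] Da",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = fit.slope * ln_mw + fit.intercept
    return float(out) if np.isscalar(mw) else out


def mw_from_kav(kav, fit: LinearFit):
    """Molecular weight (Da) whose theoretical Kav equals ``kav``.

    Exact inverse of :func:`kav_theoretical`; extrapolation beyond the
    standards' Kav range is flagged.
    """
    _check_mw_fit(fit)
    kav_arr = np.asarray(kav, dtype=float)
    k_lo, k_hi = sorted((fit.predict(fit.x_min), fit.predict(fit.x_max)))
    if np.any(kav_arr < k_lo - 1e-12) or np.any(kav_arr > k_hi + 1e-12):
        warnings.warn(
            f"Kav outside the calibrated range [{k_lo:.4g}, {k_hi:.4g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = np.exp((kav_arr - fit.intercept) / fit.slope)
    return float(out) if np.isscalar(kav) else out
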