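"""Per-region Poisson regression of daily mortality on temperature.

The model for one region's daily cardiovascular death count ``Y_t`` is a
Poisson log-linear model with smooth terms,

    log E[Y_t] = alpha + sum_k beta_k * hinge_k(T)
                 + s(rh_t, 3) + s(time_t, 7 per year) + lambda' * DOW_t,

where the hinge terms capture excess risk beyond region-specific reference
temperatures: the 10th percentile of the daily temperature distribution for
cold, the 90th for heat. Cold effects are allowed to act over two weeks and
heat effects over a few days, so temperature enters through stratified lag
variables — window means over lags 1-3, 4-8 and 9-14 days. The cold model
carries a hinge ``max(tau_low - T, 0)`` on each of the three strata (their
coefficients are summed into one reported slope, the log-rate increase for a
sustained 1 degC exceedance); the heat model carries a single hinge
``max(T - tau_high, 0)`` on the 1-3 day stratum. The sign convention makes a
positive slope mean "risk rises as the exceedance grows" on both sides.

Smooth terms are fixed-df natural cubic regression splines, which makes the
whole fit an ordinary Poisson GLM solved by iteratively reweighted least
squares. Effects are reported as the percent change in mortality per 1 degC
beyond threshold, ``(exp(beta) - 1) * 100``; negative estimates are floored
at zero (and flagged), treating "no deleterious effect" as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "TemperatureThresholds",
    "SplineBasis",
    "GamFit",
    "EffectEstimate",
    "validate_series",
    "temperature_thresholds",
    "build_lag_features",
    "natural_spline_basis",
    "assemble_design",
    "fit_poisson",
    "percent_change",
    "select_indicator_by_aic",
    "estimate_effects",
    "InsufficientDataError",
    "CollinearityError",
    "ConvergenceError",
]

INDICATORS = ("tmean", "tmax", "tmin")
LAG_WINDOWS = {"1_3": (1, 3), "4_8": (4, 8), "9_14": (9, 14)}
MAX_LAG = 14
DOW_REFERENCE = 0  # Monday


class InsufficientDataError(ValueError):
    pass


class CollinearityError(np.linalg.LinAlgError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TemperatureThresholds:
    """Reference temperatures: tau_low = p_low-th percentile, tau_high =
    p_high-th percentile of the region's daily indicator series."""

    tau_low: float
    tau_high: float
    indicator: str = "tmean"

    def __post_init__(self):
        if not self.tau_low <= self.tau_high:
            raise ValueError("tau_low must not exceed tau_high")


@dataclass
class SplineBasis:
    """A centered natural-cubic regression-spline column block."""

    name: str
    df: int
    knots: np.ndarray
    matrix: np.ndarray  # (n, df), column-centered
    column_means: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the same basis (same knots, same centering) at new x."""
        return _natural_spline_matrix(np.asarray(x, float), self.knots) - self.column_means


@dataclass
class GamFit:
    """A converged Poisson IRLS fit.

    ``params``/``cov`` are indexed by design column name; ``aic`` satisfies
    AIC = -2 loglik + 2 * n_params.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    n_obs: int
    n_iter: int
    fitted: np.ndarray
    residuals: np.ndarray  # response residuals y - mu
    deviance: float

    @property
    def alpha(self) -> float:
        return float(self.params["intercept"])

    def hinge_columns(self) -> list[str]:
        return [c for c in self.params.index if c.startswith(("cold_", "heat_"))]

    def dow_params(self) -> pd.Series:
        return self.params[[c for c in self.params.index if c.startswith("dow_")]]


@dataclass
class EffectEstimate:
    """Percent change in mortality per 1 degC beyond threshold, one side.

    ``beta_total`` is the summed hinge slope (raw, sign-preserving, used for
    interval coverage); ``percent_change`` is ``(exp(beta_total)-1)*100``
    floored at 0 with ``floored=True`` when the raw value was negative.
    """

    region_id: str
    side: str
    indicator: str
    tau: float
    beta_total: float
    se: float
    percent_change: float
    floored: bool

    def wald_interval(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (self.beta_total - z * self.se, self.beta_total + z * self.se)


# ---------------------------------------------------------------------------
# series plumbing


def validate_series(series: pd.DataFrame, require_deaths: bool = True) -> pd.DataFrame:
    """Check a daily region series and return it sorted by date."""
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in series")
    gaps = df["date"].diff().dropna()
    if (gaps != pd.Timedelta(days=1)).any():
        missing = pd.date_range(df["date"].min(), df["date"].max()).difference(df["date"])
        raise ValueError(f"series has date gaps ({len(missing)} missing day(s), "
                         f"first {missing[0].date()})")
    if require_deaths:
        if (df["deaths"] < 0).any():
            raise ValueError("negative death counts")
        if not np.allclose(df["deaths"], np.round(df["deaths"])):
            raise ValueError("death counts must be integers")
    if ((df["rh"] < 0) | (df["rh"] > 100)).any():
        raise ValueError("relative humidity outside [0, 100]")
    return df


def temperature_thresholds(series: pd.DataFrame, p_low: float = 10.0,
                           p_high: float = 90.0, indicator: str = "tmean",
                           min_days: int = 100,
                           method: str = "linear") -> TemperatureThresholds:
    """Reference temperatures from the series' empirical percentiles.

    Percentiles use numpy's linear-interpolation convention by default
    (``method`` is passed through to :func:`numpy.percentile`).
    """
    x = np.asarray(series[indicator], dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_days:
        raise InsufficientDataError(
            f"need >= {min_days} non-missing {indicator} days, have {x.size}")
    lo, hi = np.percentile(x, [p_low, p_high], method=method)
    return TemperatureThresholds(float(lo), float(hi), indicator)


def build_lag_features(series: pd.DataFrame, indicator: str = "tmean") -> pd.DataFrame:
    """Stratified lag variables: window means of the indicator over lags
    1-3, 4-8 and 9-14 days. Days without full 14-day history get NaN and
    are excluded from the analysis set downstream."""
    df = validate_series(series, require_deaths=False)
    x = df[indicator].to_numpy(dtype=float)
    out = pd.DataFrame({"date": df["date"]})
    for name, (a, b) in LAG_WINDOWS.items():
        width = b - a + 1
        acc = np.full((width, len(x)), np.nan)
        for i, lag in enumerate(range(a, b + 1)):
            acc[i, lag:] = x[: len(x) - lag]
        out[f"T_{name}"] = acc.mean(axis=0)
    # only days with the full 14-day history enter the analysis set
    out.loc[: MAX_LAG - 1, [f"T_{k}" for k in LAG_WINDOWS]] = np.nan
    return out


# ---------------------------------------------------------------------------
# spline basis


def _natural_spline_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) at the given knots.

    With K knots the natural-spline space has dimension K (including the
    constant); this returns the K-1 non-constant columns: x itself plus the
    K-2 curvature terms d_k(x) - d_{K-1}(x) with
    d_k(x) = [(x - k_k)_+^3 - (x - k_K)_+^3] / (k_K - k_k).
    Linear beyond the boundary knots by construction.
    """
    K = len(knots)
    cols = [x]

    def d(k):
        return (np.maximum(x - knots[k], 0.0) ** 3
                - np.maximum(x - knots[-1], 0.0) ** 3) / (knots[-1] - knots[k])

    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def natural_spline_basis(x, df: int, name: str = "s") -> SplineBasis:
    """Fixed-df natural cubic regression-spline block for one covariate.

    Boundary knots at min/max of ``x``, ``df - 1`` interior knots at equally
    spaced quantiles; ``df`` columns, centered so the block is identifiable
    next to an intercept. The span contains every linear function of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("spline df must be >= 2")
    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise np.linalg.LinAlgError(
            f"covariate {name!r} has {distinct.size} distinct values; "
            f"need > df = {df}")
    probs = np.linspace(0, 100, df + 1)
    knots = np.unique(np.percentile(x, probs, method="linear"))
    if knots.size < df + 1:
        raise np.linalg.LinAlgError(
            f"covariate {name!r}: tied quantiles leave {knots.size} distinct "
            f"knots for df = {df}")
    m = _natural_spline_matrix(x, knots)
    means = m.mean(axis=0)
    return SplineBasis(name, df, knots, m - means, means)


# ---------------------------------------------------------------------------
# design assembly


def time_spline_df(n_days: int, per_year: float = 7.0) -> int:
    """Calendar-time smoothness: ``per_year`` degrees of freedom per year of
    data, rounded to the nearest integer, never below 4."""
    years = n_days / 365.25
    return max(4, int(round(per_year * years)))


def assemble_design(series: pd.DataFrame, lags: pd.DataFrame,
                    thresholds: TemperatureThresholds, side: str,
                    rh_df: int = 3, time_df_per_year: float = 7.0):
    """Build the GLM design matrix and response for one side.

    Columns: intercept; hinge temperature terms (cold: ``max(tau_low - T, 0)``
    on strata 1-3/4-8/9-14; heat: ``max(T - tau_high, 0)`` on stratum 1-3);
    a df-3 humidity spline block; a calendar-time spline block with 7 df per
    year; and 6 day-of-week dummies (Monday reference).

    Returns ``(X, y, info)`` with ``X`` a DataFrame indexed like the retained
    (full-lag-history, complete-case) rows.
    """
    if side not in ("cold", "heat"):
        raise ValueError(f"side must be 'cold' or 'heat', got {side!r}")
    df = validate_series(series)
    merged = df.merge(lags, on="date", how="left")
    strata = ["1_3", "4_8", "9_14"] if side == "cold" else ["1_3"]
    lag_cols = [f"T_{k}" for k in strata]
    keep = merged[lag_cols + ["deaths", "rh"]].notna().all(axis=1)
    merged = merged.loc[keep].reset_index(drop=True)
    if len(merged) < 50:
        raise InsufficientDataError(
            f"only {len(merged)} complete days after lag trimming")

    X = pd.DataFrame({"intercept": np.ones(len(merged))})
    for k in strata:
        T = merged[f"T_{k}"].to_numpy(dtype=float)
        if side == "cold":
            X[f"cold_{k}"] = np.maximum(thresholds.tau_low - T, 0.0)
        else:
            X[f"heat_{k}"] = np.maximum(T - thresholds.tau_high, 0.0)

    rh_basis = natural_spline_basis(merged["rh"].to_numpy(), rh_df, "rh")
    for j in range(rh_df):
        X[f"rh_s{j + 1}"] = rh_basis.matrix[:, j]

    t_df = time_spline_df(len(df), time_df_per_year)
    tvar = (merged["date"] - df["date"].iloc[0]).dt.days.to_numpy(dtype=float)
    time_basis = natural_spline_basis(tvar, t_df, "time")
    for j in range(t_df):
        X[f"time_s{j + 1}"] = time_basis.matrix[:, j]

    dow = merged["date"].dt.dayofweek
    labels = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
    for d in range(7):
        if d == DOW_REFERENCE:
            continue
        col = (dow == d).astype(float)
        if col.any():
            X[f"dow_{labels[d]}"] = col

    y = merged["deaths"].to_numpy(dtype=float)
    info = {"dates": merged["date"], "thresholds": thresholds, "side": side,
            "hinge_columns": [c for c in X.columns if c.startswith(("cold_", "heat_"))],
            "time_df": t_df}
    return X, y, info


# ---------------------------------------------------------------------------
# fitting


def _check_rank(X: np.ndarray, names) -> None:
    n, p = X.shape
    if n < p:
        raise CollinearityError(f"more columns ({p}) than rows ({n})")
    # QR with pivoting flags the dependent columns by near-zero R diagonal
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(p) if diag[i] <= tol]
    if bad:
        raise CollinearityError(f"design is rank-deficient; dependent columns: {bad}")


def fit_poisson(X, y, max_iter: int = 100, tol: float = 1e-8) -> GamFit:
    """Poisson log-link maximum likelihood via IRLS.

    Convergence: relative change in deviance below ``tol`` (default 1e-8)
    or ``max_iter`` iterations, whichever first; non-convergence raises with
    the deviance trace. The coefficient covariance is the inverse Fisher
    information ``(X' W X)^{-1}`` at the optimum.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    _check_rank(Xm, names)

    mu = np.maximum(y, 0.0) + 0.5  # safe all-positive start
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    beta = np.zeros(Xm.shape[1])
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        W = mu
        XtW = Xm.T * W
        beta_new = np.linalg.solve(XtW @ Xm, XtW @ z)
        eta = np.clip(Xm @ beta_new, -30, 30)
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        trace.append(dev_new)
        beta = beta_new
        if abs(dev_new - dev) / (abs(dev) + 0.1) < tol:
            dev = dev_new
            break
        dev = dev_new
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations; deviance trace "
            f"tail: {[f'{d:.6g}' for d in trace[-5:]]}")

    fisher = (Xm.T * mu) @ Xm
    cov = np.linalg.inv(fisher)
    cov = (cov + cov.T) / 2.0
    loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    p = Xm.shape[1]
    return GamFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * p,
        n_obs=len(y),
        n_iter=it,
        fitted=mu,
        residuals=y - mu,
        deviance=float(dev),
    )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def percent_change(beta_total: float) -> float:
    """Percent change in mortality per 1 degC beyond threshold:
    ``(exp(beta) - 1) * 100``."""
    if not np.isfinite(beta_total):
        raise ValueError(f"beta must be finite, got {beta_total}")
    return float((np.exp(beta_total) - 1.0) * 100.0)


# ---------------------------------------------------------------------------
# model selection and effect estimation


def fit_side(series: pd.DataFrame, side: str, indicator: str = "tmean",
             p_low: float = 10.0, p_high: float = 90.0):
    """Fit one region / one side / one temperature indicator end to end."""
    thresholds = temperature_thresholds(series, p_low, p_high, indicator)
    lags = build_lag_features(series, indicator)
    X, y, info = assemble_design(series, lags, thresholds, side)
    fit = fit_poisson(X, y)
    return fit, thresholds, info


def select_indicator_by_aic(series: pd.DataFrame, side: str,
                            p_low: float = 10.0, p_high: float = 90.0):
    """Fit the full model once per temperature indicator (mean, max, min)
    and keep the indicator with minimal AIC; ties break mean > max > min.

    Returns ``(indicator, fits)`` with ``fits`` a dict of all three GamFits.
    """
    fits = {}
    for ind in INDICATORS:
        try:
            fits[ind], _, _ = fit_side(series, side, ind, p_low, p_high)
        except Exception as e:
            raise type(e)(f"indicator {ind!r}: {e}") from e
    best = min(INDICATORS, key=lambda ind: (fits[ind].aic, INDICATORS.index(ind)))
    return best, fits


def estimate_effects(series: pd.DataFrame, side: str, region_id: str = "",
                     indicator: str = "tmean", p_low: float = 10.0,
                     p_high: float = 90.0) -> EffectEstimate:
    """Estimate the per-degC percent change for one region and side.

    The reported slope is the sum of the side's hinge coefficients (the
    effect of a sustained 1 degC exceedance); its standard error comes from
    the delta method on the coefficient covariance. A negative percent
    change is floored at 0 and flagged, treating "no deleterious effect" as
    the reference.
    """
    fit, thresholds, info = fit_side(series, side, indicator, p_low, p_high)
    hinge = info["hinge_columns"]
    beta_total = float(fit.params[hinge].sum())
    ones = np.ones(len(hinge))
    se = float(np.sqrt(ones @ fit.cov.loc[hinge, hinge].to_numpy() @ ones))
    pc = percent_change(beta_total)
    floored = pc < 0
    return EffectEstimate(
        region_id=region_id,
        side=side,
        indicator=indicator,
        tau=thresholds.tau_low if side == "cold" else thresholds.tau_high,
        beta_total=beta_total,
        se=se,
        percent_change=0.0 if floored else pc,
        floored=floored,
    )
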