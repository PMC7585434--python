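"""Path models, meta-analytic pooling, treatment contrasts, and bivariate fits.

The causal structure linking diversity to stability across scales is fit as
a piecewise path model: each endogenous variable is regressed on its parents
by ordinary least squares after z-scoring every variable, so coefficients
are standardized and comparable across paths.  One model is fit per
experimental-duration window and treatment; coefficients are then pooled
across durations by fixed-effect inverse-variance meta-analysis
(DerSimonian-Laird random-effects reported alongside), and
control-vs-fertilized differences per path are tested with a two-group
Cochrane Q statistic (chi-square, df = 1).

Also here: bivariate diversity-stability slopes with AR(1) errors across
nested duration windows (iterated Cochrane-Orcutt), log response ratios,
residualization on climate-variability covariates, two-way ANOVA for
treatment and duration effects, and the overlapping 4-year interval helper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError

#: Default path model: diversity -> asynchrony/stability within communities,
#: beta diversity -> spatial asynchrony among them, chaining to gamma stability.
DEFAULT_PATHS = (
    ("species_stability", ("richness",)),
    ("species_asynchrony", ("richness",)),
    ("alpha_stability", ("species_stability", "species_asynchrony")),
    ("spatial_asynchrony", ("beta_diversity",)),
    ("gamma_stability", ("alpha_stability", "spatial_asynchrony")),
)

#: Exogenous variables whose association is reported as a correlation, not a path.
EXOGENOUS_CORRELATION = ("richness", "beta_diversity")


@dataclass(frozen=True)
class PathModelSpec:
    """An acyclic set of (response, predictors) regressions."""

    paths: tuple = DEFAULT_PATHS

    def __post_init__(self):
        # responses must not feed back into their own ancestry
        order: list[str] = []
        for resp, preds in self.paths:
            if resp in order:
                raise ValidationError(f"response {resp!r} appears twice")
            order.append(resp)
        known_resps = {r for r, _ in self.paths}
        for i, (resp, preds) in enumerate(self.paths):
            for p in preds:
                if p in known_resps and order.index(p) > i:
                    raise ValidationError(
                        f"path model is not acyclic at {p!r} -> {resp!r}"
                    )

    @property
    def variables(self) -> tuple:
        seen: list[str] = []
        for resp, preds in self.paths:
            for v in (*preds, resp):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def edge_names(self) -> list[str]:
        return [f"{p}->{r}" for r, preds in self.paths for p in preds]


@dataclass(frozen=True)
class PathFit:
    """Standardized coefficients for one duration x treatment fit."""

    coefficients: dict  # "pred->resp" -> (coef, se)
    r_squared: dict  # resp -> R^2
    n: int
    duration_years: int | None = None
    treatment: str | None = None
    exogenous_correlation: float | None = None

    def coef(self, edge: str) -> float:
        return self.coefficients[edge][0]

    def se(self, edge: str) -> float:
        return self.coefficients[edge][1]


@dataclass(frozen=True)
class MetaEstimate:
    """Pooled estimate for one path across durations."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    q_heterogeneity: float
    df: int
    p_heterogeneity: float
    pooled_random: float
    se_random: float
    tau_squared: float
    k: int


@dataclass(frozen=True)
class SlopeFit:
    """Bivariate slope with AR(1) errors (iterated Cochrane-Orcutt)."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    rho: float
    converged: bool
    n: int


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError(f"variable {name!r} has zero variance")
    return (x - x.mean()) / sd


def standardized_path_fit(
    metrics: pd.DataFrame,
    spec: PathModelSpec = PathModelSpec(),
    duration_years: int | None = None,
    treatment: str | None = None,
) -> PathFit:
    """Fit every path regression on z-scored variables; one row per site.

    Stability/asynchrony columns are expected already log-transformed.
    Returns standardized coefficients with their least-squares standard
    errors, per-response R^2, and (when both exogenous diversity variables
    are present) their Pearson correlation.
    """
    largest = max(len(preds) for _, preds in spec.paths)
    df = metrics.dropna(subset=list(spec.variables))
    n = len(df)
    if n < largest + 3:
        raise InsufficientDataError(
            f"need at least {largest + 3} complete rows, got {n}"
        )
    z = {v: _zscore(df[v].to_numpy(dtype=float), v) for v in spec.variables}

    coefficients: dict[str, tuple[float, float]] = {}
    r_squared: dict[str, float] = {}
    for resp, preds in spec.paths:
        X = sm.add_constant(np.column_stack([z[p] for p in preds]))
        fit = sm.OLS(z[resp], X).fit()
        for j, p in enumerate(preds, start=1):
            coefficients[f"{p}->{resp}"] = (float(fit.params[j]), float(fit.bse[j]))
        r_squared[resp] = float(fit.rsquared)

    exog_r = None
    a, b = EXOGENOUS_CORRELATION
    if a in z and b in z:
        exog_r = float(np.corrcoef(z[a], z[b])[0, 1])
    return PathFit(
        coefficients=coefficients,
        r_squared=r_squared,
        n=n,
        duration_years=duration_years,
        treatment=treatment,
        exogenous_correlation=exog_r,
    )


def meta_combine(estimates) -> MetaEstimate:
    """Inverse-variance fixed-effect pooling of (coef, SE) pairs.

    ``estimates`` is a sequence of (coefficient, standard error) across
    duration windows.  Fixed-effect weights are 1/SE^2; the Cochrane Q
    heterogeneity statistic and a DerSimonian-Laird random-effects estimate
    are reported alongside.
    """
    est = [(float(c), float(s)) for c, s in estimates]
    if len(est) < 2:
        raise ValidationError("meta_combine needs >= 2 estimates")
    if any(s <= 0 for _, s in est):
        raise ValidationError("all standard errors must be > 0")
    theta = np.array([c for c, _ in est])
    w = np.array([1.0 / s**2 for _, s in est])
    pooled = float((w * theta).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q = float((w * (theta - pooled) ** 2).sum())
    k = len(est)
    dfree = k - 1
    p_het = float(scipy.stats.chi2.sf(q, dfree))

    # DerSimonian-Laird between-duration variance
    c_dl = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - dfree) / c_dl) if c_dl > 0 else 0.0
    w_re = 1.0 / (1.0 / w + tau2)
    pooled_re = float((w_re * theta).sum() / w_re.sum())
    se_re = float(w_re.sum() ** -0.5)

    zcrit = scipy.stats.norm.ppf(0.975)
    return MetaEstimate(
        pooled=pooled,
        se=se,
        ci_low=pooled - zcrit * se,
        ci_high=pooled + zcrit * se,
        q_heterogeneity=q,
        df=dfree,
        p_heterogeneity=p_het,
        pooled_random=pooled_re,
        se_random=se_re,
        tau_squared=tau2,
        k=k,
    )


def treatment_difference_q(
    pooled_control, pooled_fertilized
) -> tuple[float, int, float]:
    """Two-group Cochrane Q contrast between pooled path coefficients.

    Q = (theta_c - theta_f)^2 / (SE_c^2 + SE_f^2), chi-square with df = 1
    under homogeneity.  Returns (Q, df, p).
    """
    (tc, sc), (tf, sf) = pooled_control, pooled_fertilized
    if sc <= 0 or sf <= 0:
        raise ValidationError("standard errors must be > 0")
    q = (tc - tf) ** 2 / (sc**2 + sf**2)
    return float(q), 1, float(scipy.stats.chi2.sf(q, 1))


def slope_with_ar1(
    y,
    x,
    series_id=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    fixed_rho: float | None = None,
) -> SlopeFit:
    """Bivariate slope with AR(1) errors within series (Cochrane-Orcutt).

    Observations sharing a ``series_id`` (e.g. one site's nested duration
    windows, in order) are treated as a time series whose errors follow a
    first-order autoregressive process.  rho is estimated from the lag-1
    autocorrelation of OLS residuals within series, the data are
    quasi-differenced (dropping each series' first observation), the model
    refit, and the two steps iterated to |drho| < ``tol``.  ``fixed_rho``
    skips estimation and fits at that autocorrelation (0 reproduces
    ordinary least squares exactly).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n:
        raise ValidationError("x and y must have equal length")
    if series_id is None:
        series_id = np.zeros(n, dtype=int)
    sid = np.asarray(series_id)

    if np.std(y) == 0 or np.std(x) == 0:
        warnings.warn("degenerate slope input (constant series)", stacklevel=2)
        return SlopeFit(0.0, float("nan"), float("nan"), float("nan"),
                        float("nan"), False, n)

    groups = [np.flatnonzero(sid == g) for g in pd.unique(sid)]

    def _ols(yy, xx):
        X = sm.add_constant(xx)
        return sm.OLS(yy, X).fit()

    def _quasi_fit(rho):
        ys, xs = [], []
        for idx in groups:
            if idx.size >= 2 and rho != 0.0:
                ys.append(y[idx][1:] - rho * y[idx][:-1])
                xs.append(x[idx][1:] - rho * x[idx][:-1])
            else:
                ys.append(y[idx])
                xs.append(x[idx])
        return _ols(np.concatenate(ys), np.concatenate(xs))

    fit = _ols(y, x)
    if fixed_rho is not None:
        fit = _quasi_fit(fixed_rho)
        slope = float(fit.params[1])
        lo, hi = fit.conf_int()[1]
        return SlopeFit(slope, float(fit.bse[1]), float(lo), float(hi),
                        float(fixed_rho), True, n)
    rho = 0.0
    converged = False
    for _ in range(max_iter):
        resid = y - fit.predict(sm.add_constant(x))
        num = den = 0.0
        for idx in groups:
            r = resid[idx]
            if r.size >= 2:
                num += float((r[1:] * r[:-1]).sum())
                den += float((r[:-1] ** 2).sum())
        rho_new = num / den if den > 0 else 0.0
        rho_new = float(np.clip(rho_new, -0.99, 0.99))
        if abs(rho_new - rho) < tol:
            rho = rho_new
            converged = True
            break
        rho = rho_new
        fit = _quasi_fit(rho)
    if not converged:
        warnings.warn("AR(1) slope estimation did not converge", stacklevel=2)

    slope = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return SlopeFit(slope, se, float(lo), float(hi), rho, converged, n)


def log_response_ratio(fertilized_value: float, control_value: float) -> float:
    """ln(fertilized / control); both values must be positive and finite."""
    f, c = float(fertilized_value), float(control_value)
    if not (np.isfinite(f) and np.isfinite(c)) or f <= 0 or c <= 0:
        raise ValidationError(
            f"log response ratio needs positive finite values, got ({f!r}, {c!r})"
        )
    return float(np.log(f / c))


def climate_residualize(y, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y on site-level climate variability covariates.

    ``covariates`` must carry columns ``MAP_VAR`` (CV of annual
    precipitation) and ``MAT_VAR`` (CV of annual temperature), one row per
    observation of ``y``.  Near-collinear covariates (|r| > 0.999) trigger a
    warning and one is dropped.  Residuals have mean zero.
    """
    y = np.asarray(y, dtype=float)
    cols = ["MAP_VAR", "MAT_VAR"]
    for c in cols:
        if c not in covariates.columns:
            raise ValidationError(f"covariate table missing column {c!r}")
    Xc = covariates[cols].to_numpy(dtype=float)
    if len(Xc) != y.size:
        raise ValidationError("covariates and y have different lengths")
    if np.abs(np.corrcoef(Xc[:, 0], Xc[:, 1])[0, 1]) > 0.999:
        warnings.warn(
            "MAP_VAR and MAT_VAR are collinear; dropping MAT_VAR", stacklevel=2
        )
        Xc = Xc[:, :1]
    X = sm.add_constant(Xc)
    fit = sm.OLS(y, X).fit()
    return np.asarray(fit.resid, dtype=float)


def anova_effects(
    metrics: pd.DataFrame,
    value: str,
    factors=("trt", "duration"),
    interaction: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA of a metric on treatment and duration (type II SS).

    Returns a table with one row per factor: F, df, p.  Raises on a factor
    with a single level.
    """
    import statsmodels.formula.api as smf

    df = metrics.dropna(subset=[value, *factors]).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise DegenerateInputError(f"factor {f!r} has a single level")
    op = "*" if interaction else "+"
    df = df.rename(columns={value: "_value"})
    formula = "_value ~ " + op.join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = table.rename(
        columns={"F": "F", "PR(>F)": "p", "df": "df"}
    )[["F", "df", "p"]]
    out.index = [
        i.replace("C(", "").replace(")", "") for i in out.index
    ]
    return out


def overlapping_windows(n_years: int) -> list[tuple[int, int]]:
    """All 4-consecutive-year windows [t, t+3] within years 1..n_years."""
    if n_years < 4:
        warnings.warn(
            f"no 4-year windows fit in {n_years} year(s)", stacklevel=2
        )
        return []
    return [(t, t + 3) for t in range(1, n_years - 2)]
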