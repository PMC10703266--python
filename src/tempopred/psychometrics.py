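"""Psychometric logistic fits, responder exclusion, and the dominance curve.

A responder's consistency with each timing algorithm is the slope of a
binomial-logit fit of their early/late responses on the normalized probe
deviation under that algorithm.  Responders whose pattern is not
distinguishable from a constant model (chi-square deviance test, p > 0.05)
are excluded.  The population-level analysis rotates the (slope_ABS,
slope_REL) plane into overall performance (sum) and algorithm dominance
(difference) and fits no-intercept polynomials of order 1-3, selected by
AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PsychometricFit",
    "SubjectSummary",
    "PolyFitResult",
    "fit_logistic_scalar",
    "fit_logistic_circular",
    "exclude_noisy",
    "fit_dominance_curve",
    "compare_groups",
    "summaries_to_frame",
]

#: cap applied to logistic slopes under (quasi-)perfect separation
SLOPE_CAP = 1e3


@dataclass
class PsychometricFit:
    """One binomial-logit fit and its deviance test against a constant model."""

    slope: float
    intercept: float
    coef: np.ndarray
    coef_se: np.ndarray
    deviance: float
    null_deviance: float
    chi2_p: float
    n_trials: int
    df: int
    excluded: bool = False
    separation: bool = False


@dataclass
class SubjectSummary:
    """Per-(simulated)participant slope pair in rotated coordinates."""

    subject_id: str
    slope_abs: float
    slope_rel: float
    excluded: bool = False
    condition: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def slope_sum(self) -> float:
        return self.slope_abs + self.slope_rel

    @property
    def slope_diff(self) -> float:
        return self.slope_abs - self.slope_rel


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "condition": s.condition,
            "slope_abs": s.slope_abs,
            "slope_rel": s.slope_rel,
            "slope_sum": s.slope_sum,
            "slope_diff": s.slope_diff,
            "excluded": s.excluded,
        }
        row.update(s.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def _glm_binomial(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Fit a binomial GLM: (params, standard errors, deviance, null deviance)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    return (
        np.asarray(res.params),
        np.asarray(res.bse),
        float(res.deviance),
        float(res.null_deviance),
    )


def _fit_logit(y: np.ndarray, regressors: np.ndarray, df: int) -> PsychometricFit:
    y = np.asarray(y, float)
    n = len(y)
    X = sm.add_constant(regressors, has_constant="add")
    one_class = y.min() == y.max()
    if one_class:
        # constant responses: the deviance test cannot reject the null
        return PsychometricFit(
            slope=0.0,
            intercept=np.inf if y[0] == 1 else -np.inf,
            coef=np.zeros(df),
            coef_se=np.full(df, np.inf),
            deviance=0.0,
            null_deviance=0.0,
            chi2_p=1.0,
            n_trials=n,
            df=df,
            excluded=True,
        )
    params, bse, dev, null_dev = _glm_binomial(y, X)
    coef = params[1:]
    separation = bool(np.any(np.abs(coef) > SLOPE_CAP))
    if separation:
        coef = np.clip(coef, -SLOPE_CAP, SLOPE_CAP)
    slope = float(np.linalg.norm(coef)) if df > 1 else float(coef[0])
    chi2_p = float(stats.chi2.sf(max(null_dev - dev, 0.0), df))
    return PsychometricFit(
        slope=slope,
        intercept=float(params[0]),
        coef=coef,
        coef_se=bse[1:],
        deviance=dev,
        null_deviance=null_dev,
        chi2_p=chi2_p,
        n_trials=n,
        df=df,
        separation=separation,
    )


def fit_logistic_scalar(deviations, responses) -> PsychometricFit:
    """Logit of response (0 = early, 1 = late) on a scalar deviation."""
    x = np.asarray(deviations, float)
    return _fit_logit(np.asarray(responses), x[:, None], df=1)


def fit_logistic_circular(phases, labels) -> PsychometricFit:
    """Logit of a binary label on ``(cos(theta), sin(theta))``.

    The reported slope is the Euclidean norm of the two phase coefficients,
    which is invariant to a common rotation of all phases; the deviance test
    has 2 degrees of freedom.
    """
    th = np.asarray(phases, float)
    X = np.column_stack([np.cos(th), np.sin(th)])
    return _fit_logit(np.asarray(labels), X, df=2)


def exclude_noisy(fits: list[PsychometricFit], alpha: float = 0.05) -> list[bool]:
    """Flag fits whose deviance test fails at ``alpha`` (noisy responders)."""
    flags = [bool(f.chi2_p > alpha) for f in fits]
    for f, flag in zip(fits, flags):
        f.excluded = f.excluded or flag
    return flags


@dataclass
class PolyFitResult:
    """No-intercept polynomial fit of dominance on overall performance."""

    orders: tuple[int, ...]
    aic: dict[int, float]
    best_order: int
    coefficients: np.ndarray  # ascending powers x^1 .. x^best_order
    adj_r_square: float
    x_grid: np.ndarray
    y_hat: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    zero_crossing_region: tuple[float, float] | None
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        powers = np.arange(1, self.best_order + 1)
        return (x[..., None] ** powers) @ self.coefficients


def _design(x: np.ndarray, order: int) -> np.ndarray:
    return x[:, None] ** np.arange(1, order + 1)


def fit_dominance_curve(
    summaries,
    *,
    orders: tuple[int, ...] = (1, 2, 3),
    alpha: float = 0.05,
    band: str = "ci",
    n_grid: int = 200,
) -> PolyFitResult:
    """Fit slope_diff on slope_sum with no intercept, AIC over orders 1-3.

    ``summaries`` is a list of included :class:`SubjectSummary` (or a
    DataFrame with ``slope_sum``/``slope_diff``).  AIC uses the full Gaussian
    log-likelihood with the ML variance; k counts the polynomial
    coefficients plus the variance.  The reported band is the 95% confidence
    interval of the fitted mean (``band="ci"``) or the prediction interval
    (``band="pi"``); ``zero_crossing_region`` is the x-range where the band
    lies strictly below zero (relative-dominant regime) if any, else where
    it lies strictly above zero.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
        if "excluded" in df:
            df = df[~df["excluded"].astype(bool)]
        x = df["slope_sum"].to_numpy(float)
        y = df["slope_diff"].to_numpy(float)
    else:
        kept = [s for s in summaries if not s.excluded]
        x = np.array([s.slope_sum for s in kept])
        y = np.array([s.slope_diff for s in kept])
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 included subjects, got {n}")

    degenerate = bool(np.allclose(y, 0.0))
    aic: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, float]] = {}
    for order in orders:
        X = _design(x, order)
        if np.linalg.matrix_rank(X) < order:
            raise np.linalg.LinAlgError(f"rank-deficient design at order {order}")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(resid @ resid)
        sigma2_ml = max(ssr / n, 1e-300)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0)
        k = order + 1  # coefficients + variance
        aic[order] = 2.0 * k - 2.0 * loglik
        fits[order] = (beta, ssr)

    best = min(aic, key=aic.get)
    beta, ssr = fits[best]
    sst = float(((y - y.mean()) ** 2).sum())
    if degenerate or sst == 0.0:
        r2 = adj_r2 = 0.0
    else:
        r2 = 1.0 - ssr / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - best)

    # band of the fitted mean (or prediction) on a grid
    Xb = _design(x, best)
    dof = n - best
    sigma2 = ssr / max(dof, 1)
    XtX_inv = np.linalg.inv(Xb.T @ Xb)
    grid = np.linspace(x.min(), x.max(), n_grid)
    G = _design(grid, best)
    var_mean = np.einsum("ij,jk,ik->i", G, XtX_inv, G) * sigma2
    if band == "pi":
        var_band = var_mean + sigma2
    elif band == "ci":
        var_band = var_mean
    else:
        raise ValueError("band must be 'ci' or 'pi'")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, max(dof, 1))
    y_hat = G @ beta
    lo = y_hat - tcrit * np.sqrt(var_band)
    hi = y_hat + tcrit * np.sqrt(var_band)

    region = None
    below = hi < 0.0
    above = lo > 0.0
    for mask in (below, above):
        if mask.any():
            xs = grid[mask]
            region = (float(xs.min()), float(xs.max()))
            break

    return PolyFitResult(
        orders=orders,
        aic=aic,
        best_order=best,
        coefficients=beta,
        adj_r_square=float(adj_r2),
        x_grid=grid,
        y_hat=y_hat,
        ci_lower=lo,
        ci_upper=hi,
        zero_crossing_region=region,
        degenerate=degenerate,
    )


def compare_groups(summaries_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rank tests on slope_diff: within conditions vs 0, between conditions.

    Within-condition: Wilcoxon signed-rank of slope_diff against zero.
    Between-condition: two-sided Mann-Whitney U for every pair, Bonferroni
    corrected for the number of pairwise comparisons.
    """
    rows = []
    names = list(summaries_by_condition)
    for name in names:
        d = np.asarray(summaries_by_condition[name], float)
        d_nz = d[d != 0.0]
        if len(d_nz) == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(d_nz).pvalue)
        rows.append(
            {
                "comparison": f"{name} vs 0",
                "test": "wilcoxon",
                "n": len(d),
                "median": float(np.median(d)),
                "p": p,
                "p_corrected": p,
            }
        )
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = max(len(pairs), 1)
    for a, b in pairs:
        da = np.asarray(summaries_by_condition[a], float)
        db = np.asarray(summaries_by_condition[b], float)
        if np.array_equal(da, db):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(da, db, alternative="two-sided").pvalue)
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "test": "mannwhitneyu",
                "n": len(da) + len(db),
                "median": float(np.median(da) - np.median(db)),
                "p": p,
                "p_corrected": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)
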