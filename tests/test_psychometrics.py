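"""Logistic fits, exclusion, and the dominance-curve analysis."""

import numpy as np
import pytest
from scipy.special import expit

from tempopred.psychometrics import (
    SLOPE_CAP,
    PolyFitResult,
    SubjectSummary,
    compare_groups,
    exclude_noisy,
    fit_dominance_curve,
    fit_logistic_circular,
    fit_logistic_scalar,
    summaries_to_frame,
)

# ------------------------------------------------------------ logistic fits


def simulate_logistic(n, slope, intercept, rng):
    x = rng.uniform(-1, 1, n)
    y = (rng.random(n) < expit(intercept + slope * x)).astype(int)
    return x, y


def test_scalar_fit_recovers_slope():
    rng = np.random.default_rng(0)
    x, y = simulate_logistic(4000, slope=3.0, intercept=0.4, rng=rng)
    fit = fit_logistic_scalar(x, y)
    assert fit.slope == pytest.approx(3.0, abs=0.35)
    assert fit.intercept == pytest.approx(0.4, abs=0.25)
    assert fit.chi2_p < 1e-6
    assert fit.df == 1 and fit.n_trials == 4000
    assert not fit.excluded and not fit.separation


def test_scalar_fit_null_when_random():
    rng = np.random.default_rng(1)
    ps = []
    for _ in range(40):
        x = rng.uniform(-1, 1, 200)
        y = rng.integers(0, 2, 200)
        ps.append(fit_logistic_scalar(x, y).chi2_p)
    # under the null the deviance p-value is ~uniform
    assert np.mean(np.asarray(ps) > 0.05) > 0.8


def test_one_class_responses_excluded():
    fit = fit_logistic_scalar([0.1, -0.2, 0.3], [1, 1, 1])
    assert fit.excluded and fit.chi2_p == 1.0 and fit.slope == 0.0


def test_separation_capped():
    # perfectly separated data on a tiny regressor scale drives the raw
    # coefficient past the cap; the fit is flagged and clipped
    x = np.array([-1e-3, -5e-4, 5e-4, 1e-3] * 10)
    y = (x > 0).astype(int)
    fit = fit_logistic_scalar(x, y)
    assert fit.separation
    assert fit.slope == SLOPE_CAP
    assert fit.chi2_p < 1e-6  # still unambiguously task-consistent


def test_circular_fit_rotation_invariance():
    rng = np.random.default_rng(2)
    th = rng.uniform(-np.pi, np.pi, 2000)
    y = (rng.random(2000) < expit(2.5 * np.sin(th))).astype(int)
    base = fit_logistic_circular(th, y)
    rot = fit_logistic_circular(np.angle(np.exp(1j * (th + 1.1))), y)
    assert base.df == 2
    assert base.slope == pytest.approx(2.5, abs=0.4)
    assert rot.slope == pytest.approx(base.slope, rel=1e-6)


def test_exclude_noisy():
    rng = np.random.default_rng(3)
    x, y_good = simulate_logistic(400, 3.0, 0.0, rng)
    y_bad = rng.integers(0, 2, 400)
    fits = [fit_logistic_scalar(x, y_good), fit_logistic_scalar(x, y_bad)]
    flags = exclude_noisy(fits)
    assert flags == [False, True]
    assert fits[1].excluded


# ------------------------------------------------------------- summaries


def test_subject_summary_rotation():
    s = SubjectSummary("s1", slope_abs=3.0, slope_rel=1.0)
    assert s.slope_sum == 4.0 and s.slope_diff == 2.0
    df = summaries_to_frame([s])
    assert df.loc[0, "slope_diff"] == 2.0


# ------------------------------------------------------- dominance curve


def synth_summaries(a, b, n, noise, rng, x_hi=12.0):
    out = []
    x = rng.uniform(0.5, x_hi, n)
    for i, xi in enumerate(x):
        y = a * xi**2 + b * xi + rng.normal(0, noise)
        slope_abs = (xi + y) / 2
        slope_rel = (xi - y) / 2
        out.append(SubjectSummary(f"s{i}", slope_abs, slope_rel))
    return out


def test_dominance_curve_recovers_quadratic():
    rng = np.random.default_rng(4)
    subs = synth_summaries(0.0196, -0.175, 200, 0.15, rng)
    fit = fit_dominance_curve(subs)
    assert fit.best_order == 2
    a_hat, = [fit.coefficients[1]]
    assert fit.coefficients[1] == pytest.approx(0.0196, abs=0.004)
    assert fit.coefficients[0] == pytest.approx(-0.175, abs=0.04)
    assert fit.adj_r_square > 0.5
    # predict() evaluates the no-intercept polynomial
    x0 = 5.0
    assert fit.predict(np.array([x0]))[0] == pytest.approx(
        fit.coefficients[0] * x0 + fit.coefficients[1] * x0**2
    )


def test_dominance_curve_zero_crossing_region():
    rng = np.random.default_rng(5)
    subs = synth_summaries(0.0196, -0.175, 300, 0.05, rng)
    fit = fit_dominance_curve(subs)
    lo, hi = fit.zero_crossing_region
    # negative (relative-dominant) dip at small slope_sum; curve crosses
    # zero at -b/a ~ 8.9
    assert 0.5 <= lo < hi < 9.5
    assert fit.predict(np.array([(lo + hi) / 2]))[0] < 0


def test_dominance_curve_excludes_flagged():
    rng = np.random.default_rng(6)
    subs = synth_summaries(0.02, -0.17, 50, 0.1, rng)
    spoiled = subs + [
        SubjectSummary("bad", 50.0, -50.0, excluded=True) for _ in range(5)
    ]
    fit_clean = fit_dominance_curve(subs)
    fit_spoiled = fit_dominance_curve(spoiled)
    np.testing.assert_allclose(fit_spoiled.coefficients, fit_clean.coefficients)


def test_dominance_curve_accepts_dataframe():
    rng = np.random.default_rng(7)
    subs = synth_summaries(0.02, -0.17, 60, 0.1, rng)
    df = summaries_to_frame(subs)
    fit_df = fit_dominance_curve(df)
    fit_ls = fit_dominance_curve(subs)
    np.testing.assert_allclose(fit_df.coefficients, fit_ls.coefficients)


def test_dominance_curve_needs_ten():
    rng = np.random.default_rng(8)
    with pytest.raises(ValueError, match=">= 10"):
        fit_dominance_curve(synth_summaries(0.02, -0.17, 9, 0.1, rng))


def test_dominance_curve_linear_when_true_model_linear():
    rng = np.random.default_rng(9)
    subs = synth_summaries(0.0, 0.3, 300, 0.05, rng)
    fit = fit_dominance_curve(subs)
    assert fit.best_order == 1
    assert fit.coefficients[0] == pytest.approx(0.3, abs=0.02)


def test_dominance_curve_band_modes():
    rng = np.random.default_rng(10)
    subs = synth_summaries(0.02, -0.17, 80, 0.2, rng)
    ci = fit_dominance_curve(subs, band="ci")
    pi = fit_dominance_curve(subs, band="pi")
    assert np.all(pi.ci_upper - pi.ci_lower >= ci.ci_upper - ci.ci_lower)
    with pytest.raises(ValueError):
        fit_dominance_curve(subs, band="bogus")


def test_compare_groups():
    rng = np.random.default_rng(11)
    groups = {
        "slow": rng.normal(0.5, 0.2, 40),
        "fast": rng.normal(-0.3, 0.2, 40),
    }
    df = compare_groups(groups)
    w = df[df.comparison == "slow vs 0"].iloc[0]
    assert w.p < 1e-4
    u = df[df.test == "mannwhitneyu"].iloc[0]
    assert u.p < 1e-4
    assert u.p_corrected >= u.p
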