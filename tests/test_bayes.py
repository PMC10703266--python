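"""Bayesian observer: fusion algebra, priors, decision rule, experiments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempopred.bayes import (
    GaussianEstimate,
    ObserverConfig,
    absolute_prior,
    absolute_prior_variance_telescoped,
    fuse,
    p_late,
    p_late_quadrature,
    relative_prior,
    run_observer_experiment,
    simulate_observer_trial,
)
from tempopred.stimuli import draw_trial, get_condition

# ------------------------------------------------------------------ fusion


def test_gaussian_estimate_validation():
    with pytest.raises(ValueError):
        GaussianEstimate(0.0, 0.0)
    assert GaussianEstimate.flat().is_flat


def test_fuse_precision_weighting():
    a = GaussianEstimate(0.0, 1.0)
    b = GaussianEstimate(1.0, 1.0)
    post = fuse(a, b)
    assert post.mu == pytest.approx(0.5)
    assert post.sigma == pytest.approx(1.0 / math.sqrt(2.0))
    # the sharper belief pulls harder
    sharp = fuse(GaussianEstimate(0.0, 0.1), GaussianEstimate(1.0, 1.0))
    assert sharp.mu < 0.05


def test_fuse_flat_cases():
    lik = GaussianEstimate(2.0, 0.3, "likelihood", 4)
    post = fuse(GaussianEstimate.flat(), lik)
    assert post.mu == 2.0 and post.sigma == 0.3 and post.kind == "posterior"
    with pytest.raises(ValueError):
        fuse(GaussianEstimate.flat(), GaussianEstimate.flat())


@settings(max_examples=50, deadline=None)
@given(
    mu1=st.floats(-5, 5),
    mu2=st.floats(-5, 5),
    s1=st.floats(0.05, 3),
    s2=st.floats(0.05, 3),
)
def test_fuse_properties(mu1, mu2, s1, s2):
    post = fuse(GaussianEstimate(mu1, s1), GaussianEstimate(mu2, s2))
    assert min(mu1, mu2) - 1e-9 <= post.mu <= max(mu1, mu2) + 1e-9
    assert post.sigma <= min(s1, s2) + 1e-12
    sym = fuse(GaussianEstimate(mu2, s2), GaussianEstimate(mu1, s1))
    assert post.mu == pytest.approx(sym.mu)
    assert post.sigma == pytest.approx(sym.sigma)


# ------------------------------------------------------------------ priors


def make_posteriors(mus, sigmas):
    return [
        GaussianEstimate(m, s, "posterior", i + 1)
        for i, (m, s) in enumerate(zip(mus, sigmas))
    ]


def test_priors_flat_before_third_tone():
    posts = make_posteriors([0.25], [0.05])
    assert relative_prior(posts, 0.045, 2).is_flat
    assert absolute_prior(posts, 0.045, 2).is_flat


def test_relative_prior_reconstructs_grid():
    # exact grid, equal precisions: prior mean is the next grid point
    T = 0.25
    posts = make_posteriors(T * np.arange(1, 9), np.full(8, 0.03))
    pr = relative_prior(posts, 0.045, 9)
    assert pr.mu == pytest.approx(T * 9, abs=1e-12)
    assert pr.sigma > 0.045  # sigma_exp floors the prior SD


def test_relative_prior_discounts_last_jitter():
    T = 0.25
    mus = T * np.arange(1, 9)
    mus_shift = mus.copy()
    mus_shift[-1] += 0.05
    pr0 = relative_prior(make_posteriors(mus, np.full(8, 0.03)), 0.045, 9)
    pr1 = relative_prior(make_posteriors(mus_shift, np.full(8, 0.03)), 0.045, 9)
    assert pr1.mu - pr0.mu < 0.05 * 0.5  # regression discounts one outlier


def test_absolute_prior_follows_last_tone():
    T = 0.25
    mus = T * np.arange(1, 9)
    mus_shift = mus.copy()
    mus_shift[-1] += 0.05
    pa0 = absolute_prior(make_posteriors(mus, np.full(8, 0.03)), 0.045, 9)
    pa1 = absolute_prior(make_posteriors(mus_shift, np.full(8, 0.03)), 0.045, 9)
    assert pa0.mu == pytest.approx(T * 9, abs=1e-12)
    # the shift enters both the mean interval and the anchor: 1 + 1/(I-1)
    assert pa1.mu - pa0.mu == pytest.approx(0.05 * (1 + 1 / 7), abs=1e-12)


def test_absolute_prior_noisier_than_relative():
    rng = np.random.default_rng(0)
    sig = rng.uniform(0.02, 0.06, 8)
    posts = make_posteriors(0.25 * np.arange(1, 9), sig)
    assert absolute_prior(posts, 0.045, 9).sigma > relative_prior(posts, 0.045, 9).sigma


# ---------------------------------------------------------------- decision


def test_p_late_symmetry():
    prior = GaussianEstimate(1.0, 0.1)
    assert p_late(prior, GaussianEstimate(1.0, 0.1)) == pytest.approx(0.5)
    assert p_late(prior, GaussianEstimate(2.0, 0.1)) > 0.99
    assert p_late(prior, GaussianEstimate(0.0, 0.1)) < 0.01


def test_observer_config_validation():
    with pytest.raises(ValueError):
        ObserverConfig(sigma_s=-1.0, sigma_exp=0.045)
    with pytest.raises(ValueError):
        ObserverConfig(sigma_s=0.05, sigma_exp=0.045, prior_type="oracle")


def test_simulate_observer_trial_structure(rng):
    cfg = get_condition("4hz")
    trial = draw_trial(cfg, rng)
    obs = ObserverConfig(sigma_s=0.03, sigma_exp=cfg.jitter_sd)
    res = simulate_observer_trial(trial, obs, rng)
    assert res.response in (0, 1)
    assert 0.0 <= res.p_late <= 1.0
    assert len(res.posteriors) == trial.n_tones
    # strictly causal: posteriors keep the likelihood means (flat priors
    # early; later posteriors sit between prior and likelihood)
    for i in (0, 1):
        assert res.posteriors[i].mu == pytest.approx(trial.cue_times[i])


def test_sharp_observer_p_late_tracks_truth(rng):
    """With vanishing sensory noise the posterior means are the true times,
    so P(late) sits on the correct side of 1/2 whenever the probe deviates
    from the duration-based prediction (the response itself stays
    stochastic: sigma_exp keeps the prior soft)."""
    cfg = get_condition("1.2hz")
    obs = ObserverConfig(sigma_s=1e-4, sigma_exp=cfg.jitter_sd)
    from tempopred.predictors import label_and_normalize

    for _ in range(60):
        trial = draw_trial(cfg, rng)
        res = simulate_observer_trial(trial, obs, rng)
        pred = label_and_normalize(trial)
        if abs(pred.dev_absolute) > 1e-3:
            assert (res.p_late > 0.5) == bool(pred.label_absolute)


# ------------------------------------------------------------- experiments


def test_run_observer_experiment_shapes():
    out = run_observer_experiment(
        conditions=("4hz",), sigma_s_grid=np.array([0.01, 0.1]), n_trials=80, seed=3
    )
    assert len(out) == 2
    for s in out:
        assert s.condition == "4hz"
        assert {"sigma_s", "sigma_p_probe", "prior_type"} <= set(s.extra)
    with pytest.raises(ValueError):
        run_observer_experiment(noise_scaling="relative")


def test_observer_dominance_tracks_sensory_noise():
    """Low sensory noise favors the duration prediction (positive diff);
    high noise lets the prior dominate and the rhythm prediction wins."""
    out = run_observer_experiment(
        conditions=("1.2hz",),
        sigma_s_grid=np.array([0.02, 0.5]),
        prior_type="absolute",
        n_trials=250,
        seed=4,
    )
    lo, hi = out[0], out[1]
    assert lo.extra["sigma_s"] == pytest.approx(0.02)
    assert lo.slope_diff > 0.5
    assert hi.slope_diff < 0.0


def test_relative_prior_observer_never_duration_dominant():
    out = run_observer_experiment(
        conditions=("1.2hz",),
        sigma_s_grid=np.geomspace(0.02, 0.5, 4),
        prior_type="relative",
        n_trials=250,
        seed=5,
    )
    assert all(s.slope_diff < 0.25 for s in out)
    assert any(s.slope_diff < -0.5 for s in out)
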