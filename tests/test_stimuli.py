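"""Stimulus generator: distributions, invariants, envelopes, sessions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempopred.stimuli import (
    CONDITIONS,
    ExperimentConfig,
    TrialSequence,
    assemble_session,
    draw_trial,
    draw_trials,
    get_condition,
    normalize_envelope,
    render_envelope,
    session_event_times,
)

# ------------------------------------------------------------------ config


def test_four_standard_conditions():
    assert set(CONDITIONS) == {"1.2hz", "1.2hz_lj", "2hz", "4hz"}
    assert CONDITIONS["1.2hz"].period_bounds == (0.700, 1.000)
    assert CONDITIONS["1.2hz"].jitter_sd == 0.170
    assert CONDITIONS["1.2hz_lj"].jitter_sd == 0.045
    assert CONDITIONS["2hz"].period_bounds == (0.400, 0.600)
    assert CONDITIONS["2hz"].jitter_sd == 0.100
    assert CONDITIONS["4hz"].period_bounds == (0.210, 0.290)
    assert CONDITIONS["4hz"].jitter_sd == 0.045


def test_condition_defaults():
    for cfg in CONDITIONS.values():
        assert cfg.tone_count_choices == (8, 9, 10)
        assert cfg.n_trials == 150
        assert cfg.probe_jitter_frac == 0.3
        assert cfg.tone_duration_frac == 0.4


def test_derived_properties():
    cfg = get_condition("4hz")
    assert cfg.mean_period == pytest.approx(0.25)
    assert cfg.tone_duration == pytest.approx(0.1)
    assert cfg.probe_bound == pytest.approx(0.075)


def test_get_condition_normalizes_name_and_overrides():
    assert get_condition("1.2HZ-LJ").jitter_sd == 0.045
    assert get_condition("4hz", n_trials=300).n_trials == 300
    with pytest.raises(KeyError):
        get_condition("3hz")


@pytest.mark.parametrize(
    "kw",
    [
        {"period_bounds": (0.3, 0.2)},
        {"period_bounds": (0.0, 0.2)},
        {"jitter_sd": 0.0},
        {"probe_jitter_frac": 0.6},
        {"tone_duration_frac": 1.1},
        {"sample_rate": -1.0},
    ],
)
def test_config_validation(kw):
    base = dict(
        condition_name="x", period_bounds=(0.21, 0.29), jitter_sd=0.045
    )
    base.update(kw)
    with pytest.raises(ValueError):
        ExperimentConfig(**base)


# ------------------------------------------------------------------- trials


def test_draw_trial_structure(cfg_4hz, rng):
    tr = draw_trial(cfg_4hz, rng)
    assert tr.n_tones in (8, 9, 10)
    b_l, b_h = cfg_4hz.period_bounds
    assert b_l <= tr.base_period <= b_h
    idx = np.arange(1, tr.n_tones + 1)
    np.testing.assert_allclose(tr.cue_times, tr.base_period * idx + tr.jitters)
    assert abs(tr.probe_jitter) <= cfg_4hz.probe_bound
    assert tr.probe_time == pytest.approx(
        tr.base_period * (tr.n_tones + 1) + tr.probe_jitter
    )
    assert tr.probe_slot == pytest.approx(tr.base_period * (tr.n_tones + 1))


def test_trial_distributions(cfg_slow):
    rng = np.random.default_rng(7)
    trials = draw_trials(cfg_slow, 4000, rng)
    T = np.array([t.base_period for t in trials])
    eps = np.concatenate([t.jitters for t in trials])
    ep = np.array([t.probe_jitter for t in trials])
    # base period uniform on bounds
    assert 0.700 < T.min() < 0.72 and 0.98 < T.max() < 1.000
    assert abs(T.mean() - 0.85) < 0.01
    # tone jitter gaussian with the condition SD
    assert abs(eps.std() - 0.170) < 0.01
    assert abs(eps.mean()) < 0.01
    # probe jitter uniform within +-0.3 * E[T]
    assert np.all(np.abs(ep) <= 0.3 * 0.85)
    assert ep.max() > 0.24 and ep.min() < -0.24


def test_tone_counts_uniform(cfg_4hz):
    rng = np.random.default_rng(3)
    counts = np.array([draw_trial(cfg_4hz, rng).n_tones for _ in range(3000)])
    for k in (8, 9, 10):
        frac = np.mean(counts == k)
        assert abs(frac - 1 / 3) < 0.04


def test_nonmonotone_flagged_not_dropped():
    # with jitter comparable to the period, reorderings occur and are kept
    cfg = get_condition("4hz", jitter_sd=0.15)
    rng = np.random.default_rng(0)
    trials = draw_trials(cfg, 200, rng)
    flags = [t.monotone for t in trials]
    assert not all(flags)  # some non-monotone trials occur ...
    assert any(flags)  # ... but not all
    # standard 4 Hz design: non-monotone trials are vanishingly rare
    std = draw_trials(get_condition("4hz"), 500, rng)
    assert np.mean([t.monotone for t in std]) > 0.99


def test_resample_nonmonotone(cfg_4hz):
    cfg = get_condition("4hz", resample_nonmonotone=True)
    rng = np.random.default_rng(0)
    assert all(t.monotone for t in draw_trials(cfg, 500, rng))


def test_trial_sequence_consistency_check():
    with pytest.raises(ValueError):
        TrialSequence(
            base_period=0.25,
            cue_times=np.array([0.3, 0.6]),
            jitters=np.array([0.0, 0.0]),
            probe_time=0.9,
            probe_jitter=0.0,
            condition="x",
        )


def test_determinism(cfg_4hz):
    a = draw_trials(cfg_4hz, 20, np.random.default_rng(99))
    b = draw_trials(cfg_4hz, 20, np.random.default_rng(99))
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.cue_times, tb.cue_times)
        assert ta.probe_time == tb.probe_time


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), cond=st.sampled_from(sorted(CONDITIONS)))
def test_trial_invariants_property(seed, cond):
    cfg = get_condition(cond)
    tr = draw_trial(cfg, np.random.default_rng(seed))
    assert tr.cue_times[0] > 0.0
    assert tr.probe_time > tr.cue_times[-1] - cfg.probe_bound
    assert len(tr.jitters) == tr.n_tones


# ---------------------------------------------------------------- envelopes


def test_normalize_envelope_properties(rng):
    x = rng.random(1000) ** 3
    y = normalize_envelope(x)
    assert abs(y.mean()) < 1e-12
    assert y.max() == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        normalize_envelope(np.ones(10))


def test_render_envelope_peaks_at_tones(cfg_4hz, rng):
    cfg = get_condition("4hz", resample_nonmonotone=True)
    tr = draw_trial(cfg, rng)
    env = render_envelope(tr, cfg)
    assert abs(env.values.mean()) < 1e-12
    assert env.values.max() == pytest.approx(1.0)
    # envelope is at plateau level mid-tone
    plateau = env.values.max()
    for onset in tr.cue_times:
        i = int((onset + cfg.tone_duration / 2) * cfg.sample_rate)
        assert env.values[i] == pytest.approx(plateau, rel=1e-6)
    # and at the pre-normalization floor between trials end and probe
    i_gap = int((tr.cue_times[-1] + cfg.tone_duration + 0.02) * cfg.sample_rate)
    assert env.values[i_gap] == pytest.approx(env.values.min())


def test_render_envelope_probe_flag(cfg_4hz, rng):
    cfg = get_condition("4hz", resample_nonmonotone=True)
    tr = draw_trial(cfg, rng)
    with_probe = render_envelope(tr, cfg, include_probe=True, overlap="clip")
    without = render_envelope(tr, cfg, overlap="clip")
    i = int((tr.probe_time + cfg.tone_duration / 2) * cfg.sample_rate)
    assert with_probe.values[i] > without.values[min(i, len(without.values) - 1)]


def test_render_envelope_overlap_raises():
    tr = TrialSequence(
        base_period=0.25,
        cue_times=np.array([0.21, 0.25]),
        jitters=np.array([0.21 - 0.25, 0.25 - 0.5]),
        probe_time=0.75,
        probe_jitter=0.0,
        condition="4hz",
    )
    cfg = get_condition("4hz")
    with pytest.raises(ValueError, match="overlap"):
        render_envelope(tr, cfg)
    env = render_envelope(tr, cfg, overlap="clip", normalize=False)
    assert env.values.max() <= 1.0  # saturates, no superposition above 1


# ----------------------------------------------------------------- sessions


def test_session_event_times_gap_is_iti(cfg_4hz, rng):
    trials = draw_trials(cfg_4hz, 30, rng)
    offsets, itis = session_event_times(trials, rng)
    assert len(itis) == 29
    assert np.all(itis >= 0.5) and np.all(itis <= 1.0)
    for k in range(1, 30):
        gap = (offsets[k] + trials[k].cue_times[0]) - (
            offsets[k - 1] + trials[k - 1].probe_time
        )
        assert gap == pytest.approx(itis[k - 1])


def test_assemble_session(cfg_4hz, rng):
    trials = draw_trials(cfg_4hz, 8, rng)
    env, offsets = assemble_session(trials, cfg_4hz, rng)
    assert len(offsets) == 8
    assert len(env.event_times) == sum(t.n_tones for t in trials)
    assert abs(env.values.mean()) < 1e-10
    assert env.values.max() == pytest.approx(1.0)
    # probe tones are not rendered: with probes there are more events
    env_p, _ = assemble_session(trials, cfg_4hz, np.random.default_rng(1), include_probe=True)
    assert len(env_p.event_times) == len(env.event_times) + 8
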