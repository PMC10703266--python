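"""Adaptive Frequency Oscillator: a Wilson-Cowan core whose tonic input
tracks the stimulus period, plus the simulated-cohort experiment.

With rho_I = -7 the model's natural period is controlled by rho_E through a
saddle-node-on-invariant-circle bifurcation.  The AFO assigns dynamics

    d(rho_E)/dt = -0.045 * (rho_E - rho_0)

where the target rho_0 is -3.4 (rest, just below the bifurcation) during
silence and, while a tone sequence is ongoing, a rational function of the
running mean inter-tone interval <t>:

    rho_0 = 0.45 * <t> / (<t> - 0.21) - 3.6

chosen so that the oscillator's natural period matches the perceived
period.  The e-fold time of the adaptation is ~22 s, so adjustment within a
trial is partial and memory persists across trials (rho_E is never reset).

A simulated participant is one coupling gain k drawn from 0.2 + U(0, 0.1);
its session is the behavioral protocol with probe tones removed, its
"responses" are read out as the oscillator phase at each trial's probe
time, and performance is scored exactly like the human data (circular
logistic fits against each timing algorithm's early/late labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._kernels import run_afo_session
from .predictors import label_and_normalize
from .psychometrics import SubjectSummary, fit_logistic_circular
from .stimuli import (
    TONE_RAMP,
    ExperimentConfig,
    TrialSequence,
    draw_trials,
    get_condition,
    session_event_times,
)
from .wilson_cowan import OscillatorTrace, WCParams, natural_period

__all__ = [
    "AFOParams",
    "CohortConfig",
    "rho0_of_period",
    "RunningMeanInterval",
    "build_rho0_schedule",
    "simulate_afo_session",
    "run_simulated_cohort",
    "scan_bifurcation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AFOParams:
    """AFO parameters: the WC core plus the rho_E adaptation law."""

    wc: WCParams = field(default_factory=lambda: WCParams(rho_e=-3.4, rho_i=-7.0))
    adapt_rate: float = 0.045  # 1/s
    rho0_silence: float = -3.4
    rho0_map: tuple[float, float, float] = (0.45, 0.21, -3.6)
    period_clamp: float = 0.23  # s; keeps <t> safely above the map's pole
    rho0_cap: float = 2.0

    def __post_init__(self) -> None:
        if self.adapt_rate <= 0.0:
            raise ValueError("adapt_rate must be positive")
        if self.rho0_silence >= -3.16:
            raise ValueError("rho0_silence must lie below the bifurcation value")


def rho0_of_period(mean_interval: float, params: AFOParams | None = None) -> float:
    """Map a perceived mean interval to the tonic-input target rho_0.

    Intervals at or below ``period_clamp`` (the map has a pole at 0.21 s)
    are clamped with a log record; the output is capped at ``rho0_cap``.
    As the interval grows the map approaches 0.45 - 3.6 = -3.15, just above
    the bifurcation, so very slow stimuli park the system near threshold.
    """
    p = params or AFOParams()
    c1, c2, c3 = p.rho0_map
    t = float(mean_interval)
    if t < p.period_clamp:
        log.debug("mean interval %.4f s clamped to %.3f s", t, p.period_clamp)
        t = p.period_clamp
    return min(c1 * t / (t - c2) + c3, p.rho0_cap)


class RunningMeanInterval:
    """Streaming mean of inter-onset intervals within one trial.

    Undefined (None) before the second onset; because the onsets are a
    stream, the mean telescopes to (last - first) / (count - 1).
    """

    def __init__(self) -> None:
        self.first: float | None = None
        self.last: float | None = None
        self.count = 0

    def update(self, onset: float) -> "RunningMeanInterval":
        # jitter can locally reorder tones; the telescoped mean is unaffected
        if self.last is not None and onset <= self.last:
            log.debug("non-increasing onset %.4f after %.4f", onset, self.last)
        if self.first is None:
            self.first = onset
        self.last = onset
        self.count += 1
        return self

    @property
    def mean(self) -> float | None:
        if self.count < 2:
            return None
        return (self.last - self.first) / (self.count - 1)


def build_rho0_schedule(
    trials: list[TrialSequence],
    offsets: np.ndarray,
    config: ExperimentConfig,
    params: AFOParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rho_0 target over a session, in sample indices.

    rho_0 sits at the silence value until a trial's second tone, then tracks
    the map of the running mean interval (updated at each subsequent tone
    onset), and falls back to silence at the last cue tone's offset.
    """
    idx = [0]
    val = [params.rho0_silence]
    dur = config.tone_duration
    for off, trial in zip(offsets, trials):
        mean = RunningMeanInterval()
        for j, t_cue in enumerate(trial.cue_times):
            mean.update(float(t_cue))
            if j >= 1:
                idx.append(int(round((off + t_cue) * (1.0 / dt))))
                val.append(rho0_of_period(mean.mean, params))
        idx.append(int(round((off + trial.cue_times[-1] + dur) / dt)))
        val.append(params.rho0_silence)
    order = np.argsort(np.asarray(idx), kind="stable")
    return np.asarray(idx, np.int64)[order], np.asarray(val, float)[order]


def simulate_afo_session(
    trials: list[TrialSequence],
    k: float,
    params: AFOParams,
    config: ExperimentConfig,
    rng: np.random.Generator,
    record_stride: int = 10,
    tail: float = 0.5,
    probe_at_slot: bool = False,
    return_trace: bool = False,
):
    """Run one continuous AFO session and read phases at the probe slots.

    The session is the concatenated trial envelopes (no probe tones) with
    inter-trial gaps of 0.75 + U(-0.25, 0.25) s.  rho_E evolves continuously
    through trials and gaps.  The phase (analytic signal of the recorded E
    series) is sampled at each trial's drawn probe time, or at the noise-free
    slot T*(I+1) with ``probe_at_slot``.

    Returns ``(phases, offsets)`` and appends the trace when requested.
    """
    dt = params.wc.dt
    offsets, _ = session_event_times(trials, rng)
    onset_times = np.sort(
        np.concatenate([off + tr.cue_times for off, tr in zip(offsets, trials)])
    )
    onsets = np.rint(onset_times / dt).astype(np.int64)
    end = offsets[-1] + trials[-1].probe_time + tail
    n_steps = int(round(end / dt))
    rho0_idx, rho0_val = build_rho0_schedule(trials, offsets, config, params, dt)
    wc = params.wc
    E_rec, rho_rec, Ef, If, rf, bad = run_afo_session(
        n_steps,
        dt,
        wc.tau,
        wc.a,
        wc.b,
        wc.c,
        wc.g,
        wc.rho_i,
        float(k),
        params.adapt_rate,
        onsets,
        config.tone_duration / dt,
        TONE_RAMP / dt,
        rho0_idx,
        rho0_val,
        0.25,
        0.25,
        params.rho0_silence,
        record_stride,
    )
    if bad >= 0:
        raise FloatingPointError(f"AFO session diverged at step {bad}")
    trace = OscillatorTrace(
        sample_rate=1.0 / (dt * record_stride), E=E_rec, rho_e=rho_rec
    )
    probe_times = np.array(
        [
            off + (tr.probe_slot if probe_at_slot else tr.probe_time)
            for off, tr in zip(offsets, trials)
        ]
    )
    phases = trace.phase_at(probe_times)
    if return_trace:
        return phases, offsets, trace
    return phases, offsets


@dataclass(frozen=True)
class CohortConfig:
    """One simulated-cohort experiment (defaults follow the study design)."""

    condition: str = "4hz"
    n_participants: int = 60
    n_trials: int = 300
    k_base: float = 0.2
    k_spread: float = 0.1
    seed: int = 0
    alpha: float = 0.05
    record_stride: int = 10
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 50:
            raise ValueError("need n_trials >= 50 for stable logistic fits")

    def experiment_config(self) -> ExperimentConfig:
        return get_condition(self.condition, **self.config_overrides)


def run_simulated_cohort(
    cohort: CohortConfig, params: AFOParams | None = None
) -> list[SubjectSummary]:
    """Simulate a cohort of AFO participants and score them like humans.

    Per participant: draw k ~ k_base + U(0, k_spread), simulate the session,
    label each trial early/late under each timing algorithm from the drawn
    probe time, fit a circular logistic per algorithm, and mark the subject
    excluded when neither fit beats the constant model (deviance test at
    ``alpha``).  Fully reproducible from (seed, config).
    """
    params = params or AFOParams()
    config = cohort.experiment_config()
    children = np.random.SeedSequence(cohort.seed).spawn(cohort.n_participants)
    out: list[SubjectSummary] = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        k = cohort.k_base + rng.uniform(0.0, cohort.k_spread)
        trials = draw_trials(config, cohort.n_trials, rng)
        phases, _ = simulate_afo_session(
            trials, k, params, config, rng, record_stride=cohort.record_stride
        )
        preds = [label_and_normalize(tr) for tr in trials]
        labels_abs = np.array([pr.label_absolute for pr in preds])
        labels_rel = np.array([pr.label_relative for pr in preds])
        fit_abs = fit_logistic_circular(phases, labels_abs)
        fit_rel = fit_logistic_circular(phases, labels_rel)
        excluded = fit_abs.chi2_p > cohort.alpha and fit_rel.chi2_p > cohort.alpha
        out.append(
            SubjectSummary(
                subject_id=f"{cohort.condition}-afo-{p:03d}",
                slope_abs=fit_abs.slope,
                slope_rel=fit_rel.slope,
                excluded=bool(excluded),
                condition=cohort.condition,
                extra={
                    "k": float(k),
                    "chi2_p_abs": fit_abs.chi2_p,
                    "chi2_p_rel": fit_rel.chi2_p,
                    "n_trials": cohort.n_trials,
                    "seed": cohort.seed,
                },
            )
        )
    return out


def _rational_period(rho, c1, c2, c3):
    """Natural period as a function of rho_E (inverse of the rho_0 map)."""
    return c2 * (rho - c3) / (rho - c3 - c1)


def scan_bifurcation(
    params: AFOParams | None = None,
    coarse_step: float = 0.02,
    fine_step: float = 0.005,
    coarse_range: tuple[float, float] = (-3.3, -2.9),
    duration: float = 60.0,
    fit: bool = True,
    fit_period_range: tuple[float, float] = (0.21, 1.2),
    extended_grid: np.ndarray | None = None,
) -> dict:
    """Locate the oscillation onset in rho_E and calibrate the rational map.

    Scans rho_E coarsely over ``coarse_range`` with no stimulus, refines the
    onset to ``fine_step`` resolution, and (optionally) refits the rational
    map rho_0(<t>) to the (rho_E, period) scan by least squares on the
    period over ``fit_period_range`` — the periods the task actually visits.

    Returns a dict with the onset value, the scan table, and the fitted
    constants (c1, c2, c3) when ``fit`` is requested.
    """
    params = params or AFOParams()
    base = params.wc

    def period_at(rho: float, dur: float = duration) -> float | None:
        return natural_period(base.with_(rho_e=float(rho)), duration=dur)

    lo, hi = coarse_range
    coarse = np.arange(lo, hi + 1e-12, coarse_step)
    rows = []
    onset_coarse = None
    for rho in coarse:
        p = period_at(rho)
        rows.append((float(rho), p))
        if onset_coarse is None and p is not None:
            onset_coarse = float(rho)
    if onset_coarse is None:
        raise RuntimeError("no oscillation found anywhere on the coarse grid")
    onset = onset_coarse
    fine = np.arange(onset_coarse - coarse_step, onset_coarse, fine_step)
    for rho in fine:
        p = period_at(rho)
        rows.append((float(rho), p))
        if p is not None and rho < onset:
            onset = float(rho)

    result = {"onset": onset, "table": None, "constants": None, "fit_rel_err": None}
    if fit:
        if extended_grid is None:
            extended_grid = np.concatenate(
                [
                    np.arange(onset, -2.90, fine_step),
                    np.arange(-2.90, -1.0, 0.05),
                    np.arange(-1.0, 2.01, 0.25),
                ]
            )
        for rho in extended_grid:
            p = period_at(float(rho), dur=min(duration, 30.0) if rho > -3.0 else duration)
            rows.append((float(rho), p))
        table = pd.DataFrame(rows, columns=["rho_e", "period"]).drop_duplicates(
            subset="rho_e"
        )
        osc = table.dropna()
        m = (osc["period"] >= fit_period_range[0]) & (
            osc["period"] <= fit_period_range[1]
        )
        rho_fit = osc.loc[m, "rho_e"].to_numpy()
        p_fit = osc.loc[m, "period"].to_numpy()
        c1, c2, c3 = params.rho0_map
        popt, _ = curve_fit(
            _rational_period, rho_fit, p_fit, p0=[c1, c2, c3], maxfev=20000
        )
        pred = _rational_period(rho_fit, *popt)
        result["table"] = table
        result["constants"] = tuple(float(v) for v in popt)
        result["fit_rel_err"] = float(np.max(np.abs(pred - p_fit) / p_fit))
    else:
        result["table"] = pd.DataFrame(rows, columns=["rho_e", "period"]).drop_duplicates(
            subset="rho_e"
        )
    return result
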