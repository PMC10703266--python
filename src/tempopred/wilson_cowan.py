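"""Wilson-Cowan neural mass model: integration, phase, and entrainment tools.

The model couples an excitatory and an inhibitory population,

    tau dE/dt = -E + S(rho_E + c*E - a*I + k*Stim)
    tau dI/dt = -I + S(rho_I + b*E - g*I)

with the logistic sigmoid ``S(x) = 1 / (1 + exp(-x))``, couplings
a = b = c = 10, g = -2, membrane time constant tau = 1/17 s, and external
drive ``Stim`` equal to the normalized stimulus envelope scaled by the
coupling gain ``k``.  Depending on the tonic inputs (rho_E, rho_I) the
system rests, or oscillates; with rho_I = -7 the oscillation is born in a
saddle-node-on-invariant-circle bifurcation as rho_E increases, so the
natural period can be steered continuously (and becomes arbitrarily long
near threshold).

Phase is defined as the angle of the analytic signal of the mean-removed
excitatory activity (zero near E maxima); phase concentration is the
modulus of the mean resultant vector of unit phasors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import find_peaks, hilbert

from ._kernels import run_wc
from .predictors import predict_absolute, predict_relative
from .stimuli import ExperimentConfig, TrialSequence, draw_trial, render_envelope

__all__ = [
    "WCParams",
    "OscillatorTrace",
    "CLASSIC_PARAMS",
    "sigmoid",
    "integrate",
    "natural_period",
    "extract_phase",
    "phase_concentration",
    "phase_response_curve",
    "concentration_at_predictions",
    "PRC_COUPLINGS",
]

#: coupling gains at which the phase response curve is evaluated
PRC_COUPLINGS = (0.02, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def sigmoid(x):
    """Logistic sigmoid S(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass(frozen=True)
class WCParams:
    """Parameters of the two-population model (times in seconds)."""

    rho_e: float
    rho_i: float
    a: float = 10.0
    b: float = 10.0
    c: float = 10.0
    g: float = -2.0
    tau: float = 1.0 / 17.0
    k: float = 1.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.tau <= 0.0:
            raise ValueError("tau must be positive")
        if self.dt > self.tau / 50.0:
            raise ValueError(f"dt={self.dt} too coarse; need dt <= tau/50")

    def with_(self, **kw) -> "WCParams":
        return replace(self, **kw)


#: fixed-frequency ("classic") oscillator operating point near a Hopf
#: bifurcation: (rho_E, rho_I) = (1.6, -2.9)
CLASSIC_PARAMS = WCParams(rho_e=1.6, rho_i=-2.9)


@dataclass
class OscillatorTrace:
    """Decimated state series of one integration."""

    sample_rate: float
    E: np.ndarray
    I: np.ndarray | None = None
    rho_e: np.ndarray | None = None
    t0: float = 0.0
    phase_: np.ndarray | None = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.E)) / self.sample_rate

    @property
    def phase(self) -> np.ndarray:
        if self.phase_ is None:
            self.phase_ = extract_phase(self.E)
        return self.phase_

    def phase_at(self, t) -> np.ndarray:
        """Phase at times ``t`` (nearest recorded sample)."""
        idx = np.rint((np.asarray(t, float) - self.t0) * self.sample_rate).astype(int)
        idx = np.clip(idx, 0, len(self.E) - 1)
        return self.phase[idx]


def integrate(
    params: WCParams,
    stim: np.ndarray | None = None,
    duration: float | None = None,
    initial: tuple[float, float] = (0.25, 0.25),
    record_stride: int = 1,
) -> OscillatorTrace:
    """Forward-Euler integration; deterministic given the initial state.

    ``stim`` must already be sampled on the ``params.dt`` grid (the
    normalized envelope); pass None with an explicit ``duration`` for the
    unforced system.  ``record_stride`` decimates the stored series.
    """
    if stim is None:
        if duration is None:
            raise ValueError("need duration when no stimulus is given")
        n_steps = int(round(duration / params.dt))
        stim_arr = np.empty(0)
    else:
        stim_arr = np.asarray(stim, float)
        n_steps = len(stim_arr)
        if duration is not None:
            n_steps = min(n_steps, int(round(duration / params.dt)))
            stim_arr = stim_arr[:n_steps]
    E, I, bad = run_wc(
        n_steps,
        params.dt,
        params.tau,
        params.a,
        params.b,
        params.c,
        params.g,
        params.rho_e,
        params.rho_i,
        params.k,
        stim_arr,
        initial[0],
        initial[1],
        record_stride,
    )
    if bad >= 0:
        raise FloatingPointError(f"integration diverged at step {bad}")
    return OscillatorTrace(sample_rate=1.0 / (params.dt * record_stride), E=E, I=I)


#: fractional prominence used for E-peak detection
PEAK_PROMINENCE = 0.10


def _peak_times(E: np.ndarray, rate: float) -> np.ndarray:
    rng = E.max() - E.min()
    if rng < 1e-6:
        return np.empty(0)
    peaks, _ = find_peaks(E, prominence=PEAK_PROMINENCE * rng)
    return peaks / rate


def natural_period(
    params: WCParams,
    duration: float = 60.0,
    transient: float = 5.0,
    record_stride: int = 1,
) -> float | None:
    """Mean inter-peak interval of unforced E, or None if it does not oscillate.

    The first ``transient`` seconds are discarded; at least two post-
    transient peaks are required.
    """
    trace = integrate(
        params.with_(k=0.0), duration=duration, record_stride=record_stride
    )
    rate = trace.sample_rate
    Ep = trace.E[int(transient * rate) :]
    tp = _peak_times(Ep, rate)
    if len(tp) < 2:
        return None
    return float(np.mean(np.diff(tp)))


def extract_phase(E: np.ndarray) -> np.ndarray:
    """Instantaneous phase: angle of the analytic signal of mean-removed E."""
    x = np.asarray(E, float)
    x = x - x.mean()
    if np.ptp(x) < 1e-12:
        raise ValueError("cannot extract phase from a constant signal")
    n = len(x)
    analytic = hilbert(x, N=next_fast_len(n))[:n]
    return np.angle(analytic)


def phase_concentration(phases) -> float:
    """Mean resultant length |mean(exp(i*theta))| in [0, 1]."""
    th = np.asarray(phases, float)
    if th.size == 0:
        raise ValueError("need at least one phase")
    return float(np.abs(np.mean(np.exp(1j * th))))


def _tone_stim(n_steps: int, onset: float, duration: float, dt: float) -> np.ndarray:
    """Normalized single-tone drive for the perturbation runs."""
    from .stimuli import TONE_RAMP, _tone_shape

    t = np.arange(n_steps) * dt
    env = _tone_shape(t, onset, duration, TONE_RAMP)
    centered = env - env.mean()
    return centered / centered.max()


def phase_response_curve(
    params: WCParams,
    k_values=PRC_COUPLINGS,
    tone_duration: float = 0.1,
    onset_step: float = 0.001,
) -> dict:
    """Phase shift caused by one tone as a function of its arrival phase.

    A reference oscillator runs unperturbed; a perturbed copy (identical
    start point) receives a single tone whose onset roves across the second
    cycle in ``onset_step`` increments.  The shift is the circular mean of
    the perturbed-minus-reference phase difference over the fourth cycle,
    reported against the reference phase at tone onset, for each coupling
    gain in ``k_values``.
    """
    p0 = natural_period(params)
    if p0 is None:
        raise ValueError("phase response curve requires an oscillatory regime")
    dt = params.dt
    total = 5.0 * p0
    n_steps = int(round(total / dt))
    ref = integrate(params.with_(k=0.0), duration=total)
    ref_phase = ref.phase
    rate = ref.sample_rate
    i3, i4 = int(3 * p0 * rate), int(4 * p0 * rate)

    onsets = np.arange(p0, 2.0 * p0, onset_step)
    result: dict[float, dict[str, np.ndarray]] = {}
    for k in k_values:
        shifts = np.empty(len(onsets))
        onset_phases = np.empty(len(onsets))
        for i, onset in enumerate(onsets):
            if k == 0.0:
                shifts[i] = 0.0
            else:
                stim = _tone_stim(n_steps, onset, tone_duration, dt)
                pert = integrate(params.with_(k=float(k)), stim=stim)
                dphi = pert.phase[i3:i4] - ref_phase[i3:i4]
                shifts[i] = float(np.angle(np.mean(np.exp(1j * dphi))))
            onset_phases[i] = ref_phase[int(round(onset * rate))]
        result[float(k)] = {
            "onset_times": onsets.copy(),
            "onset_phases": onset_phases,
            "shifts": shifts,
        }
    return result


def concentration_at_predictions(
    params: WCParams,
    config: ExperimentConfig,
    k: float,
    rng: np.random.Generator,
    n_trials: int = 300,
    transient: float = 1.0,
    n_permutations: int = 10_000,
) -> dict:
    """Phase concentration at algorithm-predicted probe times (fixed oscillator).

    Each trial's envelope (cue tones only) drives the oscillator after a
    silent lead-in; the phase is read at the probe time predicted by the
    absolute and by the relative algorithm, and concentration is taken
    across trials.  The concentration difference (abs - rel) is tested with
    a paired label-swap permutation test.
    """
    dt = params.dt
    ph_abs = np.empty(n_trials)
    ph_rel = np.empty(n_trials)
    for i in range(n_trials):
        trial = draw_trial(config, rng)
        env = render_envelope(trial, config, overlap="clip", tail=0.5)
        n_pre = int(round(transient / dt))
        stim = np.concatenate([np.zeros(n_pre), env.values])
        trace = integrate(params.with_(k=float(k)), stim=stim)
        trace.t0 = -transient
        t_abs = predict_absolute(trial.cue_times)
        t_rel = predict_relative(trial.cue_times)
        ph_abs[i], ph_rel[i] = trace.phase_at([t_abs, t_rel])
    pc_abs = phase_concentration(ph_abs)
    pc_rel = phase_concentration(ph_rel)
    obs = pc_abs - pc_rel
    swap = rng.random((n_permutations, n_trials)) < 0.5
    za, zr = np.exp(1j * ph_abs), np.exp(1j * ph_rel)
    a = np.where(swap, zr, za).mean(axis=1)
    r = np.where(swap, za, zr).mean(axis=1)
    null = np.abs(a) - np.abs(r)
    p = float((np.sum(np.abs(null) >= abs(obs)) + 1) / (n_permutations + 1))
    return {
        "pc_abs": pc_abs,
        "pc_rel": pc_rel,
        "pc_diff": obs,
        "p_value": p,
        "phases_abs": ph_abs,
        "phases_rel": ph_rel,
    }
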