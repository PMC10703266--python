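"""Jittered tone-sequence stimulus generation.

Each behavioral trial is built on an isochronous grid with base period
``T ~ U(b_l, b_h)``.  Cue tones sit at ``t_i = T*i + eps_i`` with Gaussian
jitter ``eps_i ~ N(0, sigma)`` for ``i = 1..I`` (``I`` drawn from {8, 9, 10}),
and a final probe tone at ``t_probe = T*(I+1) + eps_probe`` with
``eps_probe ~ U(-0.3*E[T], 0.3*E[T])``.  The listener's task is to judge the
probe as early or late.

Stimulus envelopes are rendered as ramped boxcars (one per tone, duration
0.4x the condition's mean period) on a regular grid and normalized to
zero mean / unit maximum, the drive used by the oscillator models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExperimentConfig",
    "TrialSequence",
    "EnvelopeSignal",
    "CONDITIONS",
    "get_condition",
    "draw_trial",
    "draw_trials",
    "render_envelope",
    "normalize_envelope",
    "assemble_session",
    "session_event_times",
]

#: ramp time of the raised-cosine on/off flanks of each tone (seconds)
TONE_RAMP = 0.005


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters of one experimental condition.

    Periods and jitters are in seconds.  ``probe_jitter_frac`` bounds the
    probe displacement as a fraction of the design mean period
    ``E[T] = (b_l + b_h) / 2``; ``tone_duration_frac`` scales tone duration
    by the same mean period.
    """

    condition_name: str
    period_bounds: tuple[float, float]
    jitter_sd: float
    probe_jitter_frac: float = 0.3
    tone_count_choices: tuple[int, ...] = (8, 9, 10)
    n_trials: int = 150
    tone_duration_frac: float = 0.4
    sample_rate: float = 10_000.0
    resample_nonmonotone: bool = False

    def __post_init__(self) -> None:
        b_l, b_h = self.period_bounds
        if not (0.0 < b_l < b_h):
            raise ValueError(f"need 0 < b_l < b_h, got {self.period_bounds}")
        if self.jitter_sd <= 0.0:
            raise ValueError("jitter_sd must be positive")
        if not (0.0 < self.probe_jitter_frac < 0.5):
            raise ValueError("probe_jitter_frac must lie in (0, 0.5)")
        if self.tone_duration_frac * b_h >= b_l:
            # tones must never overlap the next isochronous slot even at the
            # shortest admissible period
            raise ValueError(
                "tone_duration_frac * b_h must be < b_l "
                f"({self.tone_duration_frac * b_h:.3f} >= {b_l:.3f})"
            )
        if self.sample_rate <= 0.0:
            raise ValueError("sample_rate must be positive")

    @property
    def mean_period(self) -> float:
        """Design mean period E[T] = (b_l + b_h) / 2."""
        return 0.5 * (self.period_bounds[0] + self.period_bounds[1])

    @property
    def tone_duration(self) -> float:
        """Tone duration: ``tone_duration_frac`` times the mean period."""
        return self.tone_duration_frac * self.mean_period

    @property
    def probe_bound(self) -> float:
        """Hard bound on |eps_probe|: ``probe_jitter_frac * E[T]``."""
        return self.probe_jitter_frac * self.mean_period


#: The four experimental conditions (rates in Hz; LJ = low jitter).
CONDITIONS: dict[str, ExperimentConfig] = {
    "1.2hz": ExperimentConfig("1.2hz", (0.700, 1.000), 0.170),
    "1.2hz_lj": ExperimentConfig("1.2hz_lj", (0.700, 1.000), 0.045),
    "2hz": ExperimentConfig("2hz", (0.400, 0.600), 0.100),
    "4hz": ExperimentConfig("4hz", (0.210, 0.290), 0.045),
}


def get_condition(name: str, **overrides) -> ExperimentConfig:
    """Return a standard condition, optionally with fields overridden."""
    key = name.lower().replace("-", "_").replace(" ", "")
    if key not in CONDITIONS:
        raise KeyError(f"unknown condition {name!r}; have {sorted(CONDITIONS)}")
    cfg = CONDITIONS[key]
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class TrialSequence:
    """One stimulus trial in trial-local time (t = 0 one period before tone 1)."""

    base_period: float
    cue_times: np.ndarray
    jitters: np.ndarray
    probe_time: float
    probe_jitter: float
    condition: str
    monotone: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "cue_times", np.asarray(self.cue_times, float))
        object.__setattr__(self, "jitters", np.asarray(self.jitters, float))
        if self.cue_times.shape != self.jitters.shape:
            raise ValueError("cue_times and jitters must have equal length")
        idx = np.arange(1, self.n_tones + 1)
        if not np.allclose(self.cue_times - self.base_period * idx, self.jitters):
            raise ValueError("cue_times inconsistent with base_period and jitters")
        mono = bool(np.all(np.diff(self.cue_times) > 0.0))
        object.__setattr__(self, "monotone", mono)

    @property
    def n_tones(self) -> int:
        return len(self.cue_times)

    @property
    def probe_slot(self) -> float:
        """Noise-free probe location T*(I+1)."""
        return self.base_period * (self.n_tones + 1)


@dataclass
class EnvelopeSignal:
    """Normalized stimulus envelope on a regular time grid."""

    sample_rate: float
    values: np.ndarray
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


def draw_trial(config: ExperimentConfig, rng: np.random.Generator) -> TrialSequence:
    """Draw one trial from the generative model of a condition.

    Cue count is uniform over ``config.tone_count_choices``.  With large
    jitter relative to the period, cue times can come out non-monotone; by
    default such trials are kept and flagged (``TrialSequence.monotone``);
    with ``config.resample_nonmonotone`` the jitters are redrawn.
    """
    b_l, b_h = config.period_bounds
    T = rng.uniform(b_l, b_h)
    n_tones = int(rng.choice(np.asarray(config.tone_count_choices)))
    idx = np.arange(1, n_tones + 1)
    for _ in range(1000):
        eps = rng.normal(0.0, config.jitter_sd, n_tones)
        cue = T * idx + eps
        if np.all(np.diff(cue) > 0.0) or not config.resample_nonmonotone:
            break
    else:  # pragma: no cover - pathological sigma only
        raise RuntimeError("could not draw a monotone trial in 1000 attempts")
    bound = config.probe_bound
    eps_probe = rng.uniform(-bound, bound)
    probe = T * (n_tones + 1) + eps_probe
    trial = TrialSequence(
        base_period=T,
        cue_times=cue,
        jitters=eps,
        probe_time=probe,
        probe_jitter=eps_probe,
        condition=config.condition_name,
    )
    assert abs(trial.probe_jitter) <= bound + 1e-12
    return trial


def draw_trials(
    config: ExperimentConfig, n: int, rng: np.random.Generator
) -> list[TrialSequence]:
    return [draw_trial(config, rng) for _ in range(n)]


def _tone_shape(t: np.ndarray, onset: float, duration: float, ramp: float) -> np.ndarray:
    """Ramped boxcar: raised-cosine flanks of width ``ramp``, unit plateau."""
    u = t - onset
    out = np.zeros_like(u)
    rise = (u >= 0.0) & (u < ramp)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / ramp))
    out[(u >= ramp) & (u <= duration - ramp)] = 1.0
    fall = (u > duration - ramp) & (u <= duration)
    out[fall] = 0.5 * (1.0 - np.cos(np.pi * (duration - u[fall]) / ramp))
    return out


def normalize_envelope(values: np.ndarray) -> np.ndarray:
    """Remove the mean and scale so the maximum is exactly 1.

    This is the normalization applied to the acoustic envelope before it
    drives the excitatory population:
    ``(x - mean(x)) / max(x - mean(x))``.
    """
    x = np.asarray(values, float)
    centered = x - x.mean()
    peak = centered.max()
    if peak <= 0.0:
        raise ZeroDivisionError(
            "cannot normalize a constant envelope: max(x - mean(x)) is zero"
        )
    return centered / peak


def render_envelope(
    trial: TrialSequence,
    config: ExperimentConfig,
    *,
    include_probe: bool = False,
    overlap: str = "raise",
    tail: float = 0.0,
    normalize: bool = True,
) -> EnvelopeSignal:
    """Render a trial's envelope on the ``config.sample_rate`` grid.

    One ramped boxcar of duration ``config.tone_duration`` per cue tone,
    optionally plus the probe tone.  ``overlap`` controls what happens when
    jitter pushes two tone supports into each other: ``"raise"`` (strict,
    default) or ``"clip"`` (amplitude is the pointwise max, saturating at 1,
    which is how overlapping tones superpose acoustically).

    The returned envelope is normalized (zero mean, unit max) unless
    ``normalize=False``.
    """
    onsets = list(map(float, trial.cue_times))
    if include_probe:
        onsets.append(float(trial.probe_time))
    if not onsets:
        raise ValueError("trial has no tones to render")
    if overlap not in ("raise", "clip"):
        raise ValueError("overlap must be 'raise' or 'clip'")
    dur = config.tone_duration
    gaps = np.diff(sorted(onsets))
    if overlap == "raise" and np.any(gaps < dur):
        raise ValueError(
            f"overlapping tone supports (min gap {gaps.min():.3f} s < "
            f"tone duration {dur:.3f} s); use overlap='clip' to saturate"
        )
    end = max(trial.probe_time, max(onsets) + dur) + tail
    n = int(np.ceil(end * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate
    env = np.zeros(n)
    for onset in onsets:
        np.maximum(env, _tone_shape(t, onset, dur, TONE_RAMP), out=env)
    values = normalize_envelope(env) if normalize else env
    return EnvelopeSignal(config.sample_rate, values, np.asarray(onsets))


def _draw_itis(n: int, rng: np.random.Generator) -> np.ndarray:
    """Inter-trial intervals: 0.75 + U(-0.25, 0.25) seconds."""
    return 0.75 + rng.uniform(-0.25, 0.25, n)


def session_event_times(
    trials: list[TrialSequence], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Lay trials on one session time line.

    Returns ``(offsets, itis)`` where ``offsets[k]`` maps trial-local times of
    trial ``k`` to session time.  The gap between trial ``k``'s probe slot
    and trial ``k+1``'s first cue tone equals ``itis[k]``.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    itis = _draw_itis(len(trials) - 1, rng)
    offsets = np.zeros(len(trials))
    for k in range(1, len(trials)):
        prev, cur = trials[k - 1], trials[k]
        offsets[k] = offsets[k - 1] + prev.probe_time + itis[k - 1] - cur.cue_times[0]
    return offsets, itis


def assemble_session(
    trials: list[TrialSequence],
    config: ExperimentConfig,
    rng: np.random.Generator,
    *,
    include_probe: bool = False,
    tail: float = 1.0,
) -> tuple[EnvelopeSignal, np.ndarray]:
    """Concatenate trials into one normalized session envelope.

    Probe tones are rendered only when ``include_probe`` is set (the
    oscillator simulations omit them but still need the probe-slot times,
    which the returned per-trial ``offsets`` recover).  Overlapping tones
    within a trial saturate (``overlap='clip'``).
    """
    offsets, _ = session_event_times(trials, rng)
    dur = config.tone_duration
    onsets: list[float] = []
    for off, tr in zip(offsets, trials):
        onsets.extend(off + tr.cue_times)
        if include_probe:
            onsets.append(off + tr.probe_time)
    onsets_arr = np.sort(np.asarray(onsets))
    end = offsets[-1] + trials[-1].probe_time + tail
    n = int(np.ceil(end * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate
    env = np.zeros(n)
    for onset in onsets_arr:
        i0 = max(0, int(onset * config.sample_rate) - 1)
        i1 = min(n, int((onset + dur) * config.sample_rate) + 2)
        np.maximum(
            env[i0:i1], _tone_shape(t[i0:i1], onset, dur, TONE_RAMP), out=env[i0:i1]
        )
    if len(trials) > 1:
        gaps = np.diff(onsets_arr)
        if np.any(gaps <= 0):
            warnings.warn("session contains coincident tone onsets", stacklevel=2)
    return EnvelopeSignal(config.sample_rate, normalize_envelope(env), onsets_arr), offsets
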