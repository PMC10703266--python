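"""Relative and absolute probe-time predictions and deviation scoring.

Two timing algorithms define where the probe "should" be:

* **relative** (rhythm-based): ordinary least squares of cue times on tone
  index, extrapolated one index past the last cue — it reconstructs the
  underlying isochronous grid and discounts per-tone jitter;
* **absolute** (duration-based): mean inter-tone interval added to the last
  cue time — it inherits the last tone's jitter ("drift").

Responses are scored against the signed deviation of the probe from each
prediction, normalized by the trial's mean stimulus onset asynchrony so
that slopes are comparable across stimulus rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stimuli import TrialSequence

__all__ = [
    "TimingPrediction",
    "predict_relative",
    "predict_absolute",
    "label_and_normalize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimingPrediction:
    """Per-trial predictions, deviations, and early/late labels.

    ``dev_*`` are ``probe_time - prediction`` in seconds; ``dev_*_norm``
    divide by the trial's mean SOA.  Labels are 0 = early, 1 = late.
    """

    pred_relative: float
    pred_absolute: float
    dev_relative: float
    dev_absolute: float
    dev_relative_norm: float
    dev_absolute_norm: float
    label_relative: int
    label_absolute: int
    mean_soa: float


def _check(cue_times: np.ndarray) -> np.ndarray:
    t = np.asarray(cue_times, float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two cue times")
    return t


def predict_relative(cue_times) -> float:
    """OLS fit of cue time on 1-based index, evaluated at index I+1."""
    t = _check(cue_times)
    idx = np.arange(1, len(t) + 1, dtype=float)
    slope, intercept = np.polyfit(idx, t, 1)
    return float(slope * (len(t) + 1) + intercept)


def predict_absolute(cue_times) -> float:
    """Last cue time plus the mean inter-tone interval.

    The interval mean telescopes, so this equals
    ``t_I + (t_I - t_1) / (I - 1)``.
    """
    t = _check(cue_times)
    return float(t[-1] + (t[-1] - t[0]) / (len(t) - 1))


def label_and_normalize(
    trial: TrialSequence, *, use_base_period: bool = False
) -> TimingPrediction:
    """Score a trial's probe against both algorithms.

    ``mean_soa`` is the mean realized cue interval ``(t_I - t_1)/(I - 1)``
    ("the mean SOA of the corresponding trial"); set ``use_base_period`` to
    normalize by the generative period instead (sensitivity analysis).

    A probe exactly at a prediction (measure-zero) is labelled late, with a
    log record.
    """
    t = trial.cue_times
    pred_rel = predict_relative(t)
    pred_abs = predict_absolute(t)
    soa = trial.base_period if use_base_period else (t[-1] - t[0]) / (len(t) - 1)
    dev_rel = trial.probe_time - pred_rel
    dev_abs = trial.probe_time - pred_abs
    if dev_rel == 0.0 or dev_abs == 0.0:
        log.warning("probe exactly at a predicted time; tie-broken to 'late'")
    return TimingPrediction(
        pred_relative=pred_rel,
        pred_absolute=pred_abs,
        dev_relative=dev_rel,
        dev_absolute=dev_abs,
        dev_relative_norm=dev_rel / soa,
        dev_absolute_norm=dev_abs / soa,
        label_relative=int(dev_rel >= 0.0),
        label_absolute=int(dev_abs >= 0.0),
        mean_soa=float(soa),
    )
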