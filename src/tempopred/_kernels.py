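"""Numba forward-Euler kernels for the Wilson-Cowan integrations.

The long cohort simulations integrate tens of millions of 0.1 ms Euler
steps, so the inner loops are compiled.  Two kernels exist:

* :func:`run_wc` — fixed tonic inputs, stimulus supplied as a dense array
  (or empty for the unforced system);
* :func:`run_afo_session` — tonic excitatory input relaxing toward a
  piecewise-constant target, with the session envelope evaluated on the fly
  from the tone-onset list (ramped boxcars, saturating max on overlap) so
  no multi-hour session array is ever materialized.  A first pass computes
  the exact envelope mean so the normalization matches the array route
  bit-for-bit up to float addition order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_wc", "run_afo_session", "envelope_from_onsets"]


@njit(cache=True, inline="always")
def _tone_amp(u: float, dlen: float, rlen: float) -> float:
    """Ramped boxcar amplitude at ``u`` samples past onset."""
    if u < 0.0 or u > dlen:
        return 0.0
    if u < rlen:
        return 0.5 * (1.0 - np.cos(np.pi * u / rlen))
    if u <= dlen - rlen:
        return 1.0
    return 0.5 * (1.0 - np.cos(np.pi * (dlen - u) / rlen))


@njit(cache=True, inline="always")
def _env_at(step: int, onsets: np.ndarray, ptr: int, dlen: float, rlen: float) -> float:
    """Envelope at sample ``step``: max over tones active there.

    ``ptr`` indexes the latest onset <= step; at most the three most recent
    tones can still be active (overlaps involve neighbors only).
    """
    amp = 0.0
    lo = ptr - 2 if ptr >= 2 else 0
    for j in range(lo, ptr + 1):
        a = _tone_amp(float(step - onsets[j]), dlen, rlen)
        if a > amp:
            amp = a
    return amp


@njit(cache=True)
def run_wc(
    n_steps: int,
    dt: float,
    tau: float,
    a: float,
    b: float,
    c: float,
    g: float,
    rho_e: float,
    rho_i: float,
    k: float,
    stim: np.ndarray,
    E0: float,
    I0: float,
    stride: int,
):
    """Forward Euler of the two-population system with fixed tonic inputs.

    Returns decimated E and I series plus the step index of the first
    non-finite state (-1 when the run is clean).
    """
    n_rec = (n_steps + stride - 1) // stride
    E_rec = np.empty(n_rec)
    I_rec = np.empty(n_rec)
    E = E0
    I = I0
    j = 0
    have_stim = stim.size > 0
    for step in range(n_steps):
        s = stim[step] if have_stim else 0.0
        se = 1.0 / (1.0 + np.exp(-(rho_e + c * E - a * I + k * s)))
        si = 1.0 / (1.0 + np.exp(-(rho_i + b * E - g * I)))
        E = E + dt * (-E + se) / tau
        I = I + dt * (-I + si) / tau
        if not (E == E and I == I):  # NaN check
            return E_rec[:j], I_rec[:j], step
        if step % stride == 0:
            E_rec[j] = E
            I_rec[j] = I
            j += 1
    return E_rec, I_rec, -1


@njit(cache=True)
def run_afo_session(
    n_steps: int,
    dt: float,
    tau: float,
    a: float,
    b: float,
    c: float,
    g: float,
    rho_i: float,
    k: float,
    adapt_rate: float,
    onsets: np.ndarray,  # int64 sample indices of rendered tones, sorted
    tone_len: float,  # tone duration in samples
    ramp_len: float,  # ramp duration in samples
    rho0_idx: np.ndarray,  # int64 sample indices of rho0 changes (idx[0] == 0)
    rho0_val: np.ndarray,
    E0: float,
    I0: float,
    rho_e0: float,
    stride: int,
):
    """Integrate a whole session with tonic-input adaptation.

    ``rho0`` is piecewise constant between the change points in
    ``rho0_idx``; ``rho_e`` relaxes toward it at ``adapt_rate`` per second
    and is never reset (cross-trial memory).  Returns decimated E and
    ``rho_e`` series, the final state, and the first bad step (-1 if none).
    """
    # pass 1: exact envelope mean for the normalization
    total = 0.0
    ptr = -1
    for step in range(n_steps):
        while ptr + 1 < onsets.size and onsets[ptr + 1] <= step:
            ptr += 1
        if ptr >= 0:
            total += _env_at(step, onsets, ptr, tone_len, ramp_len)
    mean = total / n_steps
    scale = 1.0 - mean  # envelope peaks at exactly 1 on tone plateaus

    n_rec = (n_steps + stride - 1) // stride
    E_rec = np.empty(n_rec)
    rho_rec = np.empty(n_rec)
    E = E0
    I = I0
    rho_e = rho_e0
    ptr = -1
    rptr = 0
    j = 0
    for step in range(n_steps):
        while ptr + 1 < onsets.size and onsets[ptr + 1] <= step:
            ptr += 1
        while rptr + 1 < rho0_idx.size and rho0_idx[rptr + 1] <= step:
            rptr += 1
        env = _env_at(step, onsets, ptr, tone_len, ramp_len) if ptr >= 0 else 0.0
        s = (env - mean) / scale
        rho0 = rho0_val[rptr]
        se = 1.0 / (1.0 + np.exp(-(rho_e + c * E - a * I + k * s)))
        si = 1.0 / (1.0 + np.exp(-(rho_i + b * E - g * I)))
        E = E + dt * (-E + se) / tau
        I = I + dt * (-I + si) / tau
        rho_e = rho_e + dt * (-adapt_rate * (rho_e - rho0))
        if not (E == E and I == I and rho_e == rho_e):
            return E_rec[:j], rho_rec[:j], E, I, rho_e, step
        if step % stride == 0:
            E_rec[j] = E
            rho_rec[j] = rho_e
            j += 1
    return E_rec, rho_rec, E, I, rho_e, -1


@njit(cache=True)
def envelope_from_onsets(
    n_steps: int,
    onsets: np.ndarray,
    tone_len: float,
    ramp_len: float,
) -> np.ndarray:
    """Dense un-normalized envelope from an onset list (cross-check route)."""
    env = np.zeros(n_steps)
    ptr = -1
    for step in range(n_steps):
        while ptr + 1 < onsets.size and onsets[ptr + 1] <= step:
            ptr += 1
        if ptr >= 0:
            env[step] = _env_at(step, onsets, ptr, tone_len, ramp_len)
    return env
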