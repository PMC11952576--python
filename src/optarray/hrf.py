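"""Canonical hemodynamic response kernel used by the synthetic generator."""

from __future__ import annotations

import numpy as np


def double_gamma(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                 peak_disp: float = 1.0, under_disp: float = 1.0,
                 undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma impulse response, peak-normalized to 1.

    Positive lobe peaking near ``peak_s`` and an undershoot near
    ``undershoot_s`` scaled by 1/undershoot_ratio; zero for t < 0.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t >= 0
    a1 = peak_s / peak_disp
    a2 = undershoot_s / under_disp
    h[pos] = (gamma_dist.pdf(t[pos], a1, scale=peak_disp)
              - gamma_dist.pdf(t[pos], a2, scale=under_disp) / undershoot_ratio)
    m = h.max()
    if m > 0:
        h = h / m
    return h


def block_response(t: np.ndarray, duration_s: float, dt: float,
                   **kernel_kwargs) -> np.ndarray:
    """Boxcar of ``duration_s`` convolved with the canonical kernel.

    Evaluated on the time grid ``t`` (seconds relative to block onset) and
    normalized so that the response peak equals 1, making simulated patch
    amplitudes read directly as peak concentration changes in uM.
    """
    t = np.asarray(t, dtype=float)
    tk = np.arange(0.0, 40.0 + dt, dt)
    kern = double_gamma(tk, **kernel_kwargs)
    n_box = max(int(round(duration_s / dt)), 1)
    box = np.ones(n_box)
    conv = np.convolve(box, kern) * dt
    peak = conv.max()
    if peak > 0:
        conv = conv / peak
    t_conv = np.arange(conv.size) * dt
    return np.interp(t, t_conv, conv, left=0.0, right=0.0)
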