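"""Shared independent oracles and fixtures-by-code used across test modules."""

import numpy as np

from sprstress.scalogram import morse_freq_response, morse_peak_omega
from sprstress.simulate import SimConfig, gen_ecg, gen_event_schedule


def oracle_windowed_variance(x, w):
    """Direct enumeration: centered window variance with truncated edges."""
    x = np.asarray(x, float)
    h_lo, h_hi = w // 2, (w - 1) // 2  # np.convolve 'same' centering for even w
    out = np.empty_like(x)
    for i in range(len(x)):
        seg = x[max(0, i - h_lo): min(len(x), i + h_hi + 1)]
        out[i] = np.mean((seg - seg.mean()) ** 2)
    return out


def direct_cwt_row(x, fs, params, f_row):
    """Independent time-domain inner-product CWT at one pseudo-frequency.

    Builds the time-domain wavelet by dense numerical inverse-Fourier
    integration of the analytic frequency response, then correlates.
    """
    a = morse_peak_omega(params) * fs / (2 * np.pi * f_row)
    omega = np.linspace(0, np.pi, 10_001)
    resp = morse_freq_response(a * omega, params)
    support = int(np.ceil(15 * a))
    m = np.arange(-support, support + 1)
    # psi_a[m] = (1/2pi) * integral of Psi(a w) e^{jwm} dw over positive freqs
    psi = np.empty(len(m), dtype=complex)
    for lo in range(0, len(m), 200):
        chunk = m[lo: lo + 200]
        psi[lo: lo + 200] = np.trapezoid(
            resp[None, :] * np.exp(1j * np.outer(chunk, omega)), omega, axis=1
        ) / (2 * np.pi)
    n = len(x)
    out = np.empty(n, dtype=complex)
    for b in range(n):
        lo, hi = max(0, b - support), min(n, b + support + 1)
        out[b] = np.dot(x[lo:hi], np.conj(psi[(lo - b) + support: (hi - b) + support]))
    return np.abs(out), support


def clean_ecg(duration_s=120.0, hr=60.0, seed=0, noise_sd=0.0):
    cfg = SimConfig(duration_s=duration_s, hr_base_bpm=hr,
                    hr_event_delta_bpm=0.0, ecg_noise_sd=noise_sd, seed=seed)
    sched = gen_event_schedule(0.0, duration_s, seed=0)
    ecg, beats = gen_ecg(sched, cfg)
    return ecg, beats, cfg.fs


def match_counts(detected, truth, tol_s=0.05):
    """(true positives, false negatives, false positives) by nearest-match."""
    tp = sum(np.min(np.abs(detected - t)) <= tol_s for t in truth)
    return tp, len(truth) - tp, len(detected) - tp
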