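"""Continuous wavelet scalograms with generalized Morse wavelets.

The generalized Morse family is an analytic wavelet (zero response at
negative frequencies) whose frequency-domain form is

    Psi(omega) = U(omega) * k * omega**beta * exp(-omega**gamma)

with shape exponent gamma, decay exponent beta, and k fixed so the peak
value is 2 (the usual analytic-wavelet convention).  The spectral peak sits
at omega_p = (beta/gamma)**(1/gamma), which also defines the
scale-to-pseudo-frequency conversion.

The transform is computed in the frequency domain: per scale, the inverse
FFT of the signal spectrum times the scaled wavelet response.  The
arousal statistic of interest is the band energy: per time instant, the sum
of squared scalogram magnitudes over the rows whose pseudo-frequency falls
in a band (default [0.03, 1] Hz, where electrodermal stress responses
concentrate), and its time average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = ["MorseParams", "Scalogram", "BandEnergySeries", "morse_freq_response",
           "morse_peak_omega", "default_freq_grid", "cwt_scalogram", "band_energy"]


@dataclass(frozen=True)
class MorseParams:
    gamma: float = 3.0
    beta: float = 20.0  # time-bandwidth product beta*gamma = 60
    voices_per_octave: int = 12

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if self.voices_per_octave < 4:
            raise ValueError("need at least 4 voices per octave")


@dataclass(frozen=True)
class Scalogram:
    """|CWT| magnitude; rows are scales (descending pseudo-frequency)."""

    magnitude: np.ndarray
    pseudo_freqs: np.ndarray  # Hz, one per row
    times: np.ndarray         # s, one per column
    params: MorseParams


@dataclass(frozen=True)
class BandEnergySeries:
    energy: np.ndarray          # per-column in-band energy, a.u.
    band: tuple[float, float]   # Hz
    mean_energy: float          # time average of `energy`


def morse_peak_omega(params: MorseParams) -> float:
    """Angular frequency of the wavelet's spectral peak: (beta/gamma)**(1/gamma)."""
    return float((params.beta / params.gamma) ** (1.0 / params.gamma))


def morse_freq_response(omega: np.ndarray | float, params: MorseParams) -> np.ndarray:
    """Morse frequency response, peak-normalized to 2; zero for omega <= 0.

    Evaluated in the log domain (beta*ln(omega) can overflow the plain
    power for large beta).
    """
    om = np.asarray(omega, dtype=float)
    wp = morse_peak_omega(params)
    out = np.zeros_like(om, dtype=float)
    pos = om > 0
    log_peak = params.beta * np.log(wp) - wp ** params.gamma
    out[pos] = 2.0 * np.exp(
        params.beta * np.log(om[pos]) - om[pos] ** params.gamma - log_peak
    )
    return out if out.ndim else float(out)


def default_freq_grid(
    params: MorseParams, f_min: float = 0.02, f_max: float = 8.0
) -> np.ndarray:
    """Geometric pseudo-frequency grid, descending, spanning [f_min, f_max].

    Steps of one voice (2**(1/voices_per_octave)); the grid is extended past
    f_min so the band is fully covered.
    """
    v = params.voices_per_octave
    n_steps = int(np.ceil(np.log2(f_max / f_min) * v)) + 1
    return f_max * 2.0 ** (-np.arange(n_steps) / v)


def cwt_scalogram(
    x: np.ndarray,
    fs: float,
    params: MorseParams = MorseParams(),
    freqs: np.ndarray | None = None,
) -> Scalogram:
    """Morse-wavelet scalogram of ``x``.

    Frequency-domain implementation with zero padding to at least twice the
    signal length (the circular wrap of edge columns is pushed into the pad).
    Edge (cone-of-influence) columns are retained, not masked.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if freqs is None:
        freqs = default_freq_grid(params)
    freqs = np.asarray(freqs, dtype=float)
    if not (np.all(np.diff(freqs) < 0) or np.all(np.diff(freqs) > 0)):
        raise ValueError("pseudo-frequency grid must be strictly monotone")

    nfft = next_fast_len(2 * n)
    X = fft(x, nfft)
    omega = 2.0 * np.pi * np.arange(nfft) / nfft  # per-sample angular freq
    # only bins up to Nyquist carry positive frequencies for the analytic wavelet
    omega[nfft // 2 + 1:] = -1.0
    wp = morse_peak_omega(params)
    scales = wp * fs / (2.0 * np.pi * freqs)  # samples
    mag = np.empty((len(freqs), n))
    for i, a in enumerate(scales):
        psi = morse_freq_response(a * omega, params)
        mag[i] = np.abs(ifft(X * psi)[:n])
    return Scalogram(magnitude=mag, pseudo_freqs=freqs,
                     times=np.arange(n) / fs, params=params)


def band_energy(scal: Scalogram, f_lo: float = 0.03, f_hi: float = 1.0) -> BandEnergySeries:
    """In-band energy per time instant and its time average.

    Sums squared magnitudes over the rows with ``f_lo <= pseudo_freq <= f_hi``
    (band edges inclusive).
    """
    rows = (scal.pseudo_freqs >= f_lo) & (scal.pseudo_freqs <= f_hi)
    if not np.any(rows):
        raise ValueError("band does not intersect the scalogram's pseudo-frequencies")
    energy = np.sum(scal.magnitude[rows] ** 2, axis=0)
    return BandEnergySeries(energy=energy, band=(f_lo, f_hi),
                            mean_energy=float(energy.mean()))
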