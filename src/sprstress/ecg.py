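"""ECG processing: QRS detection, ectopic-beat correction, RR resampling.

R peaks are located with the classic Pan-Tompkins stage chain (band-pass,
derivative, squaring, moving-window integration, dual adaptive thresholds
with search-back and a 200 ms refractory period), then refined to the raw
signal's local maximum.  RR (= NN) intervals are cleaned of physiologically
implausible beats by a running-median rule and resampled to a uniform grid
by cubic-spline interpolation, the standard preparation for windowed HRV
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

__all__ = ["NoBeatsError", "RPeaks", "RrSeries", "UniformRr", "detect_r_peaks",
           "rr_from_peaks", "correct_ectopic", "resample_rr", "normalize_rr"]

from .ma import normalize_zscore_concat as normalize_rr  # same per-subject z-score contract

REFRACTORY_S = 0.2


class NoBeatsError(ValueError):
    """Raised when no QRS complexes can be detected."""


@dataclass(frozen=True)
class RPeaks:
    """Detected R-wave times, strictly increasing, >= 200 ms apart."""

    times: np.ndarray

    def __post_init__(self) -> None:
        d = np.diff(self.times)
        if np.any(d < REFRACTORY_S):
            raise ValueError("R-peak times violate the 200 ms refractory period")


@dataclass(frozen=True)
class RrSeries:
    """Beat times and the RR intervals between consecutive beats (ms)."""

    beat_times: np.ndarray
    rr_ms: np.ndarray
    corrected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.rr_ms) != len(self.beat_times) - 1:
            raise ValueError("need exactly one RR interval per consecutive beat pair")
        if np.any(np.asarray(self.rr_ms) <= 0):
            raise ValueError("RR intervals must be positive")
        if self.corrected_mask is None:
            object.__setattr__(self, "corrected_mask",
                               np.zeros(len(self.rr_ms), dtype=bool))


@dataclass(frozen=True)
class UniformRr:
    """RR and HR resampled on a uniform grid; hr_bpm = 60000 / rr_ms."""

    t: np.ndarray
    rr_ms: np.ndarray
    hr_bpm: np.ndarray
    fs_rr: float


def rr_from_peaks(peaks: RPeaks) -> RrSeries:
    """RR intervals (ms) between consecutive detected beats."""
    bt = np.asarray(peaks.times, dtype=float)
    return RrSeries(beat_times=bt, rr_ms=np.diff(bt) * 1000.0)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> RPeaks:
    """Pan-Tompkins QRS detection.

    Stages: 5-15 Hz band-pass; five-point derivative; squaring; 150 ms
    moving-window integration; dual adaptive thresholds with search-back
    for missed beats; 200 ms refractory.  Detected times are refined to the
    raw-signal local maximum within +/-40 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Sa/s")
    if len(ecg) < 5 * fs:
        raise ValueError("need at least 5 s of ECG")
    if np.any(~np.isfinite(ecg)):
        raise NoBeatsError("ECG contains non-finite samples")
    if np.ptp(ecg) == 0:
        raise NoBeatsError("flat ECG")

    b, a = butter(2, [5.0, 15.0], btype="band", fs=fs)
    bp = filtfilt(b, a, ecg)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    sq = deriv * deriv
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    cand, _ = find_peaks(mwi, distance=refr)
    if len(cand) == 0:
        raise NoBeatsError("no candidate peaks in the integrated signal")

    # adaptive threshold state, initialized from the first two seconds
    lead = mwi[: int(2 * fs)]
    spki = 0.25 * float(lead.max())
    npki = 0.5 * float(lead.mean())

    beats: list[int] = []
    rr_hist: list[float] = []
    last_idx = -np.inf
    noise_since_last: list[int] = []
    for p in cand:
        thr1 = npki + 0.25 * (spki - npki)
        rr_avg = np.mean(rr_hist[-8:]) if rr_hist else None
        # search-back: if a beat seems missed, revisit candidates above thr2
        if rr_avg is not None and (p - last_idx) > 1.66 * rr_avg and noise_since_last:
            thr2 = 0.5 * thr1
            above = [q for q in noise_since_last if mwi[q] > thr2]
            if above:
                q = max(above, key=lambda i: mwi[i])
                if q - last_idx >= refr and p - q >= refr:
                    beats.append(q)
                    rr_hist.append(q - last_idx)
                    last_idx = q
                    spki = 0.25 * mwi[q] + 0.75 * spki
                    noise_since_last = []
        if mwi[p] > thr1 and p - last_idx >= refr:
            beats.append(p)
            if np.isfinite(last_idx):
                rr_hist.append(p - last_idx)
            last_idx = p
            spki = 0.125 * mwi[p] + 0.875 * spki
            noise_since_last = []
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            noise_since_last.append(p)
    if not beats:
        raise NoBeatsError("no beats exceeded the adaptive threshold")

    # refine to the raw-signal local maximum within +/-40 ms
    half = int(round(0.040 * fs))
    refined = []
    for p in beats:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement, keeping the taller peak
    kept: list[int] = []
    for p in refined:
        if kept and p - kept[-1] < refr:
            if ecg[p] > ecg[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return RPeaks(times=np.asarray(kept) / fs)


def correct_ectopic(rr: RrSeries, threshold_frac: float = 0.25) -> RrSeries:
    """Flag and repair ectopic RR intervals.

    An interval deviating from the median of its 5-interval centered
    neighborhood (truncated at the edges) by more than ``threshold_frac``
    of that median is flagged and replaced by cubic interpolation through
    the unflagged intervals.  Beat times are left untouched.
    """
    rr_ms = np.asarray(rr.rr_ms, dtype=float)
    n = len(rr_ms)
    if n < 5:
        raise ValueError("need at least 5 intervals")
    if not np.isfinite(threshold_frac):
        return RrSeries(beat_times=rr.beat_times, rr_ms=rr_ms.copy(),
                        corrected_mask=np.zeros(n, dtype=bool))
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        med[i] = np.median(rr_ms[lo:hi])
    mask = np.abs(rr_ms - med) > threshold_frac * med
    out = rr_ms.copy()
    if mask.any() and (~mask).sum() >= 2:
        idx = np.arange(n)
        good = idx[~mask]
        if len(good) >= 4:
            spline = CubicSpline(good, rr_ms[good])
            out[mask] = spline(idx[mask])
        else:
            out[mask] = np.interp(idx[mask], good, rr_ms[good])
        np.clip(out, 1e-3, None, out=out)
    return RrSeries(beat_times=rr.beat_times, rr_ms=out, corrected_mask=mask)


def resample_rr(rr: RrSeries, fs_rr: float = 4.0,
                duration_s: float | None = None) -> UniformRr:
    """Cubic-spline resampling of the RR series onto a uniform grid.

    The spline passes through ``(beat_times[1:], rr_ms)``; the grid spans
    ``[0, duration_s)`` (default: up to the last beat) and values outside
    the beat span are held at the edge values rather than extrapolated.
    """
    if len(rr.rr_ms) < 4:
        raise ValueError("need at least 4 RR intervals for cubic-spline resampling")
    tx = np.asarray(rr.beat_times[1:], dtype=float)
    y = np.asarray(rr.rr_ms, dtype=float)
    end = duration_s if duration_s is not None else float(tx[-1])
    grid = np.arange(0.0, end, 1.0 / fs_rr)
    spline = CubicSpline(tx, y)
    vals = spline(np.clip(grid, tx[0], tx[-1]))
    return UniformRr(t=grid, rr_ms=vals, hr_bpm=60000.0 / vals, fs_rr=fs_rr)
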