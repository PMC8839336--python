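"""Motion-artifact removal by dual-channel SPR fusion.

The autonomic (desired) component of the skin potential response is common
to both hands, while steering-wheel motion artifacts perturb one hand at a
time and raise that channel's local energy.  The two raw channels are
therefore fused by a per-sample weighted average that favours the channel
with the *lower* local energy, and the result is z-normalized per subject
over the concatenation of that subject's recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyTrace", "CleanedSpr", "local_energy", "fuse_channels",
           "normalize_zscore_concat"]


@dataclass(frozen=True)
class EnergyTrace:
    """Per-sample local energy (windowed variance, mV^2)."""

    values: np.ndarray
    window_s: float


@dataclass(frozen=True)
class CleanedSpr:
    """Fused SPR signal with the per-sample weight given to the left channel."""

    signal: np.ndarray
    weights_left: np.ndarray
    fs: float


def local_energy(x: np.ndarray, fs: float, window_s: float = 2.0) -> EnergyTrace:
    """Centered sliding-window variance of ``x``.

    The window mean is removed inside each window, so the slow tonic SPR
    level does not contribute: only fast fluctuations (responses, bursts,
    noise) register as energy.  Edge windows are truncated, not padded.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    w = int(round(window_s * fs))
    if w < 3:
        raise ValueError("window must span at least 3 samples")
    if w > len(x):
        raise ValueError("window longer than the signal")
    kernel = np.ones(w)
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    s1 = np.convolve(x, kernel, mode="same")
    s2 = np.convolve(x * x, kernel, mode="same")
    mean = s1 / counts
    var = s2 / counts - mean * mean
    np.clip(var, 0.0, None, out=var)  # guard tiny negative round-off
    return EnergyTrace(values=var, window_s=window_s)


def fuse_channels(
    x1: np.ndarray,
    x2: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    eps: float = 1e-9,
) -> CleanedSpr:
    """Fuse two SPR channels, down-weighting the higher-local-energy one.

    Per sample, ``y = w*x1 + (1-w)*x2`` with
    ``w = (E2 + eps) / (E1 + E2 + 2*eps)`` where ``E1, E2`` are the local
    energies of the two channels; ``eps > 0`` makes the both-energies-zero
    case a plain average.  The output lies pointwise between the two inputs.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("channels must have equal length")
    if eps <= 0:
        raise ValueError("eps must be positive")
    e1 = local_energy(x1, fs, window_s).values
    e2 = local_energy(x2, fs, window_s).values
    w = (e2 + eps) / (e1 + e2 + 2.0 * eps)
    y = w * x1 + (1.0 - w) * x2
    return CleanedSpr(signal=y, weights_left=w, fs=fs)


def normalize_zscore_concat(signals: list[np.ndarray]) -> list[np.ndarray]:
    """Z-score a subject's signals by the mean/sd of their concatenation.

    The population (divide-by-n) standard deviation is used.  Raises on a
    degenerate (constant) concatenation.
    """
    if len(signals) == 0:
        raise ValueError("need at least one signal")
    arrays = [np.asarray(s, dtype=float) for s in signals]
    concat = np.concatenate(arrays)
    mu = concat.mean()
    sd = concat.std()  # population convention
    if sd == 0:
        raise ValueError("degenerate input: pooled standard deviation is zero")
    return [(a - mu) / sd for a in arrays]
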