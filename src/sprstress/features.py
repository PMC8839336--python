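"""Windowed feature extraction and ground-truth labeling.

Normalized SPR and RR/HR series are cut into overlapping 15 s blocks (a new
block every 5 s) and eight features are computed per block: five from the
SPR (variance, energy, mean absolute value, mean and max absolute
derivative) and three from the ECG-derived series (mean NN, SDNN, mean HR).
Blocks intersecting a stress-event interval are labeled 1.  Features are
min-max scaled to [0, 1] with parameters learned on training data only.

All intervals are half-open ``[start, end)`` with 0-based sample indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BlockSpec", "FeatureVector", "ScalerParams", "LabeledFeatureSet",
           "FEATURE_NAMES", "make_blocks", "spr_block_features",
           "ecg_block_features", "label_blocks", "fit_minmax", "apply_minmax",
           "extract_feature_vectors", "features_to_matrix"]

FEATURE_NAMES = (
    "spr_variance", "spr_energy", "spr_mean_abs", "spr_mean_abs_deriv",
    "spr_max_abs_deriv", "mean_nn", "sdnn", "mean_hr",
)


@dataclass(frozen=True)
class BlockSpec:
    block_s: float = 15.0
    hop_s: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.block_s):
            raise ValueError("need 0 < hop_s <= block_s")


@dataclass(frozen=True)
class FeatureVector:
    spr_variance: float
    spr_energy: float
    spr_mean_abs: float
    spr_mean_abs_deriv: float
    spr_max_abs_deriv: float
    mean_nn: float
    sdnn: float
    mean_hr: float
    block_start_s: float
    block_end_s: float

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature (min, max) learned on training data."""

    mins: np.ndarray
    maxs: np.ndarray


@dataclass
class LabeledFeatureSet:
    vectors: list[FeatureVector]
    labels: np.ndarray
    subject_id: str
    scenario: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.vectors) != len(self.labels):
            raise ValueError("one label per feature vector required")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


def make_blocks(duration_s: float, spec: BlockSpec = BlockSpec()) -> list[tuple[float, float]]:
    """Block intervals [k*hop, k*hop + block) fully inside the recording."""
    if duration_s < spec.block_s:
        warnings.warn("recording shorter than one block; no blocks produced")
        return []
    count = int(np.floor((duration_s - spec.block_s) / spec.hop_s)) + 1
    return [(k * spec.hop_s, k * spec.hop_s + spec.block_s) for k in range(count)]


def spr_block_features(x_block: np.ndarray, fs: float) -> tuple[float, float, float, float, float]:
    """(variance, energy, mean |x|, mean |dx/dt|, max |dx/dt|) of one block.

    Variance uses the population convention; the derivative is the first
    difference scaled by fs (units per second).
    """
    x = np.asarray(x_block, dtype=float)
    if x.size == 0:
        raise ValueError("empty block")
    d = np.abs(np.diff(x) * fs) if x.size > 1 else np.zeros(1)
    return (float(np.var(x)), float(np.sum(x * x)), float(np.mean(np.abs(x))),
            float(np.mean(d)), float(np.max(d)))


def ecg_block_features(rr_block_ms: np.ndarray, hr_block: np.ndarray) -> tuple[float, float, float]:
    """(mean NN, SDNN, mean HR) over the in-block uniform-grid samples."""
    rr = np.asarray(rr_block_ms, dtype=float)
    hr = np.asarray(hr_block, dtype=float)
    if rr.size == 0 or hr.size == 0:
        raise ValueError("empty block")
    return float(rr.mean()), float(rr.std()), float(hr.mean())


def label_blocks(blocks: list[tuple[float, float]],
                 events: list[tuple[float, float]]) -> np.ndarray:
    """1 where the half-open block intersects any half-open event interval."""
    labels = np.zeros(len(blocks), dtype=int)
    for i, (bs, be) in enumerate(blocks):
        for es, ee in events:
            if bs < ee and es < be:
                labels[i] = 1
                break
    return labels


def extract_feature_vectors(
    spr: np.ndarray,
    fs: float,
    rr_uniform: np.ndarray,
    hr_uniform: np.ndarray,
    fs_rr: float,
    spec: BlockSpec = BlockSpec(),
) -> list[FeatureVector]:
    """Per-block 8-feature vectors from aligned SPR and uniform RR/HR series."""
    duration = len(spr) / fs
    vectors = []
    for bs, be in make_blocks(duration, spec):
        xb = spr[int(round(bs * fs)): int(round(be * fs))]
        rb = rr_uniform[int(round(bs * fs_rr)): int(round(be * fs_rr))]
        hb = hr_uniform[int(round(bs * fs_rr)): int(round(be * fs_rr))]
        v, e, ma, mad, xad = spr_block_features(xb, fs)
        mnn, sdnn, mhr = ecg_block_features(rb, hb)
        vectors.append(FeatureVector(v, e, ma, mad, xad, mnn, sdnn, mhr, bs, be))
    return vectors


def features_to_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    if not vectors:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([v.values() for v in vectors])


def fit_minmax(training: np.ndarray) -> ScalerParams:
    """Learn per-feature (min, max) on the training matrix."""
    X = np.asarray(training, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_minmax(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] with training params; out-of-range values are clipped.

    A degenerate feature (max == min on the training data) maps to 0.
    """
    X = np.asarray(X, dtype=float)
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.mins) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)
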