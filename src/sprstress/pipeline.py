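"""End-to-end driver: clean, normalize, analyze, classify, summarize.

Ties the stages together for a cohort of subjects each recorded in two
driving scenarios (traffic / no traffic):

1. fuse the two SPR channels (motion-artifact removal);
2. z-normalize the cleaned SPR per subject over the concatenation of that
   subject's recordings;
3. Morse-wavelet scalogram and [0.03, 1] Hz mean band energy per recording;
4. ECG chain: R peaks, ectopic correction, uniform RR/HR, per-subject
   normalization;
5. 15 s / 5 s-hop block features, min-max scaled with training-set params;
6. classification, relabel, per-recording stress percentage;
7. paired Wilcoxon comparison of the two scenarios across subjects.

Classifiers are trained on a separately simulated labeled corpus, mirroring
the train-on-one-experiment / test-on-another protocol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import classify as cl
from . import features as ft
from .ecg import correct_ectopic, detect_r_peaks, resample_rr, rr_from_peaks
from .ma import fuse_channels, normalize_zscore_concat
from .scalogram import MorseParams, band_energy, cwt_scalogram
from .simulate import SimConfig, SprPairRecording, gen_recording
from .stats import PairedTestResult, wilcoxon_signed_rank

__all__ = ["RunConfig", "RunReport", "process_subject", "build_training_set",
           "run_pipeline", "simulate_cohort"]

SCENARIOS = ("traffic", "no_traffic")


@dataclass(frozen=True)
class RunConfig:
    n_subjects: int = 10
    n_train_subjects: int = 6
    sim: SimConfig = field(default_factory=SimConfig)
    ma_window_s: float = 2.0
    ma_eps: float = 1e-9
    morse: MorseParams = field(default_factory=MorseParams)
    band: tuple[float, float] = (0.03, 1.0)
    blocks: ft.BlockSpec = field(default_factory=ft.BlockSpec)
    fs_rr: float = 4.0
    families: tuple[str, ...] = ("svm", "random_forest", "decision_tree")
    cv_folds: int = 10
    seed: int = 1
    compute_scalograms: bool = True

    def subject_seed(self, index: int, training: bool = False) -> int:
        base = 500_000_000 if training else 0
        return int((self.seed * 10_007 + base + index) % (2**31))


@dataclass
class SubjectResult:
    subject_id: str
    feature_sets: dict[str, ft.LabeledFeatureSet]      # scenario -> features+truth
    blocks: dict[str, list[tuple[float, float]]]
    sections: dict[str, list[tuple[float, float, str]]]
    band_mean_energy: dict[str, float]


@dataclass
class RunReport:
    config: RunConfig
    band_energy: dict[str, dict[str, float]]           # subject -> scenario -> a.u.
    stress: dict[str, dict[str, dict[str, cl.StressSummary]]]  # family -> subject -> scenario
    paired_tests: dict[str, PairedTestResult | None]   # family -> Wilcoxon result
    best_params: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": _config_echo(self.config),
            "band_energy": self.band_energy,
            "stress": {
                fam: {
                    subj: {scen: dataclasses.asdict(s) for scen, s in scens.items()}
                    for subj, scens in subjects.items()
                }
                for fam, subjects in self.stress.items()
            },
            "paired_tests": {fam: (dataclasses.asdict(r) if r is not None else None)
                             for fam, r in self.paired_tests.items()},
            "best_params": self.best_params,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def simulate_cohort(config: RunConfig, training: bool = False
                    ) -> list[dict[str, SprPairRecording]]:
    """One {scenario: recording} pair per subject, with derived seeds."""
    n = config.n_train_subjects if training else config.n_subjects
    prefix = "T" if training else "S"
    cohort = []
    for i in range(n):
        cfg = replace(config.sim, seed=config.subject_seed(i, training))
        subject = f"{prefix}{i + 1:02d}"
        cohort.append({scen: gen_recording(cfg, scenario=scen, subject_id=subject)
                       for scen in SCENARIOS})
    return cohort


def process_subject(
    recordings: dict[str, SprPairRecording], config: RunConfig
) -> SubjectResult:
    """Run stages 1-5 (through raw, unscaled features) for one subject.

    Normalization pools the subject's recordings across scenarios, so the
    two conditions stay mutually comparable.
    """
    scens = list(recordings)
    cleaned = {s: fuse_channels(recordings[s].spr_left, recordings[s].spr_right,
                                recordings[s].fs, config.ma_window_s,
                                config.ma_eps).signal for s in scens}
    spr_norm = dict(zip(scens, normalize_zscore_concat([cleaned[s] for s in scens])))

    band_mean: dict[str, float] = {}
    if config.compute_scalograms:
        for s in scens:
            scal = cwt_scalogram(spr_norm[s], recordings[s].fs, config.morse)
            band_mean[s] = band_energy(scal, *config.band).mean_energy

    rr_uniform, hr_uniform = {}, {}
    for s in scens:
        rec = recordings[s]
        rr = correct_ectopic(rr_from_peaks(detect_r_peaks(rec.ecg, rec.fs)))
        uni = resample_rr(rr, config.fs_rr, duration_s=rec.duration_s)
        rr_uniform[s], hr_uniform[s] = uni.rr_ms, uni.hr_bpm
    rr_norm = dict(zip(scens, normalize_zscore_concat([rr_uniform[s] for s in scens])))
    hr_norm = dict(zip(scens, normalize_zscore_concat([hr_uniform[s] for s in scens])))

    feature_sets, blocks, sections = {}, {}, {}
    for s in scens:
        rec = recordings[s]
        vectors = ft.extract_feature_vectors(
            spr_norm[s], rec.fs, rr_norm[s], hr_norm[s], config.fs_rr, config.blocks)
        blk = ft.make_blocks(rec.duration_s, config.blocks)
        labels = ft.label_blocks(blk, rec.events.intervals())
        feature_sets[s] = ft.LabeledFeatureSet(
            vectors=vectors, labels=labels, subject_id=rec.subject_id, scenario=s)
        blocks[s] = blk
        sections[s] = rec.sections
    return SubjectResult(subject_id=recordings[scens[0]].subject_id,
                         feature_sets=feature_sets, blocks=blocks,
                         sections=sections, band_mean_energy=band_mean)


def build_training_set(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate and process the labeled training corpus; returns (X, y)."""
    train_cfg = replace(config, compute_scalograms=False)
    Xs, ys = [], []
    for recordings in simulate_cohort(config, training=True):
        res = process_subject(recordings, train_cfg)
        for s in SCENARIOS:
            Xs.append(ft.features_to_matrix(res.feature_sets[s].vectors))
            ys.append(res.feature_sets[s].labels)
    return np.vstack(Xs), np.concatenate(ys)


def run_pipeline(config: RunConfig = RunConfig(),
                 cohort: list[dict[str, SprPairRecording]] | None = None) -> RunReport:
    """Full run: training corpus, test cohort, classification, summaries."""
    if cohort is None:
        cohort = simulate_cohort(config)
    results = [process_subject(recs, config) for recs in cohort]

    X_tr, y_tr = build_training_set(config)
    scaler = ft.fit_minmax(X_tr)
    X_tr_s = ft.apply_minmax(scaler, X_tr)

    stress: dict[str, dict[str, dict[str, cl.StressSummary]]] = {}
    tests: dict[str, PairedTestResult] = {}
    best_params: dict[str, dict] = {}
    for family in config.families:
        spec = cl.ModelSpec(family=family, cv_folds=config.cv_folds, seed=config.seed)
        model = cl.train(spec, X_tr_s, y_tr)
        best_params[family] = dict(model.best_params_)
        per_subject: dict[str, dict[str, cl.StressSummary]] = {}
        traffic_pct, no_traffic_pct = [], []
        for res in results:
            per_scen: dict[str, cl.StressSummary] = {}
            for s in SCENARIOS:
                X = ft.apply_minmax(scaler, ft.features_to_matrix(res.feature_sets[s].vectors))
                labels = cl.relabel(cl.predict_sequence(model, X))
                per_scen[s] = cl.stress_percentage(labels, res.blocks[s], res.sections[s])
            per_subject[res.subject_id] = per_scen
            traffic_pct.append(per_scen["traffic"].pct_positive_total)
            no_traffic_pct.append(per_scen["no_traffic"].pct_positive_total)
        stress[family] = per_subject
        try:
            tests[family] = wilcoxon_signed_rank(np.array(traffic_pct),
                                                 np.array(no_traffic_pct))
        except ValueError:
            tests[family] = None  # cohort too small or degenerate for the paired test
    band = {res.subject_id: dict(res.band_mean_energy) for res in results}
    return RunReport(config=config, band_energy=band, stress=stress,
                     paired_tests=tests, best_params=best_params)
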