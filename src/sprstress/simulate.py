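"""Synthetic driving-session recordings with known ground truth.

Generates the kind of multichannel recording the rest of the package
consumes: two skin-potential-response (SPR) channels sampled on the two
hands, an ECG channel, a schedule of stress-evoking events, and road-section
annotations.  The statistical structure mirrors the assumptions the
processing chain relies on:

* stress events produce a fast-rise / slow-decay electrodermal pulse that is
  *identical* on both hands (it is driven by the autonomic nervous system,
  not by the hand);
* motion artifacts are short high-energy bursts that appear on *one* hand at
  a time (a hand acting on the steering wheel);
* heart rate rises during stress events and relaxes exponentially afterwards.

Every generator is deterministic for a fixed seed, and returns its ground
truth (clean shared SPR component, artifact intervals, exact beat times) so
downstream stages can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventSchedule",
    "SimConfig",
    "SprPairRecording",
    "SCENARIO_EVENT_RATES",
    "gen_event_schedule",
    "gen_spr_pair",
    "gen_ecg",
    "gen_recording",
    "biexp_pulse",
]

#: Stress-event rates (events per minute) defining the two driving scenarios:
#: dense aggressive traffic versus an empty road.
SCENARIO_EVENT_RATES = {"traffic": 3.0, "no_traffic": 0.3}

#: SPR sensor full-scale input range, mV.
SPR_FULL_SCALE_MV = 10.0


@dataclass(frozen=True)
class EventSchedule:
    """Stress-evoking events as (start_s, duration_s, amplitude_mv) triples."""

    events: list[tuple[float, float, float]]
    recording_duration_s: float

    def __post_init__(self) -> None:
        prev = -np.inf
        for start, dur, _amp in self.events:
            if start < 0 or dur <= 0:
                raise ValueError("event starts must be >= 0 and durations > 0")
            if start + dur > self.recording_duration_s + 1e-9:
                raise ValueError("event extends beyond the recording")
            if start < prev:
                raise ValueError("events must be sorted by start time")
            prev = start

    def intervals(self) -> list[tuple[float, float]]:
        """Half-open [start, end) intervals of all events."""
        return [(s, s + d) for s, d, _ in self.events]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the study conditions.

    ``event_rate_per_min=None`` means "derive from the scenario tag"
    (see :data:`SCENARIO_EVENT_RATES`).
    """

    fs: float = 200.0                     # Sa/s, sensor rate
    duration_s: float = 600.0             # ~10 min per drive
    event_rate_per_min: float | None = None
    event_min_gap_s: float = 10.0
    event_duration_s: float = 4.0         # mean obstacle-encounter length
    event_amp_mv: float = 2.0             # SPR pulse drive amplitude
    artifact_rate_per_min: float = 2.0
    artifact_amp: float = 3.0             # mV, burst envelope amplitude
    noise_sd: float = 0.05                # mV, per-channel sensor noise
    spr_rise_tau_s: float = 0.5
    spr_decay_tau_s: float = 2.0
    hr_base_bpm: float = 70.0
    hr_event_delta_bpm: float = 15.0
    ecg_noise_sd: float = 0.02            # mV
    section_split_s: float | None = None  # default duration/2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("artifact_rate_per_min",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.event_rate_per_min is not None and self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be >= 0")
        if self.spr_rise_tau_s <= 0 or self.spr_decay_tau_s <= 0:
            raise ValueError("SPR time constants must be positive")
        if not (40.0 <= self.hr_base_bpm <= 180.0):
            raise ValueError("hr_base_bpm must lie in [40, 180] bpm")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class SprPairRecording:
    """A simulated (or loaded) two-hand SPR + ECG recording.

    Ground-truth fields (``clean_spr``, ``artifacts``, ``true_r_times``) are
    populated by the simulator and ``None`` for recordings read from disk.
    """

    t: np.ndarray
    spr_left: np.ndarray
    spr_right: np.ndarray
    ecg: np.ndarray
    events: EventSchedule
    sections: list[tuple[float, float, str]]
    subject_id: str
    scenario: str
    fs: float
    seed: int | None = None
    clean_spr: np.ndarray | None = None
    artifacts: list[tuple[float, float, str]] = field(default_factory=list)
    true_r_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("spr_left", "spr_right", "ecg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time axis")
        if self.scenario not in ("traffic", "no_traffic"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs


def gen_event_schedule(
    rate_per_min: float,
    duration_s: float,
    min_gap_s: float = 10.0,
    seed: int | np.random.Generator = 0,
    event_duration_s: float = 4.0,
    amplitude_mv: float = 2.0,
) -> EventSchedule:
    """Homogeneous Poisson event arrivals thinned to a minimum gap.

    Arrival times are a Poisson process with the given rate; an arrival is
    kept only if it starts at least ``min_gap_s`` after the previously kept
    one.  Kept events get a duration uniform in [0.5, 1.5] x
    ``event_duration_s`` and an amplitude uniform in [0.7, 1.3] x
    ``amplitude_mv``, truncated so the event fits inside the recording.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_arrivals = rng.poisson(rate_per_min * duration_s / 60.0)
    starts = np.sort(rng.uniform(0.0, duration_s, size=n_arrivals))
    events: list[tuple[float, float, float]] = []
    last = -np.inf
    for s in starts:
        if s - last < min_gap_s:
            continue
        dur = event_duration_s * rng.uniform(0.5, 1.5)
        amp = amplitude_mv * rng.uniform(0.7, 1.3)
        dur = min(dur, duration_s - s)
        if dur <= 0:
            continue
        events.append((float(s), float(dur), float(amp)))
        last = s
    return EventSchedule(events=events, recording_duration_s=float(duration_s))


def biexp_pulse(t_rel: np.ndarray, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Biexponential electrodermal response A*(exp(-t/tau_d) - exp(-t/tau_r)) for t >= 0."""
    out = np.zeros_like(t_rel, dtype=float)
    m = t_rel >= 0
    tr = t_rel[m]
    out[m] = amp * (np.exp(-tr / tau_decay) - np.exp(-tr / tau_rise))
    return out


def _artifact_burst(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """A hand-movement burst: Hann-windowed oscillation, 1-4 Hz, high local energy."""
    t = np.arange(n) / fs
    f = rng.uniform(1.0, 4.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    env = np.hanning(n)
    return amp * env * np.sin(2 * np.pi * f * t + phase)


def gen_spr_pair(
    schedule: EventSchedule, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float, str]]]:
    """Two SPR channels sharing the event-driven component.

    Returns ``(spr_left, spr_right, clean, artifacts)`` where ``clean`` is
    the shared noise-free component and ``artifacts`` is a list of
    ``(start_s, end_s, hand)`` burst intervals, each on exactly one hand.
    Burst intervals never overlap each other, so no sample is artifact-bearing
    on both hands.
    """
    if schedule.recording_duration_s > cfg.duration_s + 1e-9:
        raise ValueError("schedule does not fit the configured duration")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    clean = np.zeros(n)
    for start, _dur, amp in schedule.events:
        clean += biexp_pulse(t - start, amp, cfg.spr_rise_tau_s, cfg.spr_decay_tau_s)

    left = clean + rng.normal(0.0, cfg.noise_sd, size=n)
    right = clean + rng.normal(0.0, cfg.noise_sd, size=n)

    artifacts: list[tuple[float, float, str]] = []
    n_bursts = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
    starts = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_bursts))
    last_end = -np.inf
    for s in starts:
        dur = rng.uniform(0.5, 2.0)
        if s < last_end or s + dur > cfg.duration_s:
            continue  # bursts never overlap in time, by construction
        hand = "left" if rng.random() < 0.5 else "right"
        i0, i1 = int(round(s * cfg.fs)), int(round((s + dur) * cfg.fs))
        burst = _artifact_burst(i1 - i0, cfg.fs, cfg.artifact_amp, rng)
        (left if hand == "left" else right)[i0:i1] += burst
        artifacts.append((float(s), float(s + dur), hand))
        last_end = s + dur

    fs_lim = SPR_FULL_SCALE_MV
    for name, sig in (("spr_left", left), ("spr_right", right)):
        if np.any(np.abs(sig) > fs_lim):
            warnings.warn(f"{name} exceeds the +/-{fs_lim:g} mV sensor range; clipping")
            np.clip(sig, -fs_lim, fs_lim, out=sig)
    return left, right, clean, artifacts


def _hr_drive(t: np.ndarray, schedule: EventSchedule, rise_tau: float = 2.0,
              relax_tau: float = 10.0) -> np.ndarray:
    """Normalized heart-rate drive in [0, 1]: rises during events, decays after."""
    g = np.zeros_like(t)
    for start, end in schedule.intervals():
        gi = np.zeros_like(t)
        during = (t >= start) & (t < end)
        gi[during] = 1.0 - np.exp(-(t[during] - start) / rise_tau)
        after = t >= end
        g_end = 1.0 - np.exp(-(end - start) / rise_tau)
        gi[after] = g_end * np.exp(-(t[after] - end) / relax_tau)
        np.maximum(g, gi, out=g)
    return g


# Beat template: (center offset s, width s, amplitude mV) Gaussians for the
# P wave, QRS complex, and T wave. R amplitude dominates everything else.
_BEAT_GAUSSIANS = (
    (-0.18, 0.025, 0.08),   # P
    (-0.025, 0.010, -0.10),  # Q
    (0.0, 0.012, 1.00),      # R
    (0.025, 0.010, -0.15),   # S
    (0.25, 0.060, 0.18),     # T
)


def gen_ecg(
    schedule: EventSchedule, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """ECG with event-modulated heart rate; returns (signal, true R times).

    Instantaneous rate is ``hr_base + hr_event_delta * g(t)`` with g the
    event drive; beat times are the integer crossings of the integrated rate,
    so the beat count matches the rate integral to within one beat.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    hr = cfg.hr_base_bpm + cfg.hr_event_delta_bpm * _hr_drive(t, schedule)
    # integrated beat phase, in beats
    phase = np.concatenate([[0.0], np.cumsum(hr[:-1] + hr[1:]) / 2.0 / 60.0 / cfg.fs])
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, t)

    ecg = rng.normal(0.0, cfg.ecg_noise_sd, size=n)
    half = int(round(0.4 * cfg.fs))
    for bt in beat_times:
        c = int(round(bt * cfg.fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        trel = t[lo:hi] - bt
        for mu, sd, amp in _BEAT_GAUSSIANS:
            ecg[lo:hi] += amp * np.exp(-0.5 * ((trel - mu) / sd) ** 2)
    return ecg, beat_times


def gen_recording(
    cfg: SimConfig, scenario: str = "traffic", subject_id: str = "S01"
) -> SprPairRecording:
    """Compose event schedule, SPR pair, and ECG into one recording."""
    if scenario not in SCENARIO_EVENT_RATES:
        raise ValueError(f"unknown scenario {scenario!r}")
    rate = cfg.event_rate_per_min
    if rate is None:
        rate = SCENARIO_EVENT_RATES[scenario]
        cfg = replace(cfg, event_rate_per_min=rate)
    ss = np.random.SeedSequence([cfg.seed, 0 if scenario == "traffic" else 1])
    r_sched, r_spr, r_ecg = (np.random.default_rng(s) for s in ss.spawn(3))
    schedule = gen_event_schedule(
        rate, cfg.duration_s, cfg.event_min_gap_s, r_sched,
        event_duration_s=cfg.event_duration_s, amplitude_mv=cfg.event_amp_mv,
    )
    left, right, clean, artifacts = gen_spr_pair(schedule, cfg, r_spr)
    ecg, true_r = gen_ecg(schedule, cfg, r_ecg)
    split = cfg.section_split_s if cfg.section_split_s is not None else cfg.duration_s / 2.0
    sections = [(0.0, float(split), "highway"), (float(split), cfg.duration_s, "city")]
    t = np.arange(cfg.n_samples) / cfg.fs
    return SprPairRecording(
        t=t, spr_left=left, spr_right=right, ecg=ecg, events=schedule,
        sections=sections, subject_id=subject_id, scenario=scenario,
        fs=cfg.fs, seed=cfg.seed, clean_spr=clean, artifacts=artifacts,
        true_r_times=true_r,
    )
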