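# Methods

## Signal model and processing chain

The package models a driving session as three simultaneous 200 Sa/s
channels: SPR from each hand (mV, sensor band [0.08, 8] Hz, full scale
±10 mV) and one ECG derivation (mV). The skin potential response is driven
by sympathetic sudomotor activity and is therefore *common to both hands*;
motion artifacts from steering-wheel action are hand-specific and rarely
simultaneous. This asymmetry is the entire basis of the artifact-removal
stage: whatever appears on one hand only is treated as artifact.

The chain is: dual-channel fusion → per-subject z-normalization →
(offline branch) Morse-wavelet scalogram and band energy; (block branch)
ECG-derived RR/HR series → 15 s / 5 s-hop block features → min–max scaling
→ binary classification → relabel → stress percentage per drive → paired
Wilcoxon comparison across subjects.

## Motion-artifact removal

"Local energy" is operationalized as the centered sliding-window *variance*
(window 2 s, edges truncated): subtracting the window mean removes the slow
tonic SPR level, so bursts and noise — not baseline drift — drive the
weights. The fusion weight

w = (E₂ + ε) / (E₁ + E₂ + 2ε),  ε = 1e−9 mV²

is the simplest rule that (a) weights inversely to local energy, (b) sums
to one, (c) degrades gracefully to a plain average when both energies
vanish. The output is pointwise a convex combination of the inputs and the
rule is symmetric in the two channels. The 2 s window is a compromise:
long enough to integrate over a burst's oscillation period (bursts are
0.5–2 s), short enough that an artifact does not bleed its weight far into
clean segments.

Per-subject normalization subtracts the mean and divides by the standard
deviation (population, divide-by-n convention) of the *concatenation* of
that subject's recordings across conditions, so the two conditions of one
subject remain mutually comparable and subjects are comparable to each
other.

## Morse-wavelet scalogram

The generalized Morse analytic wavelet is used in its frequency-domain
form Ψ(ω) = U(ω)·k·ω^β·e^(−ω^γ) with γ = 3 and time–bandwidth product
βγ = 60 (β = 20), k fixed so the peak value is 2 (the analytic-wavelet
convention: a real sinusoid of unit amplitude yields unit magnitude). The
spectral peak, ω_p = (β/γ)^(1/γ), defines the scale-to-pseudo-frequency
conversion f = ω_p·fs / (2π·a).

The CWT is computed per scale as the inverse FFT of the signal spectrum
times the scaled wavelet response, with zero-padding to at least twice the
signal length so circular wrap-around lands in the pad. The scale grid is
geometric, 12 voices per octave, spanning [0.02, 8] Hz in pseudo-frequency
(the grid is fixed per analysis so in-band row sets match across a
subject's recordings). Cone-of-influence columns are *retained*: the
statistic of interest is the mean in-band energy over a full ~10 min
recording, and the ~1% of columns affected by edges changes it negligibly
while keeping the statistic defined on all of the data. The band-energy
statistic sums squared magnitudes over rows with pseudo-frequency in
[0.03, 1] Hz, edges inclusive, then averages over time. Accuracy of the
FFT path is verified in the tests against a direct time-domain
inner-product CWT (dense numerical inverse-Fourier synthesis of the
wavelet) to within 1% on short signals.

## ECG processing

R peaks: the classic Pan–Tompkins chain — 5–15 Hz second-order Butterworth
band-pass (zero-phase), five-point derivative kernel [1, 2, 0, −2, −1]·fs/8,
squaring, 150 ms moving-window integration, dual adaptive thresholds
(signal/noise running estimates, threshold = NPK + 0.25·(SPK − NPK)) with
search-back at 1.66× the running RR average and a 200 ms refractory period.
Detected peaks are refined to the raw-signal maximum within ±40 ms, which
removes the group-delay bias of the integration stage.

Ectopic correction: an RR interval deviating from the median of its
5-interval centered neighborhood by more than 25% of that median is flagged
and replaced by cubic interpolation through the unflagged intervals; beat
times are untouched. The 25% running-median rule is the standard
threshold-based correction; both the fraction and the interpolation are
exposed. The rule is idempotent on the fixtures used in the tests.

Resampling: cubic spline through (beat time, preceding-interval RR) pairs,
evaluated on a uniform 4 Hz grid — conventional for HRV work and ample for
15 s block statistics — with edge values held (no spline extrapolation).
HR is defined pointwise as 60000/RR(ms), so the identity HR·RR = 60000
holds on every grid sample. RR (and HR) series are then z-normalized per
subject exactly as the SPR is.

## Features, labels, scaling

Blocks are half-open [k·5 s, k·5 s + 15 s) intervals fully inside the
recording (118 blocks for a 600 s drive). SPR features use the population
variance, energy Σx², mean |x|, and the first difference scaled by fs as
the discrete derivative. ECG features are the arithmetic means and the
population standard deviation over the in-block 4 Hz grid samples. Since
features are computed on z-normalized series, they are in normalized units
(the subsequent min–max scaling makes any affine choice immaterial to the
classifiers).

Ground truth: a block is "stress" iff its half-open interval intersects a
half-open event interval; intersection at a single boundary point (event
start == block end) does not count. Min–max parameters are learned on
training data only and applied to held-out data with clipping to [0, 1];
a degenerate feature (max == min in training) maps to 0.

## Classification and evaluation

Families: RBF-kernel SVM (grid: C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.1, 1}),
random forest (trees ∈ {100, 200}, max features ∈ {√p, 0.5}), decision tree
(depth ∈ {3, 5, 10, ∞}, criterion ∈ {gini, entropy}); hyperparameters by
stratified 10-fold cross-validation (folds capped by the minority-class
count on small sets), deterministic under the seed. The search spaces are
config-exposed; only the families and the 10-fold protocol are fixed by
design.

The relabel pass flips any label whose two neighbors both carry the
opposite value, in one sequential left-to-right pass that reads the
already-updated predecessor and the original successor. This variant was
chosen because it is idempotent and never increases the number of isolated
singletons (verified exhaustively for all binary sequences up to length
14), while the naive simultaneous-update pass can create new singletons on
alternating runs. Endpoints are never modified.

Evaluation is leave-one-person-out: scaler and classifier are fit on all
other subjects, the held-out subject's relabeled predictions are scored,
and per-subject metrics (accuracy, sensitivity, specificity, balanced
accuracy, geometric mean, all percent) are averaged arithmetically.
Because the geometric mean does not commute with averaging, the
pooled-confusion aggregation is reported alongside the per-subject mean.

The per-drive summary is the percentage of blocks labeled "stress",
overall and per road section (a block belongs to the section containing
its start). Conditions are compared with the Wilcoxon signed-rank test:
exact null distribution by full enumeration of sign assignments (a
subset-sum recursion over doubled ranks, exact under mid-ranks) for up to
25 non-zero pairs, normal approximation with tie and continuity
corrections above; zero differences dropped; two-sided by default. At
least 5 non-zero pairs are required.

## Synthetic-data generator

The generator emulates exactly the structure the pipeline exploits:

| parameter | default | unit | rationale |
|---|---|---|---|
| fs | 200 | Sa/s | sensor rate |
| duration | 600 | s | one simulated drive |
| event rate (traffic / no traffic) | 3 / 0.3 | min⁻¹ | scenario contrast detectable at n = 10 |
| event min gap | 10 | s | separates responses beyond the decay time |
| SPR rise / decay τ | 0.5 / 2 | s | standard biexponential electrodermal response; energy inside the [0.08, 8] Hz sensor band |
| event amplitude | 2 (±30%) | mV | placeholder; no published amplitude statistics exist |
| artifact rate | 2 | min⁻¹ | frequent enough to stress the fusion |
| artifact bursts | 0.5–2 s, 3 mV, 1–4 Hz | | windowed oscillation, high local energy, one hand each, mutually disjoint |
| channel noise | 0.05 | mV sd | white, per channel |
| HR base / event rise | 70 / 15 | bpm | rises during events (2 s rise), relaxes exponentially (10 s) |

Events are Poisson arrivals thinned to the minimum gap. ECG beats come
from integrating the instantaneous rate (so the beat count matches the
rate integral to ±1 beat) and each beat renders a Gaussian P-QRS-T
template with a dominant 1 mV R wave; exact beat times are returned as
ground truth.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: real electrodermal waveform variability and
habituation, amplitude statistics of real stress responses, baseline
drift/tonic level changes, realistic ECG morphology variation or true
ectopy (ectopic-beat correction is exercised with synthetic outliers),
respiration coupling, and artifacts that *do* strike both hands at once
(the fusion rule's stated blind spot). Classifier performance numbers on
this corpus characterize the pipeline's mechanics, not expected field
accuracy.

## Problem sizes

The test suite exercises stages on 1–2 min recordings and the end-to-end
check on the full 10-subject, two-scenario cohort at 600 s per recording
with a 6-subject training corpus; the acceptance script runs the same
full-size cohort. A complete default run (training, 20 scalograms, three
classifier families) takes well under two minutes on one core.

## Known limitations

* The fusion rule assumes artifacts are one-handed; simultaneous bimanual
  artifacts pass through attenuated but not removed.
* The detector is tuned for upright R waves; inverted leads would need a
  polarity flag.
* Scalogram columns inside the cone of influence are kept (documented
  above); band energies of recordings shorter than ~1 min would be
  noticeably edge-biased.
* The exact Wilcoxon enumeration is O(n²·Σrank) via the subset-sum
  recursion — fine for n ≤ 25, after which the approximation takes over.
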