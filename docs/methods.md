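# Methods

`astromea` analyses multi-channel extracellular recordings from
microelectrode arrays (MEAs) with five coordinated stages — spike/burst
metrics, ordinal-pattern complexity–entropy analysis, iAAFT surrogate
testing, spike-waveform classification and autoregressive
predictability — plus a ground-truthed synthetic recording generator
that makes every stage testable without laboratory data.  This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Preprocessing chains

Three independent chains serve the three signal views:

| chain   | filter                                   | output rate |
|---------|------------------------------------------|-------------|
| spike   | elliptic bandpass 300–3000 Hz, order 2   | unchanged   |
| C-E     | Butterworth low-pass 40 Hz, order 5      | 1 kHz       |
| predict | Butterworth low-pass 300 Hz, order 5     | 250 Hz      |

All filters are applied zero-phase (forward–backward `sosfiltfilt`), so
spike timing is unbiased; the effective order is doubled.  Elliptic
design parameters not fixed by the method description default to 0.1 dB
passband ripple and 40 dB stopband attenuation and are exposed in
`FilterSpec`.  The spike chain additionally subtracts the channel mean
so DC is removed exactly rather than merely attenuated by the finite
stopband.  Decimation keeps every k-th sample after the low-pass; the
target rate must divide the input rate (25 kHz → 1 kHz is factor 25,
25 kHz → 250 Hz factor 100, one sample per 4 ms).  Whether the original
analyses filtered causally or zero-phase is not documented; zero-phase
shifts spike times by less than one sample at these orders.

## Spike detection

σ is the plain standard deviation of the spike-band-filtered analysis
window, per channel (a median-based robust estimate is deliberately not
substituted).  Both polarities are detected at ±kσ with k = 5.  Each
contiguous supra-threshold excursion contributes one spike timed at its
absolute extremum; a 1 ms dead time merges events, keeping the larger
amplitude, which prevents double counting of multiphasic waveforms.
Constant channels (σ = 0) raise a degenerate-input error.

## CMA burst detection

Inter-spike intervals (ISIs) are pooled network-wide and histogrammed
(default 5 ms bins, capped at 1 s).  The cumulative moving average
(CMA) of the histogram is computed; the burst ISI threshold is the bin
at which the CMA has decayed to α₁·max(CMA) past its peak, with α₁
selected from the skewness of the CMA curve (< 1 → 1.0, 1–4 → 0.7,
4–9 → 0.5, > 9 → 0.3; all configurable).  The threshold is shared by
all channels ("network-wide"); bursts are then delimited per channel as
runs of ≥ 3 spikes whose successive ISIs stay at or below it.
Degenerate convention: when the pooled ISI histogram occupies a single
bin (e.g. a perfectly regular train) there is no time-scale separation
and no bursts are reported.  Metrics: spike rate SR (Hz) and burst rate
BR (Hz) normalized by the window length (default window 100–200 s),
burst duration BD (ms), percent of spikes inside burst intervals, ISIs
and inter-burst intervals (IBIs, end-to-next-start), each per channel
and network-pooled — the two aggregations can genuinely differ, so both
are emitted.

## Ordinal patterns, entropy, complexity

A series is embedded in M dimensions at lag τ; each embedding vector is
mapped to the permutation that sorts its lag components in descending
order, with exact ties resolved toward the smaller lag index at the
lower-rank position (a deterministic, total rule — implemented as the
reversed stable argsort).  With pattern probabilities P over the M!
permutations:

* normalized permutation entropy  H_S = S[P] / ln M!  with
  S[P] = −Σ p ln p and 0·ln 0 := 0 (no smoothing of unseen patterns);
* statistical complexity  C_JS = Q₀ · J(P, P_e) · H_S, where J is the
  Jensen–Shannon divergence between P and the uniform distribution P_e
  over the M! patterns and Q₀ = −2 / [((N+1)/N)·ln(N+1) − 2 ln 2N + ln N],
  N = M!, normalizes the disequilibrium to [0, 1].

Defaults M = 5, τ = 100 samples on the 1 kHz C-E chain: a 100 s window
yields 100000 − 400 embedding vectors, ample for M! = 120 patterns.
Natural logarithms are used internally; both measures are
base-invariant.  Deterministic monotone dynamics give (H_S, C_JS) →
(0, 0), white noise → (1, 0); structured signals occupy the interior
with elevated C_JS, which is what makes the plane discriminate
patterned from random activity.  τ is a plain configuration value; no
optimality criterion is imposed.

## iAAFT surrogates and the KS comparison

Each surrogate starts from a seeded random permutation of the channel
and alternates (i) imposing the original amplitude spectrum in the
Fourier domain with (ii) rank-remapping onto the original sorted
values.  The amplitude distribution is therefore preserved *exactly*
(the surrogate is a permutation of the original values) and the power
spectrum approximately.  Stopping rule: identical rank vector on two
consecutive iterations, or relative periodogram L2 error ≤ 5×10⁻³
(configurable), capped at 1000 iterations.  The spectrum-tolerance stop
matters in practice: exact rank stabilization of 10⁵-sample series
takes hundreds of iterations after the spectral error has already
floored, and the tolerance is twice as tight as the 10⁻² the
analysis requires; a stagnation stop (no >1% improvement over 15
iterations) bounds the heavy-tailed cases, counting them converged
only within 10⁻².  The iterate is carried in single precision — the
tolerance sits four orders of magnitude above float32 resolution — and
the returned surrogate is the exact float64 multiset of the input.  Surrogates are generated
from the C-E-chain (1 kHz) signals; 49 per channel by default, so a
60-channel MEA yields 2940 surrogate series, each from an independent
seeded substream.

Original and surrogate (H_S, C_JS) values are pooled per recording (a
grouping key allows pooling several recordings, e.g. per culture) and
compared measure-by-measure with a two-sample Kolmogorov–Smirnov test:
D = sup|F_a − F_b| over the two empirical CDFs, p from the asymptotic
Kolmogorov distribution at effective size n_a·n_b/(n_a+n_b), h = 1 iff
p < 0.05.  The plain asymptotic formula is used (sample sizes here are
≥ 49); note scipy's `ks_2samp(method="asymp")` additionally applies a
small-sample continuity correction, so its p-values differ by a
bounded factor while decisions agree.  At small sample sizes the
discreteness of D makes the null p-value distribution lumpy; rejection
rates remain at or below nominal level, which is what the test suite
checks.  No multiple-testing correction is applied across channels.

## Waveform classification

Cutouts span 1 ms before to 2 ms after each spike peak, defined in
time, with the sample count derived from the actual rate (75 samples at
25 kHz); spikes whose window crosses a recording edge are skipped, not
padded, because padding would distort the first/last-sample baseline.

Clustering is divisive k-means on energy-normalised cutouts: clusters
are recursively bisected and a split is kept when its silhouette score
is ≥ 0.2, up to 6 clusters.  Recursive bisection is used instead of a
flat silhouette maximization over k because one gross contrast
(positive- versus negative-going waveforms) dominates the global
silhouette and hides finer shape classes: on the five-class template
mixture the flat criterion picks k = 2 (purity 0.40) while bisection
recovers all five classes (real class splits score ≈ 0.30, spurious
within-class splits ≈ 0.03, so 0.2 sits in a wide margin).  The
clusterer is a means to averaged waveforms, not a spike sorter, and is
swappable.

On each cluster-averaged waveform, with baseline = mean of the first
and last samples, five features are measured: signed baseline-to-peak
amplitude; |1st-peak/peak| ratio (1st peak = opposite-sign extremum
before the peak); amplitude slope (peak − 1st peak)/(t_peak − t_1st) in
µV/ms; peak-to-peak time (1st to 2nd peak, ms); spike duration (peak to
2nd peak, ms), where the 2nd peak is the first opposite-sign local
extremum after the peak exceeding 5% of the main amplitude — if none
exists the duration runs to the window end and the result is flagged.

The decision tree assigns: **PS** if the amplitude is positive; else
**CS** if ≥ 2 distinct troughs reach 30% of the main amplitude at
≥ 0.3 ms separation; else **TS** if the positive phases on both sides
of the trough reach 15% of the main amplitude; else **FS** if the spike
duration is < 0.5 ms; else **RS**.  All negative-branch criteria are
ratios or durations, making classification invariant to uniform
amplitude scaling.  The numeric thresholds and the CS → TS → FS → RS
precedence are implementation defaults (exposed in `AnalysisConfig`),
chosen so that the five generator templates round-trip exactly; they
are not measured biological constants.

## Predictability

Each channel of the 250 Hz prediction chain is framed as a one-step-
ahead autoregression: 20 lagged samples (80 ms of history) predict the
next sample.  A random forest (default 100 trees, unlimited depth,
seeded) is trained on the first 70% of samples (contiguous) and
predicts the last 30% from true lags; the score is Pearson's r between
predictions and actuals.  The autoregressive framing and the finite
forest size are interpretations — the method description fixes neither
the regressor's inputs nor a tree budget — and both are configuration
values.  The score column is named `pearson_r` (range [−1, 1]); note
some reports label this same quantity "R²".  A constant train or test
segment leaves r undefined: the result is flagged and r is NaN, never
silently zero.  A multi-step horizon is left as a configuration stub.

## Synthetic recordings

The generator emulates 60-channel, 25 kHz, 5-minute MEA recordings.
Per channel: a homogeneous Poisson background with 2 ms absolute
refractory period, plus bursts with Poisson or periodic-with-jitter
onsets, a fixed spike count per burst and fixed intra-burst ISI.  Each
channel draws one waveform class from the preset mixture (an electrode
records a stereotyped unit) and spikes are rendered by adding the class
template — a sum of Gaussian-windowed phases with edges pinned to
exactly zero — into white Gaussian noise (default σ = 5 µV), with
multiplicative per-spike amplitude jitter.  Injected SNR is peak
amplitude / noise σ.

Three condition presets order the cultures from rhythmic/stereotyped to
sparse/irregular activity, standing in for decreasing neuron fractions:

| preset       | tonic (Hz) | bursts            | amplitude (µV) | jitter | classes |
|--------------|-----------|--------------------|----------------|--------|---------|
| patterned    | 2.0       | periodic 2 Hz × 25 spikes @ 8 ms, 0.02 s onset jitter | 60 | 2% | RS, FS |
| intermediate | 1.5       | periodic 1.2 Hz × 20 @ 9 ms, 0.1 s jitter | 50 | 15% | RS, FS, TS, PS |
| irregular    | 0.8       | Poisson 0.05 Hz × 4 @ 15 ms | 40 | 35% | all five |

The patterned preset's dense periodic bursting is deliberate: with
M = 5, τ = 100 at 1 kHz an embedding vector spans 0.4 s, so bursts must
recur on that time scale for patterning to register after the 40 Hz
low-pass (sparse bursting, however stereotyped, leaves most embedding
vectors on noise and H_S ≈ 1).  The intra-burst rates (~100–125 Hz) and
network-burst structure are within the range of strongly synchronized
dissociated cultures, though the patterned preset sits at the rhythmic
extreme.  What the generator does **not** model: biophysical membrane
dynamics, electrode geometry or spike propagation, correlated noise
across channels, slow local-field potentials beyond the burst envelope,
electrode drift, or overlapping units per electrode.  Passing tests
therefore demonstrate that the analysis stages recover known structure
of this generative family — not that they characterize real cultures.

## Numerical choices and degenerate inputs

* Window arithmetic: seconds, float, half-open [start, end); sample
  indices 0-based; `slice_window` takes exactly round((end−start)·rate)
  samples.
* A single global seed is fanned out to every stochastic stage through
  SHA-256 stage-name-keyed substreams (< 2³¹), so any stage can be
  reproduced in isolation.
* Ordinal patterns: the tie rule makes the symbol map total, so exact
  ties (quantized data) are handled deterministically; probabilities
  sum to 1 by construction.
* Burst detection with < 2 pooled ISIs, or a single-bin histogram,
  returns an empty burst set with a warning rather than an error.
* Flat waveforms and constant channels raise degenerate-input errors;
  constant prediction segments are flagged with NaN scores.
* Boundary spikes are counted and skipped during cutout extraction.

## Problem sizes used by tests and the acceptance script

The surrogate stage runs at full scale (60 channels × 49 surrogates on
the 100 s, 1 kHz window — 2940 series), generated channel-by-channel to
bound memory.  Condition-ordering checks use 3 channels × 120 s per
preset with a 100 s analysis window (10–110 s; window position is
immaterial for stationary synthetic data), and the predictability
comparison uses 60 s segments with 25-tree forests — orderings are
insensitive to forest size, and these sizes keep a full run on one CPU
in minutes.  Spike-recovery checks use 3 channels × 30 s at SNR 8;
classifier accuracy uses 150 cutouts per seed across 10 seeds.

## Known limitations

* The CMA α₁ skewness map and the waveform decision-tree thresholds are
  configurable defaults, not fitted constants.
* The KS p-value is asymptotic; below ~20 samples per side an exact
  method would be preferable.
* iAAFT surrogates preserve linear structure; for strongly periodic
  signals the surrogate complexity distribution can sit close to the
  original's, and discriminating them needs enough channels (the KS
  comparison pools 60 originals against 2940 surrogates).
* The waveform stage classifies cluster averages; overlapping spikes
  and multi-unit electrodes are out of scope.
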