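# Methods

## Standardization model

A PSG record is a set of named channels (EEG/EOG voltage series,
microvolts) plus a hypnogram with one stage label per 30-second epoch.
Standardization is a template-method recipe: the step order is fixed
(list → read → map channels → filter → scale → clip → resample → map
labels → persist), and a cohort adapter overrides only discovery,
reading and the two translation tables. The assumption behind the fixed
order is that cohort heterogeneity lives entirely in naming, rates and
vocabularies — not in the physics of the signal — so every numeric step
can be shared.

Signal/label coverage mismatches are resolved by truncating both to the
shorter coverage in whole epochs (a recording that outran its scoring,
or vice versa, is cut, never padded): padding would fabricate either
signal or labels.

### Scaling and clipping

Per record and per channel: `x' = (x − mean(x)) / IQR(x)`. The IQR is
used instead of the standard deviation because overnight recordings
routinely contain electrode pops and movement artifacts that dominate a
variance estimate but barely move the quartiles. Quartiles use linear
interpolation between order statistics (the common "type 7"
convention, numpy's default); IQR is convention-sensitive, so the
convention is pinned and cross-checked against a brute-force
sort-and-interpolate oracle in the tests.

Scaling statistics are computed per record and per channel — the same
basis as clipping — so a noisy night or electrode cannot contaminate
another's normalization.

Clipping then saturates samples at ±`clip_multiplier` (default 20) in
post-scaling units. Since scaling has just forced IQR = 1, the bound
"20 × IQR" is implemented as the constant ±20 rather than re-estimating
the IQR; this also keeps degenerate channels (below) from being zeroed
by a literal 20 × 0 bound. Clipping is symmetric about 0, the center of
the scaled signal. Order: clip before resample, following the recipe's
row order; a consequence is that resampling can in principle ring
slightly around clipped plateaus, which is negligible for the isolated
single-sample artifacts clipping targets.

Degenerate channels: if IQR < `iqr_epsilon` (1e−8) — a flatlined
electrode — the channel is centered only, flagged in the record
metadata, and a warning is logged.

### Filtering and resampling

Band-pass filtering is optional and off by default: a zero-phase
(forward–backward) Butterworth, order 2 per pass, so stage boundaries
stay aligned with the signal (no group delay). Cut-offs are
user-defined; (0.3, 35) Hz is a typical choice for removing drift and
high-frequency noise.

Resampling to the common 128 Hz uses polyphase rational-ratio
resampling (`scipy.signal.resample_poly`) with its built-in
anti-aliasing low-pass; the rational ratio gives exact output-length
control (`round(n·target/fs)`) and avoids the spectral leakage of
FFT-length padding. 128 Hz retains the whole sleep-relevant EEG band
(≤ 35 Hz and margin) while keeping stored data small.

### Labels

Stage vocabularies are mapped by total lookup tables into the AASM
codes 0–4 with sentinel −1 for movement/unknown epochs. Contiguous
non-negative codes suit loss functions directly; the sentinel is
excluded from metrics. Totality is enforced: an unknown token raises an
error naming the token and record, because silently mapping it to the
sentinel would hide scoring-file corruption. Bundled vocabularies:
AASM words, R&K (S3 and S4 both fold into N3, MT → sentinel), and bare
integers. Mastoid references are normalized to A1/A2 (M1/M2 accepted
as aliases); both 10-10 and extended 10-5 site names are accepted,
validated against the standard montage's name list.

## Data store

One HDF5 file per dataset, groups `/<subject>/<session>`, channel
arrays as 32-bit floats under `psg/<name>`, hypnogram as 8-bit
integers, sample rate as a session attribute. Float32 halves storage
with quantization far below the 16-bit resolution of the source EDFs.
Chunk length is one epoch's samples, so an epoch-aligned window read
touches only its own chunks — the lazy-loading contract that keeps
training memory proportional to batch size, not store size (asserted
with tracemalloc in the tests). No compression by default: read speed
is the priority for a training-time data source. Session replacement is
delete-then-write within the file; no versioning. Epoch indexing is
0-based and half-open everywhere.

## Serving

**Splits** are subject-level: with several nights per subject, a
record-level split would leak within-subject autocorrelation across
partitions. Validation and test each take the number of subjects
closest to their fraction (default 15% each) per dataset, via a seeded
shuffle; hold-out datasets go wholly to a separate partition. Datasets
with fewer than 3 subjects are rejected (three partitions cannot be
formed).

**Random sampler**: dataset uniform, then session uniform, then start
epoch uniform over the eligible range — so small cohorts are sampled as
often as large ones; per-dataset weights are a config hook. Windows
whose labels are entirely the sentinel are excluded from eligible
starts (nothing to learn from); mixed windows are served, loss masking
being the consumer's concern. Default window: 35 epochs, matching the
sequence-input scale of current sleep stagers; configurable.

**Deterministic iterator**: consecutive non-overlapping windows per
session; tails that do not fill a window are dropped, not padded, so
coverage counts stay exact.

**Pipes and augmenters**: batches flow through a left-to-right pipe
composition; each stage's output is re-validated and violations are
reported by stage name. Stock augmenters are illustrative
implementations of the two interface families — global (additive
Gaussian noise, amplitude scaling, applied to whole selected windows)
and regional (contiguous segment zero-masking, length =
⌊fraction·samples⌋) — selected per window with a configured
probability; labels are never modified.

**Spectrograms**: signals are resampled to 100 Hz (the native rate of
typical spectrogram-input stagers), each 30-s epoch transformed with a
2-s Hamming taper in 1-s hops, FFT length the next power of two above
the taper (256), output `log(magnitude + ε)` with ε = 1e−8. This gives
29 frames × 129 bins per epoch; multi-epoch windows concatenate frames
epoch-major, keeping the window × channel × frame × bin layout.

## Evaluation

Confusion counts over the five stages, dropping epoch pairs where
either side is the sentinel (they have no AASM stage to agree on).
Cohen's κ = (p_o − p_e)/(1 − p_e); undefined (signalled explicitly)
when both raters are constant and equal. F1 is macro (unweighted) by
default, matching per-dataset comparison practice; stages absent from
both sides are excluded from the mean rather than counted as zeros;
weighted F1 is an option. Per-record export (record id, κ, per-class
F1, macro F1) as CSV.

## Synthetic cohorts

The generator emulates a source cohort on disk: per-session EDF files
(written by a minimal built-in EDF writer) plus plain-text hypnogram
sidecars, one token per line, in a configurable vocabulary — the
simplest adapter-facing format, keeping embedded-annotation parsing an
optional extra. Signals are `offset + A·sin(2πft) + N(0, σ²)` with
optional single-sample spike artifacts; defaults (two EEG channels at
256 Hz, 10/8 Hz, 50 µV amplitude, 10 µV noise; two EOG channels at
128 Hz, 0.5 Hz, 80 µV) give realistic amplitude scales and exercise
mixed sample rates. Hypnograms are first-order Markov chains over the
five stages with sticky self-transitions (diagonal ≈ 0.8), giving
realistic bout lengths; the default cohort is 3 subjects × 2 nights of
50–70 epochs. Ground truth (true stages, channel parameters) is
persisted to a separate JSON so tests never look through the pipeline
under test.

What the generator does **not** emulate: physiological stage
signatures (stages are labels, not signal regimes), real artifact
morphology, montage drift, or scorer disagreement. Passing tests
therefore demonstrate the pipeline's bookkeeping, numerics and
contracts — not staging performance on real data.

## Numerical and testing choices

Problem sizes in the test suite are chosen to keep the full run in
tens of seconds while leaving comfortable statistical margins: cohorts
of 6 sessions × 20–30 epochs, 10⁵ draws for sampler uniformity
(chi-square p > 0.01 over 66 outcomes; two-dataset balance within
±1%), 10⁴ epochs for the κ-of-independent-labels check (|κ| < 0.05),
1000 random vectors (lengths 5–10⁴) for the quartile oracle (max
deviation < 1e−9). The file-format benchmark measures single-channel
extraction with `tracemalloc` (plus the Arrow allocator pool for
Parquet); it reports raw numbers only, since absolute timings are
machine-specific.

Known limitations: EDF writing supports integer sample rates and
whole-second durations (sufficient for whole 30-s epochs); the EDF
reader (mne) homogenizes mixed per-channel rates to the highest rate at
read time, with originals recorded in metadata — immaterial after the
common resampling step; non-head modalities (ECG, EMG, temperature,
events) are out of scope, as is any training code.
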