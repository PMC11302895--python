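# somnopipe

A standardization and serving pipeline for heterogeneous polysomnography
(PSG) cohorts, aimed at researchers who train sleep-staging models on
data pooled from many sleep clinics.

Open sleep cohorts disagree on almost everything: channel names ("EEG
C3-A2", "LOC-M2"), sample rates, amplitude conventions, and stage
vocabularies (AASM words, R&K's S1–S4, numeric codes). somnopipe
converts each cohort once into a single **common data store** and then
serves training windows from it lazily.

## The standardized format

Every cohort passes through the same fixed nine-step recipe; only file
discovery, reading and the translation tables vary per cohort (supplied
by a small *adapter*):

1. list records → 2. read PSG → 3. map channels → 4. band-pass filter
(optional) → 5. scale → 6. clip → 7. resample → 8. map labels →
9. persist.

For each record and channel `x`, scaling is the robust normalization

```
x' = (x − mean(x)) / IQR(x),        IQR = Q3 − Q1
```

so every channel has zero mean and unit interquartile range; outliers
are then clipped to `|x'| ≤ 20` (20 × the post-scaling IQR), and the
signal is resampled to a common 128 Hz. Channel names are mapped onto
the 10-10/10-5 electrode grammar `SITE[-REFSITE]` (EOG as E1/E2,
mastoids as A1/A2), and stage labels onto the AASM codes
W=0, N1=1, N2=2, N3=3, REM=4 (−1 for unscorable epochs, one label per
30-s epoch).

The store is one HDF5 file per dataset with the hierarchy
`/<subject>/<session>/psg/<channel>` + `/<subject>/<session>/hypnogram`,
chunked at one epoch per chunk so window reads touch only the bytes
they need. On top of it sit subject-level train/val/test splits (15% /
15% by default), a two-stage random window sampler (dataset-uniform,
then session-uniform) and a deterministic exhaustive iterator,
composable batch pipes, global/regional augmenters, and per-epoch
log-magnitude spectrogram conversion (29 frames × 129 bins per 30-s
epoch at the defaults) for spectrogram-input models. Evaluation helpers
compute per-record Cohen's κ and per-dataset macro F1.

## Worked example

Generate a small synthetic source cohort (3 subjects × 2 nights, EDF
signals + R&K-vocabulary hypnogram sidecars, known ground truth), port
it, and draw a batch:

```python
from pathlib import Path
from somnopipe.synthetic import SyntheticDatasetSpec, generate_dataset

spec = SyntheticDatasetSpec(dataset_id="demo-cohort", vocabulary_id="rk", seed=3)
generate_dataset(spec, Path("raw"))
```

then, with a YAML config declaring the adapter (channel map + label
vocabulary), cohort root and store path:

```
$ somnopipe port cohort.yaml
dataset demo-cohort: 6 ported, 0 skipped of 6 listed

$ somnopipe inspect store
dataset demo-cohort: subjects: 3, sessions: 6, epochs: 360, channels: C3-A2, C4-A1, E1, E2

$ somnopipe sample store --window-epochs 20 --n-windows 2 --channels C3-A2,E1 \
      --val-fraction 0 --test-fraction 0
batch: 2 windows x 2 channels x 76800 samples @ 128 Hz
  demo-cohort/sub-02/ses-02 epochs [8, 28)
  demo-cohort/sub-01/ses-01 epochs [0, 20)
```

All 6 sessions were standardized and stored; the batch holds 2 windows
of 20 epochs (20 × 30 s × 128 Hz = 76 800 samples per channel), each
traced back to its session and epoch range. Because the generator's
ground truth is persisted separately, the test suite verifies that the
stages read back from the store equal the generated hypnograms exactly.

A file-format benchmark (`somnopipe benchmark`) reproduces the
single-channel-extraction measurement used to choose HDF5 over Parquet
and Pickle, reporting file size, mean ± sd load time and mean peak
memory per format; absolute numbers are machine-specific and the
harness deliberately ranks nothing.

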