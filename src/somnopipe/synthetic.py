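"""Synthetic source cohorts with known ground truth.

Real PSG cohorts are large, access-restricted downloads; every pipeline
stage here is instead exercised on generated cohorts that mimic a source
layout: per-session EDF signal files plus plain-text hypnogram sidecars
(one stage token per line), in a configurable source vocabulary (AASM
words, R&K words, or numeric codes).

Signals are band-limited surrogates, not physiological EEG: per channel,
``offset + amplitude * sin(2*pi*f*t) + N(0, noise_sd)`` in microvolts,
optionally spiked with large transient artifacts to exercise outlier
clipping.  Hypnograms are first-order Markov chains over the five AASM
stages, with a default transition matrix whose strong self-transitions
give realistic stage bout lengths (stages are labels only — the signal
does not change with the stage).

Ground truth (true AASM stages, channel parameters) is written to a
separate JSON file so tests never have to look through the pipeline
under test to know the right answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._edf import write_edf
from .adapters import EDFSidecarAdapter, builtin_label_map, vocabulary_tokens
from .records import EPOCH_SECONDS, ChannelMap

GROUND_TRUTH_FILE = "ground_truth.json"


@dataclass(frozen=True)
class ChannelSpec:
    """Parameters of one generated channel (all amplitudes in microvolts)."""

    label: str
    canonical: str
    modality: str
    sample_rate: int = 256
    sinusoid_hz: float = 10.0
    amplitude: float = 50.0
    offset: float = 0.0
    noise_sd: float = 10.0
    spike_prob: float = 0.0  # per epoch
    spike_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.amplitude <= 0 or self.noise_sd < 0:
            raise ValueError("rates and amplitudes must be positive")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must be in [0, 1]")


# default transition matrix over (W, N1, N2, N3, REM): sticky stages with
# the usual descent W -> N1 -> N2 -> {N3, REM} and occasional awakenings
DEFAULT_TRANSITIONS = np.array(
    [
        [0.80, 0.15, 0.03, 0.01, 0.01],
        [0.10, 0.50, 0.35, 0.02, 0.03],
        [0.03, 0.05, 0.80, 0.08, 0.04],
        [0.02, 0.01, 0.12, 0.80, 0.05],
        [0.05, 0.05, 0.10, 0.01, 0.79],
    ]
)

DEFAULT_CHANNELS = (
    ChannelSpec(label="EEG C3-A2", canonical="C3-A2", modality="EEG", sample_rate=256),
    ChannelSpec(label="EEG C4-A1", canonical="C4-A1", modality="EEG", sample_rate=256, sinusoid_hz=8.0),
    ChannelSpec(label="LOC", canonical="E1", modality="EOG", sample_rate=128, sinusoid_hz=0.5, amplitude=80.0),
    ChannelSpec(label="ROC", canonical="E2", modality="EOG", sample_rate=128, sinusoid_hz=0.5, amplitude=80.0),
)


@dataclass
class SyntheticDatasetSpec:
    """Everything needed to generate one reproducible source cohort."""

    dataset_id: str = "synthetic-cohort"
    n_subjects: int = 3
    sessions_per_subject: int = 2
    epochs_per_session: tuple[int, int] = (50, 70)  # inclusive range
    channels: tuple[ChannelSpec, ...] = DEFAULT_CHANNELS
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_stage: int = 0
    vocabulary_id: str = "aasm"
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (5, 5) or (t < 0).any():
            raise ValueError("transition matrix must be 5x5 non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.transitions = t
        lo, hi = self.epochs_per_session
        if not 1 <= lo <= hi:
            raise ValueError("epochs_per_session range invalid")

    def channel_map(self) -> ChannelMap:
        return ChannelMap(
            {c.label: (c.canonical, c.modality) for c in self.channels},
            drop_unmapped=True,
        )

    def adapter(self) -> EDFSidecarAdapter:
        return EDFSidecarAdapter(
            self.dataset_id, self.channel_map(), builtin_label_map(self.vocabulary_id)
        )


def generate_hypnogram(
    transitions: np.ndarray,
    n_epochs: int,
    rng: np.random.Generator,
    initial_stage: int = 0,
) -> np.ndarray:
    """Realize a first-order Markov chain of AASM stage codes (0-4)."""
    t = np.asarray(transitions, dtype=float)
    if t.shape != (5, 5) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be 5x5 row-stochastic")
    stages = np.empty(n_epochs, dtype=np.int8)
    state = initial_stage
    for i in range(n_epochs):
        stages[i] = state
        state = int(rng.choice(5, p=t[state]))
    return stages


def stages_to_tokens(
    stages: Sequence[int], vocabulary_id: str, rng: np.random.Generator
) -> list[str]:
    """Emit stage codes as source-vocabulary tokens.

    When a stage has several tokens (R&K's S3/S4 both mean N3), one is
    chosen at random so the whole vocabulary gets exercised.
    """
    inv = vocabulary_tokens(vocabulary_id)
    out = []
    for s in stages:
        tokens = inv[int(s)]
        out.append(tokens[int(rng.integers(len(tokens)))] if len(tokens) > 1 else tokens[0])
    return out


def synthesize_channel(
    spec: ChannelSpec, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """One channel's samples: sinusoid + offset + Gaussian noise + spikes."""
    n = n_epochs * EPOCH_SECONDS * spec.sample_rate
    t = np.arange(n) / spec.sample_rate
    x = spec.offset + spec.amplitude * np.sin(2 * np.pi * spec.sinusoid_hz * t)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.spike_prob > 0 and spec.spike_amplitude != 0:
        spiky = rng.random(n_epochs) < spec.spike_prob
        for e in np.flatnonzero(spiky):
            pos = e * EPOCH_SECONDS * spec.sample_rate + int(
                rng.integers(EPOCH_SECONDS * spec.sample_rate)
            )
            x[pos] += spec.spike_amplitude * (1 if rng.random() < 0.5 else -1)
    return x


def generate_session(
    spec: SyntheticDatasetSpec,
    subject_id: str,
    session_id: str,
    out_dir: Path,
    rng: np.random.Generator,
    n_epochs: Optional[int] = None,
) -> dict:
    """Write one session (EDF + sidecar) and return its ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if n_epochs is None:
        lo, hi = spec.epochs_per_session
        n_epochs = int(rng.integers(lo, hi + 1))
    stages = generate_hypnogram(spec.transitions, n_epochs, rng, spec.initial_stage)
    tokens = stages_to_tokens(stages, spec.vocabulary_id, rng)
    channels = [
        (c.label, synthesize_channel(c, n_epochs, rng), c.sample_rate)
        for c in spec.channels
    ]
    write_edf(out_dir / "psg.edf", channels, recording_id=f"{subject_id}/{session_id}")
    (out_dir / "hypnogram.txt").write_text("\n".join(tokens) + "\n")
    return {
        "subject_id": subject_id,
        "session_id": session_id,
        "n_epochs": n_epochs,
        "stages": [int(s) for s in stages],
        "tokens": tokens,
    }


def generate_dataset(
    spec: SyntheticDatasetSpec, root: Path, overwrite: bool = False
) -> dict:
    """Write the full cohort tree and its ground-truth JSON.

    Layout: ``root/<dataset_id>/<subject>/<session>/{psg.edf, hypnogram.txt}``
    plus ``ground_truth.json`` at the dataset root.  Reproducible: the
    same spec (incl. seed) yields byte-identical sidecars.
    """
    root = Path(root)
    dataset_dir = root / spec.dataset_id
    if dataset_dir.exists() and any(dataset_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{dataset_dir} exists and is not empty (pass overwrite=True)"
        )
    rng = np.random.default_rng(spec.seed)
    truth: dict = {
        "dataset_id": spec.dataset_id,
        "vocabulary_id": spec.vocabulary_id,
        "seed": spec.seed,
        "channels": [asdict(c) for c in spec.channels],
        "sessions": [],
    }
    for s in range(1, spec.n_subjects + 1):
        subject_id = f"sub-{s:02d}"
        for n in range(1, spec.sessions_per_subject + 1):
            session_id = f"ses-{n:02d}"
            info = generate_session(
                spec, subject_id, session_id, dataset_dir / subject_id / session_id, rng
            )
            truth["sessions"].append(info)
    (dataset_dir / GROUND_TRUTH_FILE).write_text(json.dumps(truth, indent=2))
    return truth


def load_ground_truth(root: Path, dataset_id: str) -> dict:
    return json.loads((Path(root) / dataset_id / GROUND_TRUTH_FILE).read_text())
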