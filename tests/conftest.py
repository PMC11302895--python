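"""Shared fixtures: small generated cohorts ported into temporary stores.

Cohort generation + porting dominates test time (EDF I/O), so the two
cohorts (AASM- and R&K-vocabulary) and their stores are built once per
session and treated as read-only by every test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from somnopipe.records import PreprocessConfig
from somnopipe.standardize import PortReport, port_dataset
from somnopipe.synthetic import (
    ChannelSpec,
    SyntheticDatasetSpec,
    generate_dataset,
)


@dataclass
class PortedCohort:
    spec: SyntheticDatasetSpec
    truth: dict
    raw_root: Path
    store_dir: Path
    report: PortReport
    cfg: PreprocessConfig


def _build(tmp_root: Path, spec: SyntheticDatasetSpec, cfg: PreprocessConfig) -> PortedCohort:
    raw_root = tmp_root / "raw"
    truth = generate_dataset(spec, raw_root)
    store_dir = tmp_root / "store"
    report = port_dataset(raw_root / spec.dataset_id, spec.adapter(), cfg, store_dir)
    assert report.ported == len(truth["sessions"]), report.summary()
    return PortedCohort(spec, truth, raw_root, store_dir, report, cfg)


@pytest.fixture(scope="session")
def aasm_cohort(tmp_path_factory) -> PortedCohort:
    """3 subjects x 2 sessions, AASM word vocabulary, default preprocessing."""
    spec = SyntheticDatasetSpec(
        dataset_id="synth-aasm",
        epochs_per_session=(20, 30),
        vocabulary_id="aasm",
        seed=7,
    )
    return _build(tmp_path_factory.mktemp("aasm"), spec, PreprocessConfig())


@pytest.fixture(scope="session")
def rk_cohort(tmp_path_factory) -> PortedCohort:
    """R&K vocabulary cohort with spike artifacts on one EEG channel."""
    channels = (
        ChannelSpec(
            label="EEG C3-A2",
            canonical="C3-A2",
            modality="EEG",
            sample_rate=256,
            spike_prob=0.2,
            spike_amplitude=2000.0,
        ),
        ChannelSpec(label="LOC", canonical="E1", modality="EOG", sample_rate=128,
                    sinusoid_hz=0.5, amplitude=80.0),
    )
    spec = SyntheticDatasetSpec(
        dataset_id="synth-rk",
        epochs_per_session=(20, 30),
        channels=channels,
        vocabulary_id="rk",
        seed=11,
    )
    return _build(tmp_path_factory.mktemp("rk"), spec, PreprocessConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
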