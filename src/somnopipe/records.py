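"""Core domain types for polysomnography (PSG) standardization.

A night of sleep data is represented as a :class:`PSGRecord`: a set of
named channels (EEG/EOG time series in microvolts) plus a hypnogram — one
sleep-stage label per 30-second scoring epoch.  Cohorts in the wild label
both channels and stages in their own vocabularies; :class:`ChannelMap`
and :class:`LabelMap` carry the per-cohort translations into the canonical
scheme used throughout the pipeline:

* channel names follow the 10-10 / 10-5 scalp-electrode grammar
  ``SITE`` or ``SITE-REFSITE`` (e.g. ``C3-A2``), with ``E1``/``E2`` for
  the two EOG electrodes and mastoids spelled ``A1``/``A2`` (``M1``/``M2``
  are accepted as aliases and normalized);
* sleep stages use the AASM integer coding of :class:`StageCode`.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

EPOCH_SECONDS = 30
"""Length of one sleep-scoring epoch in seconds."""


class StageCode(IntEnum):
    """AASM sleep-stage codes, plus a sentinel for unscorable epochs.

    The sentinel ``UNSCORED`` (-1) covers movement time, unknown and
    otherwise unscorable epochs; it is excluded from evaluation metrics.
    """

    UNSCORED = -1
    WAKE = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


STAGE_VALUES = frozenset(int(s) for s in StageCode)


class Modality(str):
    pass


EEG = "EEG"
EOG = "EOG"

_EXTRA_SITES = frozenset({"A1", "A2", "M1", "M2", "E1", "E2"})


@functools.lru_cache(maxsize=1)
def canonical_sites() -> frozenset[str]:
    """Return the set of acceptable electrode site names.

    The 10-5 ("5 percent") site list is taken from mne's standard montage
    and extended with mastoid and EOG names.  Imported lazily: mne is a
    heavy import and only needed once.
    """
    from mne.channels import make_standard_montage

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        names = make_standard_montage("standard_1005").ch_names
    return frozenset(names) | _EXTRA_SITES


_MASTOID_ALIASES = {"M1": "A1", "M2": "A2"}


def normalize_canonical_name(name: str) -> str:
    """Validate ``name`` against the SITE[-REFSITE] grammar and normalize.

    Mastoid aliases M1/M2 are rewritten to A1/A2.  Raises ``ValueError``
    for names whose sites are not 10-5 / EOG site names.
    """
    parts = name.split("-")
    if not 1 <= len(parts) <= 2 or any(not p for p in parts):
        raise ValueError(f"channel name {name!r} does not match SITE[-REFSITE]")
    sites = canonical_sites()
    norm = []
    for part in parts:
        part = _MASTOID_ALIASES.get(part, part)
        if part not in sites:
            raise ValueError(f"{part!r} (in {name!r}) is not a 10-5/EOG site name")
        norm.append(part)
    return "-".join(norm)


@dataclass(frozen=True)
class RecordRef:
    """Reference to one session's files on disk, before any reading."""

    dataset_id: str
    subject_id: str
    session_id: str
    signal_paths: tuple[Path, ...]
    annotation_paths: tuple[Path, ...]

    def __post_init__(self) -> None:
        if not (self.dataset_id and self.subject_id and self.session_id):
            raise ValueError("dataset/subject/session ids must be non-empty")
        if not self.signal_paths:
            raise ValueError(f"{self.subject_id}/{self.session_id}: no signal paths")


@dataclass
class Channel:
    """One channel's samples (microvolts) and its sample rate in Hz."""

    signal: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("channel signal must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.signal) / self.sample_rate


@dataclass
class PSGRecord:
    """One night's multi-channel signals plus hypnogram and metadata.

    ``hypnogram`` is ``None`` until labels have been mapped into AASM
    codes; before that the raw source tokens live in
    ``meta['source_labels']``.
    """

    dataset_id: str
    subject_id: str
    session_id: str
    channels: dict[str, Channel]
    hypnogram: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypnogram is not None:
            self.hypnogram = np.asarray(self.hypnogram, dtype=np.int8)

    @property
    def n_epochs(self) -> int:
        if self.hypnogram is not None:
            return len(self.hypnogram)
        labels = self.meta.get("source_labels")
        return len(labels) if labels is not None else 0

    def validate_standardized(self, expected_rate: float) -> None:
        """Check the invariants required before persisting to a store."""
        if not self.channels:
            raise ValueError("record has no channels")
        if self.hypnogram is None:
            raise ValueError("record has no mapped hypnogram")
        bad = set(np.unique(self.hypnogram)) - STAGE_VALUES
        if bad:
            raise ValueError(f"hypnogram contains non-AASM codes {sorted(bad)}")
        n = len(self.hypnogram) * EPOCH_SECONDS * expected_rate
        for name, ch in self.channels.items():
            normalize_canonical_name(name)
            if ch.sample_rate != expected_rate:
                raise ValueError(
                    f"channel {name}: rate {ch.sample_rate} != {expected_rate}"
                )
            if len(ch.signal) != int(round(n)):
                raise ValueError(
                    f"channel {name}: length {len(ch.signal)} != {int(round(n))} "
                    "(hypnogram epochs x 30 s x rate)"
                )


@dataclass(frozen=True)
class ChannelMapEntry:
    canonical: str
    modality: str  # EEG or EOG


class ChannelMap:
    """Translation from a cohort's channel labels to canonical names."""

    def __init__(
        self,
        entries: Mapping[str, tuple[str, str]],
        drop_unmapped: bool = True,
    ) -> None:
        self.entries: dict[str, ChannelMapEntry] = {}
        seen_targets: dict[str, str] = {}
        for source, (canonical, modality) in entries.items():
            canonical = normalize_canonical_name(canonical)
            if modality not in (EEG, EOG):
                raise ValueError(f"modality must be EEG or EOG, got {modality!r}")
            self.entries[source] = ChannelMapEntry(canonical, modality)
            seen_targets.setdefault(canonical, source)
        self.drop_unmapped = drop_unmapped

    def __contains__(self, source: str) -> bool:
        return source in self.entries

    def __getitem__(self, source: str) -> ChannelMapEntry:
        return self.entries[source]


class LabelMap:
    """Translation from a cohort's stage tokens to AASM codes.

    The map is total over its declared vocabulary: any token outside it is
    an error, surfaced with the offending token's name.
    """

    def __init__(self, entries: Mapping[str, int], vocabulary_id: str) -> None:
        self.entries = {}
        for token, code in entries.items():
            code = int(code)
            if code not in STAGE_VALUES:
                raise ValueError(f"{token!r} maps to invalid stage code {code}")
            self.entries[str(token)] = code
        self.vocabulary_id = vocabulary_id

    def map_token(self, token: str, context: str = "") -> int:
        try:
            return self.entries[str(token)]
        except KeyError:
            where = f" in {context}" if context else ""
            raise KeyError(
                f"label {token!r}{where} is outside vocabulary "
                f"{self.vocabulary_id!r}"
            ) from None


AASM_IDENTITY_LABELS = LabelMap(
    {"-1": -1, "0": 0, "1": 1, "2": 2, "3": 3, "4": 4}, vocabulary_id="aasm-int"
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the standardization chain.

    target_sample_rate
        Common output rate, Hz.  128 Hz by default: high enough for the
        sleep-relevant EEG band, small enough for fast training-time reads.
    clip_multiplier
        Outlier clipping bound in multiples of the post-scaling IQR
        (which is 1), applied symmetrically about zero.
    bandpass
        Optional ``(low, high)`` cut-off frequencies in Hz; ``None``
        disables filtering.
    iqr_epsilon
        Channels whose IQR falls below this are treated as degenerate:
        centered only, never divided.
    include_channels
        Optional whitelist of canonical names to retain; everything else
        is discarded to keep the store small.
    """

    target_sample_rate: float = 128.0
    clip_multiplier: float = 20.0
    bandpass: Optional[tuple[float, float]] = None
    iqr_epsilon: float = 1e-8
    include_channels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.target_sample_rate <= 0:
            raise ValueError("target_sample_rate must be positive")
        if self.clip_multiplier <= 0:
            raise ValueError("clip_multiplier must be positive")
        if self.bandpass is not None:
            low, high = self.bandpass
            if not 0 < low < high:
                raise ValueError(f"invalid bandpass ({low}, {high})")
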