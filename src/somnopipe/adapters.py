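"""Per-cohort adapters: listing, reading and mapping logic.

The standardization recipe (see :mod:`somnopipe.standardize`) is fixed;
what varies between cohorts is how sessions are found on disk, how their
files are read, and the channel/label vocabularies.  A
:class:`CohortAdapter` bundles exactly those parts, so adding a cohort
whose layout matches an existing adapter requires only new maps —
typically just the channel map.

:class:`EDFSidecarAdapter` covers the common layout of one EDF per
session plus a plain-text hypnogram sidecar (one stage token per line),
which is also the layout the synthetic generator emits.  Adapters are
constructible from a YAML declaration via :func:`adapter_from_config`.
"""

from __future__ import annotations

import abc
import logging
from pathlib import Path

import numpy as np
import yaml

from .records import Channel, ChannelMap, LabelMap, PSGRecord, RecordRef

logger = logging.getLogger(__name__)


class CohortAdapter(abc.ABC):
    """Cohort-specific half of the standardization recipe.

    Subclasses supply file discovery (:meth:`list_records`), file reading
    (:meth:`read_psg`) and the two translation tables.  Everything else —
    filtering, scaling, clipping, resampling, label mapping, persistence —
    is shared and never reimplemented per cohort.
    """

    def __init__(self, dataset_id: str, channel_map: ChannelMap, label_map: LabelMap):
        self.dataset_id = dataset_id
        self.channel_map = channel_map
        self.label_map = label_map

    @abc.abstractmethod
    def list_records(self, dataset_root: Path) -> list[RecordRef]:
        """Enumerate all sessions under ``dataset_root``."""

    @abc.abstractmethod
    def read_psg(self, ref: RecordRef) -> PSGRecord:
        """Read one session's signals and raw labels."""


class EDFSidecarAdapter(CohortAdapter):
    """Adapter for ``root/<subject>/<session>/*.edf`` + text sidecar trees.

    The sidecar holds one stage token per line, one line per 30-s epoch,
    in the cohort's own vocabulary; tokens are mapped later by the label
    map.  A session directory with signals but no sidecar is skipped with
    a warning, mirroring how incomplete sessions appear in real cohorts.
    """

    SIDECAR_SUFFIXES = (".txt", ".csv", ".tsv")

    def list_records(self, dataset_root: Path) -> list[RecordRef]:
        dataset_root = Path(dataset_root)
        if not dataset_root.is_dir():
            raise FileNotFoundError(f"dataset root {dataset_root} does not exist")
        refs: list[RecordRef] = []
        for subject_dir in sorted(p for p in dataset_root.iterdir() if p.is_dir()):
            for session_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
                signals = sorted(session_dir.glob("*.edf"))
                sidecars = sorted(
                    p
                    for p in session_dir.iterdir()
                    if p.suffix.lower() in self.SIDECAR_SUFFIXES
                )
                if not signals:
                    continue
                if not sidecars:
                    logger.warning(
                        "skipping %s/%s: signals present but no annotation sidecar",
                        subject_dir.name,
                        session_dir.name,
                    )
                    continue
                refs.append(
                    RecordRef(
                        dataset_id=self.dataset_id,
                        subject_id=subject_dir.name,
                        session_id=session_dir.name,
                        signal_paths=tuple(signals),
                        annotation_paths=tuple(sidecars),
                    )
                )
        if not refs:
            logger.warning("no records found under %s", dataset_root)
        return refs

    @staticmethod
    def _native_rates(edf_path: Path) -> dict[str, float]:
        """Per-channel sample rates from the EDF header fields."""
        with open(edf_path, "rb") as fh:
            header = fh.read(256)
            ns = int(header[252:256])
            duration = float(header[244:252])
            per_signal = fh.read(256 * ns)
        labels = [
            per_signal[i * 16 : (i + 1) * 16].decode("ascii").strip() for i in range(ns)
        ]
        offset = ns * 216  # label/transducer/dim/phys+dig ranges/prefilter fields
        rates = {}
        for i, label in enumerate(labels):
            n_samp = int(per_signal[offset + i * 8 : offset + (i + 1) * 8])
            rates[label] = n_samp / duration
        return rates

    def read_psg(self, ref: RecordRef) -> PSGRecord:
        import mne

        raw = mne.io.read_raw_edf(ref.signal_paths[0], preload=True, verbose="error")
        # mne homogenizes mixed-rate EDFs at the highest rate; that uniform
        # rate becomes the working rate, originals are kept in meta.
        rate = float(raw.info["sfreq"])
        data = raw.get_data(units="uV")
        if data.shape[0] == 0:
            raise ValueError(f"{ref.signal_paths[0]}: no channels")
        channels = {
            name: Channel(signal=data[i], sample_rate=rate)
            for i, name in enumerate(raw.ch_names)
        }
        tokens = [
            line.strip()
            for line in ref.annotation_paths[0].read_text().splitlines()
            if line.strip()
        ]
        rec = PSGRecord(
            dataset_id=ref.dataset_id,
            subject_id=ref.subject_id,
            session_id=ref.session_id,
            channels=channels,
            meta={
                "source_labels": tokens,
                "source_channel_names": list(raw.ch_names),
                "source_sample_rate": rate,
                "source_native_rates": self._native_rates(ref.signal_paths[0]),
                "source_vocabulary": self.label_map.vocabulary_id,
            },
        )
        return rec


_VOCABULARIES: dict[str, dict[str, int]] = {
    # AASM words, the modern scoring scheme
    "aasm": {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4, "UNKNOWN": -1},
    # Rechtschaffen & Kales: S3 and S4 both fold into N3, MT (movement
    # time) has no AASM stage and maps to the sentinel
    "rk": {"W": 0, "S1": 1, "S2": 2, "S3": 3, "S4": 3, "REM": 4, "MT": -1},
    # bare integer codes as used by several open cohorts
    "numeric": {"0": 0, "1": 1, "2": 2, "3": 3, "4": 4, "-1": -1},
}


def builtin_label_map(vocabulary_id: str) -> LabelMap:
    """Label map for one of the bundled vocabularies (aasm, rk, numeric)."""
    try:
        entries = _VOCABULARIES[vocabulary_id]
    except KeyError:
        raise KeyError(
            f"unknown vocabulary {vocabulary_id!r}; "
            f"known: {sorted(_VOCABULARIES)}"
        ) from None
    return LabelMap(entries, vocabulary_id=vocabulary_id)


def vocabulary_tokens(vocabulary_id: str) -> dict[int, list[str]]:
    """Inverse view of a bundled vocabulary: stage code -> emitting tokens."""
    inv: dict[int, list[str]] = {}
    for token, code in _VOCABULARIES[vocabulary_id].items():
        inv.setdefault(code, []).append(token)
    return inv


def adapter_from_config(config: dict | str | Path) -> EDFSidecarAdapter:
    """Build an adapter from a YAML declaration (path, YAML text, or dict).

    Schema::

        dataset_id: my-cohort
        channel_map:
          "EEG C3-A2": {canonical: C3-A2, modality: EEG}
          "LOC-M2":    {canonical: E1-A2, modality: EOG}
        drop_unmapped: true
        labels:
          vocabulary: rk            # a bundled vocabulary name ...
          # ... or an explicit map:
          # entries: {Wake: 0, Stage1: 1, ...}
          # vocabulary_id: my-vocab
    """
    if isinstance(config, (str, Path)):
        p = Path(config)
        text = p.read_text() if p.exists() else str(config)
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError("adapter config must be a mapping")
    for key in ("dataset_id", "channel_map", "labels"):
        if key not in config:
            raise ValueError(f"adapter config is missing required field {key!r}")
    cmap_entries = {
        source: (entry["canonical"], entry["modality"])
        for source, entry in config["channel_map"].items()
    }
    channel_map = ChannelMap(cmap_entries, drop_unmapped=config.get("drop_unmapped", True))
    labels = config["labels"]
    if "vocabulary" in labels:
        label_map = builtin_label_map(labels["vocabulary"])
    else:
        label_map = LabelMap(labels["entries"], labels.get("vocabulary_id", "custom"))
    return EDFSidecarAdapter(config["dataset_id"], channel_map, label_map)
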