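"""The common data store: one HDF5 file per dataset, subject/session groups.

On-disk layout (paths are exact)::

    <store_dir>/<dataset_id>.hdf5
        /<subject_id>/<session_id>/psg/<channel>   float32, 1-D
        /<subject_id>/<session_id>/hypnogram       int8, 1-D
        session group attrs: sample_rate, plus source metadata strings

Channel datasets are chunked at one 30-s epoch per chunk, so a window
read touches only the chunks it overlaps — that is the whole point of
the store: during training, data is read lazily in window-sized slices
rather than whole nights or whole files.  No compression by default;
read speed is the priority for a training-time data source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

from .records import EPOCH_SECONDS, PSGRecord


def store_file(store_dir: Path, dataset_id: str) -> Path:
    return Path(store_dir) / f"{dataset_id}.hdf5"


def persist_record(store_dir: Path, rec: PSGRecord, expected_rate: float) -> None:
    """Step 9 of the recipe: write one standardized record into the store.

    The record is validated against the standardized-format invariants
    before any write.  Re-persisting a session deletes and rewrites its
    group, so the second content wins and re-runs are idempotent.
    """
    rec.validate_standardized(expected_rate)
    store_dir = Path(store_dir)
    store_dir.mkdir(parents=True, exist_ok=True)
    chunk = int(round(EPOCH_SECONDS * expected_rate))
    with h5py.File(store_file(store_dir, rec.dataset_id), "a") as f:
        subj = f.require_group(rec.subject_id)
        if rec.session_id in subj:
            del subj[rec.session_id]
        sess = subj.create_group(rec.session_id)
        sess.attrs["sample_rate"] = float(expected_rate)
        for key, value in rec.meta.items():
            try:
                sess.attrs[f"meta_{key}"] = json.dumps(value)
            except TypeError:
                sess.attrs[f"meta_{key}"] = str(value)
        psg = sess.create_group("psg")
        for name, ch in rec.channels.items():
            data = np.asarray(ch.signal, dtype=np.float32)
            psg.create_dataset(name, data=data, chunks=(min(chunk, len(data)),))
        sess.create_dataset("hypnogram", data=np.asarray(rec.hypnogram, dtype=np.int8))


@dataclass(frozen=True)
class SessionInfo:
    dataset_id: str
    subject_id: str
    session_id: str
    channels: tuple[str, ...]
    n_epochs: int
    sample_rate: float


@dataclass
class StoreManifest:
    """In-memory inventory of a store directory, rebuildable by a full scan."""

    sessions: list[SessionInfo] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def datasets(self) -> list[str]:
        return sorted({s.dataset_id for s in self.sessions})

    def subjects(self, dataset_id: str | None = None) -> list[tuple[str, str]]:
        return sorted(
            {
                (s.dataset_id, s.subject_id)
                for s in self.sessions
                if dataset_id is None or s.dataset_id == dataset_id
            }
        )

    def sessions_of(self, dataset_id: str, subject_id: str | None = None) -> list[SessionInfo]:
        return [
            s
            for s in self.sessions
            if s.dataset_id == dataset_id
            and (subject_id is None or s.subject_id == subject_id)
        ]

    def __len__(self) -> int:
        return len(self.sessions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "datasets": {
                    d: {
                        subj: {
                            s.session_id: {
                                "channels": list(s.channels),
                                "n_epochs": s.n_epochs,
                                "sample_rate": s.sample_rate,
                            }
                            for s in self.sessions_of(d, subj)
                        }
                        for _, subj in self.subjects(d)
                    }
                    for d in self.datasets
                },
                "errors": self.errors,
            },
            indent=2,
        )


def build_manifest(store_dir: Path) -> StoreManifest:
    """Scan every ``*.hdf5`` under ``store_dir`` into a manifest.

    Malformed session groups (e.g. missing hypnogram) are listed under
    ``manifest.errors`` rather than aborting the scan.
    """
    store_dir = Path(store_dir)
    manifest = StoreManifest()
    for path in sorted(store_dir.glob("*.hdf5")):
        dataset_id = path.stem
        with h5py.File(path, "r") as f:
            for subject_id in sorted(f.keys()):
                for session_id in sorted(f[subject_id].keys()):
                    sess = f[subject_id][session_id]
                    loc = f"{dataset_id}/{subject_id}/{session_id}"
                    if "hypnogram" not in sess or "psg" not in sess:
                        manifest.errors.append(f"{loc}: missing hypnogram or psg group")
                        continue
                    manifest.sessions.append(
                        SessionInfo(
                            dataset_id=dataset_id,
                            subject_id=subject_id,
                            session_id=session_id,
                            channels=tuple(sorted(sess["psg"].keys())),
                            n_epochs=int(sess["hypnogram"].shape[0]),
                            sample_rate=float(sess.attrs["sample_rate"]),
                        )
                    )
    return manifest


@dataclass(frozen=True)
class SampleWindow:
    """A half-open, epoch-aligned slice [start, start + num) of one session."""

    dataset_id: str
    subject_id: str
    session_id: str
    start_epoch: int
    num_epochs: int

    def __post_init__(self) -> None:
        if self.start_epoch < 0 or self.num_epochs < 0:
            raise ValueError("window indices must be non-negative")


def read_window(
    store_dir: Path,
    window: SampleWindow,
    channels: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Read one window's signals and labels, touching only its byte range.

    Returns ``(signals, labels)`` with ``signals`` of shape
    ``(len(channels), num_epochs * 30 * sample_rate)`` (float32) and
    ``labels`` of length ``num_epochs`` (int8).  Peak memory scales with
    the window, not the session: only the requested HDF5 chunks are read.
    """
    path = store_file(store_dir, window.dataset_id)
    with h5py.File(path, "r") as f:
        try:
            sess = f[window.subject_id][window.session_id]
        except KeyError:
            raise KeyError(
                f"no session {window.dataset_id}/{window.subject_id}/"
                f"{window.session_id} in store"
            ) from None
        n_epochs = int(sess["hypnogram"].shape[0])
        if window.start_epoch + window.num_epochs > n_epochs:
            raise IndexError(
                f"window [{window.start_epoch}, "
                f"{window.start_epoch + window.num_epochs}) exceeds session "
                f"length {n_epochs} epochs"
            )
        rate = float(sess.attrs["sample_rate"])
        spe = int(round(EPOCH_SECONDS * rate))
        lo, hi = window.start_epoch * spe, (window.start_epoch + window.num_epochs) * spe
        psg = sess["psg"]
        available = sorted(psg.keys())
        signals = np.empty((len(channels), hi - lo), dtype=np.float32)
        for i, name in enumerate(channels):
            if name not in psg:
                raise KeyError(
                    f"channel {name!r} not in session; available: {available}"
                )
            if hi > lo:
                psg[name].read_direct(signals, np.s_[lo:hi], np.s_[i, :])
        labels = sess["hypnogram"][
            window.start_epoch : window.start_epoch + window.num_epochs
        ].astype(np.int8)
    return signals, labels


def read_hypnogram(store_dir: Path, dataset_id: str, subject_id: str, session_id: str) -> np.ndarray:
    with h5py.File(store_file(store_dir, dataset_id), "r") as f:
        return f[subject_id][session_id]["hypnogram"][:].astype(np.int8)


def iter_sessions(manifest: StoreManifest) -> Iterator[SessionInfo]:
    yield from manifest.sessions
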