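"""The fixed standardization recipe that turns raw cohorts into canonical records.

Every cohort, however it is laid out on disk, passes through the same
ordered steps:

1. list records          — enumerate session files (adapter)
2. read PSG              — load signals + raw labels (adapter)
3. map channels          — rename into the 10-10/10-5 canonical grammar
4. filter channels       — optional zero-phase band-pass
5. scale channels        — robust normalization: zero mean, IQR = 1
6. clip channels         — saturate outliers at ±20 (in IQR units)
7. resample channels     — common 128 Hz rate
8. map labels            — translate stage tokens into AASM codes
9. persist               — write into the HDF5 common data store

Only steps 1-3 ever vary between cohorts, and they are delegated to the
:class:`~somnopipe.adapters.CohortAdapter`; steps 4-9 are shared.
:func:`port_dataset` is the recipe function executing the whole chain.

Robust scaling uses the interquartile range rather than the standard
deviation because overnight EEG routinely contains large transient
artifacts (electrode pops, movement) that would dominate a variance
estimate; quartiles are computed with linear interpolation between order
statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy import signal as sps

from .adapters import CohortAdapter
from .records import (
    EPOCH_SECONDS,
    Channel,
    ChannelMap,
    LabelMap,
    PreprocessConfig,
    PSGRecord,
    RecordRef,
)

logger = logging.getLogger(__name__)

#: canonical step order; port_dataset executes exactly this sequence
PIPELINE_STEPS = (
    "list_records",
    "read_psg",
    "map_channels",
    "filter_channels",
    "scale_channels",
    "clip_channels",
    "resample_channels",
    "map_labels",
    "persist_record",
)


def list_records(dataset_root: Path, adapter: CohortAdapter) -> list[RecordRef]:
    """Step 1: enumerate every session of the cohort, in deterministic order."""
    return adapter.list_records(Path(dataset_root))


def read_psg(ref: RecordRef, adapter: CohortAdapter) -> PSGRecord:
    """Step 2: read one session's signals and raw labels.

    Signal and label coverage are reconciled by truncating both to the
    shorter of the two, in whole 30-s epochs: a recording that ran past
    the last scored epoch (or a scoring sheet longer than the signal) is
    cut, never padded.
    """
    rec = adapter.read_psg(ref)
    if not rec.channels:
        raise ValueError(f"{ref.subject_id}/{ref.session_id}: no channels read")
    labels = rec.meta.get("source_labels", [])
    duration = min(ch.duration for ch in rec.channels.values())
    n_epochs = min(int(duration // EPOCH_SECONDS), len(labels))
    if n_epochs <= 0:
        raise ValueError(
            f"{ref.subject_id}/{ref.session_id}: no complete scored epoch "
            f"(signal {duration:.1f} s, {len(labels)} labels)"
        )
    for name, ch in rec.channels.items():
        want = int(round(n_epochs * EPOCH_SECONDS * ch.sample_rate))
        if len(ch.signal) != want:
            ch.signal = ch.signal[:want]
    if len(labels) != n_epochs:
        rec.meta["source_labels"] = labels[:n_epochs]
    return rec


def map_channels(rec: PSGRecord, cmap: ChannelMap) -> PSGRecord:
    """Step 3: rename channels canonically; drop or reject unmapped ones."""
    out: dict[str, Channel] = {}
    originals: dict[str, str] = {}
    for source, ch in rec.channels.items():
        if source not in cmap:
            if cmap.drop_unmapped:
                logger.info(
                    "%s/%s: dropping unmapped channel %r",
                    rec.subject_id,
                    rec.session_id,
                    source,
                )
                continue
            raise KeyError(
                f"{rec.subject_id}/{rec.session_id}: channel {source!r} "
                "has no mapping and drop_unmapped is off"
            )
        entry = cmap[source]
        if entry.canonical in out:
            raise ValueError(
                f"{rec.subject_id}/{rec.session_id}: channels "
                f"{originals[entry.canonical]!r} and {source!r} both map to "
                f"{entry.canonical!r}"
            )
        out[entry.canonical] = ch
        originals[entry.canonical] = source
    rec.channels = out
    rec.meta["original_channel_names"] = originals
    return rec


def filter_channels(rec: PSGRecord, cfg: PreprocessConfig) -> PSGRecord:
    """Step 4: optional zero-phase Butterworth band-pass (order 2 per pass).

    Identity when no band is configured.  Forward-backward filtering keeps
    stage boundaries aligned with the signal (no group delay).
    """
    if cfg.bandpass is None:
        return rec
    low, high = cfg.bandpass
    for name, ch in rec.channels.items():
        nyq = ch.sample_rate / 2
        if not 0 < low < high < nyq:
            raise ValueError(
                f"bandpass ({low}, {high}) Hz invalid for channel {name} "
                f"at {ch.sample_rate} Hz (Nyquist {nyq})"
            )
        sos = sps.butter(2, (low, high), btype="bandpass", fs=ch.sample_rate, output="sos")
        ch.signal = sps.sosfiltfilt(sos, ch.signal)
    return rec


def channel_iqr(x: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quartiles (type 7)."""
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def scale_channels(rec: PSGRecord, cfg: PreprocessConfig) -> PSGRecord:
    """Step 5: per record, per channel: subtract mean, divide by IQR.

    Degenerate channels (IQR below ``cfg.iqr_epsilon``, e.g. a flatlined
    electrode) are centered only and flagged, since dividing by ~0 would
    manufacture huge values out of noise.
    """
    for name, ch in rec.channels.items():
        x = ch.signal
        if x.size == 0:
            raise ValueError(f"channel {name} is empty")
        iqr = channel_iqr(x)
        centered = x - np.mean(x)
        if iqr < cfg.iqr_epsilon:
            logger.warning(
                "%s/%s channel %s: degenerate IQR (%g); centered only",
                rec.subject_id,
                rec.session_id,
                name,
                iqr,
            )
            rec.meta.setdefault("degenerate_channels", []).append(name)
            ch.signal = centered
        else:
            ch.signal = centered / iqr
    return rec


def clip_channels(rec: PSGRecord, cfg: PreprocessConfig) -> PSGRecord:
    """Step 6: saturate outliers at ±clip_multiplier (post-scale IQR units).

    Called after scaling, where each non-degenerate channel has IQR 1, so
    the bound is simply ±clip_multiplier; samples inside it are untouched.
    """
    b = cfg.clip_multiplier
    for ch in rec.channels.values():
        np.clip(ch.signal, -b, b, out=ch.signal)
    return rec


def resample_channels(rec: PSGRecord, cfg: PreprocessConfig) -> PSGRecord:
    """Step 7: bring every channel to the common target rate (128 Hz default).

    Polyphase rational-ratio resampling with its built-in anti-aliasing
    low-pass; output length is ``round(n_in * target / fs_in)`` exactly.
    """
    target = cfg.target_sample_rate
    for name, ch in rec.channels.items():
        if ch.sample_rate <= 0:
            raise ValueError(f"channel {name}: non-positive sample rate")
        if ch.sample_rate == target:
            continue
        ratio = Fraction(target / ch.sample_rate).limit_denominator(1000)
        n_out = int(round(len(ch.signal) * target / ch.sample_rate))
        y = sps.resample_poly(ch.signal, ratio.numerator, ratio.denominator)
        if len(y) > n_out:
            y = y[:n_out]
        elif len(y) < n_out:
            y = np.pad(y, (0, n_out - len(y)))
        ch.signal = y
        ch.sample_rate = target
    return rec


def map_labels(rec: PSGRecord, lmap: LabelMap) -> PSGRecord:
    """Step 8: translate raw stage tokens into AASM codes.

    Total over the declared vocabulary: an unknown token is an error
    naming the token and the record, never silently a sentinel.
    """
    context = f"{rec.dataset_id}/{rec.subject_id}/{rec.session_id}"
    if rec.hypnogram is not None and "source_labels" not in rec.meta:
        # already coded: re-mapping through an integer map is allowed
        tokens = [str(int(v)) for v in rec.hypnogram]
    else:
        tokens = rec.meta.get("source_labels", [])
    codes = [lmap.map_token(t, context) for t in tokens]
    rec.hypnogram = np.asarray(codes, dtype=np.int8)
    rec.meta.pop("source_labels", None)
    return rec


@dataclass
class PortReport:
    """Outcome of porting one cohort: per-record tallies and reasons."""

    dataset_id: str
    listed: int = 0
    ported: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (record, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def summary(self) -> str:
        lines = [
            f"dataset {self.dataset_id}: {self.ported} ported, "
            f"{self.n_skipped} skipped of {self.listed} listed"
        ]
        lines += [f"  skipped {rec}: {why}" for rec, why in self.skipped]
        return "\n".join(lines)


def port_dataset(
    dataset_root: Path,
    adapter: CohortAdapter,
    cfg: PreprocessConfig,
    store_path: Path,
    step_hook: Optional[Callable[[str, str], None]] = None,
) -> PortReport:
    """Run the full recipe over a cohort and persist it into ``store_path``.

    Per-record failures (unreadable files, unmapped labels, ...) are
    collected into the report and do not abort the remaining records.
    Re-running over an existing store replaces each session's group, so
    the operation is idempotent.  ``step_hook(step_name, record_id)`` is
    called as each step runs — useful for progress display and for
    verifying the recipe order.
    """
    from .store import persist_record  # local import: store depends on records only

    def hook(step: str, rid: str) -> None:
        if step_hook is not None:
            step_hook(step, rid)

    report = PortReport(dataset_id=adapter.dataset_id)
    hook("list_records", "*")
    refs = list_records(dataset_root, adapter)
    report.listed = len(refs)
    for ref in refs:
        rid = f"{ref.subject_id}/{ref.session_id}"
        try:
            hook("read_psg", rid)
            rec = read_psg(ref, adapter)
            hook("map_channels", rid)
            rec = map_channels(rec, adapter.channel_map)
            if cfg.include_channels is not None:
                keep = set(cfg.include_channels)
                rec.channels = {k: v for k, v in rec.channels.items() if k in keep}
            if not rec.channels:
                raise ValueError("no channels left after mapping/selection")
            hook("filter_channels", rid)
            rec = filter_channels(rec, cfg)
            hook("scale_channels", rid)
            rec = scale_channels(rec, cfg)
            hook("clip_channels", rid)
            rec = clip_channels(rec, cfg)
            hook("resample_channels", rid)
            rec = resample_channels(rec, cfg)
            hook("map_labels", rid)
            rec = map_labels(rec, adapter.label_map)
            hook("persist_record", rid)
            persist_record(store_path, rec, expected_rate=cfg.target_sample_rate)
        except Exception as exc:  # noqa: BLE001 — per-record isolation is the contract
            logger.warning("skipping %s: %s", rid, exc)
            report.skipped.append((rid, str(exc)))
            continue
        report.ported += 1
    return report
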