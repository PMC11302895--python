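"""Data serving: splits, samplers, composable pipes, augmenters, spectrograms.

Once cohorts sit in the common data store, training a sleep-staging
model needs (a) a leakage-safe train/validation/test split, (b) a way to
draw fixed-length windows of consecutive epochs — randomly for training,
deterministically and exhaustively for evaluation — and (c) a chain of
batch transformations (augmentation, spectrogram conversion) between the
store and the model.  Everything here is lazy: a batch touches only the
byte ranges of its own windows.

Splitting is done at the *subject* level so that no subject contributes
epochs to two partitions; with multiple nights per subject, a record-level
split would leak strongly autocorrelated data across partitions.

Random sampling is two-stage: first a dataset uniformly at random, then
a session uniformly within it, then a start epoch uniformly among the
eligible starts.  Small cohorts are thus seen as often as huge ones,
which counteracts the orders-of-magnitude size imbalance between open
sleep cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .records import EPOCH_SECONDS, STAGE_VALUES
from .store import SampleWindow, SessionInfo, StoreManifest, read_window

Partition = str  # "train" | "val" | "test" | "holdout"
PARTITIONS = ("train", "val", "test", "holdout")


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitSpec:
    """Subject-level partition assignment.

    ``assignment`` maps ``(dataset_id, subject_id)`` to a partition name.
    Hold-out datasets are wholly assigned to ``holdout`` and never touch
    the other partitions.
    """

    assignment: dict[tuple[str, str], Partition]
    fractions: tuple[float, float]
    seed: int

    def partition_of(self, dataset_id: str, subject_id: str) -> Partition:
        return self.assignment[(dataset_id, subject_id)]

    def subjects_in(self, partition: Partition) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.assignment.items() if v == partition)

    def sessions_in(self, manifest: StoreManifest, partition: Partition) -> list[SessionInfo]:
        return [
            s
            for s in manifest.sessions
            if self.assignment.get((s.dataset_id, s.subject_id)) == partition
        ]


def split_records(
    manifest: StoreManifest,
    holdout_datasets: Sequence[str] = (),
    fractions: tuple[float, float] = (0.15, 0.15),
    seed: int = 0,
) -> SplitSpec:
    """Assign subjects to train/val/test (or holdout) partitions.

    Per non-holdout dataset, the validation and test partitions each
    receive ``round(n_subjects * fraction)`` subjects — the integer count
    closest to the requested fraction — drawn by a seeded shuffle; the
    rest train.  Deterministic given the seed.
    """
    val_f, test_f = fractions
    if val_f < 0 or test_f < 0 or val_f + test_f >= 1:
        raise ValueError("fractions must be non-negative and sum to < 1")
    holdout = set(holdout_datasets)
    unknown = holdout - set(manifest.datasets)
    if unknown:
        raise KeyError(f"holdout datasets not in manifest: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    assignment: dict[tuple[str, str], Partition] = {}
    for dataset_id in manifest.datasets:
        subjects = [subj for _, subj in manifest.subjects(dataset_id)]
        if dataset_id in holdout:
            for subj in subjects:
                assignment[(dataset_id, subj)] = "holdout"
            continue
        if len(subjects) < 3:
            raise ValueError(
                f"dataset {dataset_id} has {len(subjects)} subjects; "
                "at least 3 are needed to form train/val/test partitions"
            )
        order = list(rng.permutation(len(subjects)))
        n_val = int(np.floor(len(subjects) * val_f + 0.5))
        n_test = int(np.floor(len(subjects) * test_f + 0.5))
        for rank, idx in enumerate(order):
            if rank < n_val:
                part = "val"
            elif rank < n_val + n_test:
                part = "test"
            else:
                part = "train"
            assignment[(dataset_id, subjects[idx])] = part
    return SplitSpec(assignment=assignment, fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# samplers


class RandomWindowSampler:
    """Two-stage uniform random window drawing over one partition.

    Stage 1 picks a dataset uniformly (optionally weighted), stage 2 a
    session uniformly within it, stage 3 a start epoch uniformly over the
    eligible starts ``[0, epochs - window]``.  If a store directory is
    given, windows whose labels are entirely the unscored sentinel are
    excluded from the eligible starts (their hypnograms are cached; they
    are tiny).
    """

    def __init__(
        self,
        manifest: StoreManifest,
        split: SplitSpec,
        partition: Partition,
        window_epochs: int = 35,
        store_dir: Optional[Path] = None,
        dataset_weights: Optional[dict[str, float]] = None,
    ) -> None:
        if window_epochs < 1:
            raise ValueError("window_epochs must be >= 1")
        self.window_epochs = window_epochs
        self.store_dir = Path(store_dir) if store_dir is not None else None
        sessions = [
            s
            for s in split.sessions_in(manifest, partition)
            if s.n_epochs >= window_epochs
        ]
        self._by_dataset: dict[str, list[SessionInfo]] = {}
        for s in sessions:
            self._by_dataset.setdefault(s.dataset_id, []).append(s)
        if not self._by_dataset:
            raise ValueError(
                f"partition {partition!r} has no session of >= {window_epochs} epochs"
            )
        self._datasets = sorted(self._by_dataset)
        weights = np.array(
            [(dataset_weights or {}).get(d, 1.0) for d in self._datasets], dtype=float
        )
        self._weights = weights / weights.sum()
        self._eligible_starts: dict[tuple[str, str, str], np.ndarray] = {}

    def _starts(self, info: SessionInfo) -> np.ndarray:
        key = (info.dataset_id, info.subject_id, info.session_id)
        cached = self._eligible_starts.get(key)
        if cached is not None:
            return cached
        n_starts = info.n_epochs - self.window_epochs + 1
        starts = np.arange(n_starts)
        if self.store_dir is not None:
            from .store import read_hypnogram

            hyp = read_hypnogram(self.store_dir, *key)
            scored = (hyp != -1).astype(int)
            # window [s, s+w) is eligible iff it contains a scored epoch
            csum = np.concatenate([[0], np.cumsum(scored)])
            has_scored = csum[self.window_epochs :] - csum[:-self.window_epochs]
            starts = starts[has_scored[: n_starts] > 0]
        self._eligible_starts[key] = starts
        return starts

    def draw(self, rng: np.random.Generator) -> SampleWindow:
        d = self._datasets[rng.choice(len(self._datasets), p=self._weights)]
        sessions = self._by_dataset[d]
        info = sessions[int(rng.integers(len(sessions)))]
        starts = self._starts(info)
        if starts.size == 0:
            # entirely-unscored session: fall back to a sibling
            eligible = [s for s in sessions if self._starts(s).size]
            if not eligible:
                raise ValueError(f"dataset {d}: no eligible window start")
            info = eligible[int(rng.integers(len(eligible)))]
            starts = self._starts(info)
        start = int(starts[int(rng.integers(starts.size))])
        return SampleWindow(
            dataset_id=info.dataset_id,
            subject_id=info.subject_id,
            session_id=info.session_id,
            start_epoch=start,
            num_epochs=self.window_epochs,
        )

    def draws(self, rng: np.random.Generator, n: int) -> Iterable[SampleWindow]:
        for _ in range(n):
            yield self.draw(rng)


def random_sample(
    manifest: StoreManifest,
    split: SplitSpec,
    partition: Partition,
    window_epochs: int,
    rng: np.random.Generator,
    store_dir: Optional[Path] = None,
) -> SampleWindow:
    """One-shot convenience wrapper around :class:`RandomWindowSampler`."""
    sampler = RandomWindowSampler(manifest, split, partition, window_epochs, store_dir)
    return sampler.draw(rng)


def deterministic_iterate(
    manifest: StoreManifest,
    split: SplitSpec,
    partition: Partition,
    window_epochs: int,
) -> list[SampleWindow]:
    """Exhaustive, non-overlapping window enumeration for validation/testing.

    Consecutive windows per session in manifest order; a tail shorter
    than ``window_epochs`` is dropped, never padded, so each epoch is
    covered at most once (exactly once when the session length divides).
    """
    if window_epochs < 1:
        raise ValueError("window_epochs must be >= 1")
    windows: list[SampleWindow] = []
    for info in split.sessions_in(manifest, partition):
        for start in range(0, info.n_epochs - window_epochs + 1, window_epochs):
            windows.append(
                SampleWindow(
                    dataset_id=info.dataset_id,
                    subject_id=info.subject_id,
                    session_id=info.session_id,
                    start_epoch=start,
                    num_epochs=window_epochs,
                )
            )
    return windows


# ---------------------------------------------------------------------------
# batches and pipes


@dataclass
class Batch:
    """A collated set of windows: signals (window x channel x sample),
    labels (window x epoch), sample rate, and window provenance."""

    signals: np.ndarray
    labels: np.ndarray
    sample_rate: float
    provenance: list[SampleWindow] = field(default_factory=list)
    channel_names: tuple[str, ...] = ()

    def validate(self) -> "Batch":
        if self.signals.ndim != 3:
            raise ValueError(f"signals must be 3-axis, got shape {self.signals.shape}")
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-axis, got shape {self.labels.shape}")
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"window axis mismatch: {self.signals.shape[0]} signals vs "
                f"{self.labels.shape[0]} labels"
            )
        spe = EPOCH_SECONDS * self.sample_rate
        if self.signals.shape[2] != int(round(self.labels.shape[1] * spe)):
            raise ValueError(
                f"sample axis {self.signals.shape[2]} inconsistent with "
                f"{self.labels.shape[1]} epochs at {self.sample_rate} Hz"
            )
        bad = set(np.unique(self.labels)) - STAGE_VALUES
        if bad:
            raise ValueError(f"labels contain invalid codes {sorted(bad)}")
        return self


def collate_windows(
    store_dir: Path,
    windows: Sequence[SampleWindow],
    channels: Sequence[str],
) -> Batch:
    """Read ``windows`` lazily from the store and stack them into a Batch."""
    if not windows:
        raise ValueError("cannot collate an empty window list")
    sigs, labs = [], []
    for w in windows:
        s, l = read_window(store_dir, w, channels)
        sigs.append(s)
        labs.append(l)
    from .store import store_file  # rate lookup
    import h5py

    with h5py.File(store_file(store_dir, windows[0].dataset_id), "r") as f:
        rate = float(f[windows[0].subject_id][windows[0].session_id].attrs["sample_rate"])
    return Batch(
        signals=np.stack(sigs),
        labels=np.stack(labs),
        sample_rate=rate,
        provenance=list(windows),
        channel_names=tuple(channels),
    ).validate()


class IPipe:
    """A Batch -> Batch transformation stage.

    Subclasses implement :meth:`apply`; stages compose left-to-right via
    :func:`apply_pipes` or the ``|`` operator.
    """

    name: str = "pipe"

    def apply(self, batch: Batch) -> Batch:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, batch: Batch) -> Batch:
        return self.apply(batch)

    def __or__(self, other: "IPipe") -> "PipeChain":
        return PipeChain([self, other])


class PipeChain(IPipe):
    name = "chain"

    def __init__(self, stages: Sequence[IPipe]):
        self.stages = list(stages)

    def apply(self, batch: Batch) -> Batch:
        return apply_pipes(batch, self.stages)


class FunctionPipe(IPipe):
    """Wrap a plain callable as a pipe stage."""

    def __init__(self, fn: Callable[[Batch], Batch], name: str = "function"):
        self.fn = fn
        self.name = name

    def apply(self, batch: Batch) -> Batch:
        return self.fn(batch)


def apply_pipes(batch: Batch, pipes: Sequence[IPipe]) -> Batch:
    """Left-to-right composition; the empty pipeline is the identity.

    A stage whose output violates the batch invariants is reported by
    name — spectrogram stages are exempt from re-validation since they
    change the axis layout on purpose.
    """
    for stage in pipes:
        out = stage(batch)
        if isinstance(out, Batch):
            try:
                out.validate()
            except ValueError as exc:
                raise ValueError(f"pipe stage {stage.name!r}: {exc}") from exc
        batch = out
    return batch


# ---------------------------------------------------------------------------
# augmenters


@dataclass(frozen=True)
class AugmenterSpec:
    """Declarative augmenter description.

    kind
        ``"noise"`` (global additive Gaussian), ``"scale"`` (global
        amplitude scaling) or ``"mask"`` (regional contiguous zeroing).
    probability
        Per-window application probability.
    magnitude
        Noise standard deviation (post-normalization units) or the
        half-width of the scaling range ``[1 - m, 1 + m]``.
    fraction_range
        For regional kinds: bounds on the masked fraction of the window.
    """

    kind: str = "noise"
    probability: float = 1.0
    magnitude: float = 0.1
    fraction_range: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        if self.kind not in ("noise", "scale", "mask"):
            raise ValueError(f"unknown augmenter kind {self.kind!r}")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must be in [0, 1]")
        lo, hi = self.fraction_range
        if not 0 < lo <= hi <= 1:
            if self.kind == "mask":
                raise ValueError("regional fraction bounds must satisfy 0 < lo <= hi <= 1")

    @property
    def scope(self) -> str:
        return "regional" if self.kind == "mask" else "global"


class Augmenter:
    """Base augmenter: transforms the signals of one selected window."""

    def transform(self, window: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class GlobalAugmenter(Augmenter):
    """Applies to the whole window."""


class RegionalAugmenter(Augmenter):
    """Applies to a contiguous random sub-segment of the window."""

    def __init__(self, fraction_range: tuple[float, float]):
        self.fraction_range = fraction_range

    def transform(self, window: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = window.shape[-1]
        lo, hi = self.fraction_range
        frac = lo if lo == hi else float(rng.uniform(lo, hi))
        length = int(np.floor(frac * n))
        if length == 0:
            return window
        start = int(rng.integers(0, n - length + 1))
        return self.transform_segment(window, start, length, rng)

    def transform_segment(
        self, window: np.ndarray, start: int, length: int, rng: np.random.Generator
    ) -> np.ndarray:
        raise NotImplementedError


class GaussianNoise(GlobalAugmenter):
    def __init__(self, sd: float):
        self.sd = sd

    def transform(self, window, rng):
        return window + rng.normal(0.0, self.sd, size=window.shape)


class AmplitudeScale(GlobalAugmenter):
    def __init__(self, half_width: float):
        self.half_width = half_width

    def transform(self, window, rng):
        return window * float(rng.uniform(1 - self.half_width, 1 + self.half_width))


class SegmentMask(RegionalAugmenter):
    """Zero out the chosen segment across all channels."""

    def transform_segment(self, window, start, length, rng):
        out = window.copy()
        out[..., start : start + length] = 0.0
        return out


def _build(spec: AugmenterSpec) -> Augmenter:
    if spec.kind == "noise":
        return GaussianNoise(spec.magnitude)
    if spec.kind == "scale":
        return AmplitudeScale(spec.magnitude)
    return SegmentMask(spec.fraction_range)


def augment(batch: Batch, spec: AugmenterSpec, rng: np.random.Generator) -> Batch:
    """Apply an augmenter to each window with the spec's probability.

    Labels, axis sizes and un-selected windows are never modified; with
    probability 0 the batch passes through bitwise identical.
    """
    if spec.probability == 0.0:
        return batch
    aug = _build(spec)
    signals = batch.signals.astype(np.float64, copy=True)
    for w in range(signals.shape[0]):
        if rng.random() < spec.probability:
            signals[w] = aug.transform(signals[w], rng)
    return replace(batch, signals=signals.astype(batch.signals.dtype), labels=batch.labels)


class AugmentPipe(IPipe):
    """Pipe stage wrapping :func:`augment` with its own seeded generator."""

    name = "augment"

    def __init__(self, spec: AugmenterSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng

    def apply(self, batch: Batch) -> Batch:
        return augment(batch, self.spec, self.rng)


# ---------------------------------------------------------------------------
# spectrograms


@dataclass(frozen=True)
class SpectrogramConfig:
    """Short-time transform settings for spectrogram-input models.

    Signals are first resampled to ``intermediate_rate`` (100 Hz — the
    native rate of typical spectrogram-input sleep stagers), then each
    30-s epoch is transformed with a 2-s taper sliding in 1-s hops and
    compressed as ``log(magnitude + epsilon)``.  The FFT length is the
    next power of two above the taper (256 samples at the defaults),
    giving 129 frequency bins and 29 frames per epoch.
    """

    intermediate_rate: float = 100.0
    window_seconds: float = 2.0
    hop_seconds: float = 1.0
    taper: str = "hamming"
    log_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not self.window_seconds >= self.hop_seconds > 0:
            raise ValueError("need window_seconds >= hop_seconds > 0")
        if self.intermediate_rate <= 0:
            raise ValueError("intermediate_rate must be positive")

    @property
    def nperseg(self) -> int:
        return int(round(self.window_seconds * self.intermediate_rate))

    @property
    def nfft(self) -> int:
        return int(2 ** np.ceil(np.log2(self.nperseg)))

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1

    @property
    def frames_per_epoch(self) -> int:
        hop = int(round(self.hop_seconds * self.intermediate_rate))
        n = int(round(EPOCH_SECONDS * self.intermediate_rate))
        return (n - self.nperseg) // hop + 1

    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft, d=1.0 / self.intermediate_rate)


@dataclass
class SpectrogramBatch:
    """Spectrogram view of a batch: window x channel x frame x frequency-bin.

    Frames run epoch-major: with F frames per epoch, frames
    ``[e*F, (e+1)*F)`` belong to epoch ``e`` of the window.
    """

    values: np.ndarray
    labels: np.ndarray
    frequencies: np.ndarray
    frames_per_epoch: int
    provenance: list[SampleWindow] = field(default_factory=list)
    channel_names: tuple[str, ...] = ()


def to_spectrogram(batch: Batch, cfg: SpectrogramConfig = SpectrogramConfig()) -> SpectrogramBatch:
    """Resample to the intermediate rate and transform each epoch.

    A 30-s epoch at the defaults yields 29 frames x 129 bins per channel.
    """
    from fractions import Fraction

    n_windows, n_channels, _ = batch.signals.shape
    n_epochs = batch.labels.shape[1]
    spe = int(round(EPOCH_SECONDS * cfg.intermediate_rate))
    if spe < cfg.nperseg:
        raise ValueError(
            f"epoch ({spe} samples) shorter than the {cfg.nperseg}-sample taper"
        )
    x = batch.signals.astype(np.float64)
    if batch.sample_rate != cfg.intermediate_rate:
        ratio = Fraction(cfg.intermediate_rate / batch.sample_rate).limit_denominator(1000)
        y = sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)
        n_out = n_epochs * spe
        y = y[..., :n_out] if y.shape[-1] >= n_out else np.pad(
            y, [(0, 0), (0, 0), (0, n_out - y.shape[-1])]
        )
    else:
        y = x
    hop = int(round(cfg.hop_seconds * cfg.intermediate_rate))
    epochs = y.reshape(n_windows, n_channels, n_epochs, spe)
    _, _, mag = sps.spectrogram(
        epochs,
        fs=cfg.intermediate_rate,
        window=cfg.taper,
        nperseg=cfg.nperseg,
        noverlap=cfg.nperseg - hop,
        nfft=cfg.nfft,
        detrend=False,
        mode="magnitude",
        axis=-1,
    )
    # mag: (W, C, E, bins, frames) -> epoch-major frames: (W, C, E*frames, bins)
    mag = np.moveaxis(mag, -1, -2)
    values = np.log(mag + cfg.log_epsilon).reshape(
        n_windows, n_channels, n_epochs * cfg.frames_per_epoch, cfg.n_bins
    )
    return SpectrogramBatch(
        values=values,
        labels=batch.labels,
        frequencies=cfg.frequencies(),
        frames_per_epoch=cfg.frames_per_epoch,
        provenance=batch.provenance,
        channel_names=batch.channel_names,
    )


class SpectrogramPipe(IPipe):
    name = "spectrogram"

    def __init__(self, cfg: SpectrogramConfig = SpectrogramConfig()):
        self.cfg = cfg

    def apply(self, batch: Batch) -> SpectrogramBatch:  # type: ignore[override]
        return to_spectrogram(batch, self.cfg)


# ---------------------------------------------------------------------------
# framework adapter


class WindowDataset:
    """Iterable over (signals, labels) pairs for a DL framework's loader.

    Deliberately framework-free: yields numpy arrays; wrap it in your
    framework's dataset/loader abstraction of choice.
    """

    def __init__(
        self,
        store_dir: Path,
        windows: Sequence[SampleWindow],
        channels: Sequence[str],
        batch_size: int = 1,
        pipes: Sequence[IPipe] = (),
    ):
        self.store_dir = Path(store_dir)
        self.windows = list(windows)
        self.channels = list(channels)
        self.batch_size = batch_size
        self.pipes = list(pipes)

    def __len__(self) -> int:
        return (len(self.windows) + self.batch_size - 1) // self.batch_size

    def __iter__(self):
        for i in range(0, len(self.windows), self.batch_size):
            batch = collate_windows(
                self.store_dir, self.windows[i : i + self.batch_size], self.channels
            )
            yield apply_pipes(batch, self.pipes)
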