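"""File-format benchmark: HDF5 vs Parquet vs Pickle for one PSG record.

Reproduces the measurement methodology used to choose the store's file
format: serialize the same multi-channel record to each candidate
format, then repeatedly extract a single channel, recording wall time
and peak memory per trial.  Absolute numbers are machine-specific; the
harness reports them raw and deliberately refuses to pick a winner.

Memory is metered with ``tracemalloc`` (numpy registers its buffers with
it); during Parquet trials the Arrow allocator pool is sampled too,
since Arrow's C++ allocations bypass the Python tracer.
"""

from __future__ import annotations

import pickle
import platform
import time
import tracemalloc
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

FORMATS = ("hdf5", "parquet", "pickle")


@dataclass
class FormatResult:
    format: str
    file_size_mb: float
    load_times_ms: list[float] = field(default_factory=list)
    peak_memory_mb: list[float] = field(default_factory=list)

    @property
    def mean_time_ms(self) -> float:
        return float(np.mean(self.load_times_ms))

    @property
    def sd_time_ms(self) -> float:
        return float(np.std(self.load_times_ms, ddof=1)) if len(self.load_times_ms) > 1 else 0.0

    @property
    def mean_memory_mb(self) -> float:
        return float(np.mean(self.peak_memory_mb))


@dataclass
class BenchmarkReport:
    results: dict[str, FormatResult]
    trials: int
    channel: str
    machine: str = field(default_factory=platform.platform)

    def summary(self) -> str:
        lines = [
            f"single-channel extraction ({self.channel!r}), {self.trials} trials "
            f"on {self.machine}",
            f"{'format':<8} {'size MB':>9} {'peak mem MB':>12} {'load ms':>16}",
        ]
        for name, r in self.results.items():
            lines.append(
                f"{name:<8} {r.file_size_mb:>9.1f} {r.mean_memory_mb:>12.1f} "
                f"{r.mean_time_ms:>9.1f}±{r.sd_time_ms:.1f}"
            )
        lines.append("(absolute values are machine-specific; no ranking implied)")
        return "\n".join(lines)


def _write_hdf5(path: Path, record: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("psg")
        for name, x in record.items():
            g.create_dataset(name, data=x, chunks=(min(len(x), 30 * 128),))


def _write_parquet(path: Path, record: dict[str, np.ndarray]) -> None:
    import pyarrow as pa
    import pyarrow.parquet as pq

    pq.write_table(pa.table({k: v for k, v in record.items()}), path)


def _write_pickle(path: Path, record: dict[str, np.ndarray]) -> None:
    with open(path, "wb") as f:
        pickle.dump(record, f, protocol=pickle.HIGHEST_PROTOCOL)


def _load_hdf5(path: Path, channel: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["psg"][channel][:]


def _load_parquet(path: Path, channel: str) -> np.ndarray:
    import pyarrow.parquet as pq

    return pq.read_table(path, columns=[channel])[channel].to_numpy()


def _load_pickle(path: Path, channel: str) -> np.ndarray:
    with open(path, "rb") as f:
        return pickle.load(f)[channel]


_WRITERS = {"hdf5": _write_hdf5, "parquet": _write_parquet, "pickle": _write_pickle}
_LOADERS = {"hdf5": _load_hdf5, "parquet": _load_parquet, "pickle": _load_pickle}
_SUFFIX = {"hdf5": ".hdf5", "parquet": ".parquet", "pickle": ".pkl"}


def measure_single_load(path: Path, fmt: str, channel: str) -> tuple[float, float]:
    """One trial: (load time ms, peak memory MB) for a single-channel read."""
    loader = _LOADERS[fmt]
    arrow_before = 0
    if fmt == "parquet":
        import pyarrow as pa

        arrow_before = pa.total_allocated_bytes()
    tracemalloc.start()
    t0 = time.perf_counter()
    data = loader(path, channel)
    dt = (time.perf_counter() - t0) * 1000.0
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    if fmt == "parquet":
        import pyarrow as pa

        peak = max(peak, pa.total_allocated_bytes() - arrow_before)
    del data
    return dt, peak / 1e6


def run_benchmark(
    record: dict[str, np.ndarray],
    work_dir: Path,
    formats: tuple[str, ...] = FORMATS,
    trials: int = 100,
    channel: str | None = None,
) -> BenchmarkReport:
    """Serialize ``record`` once per format, then run extraction trials."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    unknown = set(formats) - set(FORMATS)
    if unknown:
        raise ValueError(f"unknown formats {sorted(unknown)}; known: {FORMATS}")
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    record = {k: np.asarray(v, dtype=np.float32) for k, v in record.items()}
    channel = channel or next(iter(record))
    results: dict[str, FormatResult] = {}
    for fmt in formats:
        path = work_dir / f"benchmark{_SUFFIX[fmt]}"
        _WRITERS[fmt](path, record)
        res = FormatResult(format=fmt, file_size_mb=path.stat().st_size / 1e6)
        for _ in range(trials):
            dt, mem = measure_single_load(path, fmt, channel)
            res.load_times_ms.append(dt)
            res.peak_memory_mb.append(mem)
        results[fmt] = res
    return BenchmarkReport(results=results, trials=trials, channel=channel)


def synthetic_benchmark_record(
    n_channels: int = 16, n_samples: int = 500_000, seed: int = 0
) -> dict[str, np.ndarray]:
    """A multi-channel record of noise, sized for a quick benchmark run."""
    rng = np.random.default_rng(seed)
    return {
        f"ch{i:02d}": rng.standard_normal(n_samples).astype(np.float32)
        for i in range(n_channels)
    }
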