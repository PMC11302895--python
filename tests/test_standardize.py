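"""Standardization chain: per-step behavior, recipe order, adapter reuse."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnopipe._edf import write_edf
from somnopipe.adapters import EDFSidecarAdapter, builtin_label_map
from somnopipe.records import (
    AASM_IDENTITY_LABELS,
    Channel,
    ChannelMap,
    PreprocessConfig,
    PSGRecord,
    RecordRef,
)
from somnopipe.standardize import (
    PIPELINE_STEPS,
    clip_channels,
    filter_channels,
    list_records,
    map_channels,
    map_labels,
    port_dataset,
    read_psg,
    resample_channels,
    scale_channels,
)

from .oracles import scale_brute


def make_record(signals: dict[str, tuple[np.ndarray, float]], labels=None) -> PSGRecord:
    return PSGRecord(
        "d", "s01", "n01",
        channels={k: Channel(x, fs) for k, (x, fs) in signals.items()},
        meta={} if labels is None else {"source_labels": list(labels)},
    )


class TestListAndRead:
    def test_empty_directory_yields_empty_list_with_warning(self, tmp_path, caplog):
        adapter = EDFSidecarAdapter("d", ChannelMap({}), builtin_label_map("aasm"))
        with caplog.at_level("WARNING"):
            assert list_records(tmp_path, adapter) == []
        assert any("no records" in m for m in caplog.messages)

    def test_missing_root_is_fatal(self, tmp_path):
        adapter = EDFSidecarAdapter("d", ChannelMap({}), builtin_label_map("aasm"))
        with pytest.raises(FileNotFoundError):
            list_records(tmp_path / "nope", adapter)

    def test_annotationless_session_skipped_with_warning(self, tmp_path, caplog):
        fs, n_epochs = 128, 2
        x = np.zeros(n_epochs * 30 * fs)
        for subj, sess, with_sidecar in [
            ("sub-01", "ses-01", True),
            ("sub-01", "ses-02", False),
            ("sub-02", "ses-01", True),
        ]:
            d = tmp_path / subj / sess
            d.mkdir(parents=True)
            write_edf(d / "psg.edf", [("EEG C3-A2", x, fs)])
            if with_sidecar:
                d.joinpath("hypnogram.txt").write_text("W\nW\n")
        adapter = EDFSidecarAdapter(
            "d", ChannelMap({"EEG C3-A2": ("C3-A2", "EEG")}), builtin_label_map("aasm")
        )
        with caplog.at_level("WARNING"):
            refs = list_records(tmp_path, adapter)
        assert [(r.subject_id, r.session_id) for r in refs] == [
            ("sub-01", "ses-01"),
            ("sub-02", "ses-01"),
        ]
        assert any("no annotation sidecar" in m for m in caplog.messages)

    def test_read_truncates_signal_and_labels_to_common_epochs(self, tmp_path):
        # 61.2 epochs of signal, 61 labels -> 61 whole epochs survive
        fs = 128
        d = tmp_path / "sub-01" / "ses-01"
        d.mkdir(parents=True)
        write_edf(d / "psg.edf", [("EEG C3-A2", np.zeros(int(61.2 * 30) * fs), fs)])
        d.joinpath("hypnogram.txt").write_text("\n".join(["W"] * 61) + "\n")
        adapter = EDFSidecarAdapter(
            "d", ChannelMap({"EEG C3-A2": ("C3-A2", "EEG")}), builtin_label_map("aasm")
        )
        (ref,) = list_records(tmp_path, adapter)
        rec = read_psg(ref, adapter)
        assert len(rec.meta["source_labels"]) == 61
        assert len(rec.channels["EEG C3-A2"].signal) == 61 * 30 * fs

    def test_expected_sample_count_from_edf(self, tmp_path):
        fs, n_epochs = 256, 60
        d = tmp_path / "sub-01" / "ses-01"
        d.mkdir(parents=True)
        sig = np.sin(np.arange(n_epochs * 30 * fs) / fs)
        write_edf(d / "psg.edf", [("EEG C3-A2", sig, fs), ("EEG C4-A1", sig, fs)])
        d.joinpath("hypnogram.txt").write_text("\n".join(["N2"] * n_epochs) + "\n")
        adapter = EDFSidecarAdapter(
            "d",
            ChannelMap({"EEG C3-A2": ("C3-A2", "EEG"), "EEG C4-A1": ("C4-A1", "EEG")}),
            builtin_label_map("aasm"),
        )
        rec = read_psg(list_records(tmp_path, adapter)[0], adapter)
        assert len(rec.channels) == 2
        assert all(len(c.signal) == 460_800 for c in rec.channels.values())
        assert len(rec.meta["source_labels"]) == 60


class TestMapChannels:
    CMAP = ChannelMap(
        {"EEG C3-A2": ("C3-A2", "EEG"), "LOC-M2": ("E1-M2", "EOG")}, drop_unmapped=True
    )

    def test_rename_and_eog_mapping(self):
        rec = make_record({"EEG C3-A2": (np.zeros(10), 128.0), "LOC-M2": (np.zeros(10), 128.0)})
        out = map_channels(rec, self.CMAP)
        assert set(out.channels) == {"C3-A2", "E1-A2"}  # M2 normalized to A2
        assert out.meta["original_channel_names"]["C3-A2"] == "EEG C3-A2"

    def test_unmapped_dropped_or_error(self):
        rec = make_record({"ECG": (np.zeros(10), 128.0), "EEG C3-A2": (np.zeros(10), 128.0)})
        out = map_channels(rec, self.CMAP)
        assert "ECG" not in out.channels and len(out.channels) == 1
        strict = ChannelMap({"EEG C3-A2": ("C3-A2", "EEG")}, drop_unmapped=False)
        with pytest.raises(KeyError, match="ECG"):
            map_channels(make_record({"ECG": (np.zeros(10), 128.0)}), strict)

    def test_duplicate_canonical_target_is_error(self):
        cmap = ChannelMap({"A": ("C3-A2", "EEG"), "B": ("C3-A2", "EEG")})
        rec = make_record({"A": (np.zeros(10), 128.0), "B": (np.zeros(10), 128.0)})
        with pytest.raises(ValueError, match="both map to"):
            map_channels(rec, cmap)


class TestFilterChannels:
    def test_no_band_is_bitwise_identity(self):
        x = np.random.default_rng(0).normal(size=1000)
        rec = make_record({"C3-A2": (x.copy(), 128.0)})
        out = filter_channels(rec, PreprocessConfig())
        assert out.channels["C3-A2"].signal is rec.channels["C3-A2"].signal
        np.testing.assert_array_equal(out.channels["C3-A2"].signal, x)

    def test_stopband_attenuation_on_white_noise(self, rng):
        # (0.3, 35) Hz band at 128 Hz: 45-64 Hz power down >= 20 dB
        from scipy.signal import periodogram

        x = rng.normal(size=128 * 300)
        rec = make_record({"C3-A2": (x.copy(), 128.0)})
        out = filter_channels(rec, PreprocessConfig(bandpass=(0.3, 35.0)))
        f, p_in = periodogram(x, fs=128.0)
        _, p_out = periodogram(out.channels["C3-A2"].signal, fs=128.0)
        band = (f >= 45) & (f <= 64)
        atten_db = 10 * np.log10(p_in[band].mean() / p_out[band].mean())
        assert atten_db >= 20

    def test_inverted_band_is_error(self):
        with pytest.raises(ValueError):
            PreprocessConfig(bandpass=(35.0, 0.3))
        # band above Nyquist caught per channel
        rec = make_record({"C3-A2": (np.zeros(1000), 128.0)})
        with pytest.raises(ValueError, match="Nyquist"):
            filter_channels(rec, PreprocessConfig(bandpass=(0.3, 70.0)))


class TestScaleChannels:
    def test_linear_interpolation_quartiles_hand_case(self):
        rec = make_record({"C3-A2": (np.array([0.0, 1, 2, 3, 4]), 128.0)})
        out = scale_channels(rec, PreprocessConfig())
        np.testing.assert_allclose(
            out.channels["C3-A2"].signal, [-1.0, -0.5, 0.0, 0.5, 1.0], atol=1e-12
        )

    def test_constant_channel_centered_only_and_flagged(self, caplog):
        rec = make_record({"C3-A2": (np.full(100, 7.0), 128.0)})
        with caplog.at_level("WARNING"):
            out = scale_channels(rec, PreprocessConfig())
        np.testing.assert_array_equal(out.channels["C3-A2"].signal, np.zeros(100))
        assert "C3-A2" in out.meta["degenerate_channels"]

    def test_already_normalized_is_fixed_point(self, rng):
        x = rng.normal(size=5000)
        x = (x - x.mean()) / (np.percentile(x, 75) - np.percentile(x, 25))
        rec = make_record({"C3-A2": (x.copy(), 128.0)})
        out = scale_channels(rec, PreprocessConfig())
        np.testing.assert_allclose(out.channels["C3-A2"].signal, x, atol=1e-9)

    def test_empty_channel_is_error(self):
        rec = make_record({"C3-A2": (np.array([]), 128.0)})
        with pytest.raises(ValueError, match="empty"):
            scale_channels(rec, PreprocessConfig())

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(min_value=5, max_value=2000),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_agrees_with_brute_force_quartiles(self, n, seed):
        x = np.random.default_rng(seed).normal(scale=50.0, size=n)
        rec = make_record({"C3-A2": (x.copy(), 128.0)})
        out = scale_channels(rec, PreprocessConfig())
        np.testing.assert_allclose(
            out.channels["C3-A2"].signal, scale_brute(x), atol=1e-9
        )


class TestClipChannels:
    @pytest.mark.parametrize("value,expected", [(25.0, 20.0), (-100.0, -20.0)])
    def test_saturation(self, value, expected):
        x = np.array([0.0, value])
        rec = make_record({"C3-A2": (x, 128.0)})
        out = clip_channels(rec, PreprocessConfig())
        assert out.channels["C3-A2"].signal[1] == expected

    def test_in_range_record_unchanged(self, rng):
        x = rng.uniform(-7.3, 7.3, size=1000)
        rec = make_record({"C3-A2": (x.copy(), 128.0)})
        out = clip_channels(rec, PreprocessConfig())
        np.testing.assert_array_equal(out.channels["C3-A2"].signal, x)


class TestResampleChannels:
    @pytest.mark.parametrize(
        "n_in,fs_in,n_out",
        [(2560, 256.0, 1280), (3000, 100.0, 3840), (1280, 128.0, 1280)],
    )
    def test_output_length(self, n_in, fs_in, n_out):
        rec = make_record({"C3-A2": (np.zeros(n_in), fs_in)})
        out = resample_channels(rec, PreprocessConfig())
        ch = out.channels["C3-A2"]
        assert len(ch.signal) == n_out and ch.sample_rate == 128.0

    def test_tone_below_output_nyquist_survives(self):
        from scipy.signal import periodogram

        fs_in = 256.0
        t = np.arange(int(fs_in * 120)) / fs_in
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = make_record({"C3-A2": (x, fs_in)})
        out = resample_channels(rec, PreprocessConfig())
        f, p = periodogram(out.channels["C3-A2"].signal, fs=128.0)
        assert abs(f[np.argmax(p)] - 10.0) < 0.1

    def test_non_positive_rate_is_error(self):
        with pytest.raises(ValueError):
            make_record({"C3-A2": (np.zeros(10), -1.0)})


class TestMapLabels:
    def test_rk_vocabulary(self):
        lmap = builtin_label_map("rk")
        rec = make_record({"C3-A2": (np.zeros(10), 128.0)},
                          labels=["W", "S1", "S2", "S3", "S4", "REM", "MT"])
        out = map_labels(rec, lmap)
        assert out.hypnogram.tolist() == [0, 1, 2, 3, 3, 4, -1]

    def test_token_outside_vocabulary_names_token_and_record(self):
        rec = make_record({"C3-A2": (np.zeros(10), 128.0)}, labels=["W", "??"])
        with pytest.raises(KeyError, match=r"\?\?.*s01/n01"):
            map_labels(rec, builtin_label_map("aasm"))

    def test_aasm_identity_map_is_idempotent(self):
        rec = make_record({"C3-A2": (np.zeros(10), 128.0)}, labels=["2", "-1", "4"])
        once = map_labels(rec, AASM_IDENTITY_LABELS)
        first = once.hypnogram.copy()
        twice = map_labels(once, AASM_IDENTITY_LABELS)
        np.testing.assert_array_equal(twice.hypnogram, first)


class TestPortDataset:
    def test_recipe_runs_steps_in_fixed_order(self, aasm_cohort, tmp_path):
        calls: dict[str, list[str]] = {}
        spec = aasm_cohort.spec

        def hook(step, rid):
            calls.setdefault(rid, []).append(step)

        report = port_dataset(
            aasm_cohort.raw_root / spec.dataset_id,
            spec.adapter(),
            aasm_cohort.cfg,
            tmp_path / "store",
            step_hook=hook,
        )
        assert report.ported == 6
        per_record = [v for k, v in calls.items() if k != "*"]
        assert len(per_record) == 6
        for seq in per_record:
            assert tuple(seq) == PIPELINE_STEPS[1:]

    def test_corrupt_edf_skipped_with_reason(self, tmp_path, aasm_cohort):
        import shutil

        spec = aasm_cohort.spec
        root = tmp_path / "raw"
        shutil.copytree(aasm_cohort.raw_root / spec.dataset_id, root)
        bad = root / "sub-02" / "ses-01" / "psg.edf"
        bad.write_bytes(b"not an edf at all")
        report = port_dataset(root, spec.adapter(), aasm_cohort.cfg, tmp_path / "store")
        assert report.ported == 5
        assert len(report.skipped) == 1
        assert report.skipped[0][0] == "sub-02/ses-01"

    def test_rerun_is_idempotent(self, aasm_cohort, tmp_path):
        from somnopipe.store import build_manifest

        spec = aasm_cohort.spec
        store = tmp_path / "store"
        for _ in range(2):
            port_dataset(aasm_cohort.raw_root / spec.dataset_id, spec.adapter(),
                         aasm_cohort.cfg, store)
        assert build_manifest(store).to_json() == build_manifest(aasm_cohort.store_dir).to_json()

    def test_new_cohort_needs_only_a_channel_map(self, aasm_cohort, tmp_path):
        """A subclass overriding nothing but the channel map ports fine."""

        class RenamedCohortAdapter(EDFSidecarAdapter):
            """Only the translation tables differ; all steps are inherited."""

        cmap = ChannelMap({"EEG C3-A2": ("F3-A2", "EEG")})  # remap to a new site
        adapter = RenamedCohortAdapter("renamed", cmap, builtin_label_map("aasm"))
        report = port_dataset(
            aasm_cohort.raw_root / aasm_cohort.spec.dataset_id,
            adapter, aasm_cohort.cfg, tmp_path / "store",
        )
        assert report.ported == 6
        from somnopipe.store import build_manifest

        manifest = build_manifest(tmp_path / "store")
        assert all(s.channels == ("F3-A2",) for s in manifest.sessions)


class TestStandardizedContract:
    def test_post_chain_invariants_on_ported_store(self, aasm_cohort):
        """Every stored channel: |mean|<1e-6 pre-resample basis, max|x|<=20, 128 Hz."""
        from somnopipe.store import SampleWindow, build_manifest, read_window

        manifest = build_manifest(aasm_cohort.store_dir)
        assert len(manifest) == 6
        for info in manifest.sessions:
            assert info.sample_rate == 128.0
            w = SampleWindow(info.dataset_id, info.subject_id, info.session_id,
                             0, info.n_epochs)
            signals, labels = read_window(aasm_cohort.store_dir, w, list(info.channels))
            assert np.abs(signals).max() <= 20.0
            assert len(labels) == info.n_epochs
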