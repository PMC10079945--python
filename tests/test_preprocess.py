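"""Normalization, windowing, labeling, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeraster.preprocess import (NOISE_LABEL, SplitSpec, WindowSet,
                                    balance_noise, l2_normalize,
                                    load_binary_epochs, load_windowset,
                                    rescale_unit_interval, save_windowset,
                                    segment, split)
from spikeraster.synth import (Annotation, Recording, SimulationConfig,
                               simulate_binary_epochs, simulate_recording,
                               write_binary_epochs_csv)


class TestL2Normalize:
    def test_three_four_five_triangle(self):
        np.testing.assert_allclose(l2_normalize([3.0, 4.0]), [0.6, 0.8])

    def test_unit_basis_vector_unchanged(self):
        e = np.zeros(8)
        e[2] = 1.0
        np.testing.assert_array_equal(l2_normalize(e), e)

    def test_output_norm_one_and_proportional(self, rng):
        x = rng.normal(size=257)
        y = l2_normalize(x)
        assert np.sqrt(np.sum(y * y)) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(y * np.sqrt(np.sum(x * x)), x, rtol=1e-12)

    @pytest.mark.parametrize("bad", [np.zeros(5), np.array([1.0, np.nan]),
                                     np.array([np.inf, 1.0])])
    def test_zero_or_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            l2_normalize(bad)


class TestRescaleUnitInterval:
    def test_symmetric_range(self):
        np.testing.assert_allclose(rescale_unit_interval([-1.0, 0.0, 1.0]),
                                   [0.0, 0.5, 1.0])

    def test_already_unit_interval_unchanged(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(rescale_unit_interval(x), x)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(
        lambda v: max(v) > min(v)))
    def test_bounds_and_order_preserved(self, values):
        y = rescale_unit_interval(np.array(values))
        assert y.min() == 0.0 and y.max() == pytest.approx(1.0, abs=1e-12)
        # order preserved up to float rounding: no sign inversions
        assert np.all(np.diff(y) * np.diff(values) >= 0.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rescale_unit_interval(np.full(10, 3.3))


def _toy_recording(samples, annotations, fs=20_000.0):
    return Recording(samples=np.asarray(samples, float), fs=fs,
                     annotations=tuple(annotations), snr=1.0, seed=0)


class TestSegment:
    def test_single_annotation_yields_centered_spike_window(self):
        values = np.linspace(0.0, 1.0, 200)
        rec = _toy_recording(values, [Annotation(100, 2)])
        ws = segment(rec, 56, values=values)
        spikes = [w for w in ws.windows() if w.label == "spike-2"]
        assert len(spikes) == 1
        start = spikes[0].source[1]
        assert start + 56 // 2 == 100  # center sample = annotation index
        np.testing.assert_array_equal(spikes[0].values, values[start:start + 56])

    def test_noise_only_recording_splits_into_consecutive_windows(self):
        values = np.linspace(0.0, 1.0, 560)
        rec = _toy_recording(values, [])
        ws = segment(rec, 56, values=values)
        assert ws.class_counts == {NOISE_LABEL: 10}
        starts = [s[1] for s in ws.sources]
        assert starts == [56 * i for i in range(10)]

    def test_window_duration_is_2_8_ms(self):
        assert 56 / 20_000.0 == pytest.approx(2.8e-3)

    def test_edge_annotations_dropped(self):
        values = np.linspace(0.0, 1.0, 100)
        rec = _toy_recording(values, [Annotation(5, 1), Annotation(60, 1)])
        ws = segment(rec, 56, values=values)
        assert ws.class_counts.get("spike-1", 0) == 1

    def test_windows_overlapping_two_classes_discarded(self):
        values = np.linspace(0.0, 1.0, 400)
        rec = _toy_recording(values, [Annotation(150, 1), Annotation(180, 2)])
        ws = segment(rec, 56, values=values)
        assert not any(lbl.startswith("spike") for lbl in ws.labels)

    def test_noise_windows_avoid_spike_support(self, short_recording):
        cfg, rec = short_recording
        ws = segment(rec, 56, support_len=cfg.support_samples)
        half = cfg.support_samples // 2
        spans = [(a.time_index - half, a.time_index - half + cfg.support_samples)
                 for a in rec.annotations]
        for w in ws.windows():
            if w.label != NOISE_LABEL:
                continue
            s = w.source[1]
            assert not any(s < hi and s + 56 > lo for lo, hi in spans)

    def test_roundtrip_values_match_source_slices(self, short_recording):
        cfg, rec = short_recording
        from spikeraster.preprocess import l2_normalize, rescale_unit_interval
        values = rescale_unit_interval(l2_normalize(rec.samples))
        ws = segment(rec, 56, values=values, support_len=cfg.support_samples)
        assert len(ws) > 0
        assert ws.values.min() >= 0.0 and ws.values.max() <= 1.0
        for w in ws.windows():
            np.testing.assert_array_equal(
                w.values, values[w.source[1]:w.source[1] + 56])

    def test_short_window_rejected(self):
        rec = _toy_recording(np.linspace(0, 1, 100), [])
        with pytest.raises(ValueError):
            segment(rec, 1)


def _windowset(counts: dict[str, int], n: int = 4) -> WindowSet:
    labels = [lbl for lbl, c in counts.items() for _ in range(c)]
    values = np.linspace(0, 1, len(labels) * n).reshape(len(labels), n)
    return WindowSet(values, labels, [("r", i) for i in range(len(labels))])


class TestBalanceNoise:
    def test_cap_arithmetic(self):
        ws = _windowset({"spike-1": 100, "spike-2": 100, "spike-3": 100,
                         NOISE_LABEL: 500})
        out = balance_noise(ws, cap_ratio=1.2, seed=0)
        assert out.class_counts[NOISE_LABEL] == 120
        assert all(out.class_counts[f"spike-{k}"] == 100 for k in (1, 2, 3))

    def test_noop_when_under_cap(self):
        ws = _windowset({"spike-1": 100, NOISE_LABEL: 90})
        out = balance_noise(ws, cap_ratio=1.2, seed=0)
        assert out.class_counts == ws.class_counts

    def test_table_like_ratio(self):
        # noise ~= 1.18 x mean spike count, as in the reference class balance
        ws = _windowset({"spike-1": 6423, "spike-2": 6595, "spike-3": 6597,
                         NOISE_LABEL: 9000}, n=2)
        out = balance_noise(ws, cap_ratio=1.18, seed=1)
        mean_spikes = (6423 + 6595 + 6597) / 3
        assert out.class_counts[NOISE_LABEL] == int(1.18 * mean_spikes)


class TestSplit:
    def test_thirty_percent_split_of_reference_total(self):
        ws = _windowset({"a": 27_371}, n=2)
        train, test = split(ws, SplitSpec(train_fraction=0.30, seed=0))
        assert len(train) == 8_211
        assert len(test) == 19_160

    def test_even_split(self):
        ws = _windowset({"a": 10}, n=2)
        train, test = split(ws, SplitSpec(train_fraction=0.5, seed=0))
        assert (len(train), len(test)) == (5, 5)

    def test_partition_disjoint_and_exhaustive(self):
        ws = _windowset({"a": 7, "b": 6}, n=3)
        train, test = split(ws, SplitSpec(train_fraction=0.4, seed=5))
        seen = sorted(train.sources + test.sources)
        assert seen == sorted(ws.sources)
        assert len(train) + len(test) == len(ws)
        assert not set(train.sources) & set(test.sources)

    def test_same_seed_same_partition(self):
        ws = _windowset({"a": 40}, n=2)
        first = split(ws, SplitSpec(seed=9))
        second = split(ws, SplitSpec(seed=9))
        assert first[0].sources == second[0].sources

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            split(WindowSet(np.empty((0, 4)), [], []), SplitSpec())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


def test_windowset_csv_roundtrip(tmp_path, short_recording):
    cfg, rec = short_recording
    ws = segment(rec, 56, support_len=cfg.support_samples)
    save_windowset(ws, tmp_path / "ws.csv")
    back = load_windowset(tmp_path / "ws.csv")
    np.testing.assert_allclose(back.values, ws.values, rtol=1e-9)
    assert back.labels == ws.labels
    assert back.sources == ws.sources


def test_binary_epoch_ingestion_binarizes_and_rescales(tmp_path):
    frame = simulate_binary_epochs(8, window_len=20, seed=4)
    # emulate the five-class labeling: relabel non-seizure rows to classes 2-5
    y = frame["y"].to_numpy().copy()
    y[y == 0] = 2 + (np.arange((y == 0).sum()) % 4)
    frame["y"] = y
    write_binary_epochs_csv(frame, tmp_path / "eeg.csv")
    ws = load_binary_epochs(tmp_path / "eeg.csv")
    assert set(ws.labels) == {"seizure", "non-seizure"}
    assert ws.labels.count("seizure") == 8
    assert ws.values.min() == 0.0 and ws.values.max() == pytest.approx(1.0)
    # per-row rescale: every row attains both bounds
    np.testing.assert_allclose(ws.values.max(axis=1), 1.0)
    np.testing.assert_allclose(ws.values.min(axis=1), 0.0)
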