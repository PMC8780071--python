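"""Alignment, cropping, spectra, standardisation, augmentation, splits."""

import dataclasses

import numpy as np
import pytest

from ripetap.preprocess import (Measurement, Standardiser, align_to_max,
                                augment_flips, build_features, crop_roi,
                                label_from_shelf_life, load_metadata_csv,
                                split_dataset, to_spectrum)
from ripetap.signal import TimeSignal
from ripetap.synthetic import write_dataset

FS = 44_100


def _measurement(samples, fruit_id="f0", zone=1, label=1, days=0):
    return Measurement(signal=TimeSignal(np.asarray(samples, float), FS),
                       fruit_id=fruit_id, shelf_life_days=days, zone=zone,
                       weight=1000.0, temperature=20.0, humidity=50.0,
                       label=label)


class TestAlign:
    def test_impulse_moved_to_target(self):
        x = np.zeros(200)
        x[37] = 1.0
        out = align_to_max(TimeSignal(x, FS), target_index=100)
        assert out.samples[100] == 1.0 and out.samples.sum() == 1.0
        assert len(out) == 200

    def test_already_aligned_unchanged(self):
        x = np.zeros(50)
        x[10] = -2.0  # absolute maximum
        out = align_to_max(TimeSignal(x, FS), target_index=10)
        assert np.array_equal(out.samples, x)

    def test_tie_breaks_to_earliest(self):
        x = np.zeros(60)
        x[5] = x[40] = 1.0
        out = align_to_max(TimeSignal(x, FS), target_index=20)
        assert out.samples[20] == 1.0
        # the later duplicate shifted along with the rest
        assert out.samples[55] == 1.0

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            align_to_max(TimeSignal(np.zeros(10), FS))


class TestCrop:
    def test_impulse_window(self):
        x = np.zeros(500)
        x[100] = 1.0
        out = crop_roi(TimeSignal(x, FS), pre_samples=10, post_samples=90,
                       center_index=100)
        assert len(out) == 100
        assert out.samples[10] == 1.0

    def test_equals_slice_of_input(self, rng):
        x = rng.normal(size=400)
        out = crop_roi(TimeSignal(x, FS), pre_samples=20, post_samples=80,
                       center_index=120)
        assert np.array_equal(out.samples, x[100:200])

    def test_out_of_bounds_pads_and_warns(self):
        x = np.ones(50)
        with pytest.warns(UserWarning, match="zero-padded"):
            out = crop_roi(TimeSignal(x, FS), pre_samples=10,
                           post_samples=90, center_index=10)
        assert len(out) == 100
        assert np.all(out.samples[50:] == 0)


class TestSpectrum:
    def test_dc_signal(self):
        amp, ph = to_spectrum(TimeSignal(np.full(64, 3.0), FS))
        assert amp[0] == pytest.approx(64 * 3.0)
        assert np.allclose(amp[1:], 0, atol=1e-9)
        assert amp.size == 33

    def test_bin_centred_cosine_matches_direct_dft(self, rng):
        n, k = 128, 7
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        amp, ph = to_spectrum(TimeSignal(x, FS))
        direct = np.fft.rfft(x)
        assert int(np.argmax(amp)) == k
        assert np.allclose(amp, np.abs(direct))
        assert np.allclose(ph, np.angle(direct))

    def test_phases_principal_range(self, rng):
        _, ph = to_spectrum(TimeSignal(rng.normal(size=100), FS))
        assert np.all(np.isfinite(ph))
        assert np.all((ph > -np.pi - 1e-12) & (ph <= np.pi + 1e-12))


class TestStandardiser:
    def test_train_is_standardised_to_itself(self, rng):
        amp = rng.normal(2, 3, (50, 8))
        ph = rng.normal(-1, 0.5, (50, 8))
        aux = rng.uniform(10, 20, (50, 3))
        std = Standardiser().fit(amp, ph, aux)
        a, p, x = std.transform(amp, ph, aux)
        assert np.allclose(a.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(a.std(axis=0), 1, atol=1e-9)
        assert np.allclose(p.std(axis=0), 1, atol=1e-9)
        assert x.min() >= 0 and x.max() <= 1

    def test_constant_component_maps_to_zero(self):
        amp = np.full((10, 2), 7.0)
        std = Standardiser().fit(amp, amp, amp)
        a, _, _ = std.transform(amp, amp, amp)
        assert np.allclose(a, 0)

    def test_heldout_uses_train_statistics(self, rng):
        train = rng.normal(0, 1, (40, 5))
        held = rng.normal(5, 2, (10, 5))
        std = Standardiser().fit(train, train, train)
        a, _, _ = std.transform(held, held, held)
        manual = (held - train.mean(axis=0)) / np.maximum(
            train.std(axis=0), 1e-8)
        assert np.allclose(a, manual)

    def test_unfitted_transform_rejected(self, rng):
        x = rng.normal(size=(3, 4))
        with pytest.raises(RuntimeError, match="before fit"):
            Standardiser().transform(x, x, x)

    def test_json_roundtrip(self, rng):
        x = rng.normal(size=(10, 4))
        std = Standardiser().fit(x, x, x)
        back = Standardiser.from_json(std.to_json())
        a1, _, _ = std.transform(x, x, x)
        a2, _, _ = back.transform(x, x, x)
        assert np.allclose(a1, a2)


class TestAugmentation:
    def test_flip_definitions(self):
        m = _measurement([1.0, 2.0, 3.0])
        out = augment_flips([m])
        signals = [v.signal.samples.tolist() for v in out]
        assert [1, 2, 3] in signals
        assert [-1, -2, -3] in signals          # vertical
        assert [3, 2, 1] in signals             # horizontal
        assert [-3, -2, -1] in signals          # both
        assert len(out) == 4

    def test_double_vertical_flip_is_identity(self):
        m = _measurement([1.0, -2.0, 0.5])
        once = augment_flips([m], vertical=True, horizontal=False)[1]
        twice = augment_flips([once], vertical=True, horizontal=False)[1]
        assert np.array_equal(twice.signal.samples, m.signal.samples)

    def test_counts_and_metadata_preserved(self):
        ms = [_measurement([1.0, 2.0], fruit_id=f"f{i}", label=2, zone=3)
              for i in range(5)]
        out = augment_flips(ms)
        assert len(out) == 20
        assert all(v.label == 2 and v.zone == 3 for v in out)


class TestSplit:
    @staticmethod
    def _fleet(n_fruits, per_fruit=4):
        return [_measurement(np.arange(1, 9.0), fruit_id=f"f{i:02d}")
                for i in range(n_fruits) for _ in range(per_fruit)]

    def test_equal_fruits_hit_exact_fractions(self):
        train, test, val = split_dataset(self._fleet(20), seed=3)
        fruits = lambda sub: {m.fruit_id for m in sub}
        assert (len(fruits(train)), len(fruits(test)), len(fruits(val))) \
            == (12, 5, 3)

    def test_deterministic_for_seed(self):
        a = split_dataset(self._fleet(10), seed=7)
        b = split_dataset(self._fleet(10), seed=7)
        for sa, sb in zip(a, b):
            assert [m.fruit_id for m in sa] == [m.fruit_id for m in sb]

    def test_no_fruit_in_two_subsets(self):
        train, test, val = split_dataset(self._fleet(11), seed=0)
        groups = [{m.fruit_id for m in s} for s in (train, test, val)]
        assert not (groups[0] & groups[1])
        assert not (groups[0] & groups[2])
        assert not (groups[1] & groups[2])
        assert len(train) + len(test) + len(val) == 44

    def test_too_few_fruits_rejected(self):
        with pytest.raises(ValueError, match="at least 3 fruits"):
            split_dataset(self._fleet(2))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(self._fleet(5), fractions=(0.5, 0.4, 0.2))


@pytest.mark.parametrize("days,expected", [
    (0, 1), (6, 1), (7, 2), (10, 2), (13, 2), (15, 3), (17, 3),
    (21, 4), (62, 4),
])
def test_label_from_shelf_life(days, expected):
    assert label_from_shelf_life(days) == expected


class TestPipeline:
    def test_feature_shapes_and_determinism(self, tiny_measurements):
        train, test, val = split_dataset(tiny_measurements, seed=1)
        split1, _ = build_features(train, test, val, pre_samples=32,
                                   post_samples=480)
        split2, _ = build_features(train, test, val, pre_samples=32,
                                   post_samples=480)
        assert split1.train.amplitude.shape[1] == 512 // 2 + 1
        assert split1.train.aux.shape[1] == 9
        assert np.array_equal(split1.train.amplitude, split2.train.amplitude)
        assert np.array_equal(split1.test.phase, split2.test.phase)

    def test_standardisation_fitted_on_train_only(self, tiny_measurements):
        train, test, val = split_dataset(tiny_measurements, seed=1)
        split, std = build_features(train, test, val, pre_samples=32,
                                    post_samples=480)
        assert np.allclose(split.train.amplitude.mean(axis=0), 0, atol=1e-9)
        assert not np.allclose(split.test.amplitude.mean(axis=0), 0, atol=1e-3)

    def test_max_freq_truncates_bins(self, tiny_measurements):
        train, test, val = split_dataset(tiny_measurements, seed=1)
        split, _ = build_features(train, test, val, pre_samples=32,
                                  post_samples=480, max_freq=2500.0)
        expected = int(2500.0 * 512 / FS) + 1
        assert split.train.amplitude.shape[1] == expected

    def test_csv_wav_roundtrip(self, tiny_measurements, tmp_path):
        subset = tiny_measurements[:6]
        csv_path = write_dataset(subset, tmp_path)
        back = load_metadata_csv(csv_path)
        assert len(back) == 6
        for orig, loaded in zip(subset, back):
            assert loaded.fruit_id == orig.fruit_id
            assert loaded.label == orig.label
            assert loaded.zone == orig.zone
            assert loaded.weight == pytest.approx(orig.weight, abs=0.01)
            assert np.allclose(loaded.signal.samples, orig.signal.samples,
                               atol=1e-7)

    def test_missing_metadata_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="metadata"):
            load_metadata_csv(tmp_path / "nope.csv")
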