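"""Five-zone encoder: normalization, range expansion, image rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualpathcnn.sensor import (
    DEFAULT_LAYOUT,
    PressureRange,
    SensorImageEncoder,
    SensorSpecimen,
    ZoneLayout,
    encode_dataset,
    encode_specimen,
    expand_pressure_range,
    normalize_parameters,
    read_specimens,
    write_specimens,
)


def make_specimen(doping=1.0, angle=30.0, force=2.0, pressure=50000.0,
                  current=4.0, label=0):
    return SensorSpecimen(doping, angle, force, pressure, current, label)


class TestNormalize:
    def test_single_specimen_maps_to_all_ones(self):
        (out,) = normalize_parameters([make_specimen()])
        assert out.values() == pytest.approx(np.ones(5))

    def test_max_scaling_by_hand(self):
        a = make_specimen(current=2.0)
        b = make_specimen(current=4.0)
        na, nb = normalize_parameters([a, b])
        assert na.current == pytest.approx(0.5)
        assert nb.current == pytest.approx(1.0)

    def test_no_value_exceeds_one(self):
        rng = np.random.default_rng(0)
        specimens = [
            make_specimen(*rng.uniform(0.1, 100, size=5), label=int(i % 5))
            for i in range(20)
        ]
        for s in normalize_parameters(specimens):
            assert (s.values() <= 1.0 + 1e-12).all()
            assert (s.values() >= 0.0).all()

    def test_all_zero_column_warns_and_stays_zero(self):
        specimens = [make_specimen(force=0.0), make_specimen(force=0.0, label=1)]
        with pytest.warns(UserWarning, match="force"):
            out = normalize_parameters(specimens)
        assert all(s.force == 0.0 for s in out)


class TestExpandPressureRange:
    def test_increment_295_over_590_gives_three_steps(self):
        s = make_specimen(pressure=PressureRange(0.0, 590.0, 295.0))
        expanded = expand_pressure_range(s)
        assert [e.pressure for e in expanded] == [0.0, 295.0, 590.0]

    def test_fractional_increment(self):
        s = make_specimen(pressure=PressureRange(0.0, 590.0, 147.5))
        assert len(expand_pressure_range(s)) == 5

    def test_degenerate_range_yields_one_specimen(self):
        s = make_specimen(pressure=PressureRange(100.0, 100.0, 295.0))
        assert len(expand_pressure_range(s)) == 1

    def test_other_fields_are_copied(self):
        s = make_specimen(pressure=PressureRange(0.0, 590.0), label=3)
        for e in expand_pressure_range(s):
            assert (e.doping_code, e.angle, e.force, e.current, e.label) == \
                (s.doping_code, s.angle, s.force, s.current, 3)

    def test_nonpositive_increment_rejected(self):
        with pytest.raises(ValueError):
            PressureRange(0.0, 10.0, 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        low=st.floats(0, 1e5, allow_nan=False),
        span=st.floats(0, 1e5, allow_nan=False),
        inc=st.floats(1.0, 1e4, allow_nan=False),
    )
    def test_cardinality_formula(self, low, span, inc):
        rng = PressureRange(low, low + span, inc)
        s = make_specimen(pressure=rng)
        expected = int(np.floor((rng.high - rng.low) / rng.increment)) + 1
        assert len(expand_pressure_range(s)) == expected


class TestZoneLayout:
    def test_default_zones_are_disjoint_and_inside_canvas(self):
        masks = DEFAULT_LAYOUT.masks()
        total = np.zeros(DEFAULT_LAYOUT.canvas, dtype=int)
        for m in masks:
            total += m
        assert total.max() == 1  # disjoint; background is the complement
        assert sum(m.sum() for m in masks) == 5 * 20 * 20

    def test_overlapping_zones_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ZoneLayout(zones=((0, 0, 20, 20), (10, 10, 20, 20), (0, 40, 20, 20),
                              (40, 0, 20, 20), (40, 40, 20, 20)))


class TestEncode:
    def test_all_zero_specimen_gives_black_image(self):
        img = encode_specimen(make_specimen(0, 0, 0, 0, 0))
        assert img.shape == (64, 64) and img.dtype == np.uint8
        assert (img == 0).all()

    def test_full_current_renders_zone5_white(self):
        img = encode_specimen(make_specimen(0, 0, 0, 0, 1.0))
        r, c, h, w = DEFAULT_LAYOUT.zones[4]
        assert (img[r:r + h, c:c + w] == 255).all()
        assert img.sum() == 255 * h * w  # nothing else lit

    def test_locality_of_zone_encoding(self):
        a = encode_specimen(make_specimen(0.5, 0.2, 0.5, 0.5, 0.5))
        b = encode_specimen(make_specimen(0.5, 0.9, 0.5, 0.5, 0.5))
        diff = a != b
        zone2 = np.zeros((64, 64), dtype=bool)
        r, c, h, w = DEFAULT_LAYOUT.zones[1]
        zone2[r:r + h, c:c + w] = True
        assert diff[zone2].all() and not diff[~zone2].any()

    def test_unnormalized_values_are_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            encode_specimen(make_specimen(current=4.0))

    def test_round_trip_zone_mean_within_quantization(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            vals = rng.uniform(0, 1, size=5)
            img = encode_specimen(make_specimen(*vals))
            for (r, c, h, w), v in zip(DEFAULT_LAYOUT.zones, vals):
                assert abs(img[r:r + h, c:c + w].mean() / 255.0 - v) <= 1 / 255

    def test_injective_on_quantized_grid(self):
        rng = np.random.default_rng(2)
        tuples = {tuple(np.floor(rng.uniform(0, 1, 5) * 255 + 0.5).astype(int))
                  for _ in range(50)}
        images = {}
        for q in tuples:
            img = encode_specimen(make_specimen(*(np.array(q) / 255.0)))
            images[img.tobytes()] = q
        assert len(images) == len(tuples)


class TestEncodeDataset:
    def test_counts_and_idempotence(self, tmp_path):
        specimens = normalize_parameters([make_specimen(label=i % 5) for i in range(3)])
        out = tmp_path / "imgs"
        table = encode_dataset(specimens, out_dir=out)
        assert len(table) == 3
        pngs = sorted(out.glob("*.png"))
        assert len(pngs) == 3
        first = [p.read_bytes() for p in pngs]
        encode_dataset(specimens, out_dir=out)
        assert [p.read_bytes() for p in sorted(out.glob("*.png"))] == first

    def test_range_expansion_multiplies_dataset(self, tmp_path):
        specimens = [
            make_specimen(pressure=PressureRange(1000.0 * i, 1000.0 * i + 2950.0, 295.0),
                          label=i % 5)
            for i in range(8)
        ]
        expanded = [e for s in specimens for e in expand_pressure_range(s)]
        assert len(expanded) == 8 * 11
        table = encode_dataset(normalize_parameters(expanded), out_dir=tmp_path / "d")
        assert len(table) == 88


def test_specimen_csv_round_trip(tmp_path):
    specimens = [
        make_specimen(label=1),
        make_specimen(pressure=PressureRange(10.0, 900.0, 295.0), label=4),
    ]
    path = tmp_path / "specimens.csv"
    write_specimens(specimens, path)
    again = read_specimens(path)
    assert again == specimens


class TestSensorImageEncoder:
    def test_transform_matches_functional_pipeline(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 10, size=(12, 5))
        enc = SensorImageEncoder().fit(X)
        images = enc.transform(X)
        specimens = [SensorSpecimen(*row, label=0) for row in X]
        expected = np.stack([encode_specimen(s) for s in normalize_parameters(specimens)])
        assert images.shape == (12, 64, 64)
        assert (images == expected).all()

    def test_values_beyond_training_max_clip_to_white(self):
        enc = SensorImageEncoder().fit(np.ones((2, 5)))
        img = enc.transform(np.full((1, 5), 7.0))[0]
        r, c, h, w = DEFAULT_LAYOUT.zones[0]
        assert (img[r:r + h, c:c + w] == 255).all()

    def test_sklearn_param_interface(self):
        enc = SensorImageEncoder()
        assert "layout" in enc.get_params()
        cloned = type(enc)(**enc.get_params())
        assert cloned.layout == enc.layout
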