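"""Tests for object detection, gate derivation and live counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from calcytox import (DetectionParams, Gate, GatingError, ImageSpec,
                      InvalidParameterError, count_live, derive_gate,
                      detect_objects, read_object_table, render_field,
                      write_object_table)
from calcytox.cytometry import OBJECT_COLUMNS
from calcytox.imaging import PlacedParticle, _accumulate_spot

from _oracles import brute_force_detect, sort_percentile


def synthetic_image(rng, shape=(64, 64), n_blobs=None, offset=100.0):
    """Random blobby test image: Poisson background plus Gaussian spots."""
    expected = np.zeros(shape)
    n_blobs = rng.poisson(4) if n_blobs is None else n_blobs
    for _ in range(n_blobs):
        _accumulate_spot(expected,
                         total=float(rng.uniform(500, 6000)),
                         row=float(rng.uniform(5, shape[0] - 5)),
                         col=float(rng.uniform(5, shape[1] - 5)),
                         sigma=float(rng.uniform(0.7, 2.0)))
    img = rng.poisson(expected + offset)
    return np.clip(img, 0, 65535).astype(np.uint16)


def table_from_intensities(intensities, diameter=12.0):
    n = len(intensities)
    return pd.DataFrame({
        "label": np.arange(1, n + 1),
        "area_px": np.full(n, 30),
        "equiv_diameter_um": np.full(n, diameter),
        "centroid_row": np.zeros(n),
        "centroid_col": np.zeros(n),
        "integrated_intensity": np.asarray(intensities, dtype=float),
    })


class TestDetectObjects:
    def test_constant_image_warns_and_returns_empty(self):
        img = np.full((64, 64), 100, dtype=np.uint16)
        with pytest.warns(UserWarning):
            table = detect_objects(img, DetectionParams(), um_per_px=1.0)
        assert table.empty
        assert list(table.columns) == OBJECT_COLUMNS

    def test_two_separated_cells_measured_to_one_percent(self):
        spec = ImageSpec(width_px=256, height_px=256, shot_noise=False,
                         read_noise_sd=0.0)
        placed = [
            PlacedParticle(0, "live_cell", 80.0, 16.0, 64.0, 64.0),
            PlacedParticle(1, "live_cell", 120.0, 16.0, 180.0, 190.0),
        ]
        img = render_field(placed, spec, seed=0)
        table = detect_objects(img)
        assert len(table) == 2
        truth = img.truth.sort_values("x_px")["true_total_counts"].to_numpy()
        got = table.sort_values("centroid_col")["integrated_intensity"].to_numpy()
        np.testing.assert_allclose(got, truth, rtol=0.01)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_flood_fill(self, connectivity):
        rng = np.random.default_rng(12)
        params = DetectionParams(connectivity=connectivity,
                                 min_diameter_um=0.0)
        for _ in range(15):
            img = synthetic_image(rng)
            table = detect_objects(img, params, um_per_px=1.0)
            oracle = brute_force_detect(img, connectivity=connectivity)
            assert len(table) == len(oracle)
            table = table.sort_values(
                ["centroid_row", "centroid_col"], ignore_index=True)
            oracle = sorted(oracle, key=lambda d: d["centroid"])
            for (_, row), ref in zip(table.iterrows(), oracle):
                assert row["area_px"] == ref["area"]
                assert row["integrated_intensity"] == pytest.approx(
                    ref["intensity"], rel=1e-9)

    def test_otsu_threshold_detects_bright_blob(self):
        rng = np.random.default_rng(3)
        img = synthetic_image(rng, n_blobs=3)
        table = detect_objects(img, DetectionParams(threshold_method="otsu"),
                               um_per_px=1.0)
        assert len(table) >= 1

    def test_size_cutoff_drops_small_objects(self):
        rng = np.random.default_rng(5)
        img = synthetic_image(rng, n_blobs=5)
        loose = detect_objects(
            img, DetectionParams(min_diameter_um=0.0), um_per_px=1.0)
        tight = detect_objects(
            img, DetectionParams(min_diameter_um=3.0), um_per_px=1.0)
        assert set(tight["label"]) <= set(loose["label"])
        assert (tight["equiv_diameter_um"] >= 3.0).all()

    def test_um_per_px_required_for_bare_arrays(self):
        with pytest.raises(InvalidParameterError):
            detect_objects(np.zeros((8, 8)), DetectionParams())


class TestDeriveGate:
    def test_q_zero_equals_pooled_minimum(self):
        table = table_from_intensities([500.0, 900.0, 1500.0])
        gate = derive_gate([table], q=0.0)
        assert gate.min_integrated_intensity == 500.0

    def test_degenerate_distribution_gate_is_the_value(self):
        table = table_from_intensities([1000.0] * 8)
        for q in (0.0, 5.0, 50.0, 100.0):
            assert derive_gate([table], q=q).min_integrated_intensity == 1000.0

    def test_matches_sort_based_percentile_oracle(self):
        values = np.arange(1.0, 1001.0)
        rng = np.random.default_rng(0)
        rng.shuffle(values)
        gate = derive_gate([table_from_intensities(values)], q=5.0)
        assert gate.min_integrated_intensity == pytest.approx(
            sort_percentile(values, 5.0), abs=1.0)

    def test_pooling_across_wells(self):
        t1 = table_from_intensities([100.0, 200.0])
        t2 = table_from_intensities([300.0, 400.0])
        gate = derive_gate([t1, t2], q=0.0)
        assert gate.min_integrated_intensity == 100.0

    def test_diameter_prefilter_applies_before_percentile(self):
        small = table_from_intensities([10.0, 20.0], diameter=0.5)
        big = table_from_intensities([1000.0, 2000.0], diameter=12.0)
        gate = derive_gate([pd.concat([small, big], ignore_index=True)],
                           q=0.0, min_diameter_um=1.0)
        assert gate.min_integrated_intensity == 1000.0

    def test_empty_pool_raises_gating_error(self):
        with pytest.raises(GatingError):
            derive_gate([table_from_intensities([])], q=5.0)


class TestCountLive:
    def test_all_above_gate(self):
        table = table_from_intensities([100.0, 200.0, 300.0])
        assert count_live(table, Gate(50.0)) == 3

    def test_threshold_between_values(self):
        table = table_from_intensities([10.0, 20.0, 30.0])
        assert count_live(table, Gate(15.0)) == 2

    def test_boundary_is_inclusive(self):
        table = table_from_intensities([10.0, 20.0, 30.0])
        assert count_live(table, Gate(20.0)) == 2

    def test_diameter_bound_also_applies(self):
        table = pd.concat([table_from_intensities([500.0], diameter=0.5),
                           table_from_intensities([500.0], diameter=12.0)],
                          ignore_index=True)
        assert count_live(table, Gate(100.0, min_diameter_um=1.0)) == 1

    @given(st.lists(st.floats(0, 1e5), min_size=1, max_size=30),
           st.floats(0, 1e5), st.floats(0, 1e4))
    def test_raising_gate_never_increases_count(self, values, cut, bump):
        table = table_from_intensities(values)
        low = count_live(table, Gate(cut))
        high = count_live(table, Gate(cut + bump))
        assert high <= low

    @given(st.lists(st.floats(1, 1e5), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_object_order_is_irrelevant(self, values, rnd):
        table = table_from_intensities(values)
        shuffled = table.sample(frac=1.0, random_state=rnd.randint(0, 2**16))
        gate = derive_gate([table], q=5.0)
        gate2 = derive_gate([shuffled], q=5.0)
        assert gate.min_integrated_intensity == pytest.approx(
            gate2.min_integrated_intensity)
        assert count_live(table, gate) == count_live(shuffled, gate)


class TestSerialization:
    def test_object_table_roundtrip(self, tmp_path):
        table = table_from_intensities([1.5, 2.5, 3.5])
        path = write_object_table(table, tmp_path / "objects.csv")
        back = read_object_table(path)
        pd.testing.assert_frame_equal(
            back, table[OBJECT_COLUMNS], check_dtype=False)

    def test_gate_json_roundtrip(self, tmp_path):
        gate = Gate(1234.5, min_diameter_um=1.0, percentile_q=5.0)
        gate.to_json(tmp_path / "gate.json")
        assert Gate.from_json(tmp_path / "gate.json") == gate
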