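"""Tests for field sampling, spot rendering and the camera noise model."""

import numpy as np
import pytest
from scipy.stats import binom

from calcytox import (ImageSpec, InvalidParameterError, acquire_fields,
                      read_field, render_field, sample_field, write_field)
from calcytox.assay import APOPTOTIC_BODY, LIVE_CELL
from calcytox.imaging import PLACEMENT_PADDING, PlacedParticle, spot_sigma_px

from conftest import make_well


def place(calcein, row, col, diameter=16.0, kind=LIVE_CELL, pid=0):
    return PlacedParticle(particle_id=pid, kind=kind, calcein=calcein,
                          diameter_um=diameter, row_px=row, col_px=col)


class TestSampleField:
    def test_full_fraction_retains_all_particles(self, params):
        state = make_well("spontaneous", n=300, seed=2, params=params)
        spec = ImageSpec(sampled_fraction=1.0)
        placed = sample_field(state, spec, seed=0)
        assert len(placed) == 300

    def test_retention_is_binomial(self, params):
        # small cells keep the single frame dilute at this particle count
        small = params.replace(live_diameter_um=5.0, body_diameter_um=4.0)
        state = make_well("spontaneous", n=10_000, seed=3, params=small)
        spec = ImageSpec(sampled_fraction=0.2)
        counts = [len(sample_field(state, spec, seed=s)) for s in range(20)]
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.2)
        assert sum(lo <= c <= hi for c in counts) >= 18

    def test_empty_well_yields_empty_field(self, params):
        state = make_well("maximum", n=100, seed=0, params=params)
        assert sample_field(state, ImageSpec(), seed=0) == []


class TestAcquireFields:
    def test_adds_frames_to_stay_dilute(self, params):
        state = make_well("spontaneous", n=10_000, seed=1, params=params)
        spec = ImageSpec()  # 0.4 sampling -> ~4000 cells, several frames
        fields = acquire_fields(state, spec, seed=0)
        assert len(fields) > 1
        interior = (spec.height_px - 1 - 2 * spec.edge_margin_px) ** 2
        for fi in fields:
            # frame fill stays below the configured ceiling
            rad = np.array([max(PLACEMENT_PADDING * d / spec.um_per_px / 2,
                                2.0)
                            for d in [16.0] * len(fi.truth)])
            assert np.pi * (rad ** 2).sum() <= spec.max_fill_fraction \
                * interior * 1.05

    def test_total_rendered_count_is_binomial_over_frames(self, params):
        state = make_well("spontaneous", n=4_000, seed=2, params=params)
        spec = ImageSpec()
        totals = [sum(len(fi.truth) for fi in
                      acquire_fields(state, spec, seed=s))
                  for s in range(6)]
        lo, hi = binom.ppf([0.0025, 0.9975], 4_000, spec.sampled_fraction)
        assert all(lo <= t <= hi for t in totals)

    def test_deterministic_for_fixed_seed(self, params):
        state = make_well("test", et=1.0, n=2000, seed=3, params=params)
        spec = ImageSpec()
        a = acquire_fields(state, spec, seed=9)
        b = acquire_fields(state, spec, seed=9)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.pixels, fb.pixels)

    def test_empty_well_gives_single_blank_frame(self, params):
        state = make_well("maximum", n=50, seed=0, params=params)
        fields = acquire_fields(state, ImageSpec(), seed=1)
        assert len(fields) == 1 and fields[0].truth.empty

    def test_minimum_separation_and_margin(self, params):
        state = make_well("test", et=1.0, n=4000, seed=5, params=params)
        spec = ImageSpec(sampled_fraction=0.05)  # dilute single frame
        placed = sample_field(state, spec, seed=1)
        pos = np.array([(p.row_px, p.col_px) for p in placed])
        rad = np.array([PLACEMENT_PADDING * p.diameter_um / 2
                        / spec.um_per_px for p in placed])
        assert pos.min() >= spec.edge_margin_px
        assert pos[:, 0].max() <= spec.height_px - 1 - spec.edge_margin_px
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        need = (rad[:, None] + rad[None, :]) ** 2
        np.fill_diagonal(d2, np.inf)
        assert (d2 >= need * (1 - 1e-12)).all()


class TestRenderField:
    def test_background_only_poisson_mean(self):
        spec = ImageSpec(width_px=256, height_px=256, read_noise_sd=0.0,
                         background_offset=100.0)
        img = render_field([], spec, seed=4)
        assert abs(img.pixels.mean() - 100.0) / 100.0 < 0.01
        assert img.truth.empty

    def test_single_particle_integrated_signal(self):
        # total signal 50 AU x gain 20 = 1000 counts; Poisson total ~ N(1000, ~1000)
        spec = ImageSpec(width_px=128, height_px=128, gain=20.0,
                         background_offset=100.0, read_noise_sd=0.0)
        sums = []
        for seed in range(10):
            img = render_field([place(50.0, 64.0, 64.0, diameter=4.0)],
                               spec, seed=seed)
            window = img.pixels[54:75, 54:75].astype(float)
            sums.append(window.sum() - 100.0 * window.size)
        sd = np.sqrt(1000 + 100 * 441)  # Poisson on spot + background window
        assert all(abs(s - 1000) < 3 * sd for s in sums)

    def test_saturation_clips_without_wraparound(self):
        spec = ImageSpec(width_px=64, height_px=64, gain=1e7)
        img = render_field([place(1e4, 32.0, 32.0, diameter=4.0)], spec,
                           seed=0)
        assert img.pixels.max() == 65535
        assert img.pixels.dtype == np.uint16

    def test_noiseless_render_conserves_signal(self):
        spec = ImageSpec(width_px=256, height_px=256, shot_noise=False,
                         read_noise_sd=0.0, gain=150.0)
        placed = [place(80.0, 64.0, 64.0), place(120.0, 180.0, 90.0),
                  place(12.0, 128.0, 200.0, diameter=4.0,
                        kind=APOPTOTIC_BODY)]
        img = render_field(placed, spec, seed=0)
        measured = img.pixels.astype(float).sum() - spec.background_offset * 256 * 256
        expected = spec.gain * sum(p.calcein for p in placed)
        assert abs(measured - expected) / expected < 0.005

    def test_truth_records_noiseless_totals(self, image_spec):
        placed = [place(80.0, 100.0, 100.0, pid=0),
                  place(5.0, 200.0, 200.0, diameter=4.0,
                        kind=APOPTOTIC_BODY, pid=1)]
        img = render_field(placed, image_spec, seed=1)
        assert len(img.truth) == 2
        np.testing.assert_allclose(
            img.truth["true_total_counts"],
            [image_spec.gain * 80.0, image_spec.gain * 5.0])

    def test_bodies_dimmer_and_smaller_than_live_cells(self, params):
        state = make_well("test", et=2.0, n=4000, seed=9, params=params)
        spec = ImageSpec()
        img = render_field(sample_field(state, spec, seed=2), spec, seed=3)
        truth = img.truth
        live = truth[truth["kind"] == LIVE_CELL]["true_total_counts"]
        body = truth[truth["kind"] == APOPTOTIC_BODY]["true_total_counts"]
        assert len(live) and len(body)
        assert body.max() < live.mean()

    def test_same_seed_bitwise_identical(self, params):
        state = make_well("spontaneous", n=500, seed=7, params=params)
        spec = ImageSpec()
        a = render_field(sample_field(state, spec, seed=11), spec, seed=12)
        b = render_field(sample_field(state, spec, seed=11), spec, seed=12)
        assert np.array_equal(a.pixels, b.pixels)

    def test_spot_sigma_contract(self):
        spec = ImageSpec(psf_sigma_um=1.0, um_per_px=2.0)
        assert spot_sigma_px(16.0, spec) == pytest.approx(2.0)  # d/4 wins
        assert spot_sigma_px(2.0, spec) == pytest.approx(0.5)  # psf floor


class TestFieldIO:
    def test_tiff_and_truth_roundtrip(self, tmp_path, params):
        state = make_well("spontaneous", n=200, seed=4, params=params)
        spec = ImageSpec()
        img = render_field(sample_field(state, spec, seed=5), spec, seed=6)
        path = write_field(img, tmp_path / "well.tiff")
        back = read_field(path, spec)
        assert np.array_equal(back.pixels, img.pixels)
        assert len(back.truth) == len(img.truth)
        np.testing.assert_allclose(back.truth["true_total_counts"],
                                   img.truth["true_total_counts"])

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            ImageSpec(sampled_fraction=0.0)
        with pytest.raises(InvalidParameterError):
            ImageSpec(bit_depth=12)
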