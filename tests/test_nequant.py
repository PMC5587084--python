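"""NE-enrichment quantification tests: band geometry, the intensity-ratio
statistic, baseline normalization, and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernetics import nequant, synthkit
from ernetics.core import (BandDegenerate, CellGeometry, ImagingConfig,
                          NoNucleusFound, NoSignal)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[1]) ** 2 + (yy - center[0]) ** 2 <= radius ** 2


class TestBandSpec:
    def test_pixel_widths_at_115nm_sampling(self):
        spec = nequant.NEBandSpec(230, 920, 115)
        assert spec.out_px == 2 and spec.in_px == 8

    def test_minimum_one_pixel(self):
        spec = nequant.NEBandSpec(230, 920, 600)
        assert spec.out_px == 1 and spec.in_px == 2

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            nequant.NEBandSpec(0, 920, 100)


class TestBuildBand:
    def test_circular_band_area_matches_analytic_annulus(self):
        """r = 8 um nucleus at 100 nm sampling: band area within 10% of
        pi*((r+0.23)^2 - (r-0.92)^2)."""
        mask = disk_mask((200, 200), (100, 100), 80)  # 8 um at 100 nm px
        band, _ = nequant.build_ne_band(mask, nequant.NEBandSpec(230, 920, 100))
        area = band.sum() * 0.01  # um^2 per px
        analytic = np.pi * ((8 + 0.23) ** 2 - (8 - 0.92) ** 2)
        assert area == pytest.approx(analytic, rel=0.10)

    def test_band_disjoint_from_interior(self):
        mask = disk_mask((80, 80), (40, 40), 25)
        band, interior = nequant.build_ne_band(
            mask, nequant.NEBandSpec(230, 920, 100))
        assert not np.any(band & interior)

    def test_erosion_emptying_mask_raises(self):
        mask = disk_mask((40, 40), (20, 20), 5)
        with pytest.raises(BandDegenerate):
            nequant.build_ne_band(mask, nequant.NEBandSpec(230, 920, 100))


class TestComputeFraction:
    def test_all_signal_in_band_gives_one(self):
        img = np.zeros((40, 40))
        band = disk_mask((40, 40), (20, 20), 5)
        er = disk_mask((40, 40), (5, 5), 3)
        img[band] = 7.0
        m = nequant.compute_ne_fraction(img, band, er)
        assert m.fraction == 1.0

    def test_uniform_intensity_gives_area_ratio(self):
        img = np.full((40, 40), 3.0)
        band = disk_mask((40, 40), (20, 20), 5)
        er = disk_mask((40, 40), (8, 8), 4) & ~band
        m = nequant.compute_ne_fraction(img, band, er)
        assert m.fraction == pytest.approx(
            band.sum() / (band.sum() + er.sum()))

    def test_zero_signal_raises(self):
        img = np.zeros((40, 40))
        band = disk_mask((40, 40), (20, 20), 5)
        er = disk_mask((40, 40), (8, 8), 4)
        with pytest.raises(NoSignal):
            nequant.compute_ne_fraction(img, band, er)

    def test_integrated_sums_match_per_pixel_oracle(self):
        """Hand-built 16x16 masks: i_ne/i_er equal brute-force loops."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (16, 16))
        band = np.zeros((16, 16), bool)
        band[4:6, :] = True
        er = np.zeros((16, 16), bool)
        er[10:13, 2:9] = True
        m = nequant.compute_ne_fraction(img, band, er, background_level=1.0)
        i_ne = sum(max(img[r, c] - 1.0, 0.0) for r in range(16)
                   for c in range(16) if band[r, c])
        i_er = sum(max(img[r, c] - 1.0, 0.0) for r in range(16)
                   for c in range(16) if er[r, c])
        assert m.i_ne == pytest.approx(i_ne)
        assert m.i_er == pytest.approx(i_er)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        img = np.zeros((30, 30))
        band = disk_mask((30, 30), (15, 15), 4)
        er = disk_mask((30, 30), (6, 6), 3)
        img[band] = 2.0
        img[er] = 5.0
        f1 = nequant.compute_ne_fraction(img, band, er).fraction
        f2 = nequant.compute_ne_fraction(img * c, band, er).fraction
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_moving_signal_into_band_increases_fraction(self):
        img = np.zeros((30, 30))
        band = disk_mask((30, 30), (15, 15), 4)
        er = disk_mask((30, 30), (6, 6), 3)
        img[band] = 2.0
        img[er] = 5.0
        f1 = nequant.compute_ne_fraction(img, band, er).fraction
        img2 = img.copy()
        r, c = np.argwhere(er)[0]
        img2[r, c] -= 3.0
        img2[np.argwhere(band)[0][0], np.argwhere(band)[0][1]] += 3.0
        f2 = nequant.compute_ne_fraction(img2, band, er).fraction
        assert f2 > f1


class TestNormalizeToBaseline:
    @pytest.mark.parametrize("frac,baseline,expected", [
        (0.16, 0.16, 0.0),
        (1.0, 0.16, 100.0),
        (0.58, 0.16, 50.0),
    ])
    def test_affine_examples(self, frac, baseline, expected):
        assert nequant.normalize_to_baseline(frac, baseline) == \
            pytest.approx(expected)

    def test_below_baseline_clamps_to_zero(self):
        assert nequant.normalize_to_baseline(0.05, 0.16) == 0.0

    def test_baseline_of_one_rejected(self):
        with pytest.raises(ValueError):
            nequant.normalize_to_baseline(0.5, 1.0)

    def test_ratio_mode(self):
        assert nequant.normalize_to_baseline(0.32, 0.16, mode="ratio") == \
            pytest.approx(200.0)


class TestSegmentNucleus:
    def test_rendered_ellipse_iou(self, clean_config, geometry, base_graph):
        img, _ = synthkit.render_cell(geometry, base_graph, 0.5, 1e5,
                                      clean_config, seed=1)
        masks = nequant.segment_nucleus(img.channel("dapi"), 100)
        truth = geometry.nucleus_mask(160, 160, 0.1)
        iou = (masks[0] & truth).sum() / (masks[0] | truth).sum()
        assert iou >= 0.95

    def test_blank_image_raises(self):
        with pytest.raises(NoNucleusFound):
            nequant.segment_nucleus(np.zeros((64, 64)), 100)

    def test_two_nuclei_give_two_masks(self):
        img = np.zeros((120, 200))
        img[disk_mask((120, 200), (60, 50), 30)] = 10.0
        img[disk_mask((120, 200), (60, 150), 30)] = 10.0
        masks = nequant.segment_nucleus(img, 100)
        assert len(masks) == 2

    def test_small_specks_discarded(self):
        img = np.zeros((120, 120))
        img[disk_mask((120, 120), (60, 60), 30)] = 10.0
        img[5:7, 5:7] = 10.0
        masks = nequant.segment_nucleus(img, 100, min_area_um2=5.0)
        assert len(masks) == 1


class TestErMask:
    def test_covers_true_tubules(self, clean_config, geometry, base_graph):
        img, _ = synthkit.render_cell(geometry, base_graph, 0.5, 2e6,
                                      clean_config, seed=2)
        spec = nequant.NEBandSpec(pixel_size_nm=100)
        nuc = geometry.nucleus_mask(160, 160, 0.1)
        er = nequant.er_mask_from_reporter(img.channel("gfp"), nuc, spec)
        # true tubule pixels: nonzero in an ER-only render
        er_only, _ = synthkit.render_cell(geometry, base_graph, 0.0, 2e6,
                                          clean_config, seed=2)
        truth = er_only.channel("gfp") > 0
        band, interior = nequant.build_ne_band(nuc, spec)
        from scipy import ndimage
        near_ne = ndimage.binary_dilation(band | interior, iterations=3)
        truth &= ~near_ne
        assert (er & truth).sum() / truth.sum() >= 0.8

    def test_blank_reporter_raises(self):
        nuc = disk_mask((80, 80), (40, 40), 25)
        with pytest.raises(NoSignal):
            nequant.er_mask_from_reporter(np.zeros((80, 80)), nuc,
                                          nequant.NEBandSpec(pixel_size_nm=100))

    def test_disjoint_from_band(self, clean_config, geometry, base_graph):
        img, _ = synthkit.render_cell(geometry, base_graph, 0.5, 2e6,
                                      clean_config, seed=3)
        spec = nequant.NEBandSpec(pixel_size_nm=100)
        nuc = geometry.nucleus_mask(160, 160, 0.1)
        er = nequant.er_mask_from_reporter(img.channel("gfp"), nuc, spec)
        band, _ = nequant.build_ne_band(nuc, spec)
        assert not np.any(er & band)


class TestGolgi:
    def test_all_signal_in_golgi_gives_one(self):
        img = np.zeros((50, 50))
        golgi = disk_mask((50, 50), (25, 25), 5)
        img[golgi] = 4.0
        assert nequant.golgi_enrichment(img, golgi)["fraction"] == 1.0

    def test_uniform_image_gives_area_ratio(self):
        img = np.ones((50, 50))
        golgi = disk_mask((50, 50), (25, 25), 5)
        out = nequant.golgi_enrichment(img, golgi)
        assert out["fraction"] == pytest.approx(golgi.sum() / 2500.0)

    def test_two_compartment_exit_series_is_monotone(self):
        """Golgi fraction of a first-order ER->Golgi exit model rises
        monotonically to its plateau."""
        golgi = disk_mask((50, 50), (25, 25), 5)
        cell = np.ones((50, 50), bool)
        k = 0.2
        fracs = []
        for t in np.arange(0, 20, 2.0):
            g_amt = 1.0 - np.exp(-k * t)
            img = np.zeros((50, 50))
            img[cell] = (1.0 - g_amt) / (cell.sum() - golgi.sum())
            img[golgi] = g_amt / golgi.sum()
            fracs.append(nequant.golgi_enrichment(img, golgi, cell)["fraction"])
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_zero_intensity_raises(self):
        with pytest.raises(NoSignal):
            nequant.golgi_enrichment(np.zeros((20, 20)),
                                     disk_mask((20, 20), (10, 10), 3))
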