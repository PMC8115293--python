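"""Spheroid invasion pipeline: projection, flatfield, segmentation, metrics."""

import numpy as np
import pytest

from ecmquant import synthgen
from ecmquant.spheroid import (
    SpheroidSegmentation,
    detect_single_cells,
    flatfield_correct,
    gaussian_blur,
    invasive_area_pct,
    max_project,
    quantify_spheroid,
    segment_spheroid,
)


class TestMaxProject:
    def test_single_slice_identity(self):
        img = np.random.default_rng(0).random((16, 16))
        assert np.array_equal(max_project([img]), img)

    def test_constant_slices(self):
        out = max_project([np.full((4, 4), 3.0), np.full((4, 4), 7.0)])
        assert np.array_equal(out, np.full((4, 4), 7.0))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        stack = [rng.random((12, 9)) for _ in range(5)]
        expected = np.array(
            [[max(s[i, j] for s in stack) for j in range(9)] for i in range(12)]
        )
        assert np.array_equal(max_project(stack), expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            max_project([np.zeros((4, 4)), np.zeros((5, 4))])


class TestFlatfield:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 5.0)
        assert np.allclose(flatfield_correct(img), img)

    def test_preserves_mean(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64)) + 1.0
        out = flatfield_correct(img)
        assert out.mean() == pytest.approx(img.mean(), rel=0.01)

    def test_ramp_cv_reduced_fivefold(self):
        """A planar illumination ramp over a flat field is largely removed."""
        shading = synthgen._illumination_ramp((128, 128), 0.4, np.random.default_rng(3))
        img = 10.0 * shading
        out = flatfield_correct(img)
        cv = lambda a: a.std() / a.mean()
        assert cv(img) / cv(out) >= 5

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(4)
        shading = synthgen._illumination_ramp((64, 64), 0.3, rng)
        img = (rng.random((64, 64)) + 2.0) * shading
        once = flatfield_correct(img)
        twice = flatfield_correct(once)
        assert np.max(np.abs(twice - once)) / once.mean() < 0.01

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            flatfield_correct(np.zeros((8, 8)))


class TestGaussianBlur:
    def test_constant_preserved(self):
        assert np.allclose(gaussian_blur(np.full((16, 16), 2.5)), 2.5)

    def test_delta_kernel_unit_mass(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        assert gaussian_blur(img, 2.0).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_convolution(self):
        """Interior pixels agree with explicit convolution against the kernel."""
        rng = np.random.default_rng(5)
        img = rng.random((16, 16))
        sigma = 2.0
        r = 8
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        kernel = np.outer(k1, k1)
        kernel /= kernel.sum()
        out = gaussian_blur(img, sigma)
        # brute-force value at the centre pixel (far enough from edges after padding)
        pad = np.pad(img, r, mode="symmetric")  # scipy's 'reflect' convention
        expected = float((pad[8 : 8 + 2 * r + 1, 8 : 8 + 2 * r + 1] * kernel).sum())
        assert out[8, 8] == pytest.approx(expected, abs=1e-6)


class TestSegmentation:
    def test_clean_disc_no_halo(self):
        spec = synthgen.SpheroidSpec(
            halo_cell_count=0, single_cell_count=0, snr=np.inf,
            illumination_gradient_amplitude=0.0, seed=3,
        )
        stack, truth = synthgen.make_spheroid_image(spec)
        img = gaussian_blur(flatfield_correct(max_project(stack)))
        seg = segment_spheroid(img)
        assert seg.invasion_mask.sum() == 0
        assert seg.core_mask.sum() == pytest.approx(truth.core_area_px2, rel=0.05)

    def test_disc_plus_halo_recovers_coverage(self, clean_spheroid):
        spec, stack, truth = clean_spheroid
        img = gaussian_blur(flatfield_correct(max_project(stack)))
        seg = segment_spheroid(img, nucleus_radius_px=spec.nucleus_radius_px)
        assert seg.invasion_mask.sum() == pytest.approx(truth.halo_area_px2, rel=0.15)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="no spheroid"):
            segment_spheroid(np.random.default_rng(0).normal(0, 0.01, (64, 64)))

    def test_masks_disjoint_and_perimeter_thin(self, clean_spheroid):
        spec, stack, _ = clean_spheroid
        img = gaussian_blur(flatfield_correct(max_project(stack)))
        seg = segment_spheroid(img, nucleus_radius_px=spec.nucleus_radius_px)
        assert not np.any(seg.core_mask & seg.invasion_mask)
        union = seg.core_mask | seg.invasion_mask
        assert np.all(seg.perimeter_mask <= union)

    def test_intensity_rescale_invariance(self, clean_spheroid):
        """Masks are exactly invariant under positive intensity scaling."""
        spec, stack, _ = clean_spheroid
        img = gaussian_blur(flatfield_correct(max_project(stack)))
        seg1 = segment_spheroid(img, nucleus_radius_px=spec.nucleus_radius_px)
        seg2 = segment_spheroid(3.7 * img, nucleus_radius_px=spec.nucleus_radius_px)
        assert np.array_equal(seg1.core_mask, seg2.core_mask)
        assert np.array_equal(seg1.invasion_mask, seg2.invasion_mask)


class TestInvasiveAreaPct:
    @staticmethod
    def _seg(core_n, inv_n):
        core = np.zeros((40, 40), bool)
        inv = np.zeros((40, 40), bool)
        core.ravel()[:core_n] = True
        inv.ravel()[core_n : core_n + inv_n] = True
        return SpheroidSegmentation(core, inv, np.zeros((40, 40), bool), (0.0, 0.0))

    @pytest.mark.parametrize("core,inv,expected", [(100, 0, 0.0), (100, 100, 50.0), (300, 100, 25.0)])
    def test_definition(self, core, inv, expected):
        assert invasive_area_pct(self._seg(core, inv)) == expected

    def test_core_only_denominator_option(self):
        assert invasive_area_pct(self._seg(200, 100), total="core") == 50.0

    def test_empty_masks_rejected(self):
        with pytest.raises(ValueError):
            invasive_area_pct(self._seg(0, 0))


class TestSingleCellDetection:
    def test_zero_planted_zero_detected(self):
        spec = synthgen.SpheroidSpec(single_cell_count=0, seed=12)
        stack, _ = synthgen.make_spheroid_image(spec)
        m, _ = quantify_spheroid(stack)
        assert m.single_cell_count == 0

    def test_planted_singles_recovered(self, clean_spheroid):
        from ecmquant.spheroid import centroid_match_f1

        spec, stack, truth = clean_spheroid
        m, _ = quantify_spheroid(stack, nucleus_radius_px=spec.nucleus_radius_px)
        assert m.single_cell_count == pytest.approx(25, abs=3)
        f1 = centroid_match_f1(
            truth.single_cell_centroids, m.single_cell_centroids, spec.nucleus_radius_px
        )
        assert f1 >= 0.9

    def test_detections_outside_spheroid(self, clean_spheroid):
        spec, stack, _ = clean_spheroid
        m, seg = quantify_spheroid(stack, nucleus_radius_px=spec.nucleus_radius_px)
        for x, y in m.single_cell_centroids:
            assert not seg.union[int(round(y)), int(round(x))]

    def test_doubling_planted_singles_increases_count(self):
        counts = []
        for n in (25, 50):
            spec = synthgen.SpheroidSpec(single_cell_count=n, seed=13)
            stack, _ = synthgen.make_spheroid_image(spec)
            img = gaussian_blur(flatfield_correct(max_project(stack)))
            seg = segment_spheroid(img)
            c, _ = detect_single_cells(img, seg)
            counts.append(c)
        assert counts[1] > counts[0]
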