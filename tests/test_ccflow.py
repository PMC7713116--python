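"""CC slab, compensation, Phansalkar binarization and FD metrics."""

import numpy as np
import pytest

from maculaflow.ccflow import (CcFlowError, CcSlabSpec, PhansalkarParams,
                               compensate_flow, extract_cc_slab, fd_metrics,
                               phansalkar_binarize,
                               remove_projection_artifacts,
                               remove_small_deficits)
from maculaflow.geometry import Raster, Surface, segment_rpe


def phansalkar_bruteforce(values, params=PhansalkarParams()):
    """Per-pixel window-enumeration oracle (independent of the filter
    implementation): circular window, truncated at borders."""
    v = values.astype(float)
    r = params.window_radius_px
    rows, cols = v.shape
    out = np.zeros_like(v, dtype=bool)
    for i in range(rows):
        for j in range(cols):
            pix = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di * di + dj * dj > r * r:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols:
                        pix.append(v[ii, jj])
            pix = np.array(pix)
            m, s = pix.mean(), pix.std()
            T = m * (1 + params.p * np.exp(-params.q * m)
                     + params.k * (s / params.R - 1))
            out[i, j] = v[i, j] <= T
    return out


class TestExtractCcSlab:
    def test_uniform_subfloor_band_gives_constant_raster(self,
                                                         noiseless_volume):
        volume, truth = noiseless_volume
        slab = extract_cc_slab(volume, truth.true_bm_surface)
        # the sub-RPE band of the phantom is uniform choroid
        assert np.allclose(slab.values, slab.values.flat[0], rtol=1e-6)

    def test_slab_below_volume_rejected(self, noiseless_volume):
        volume, truth = noiseless_volume
        deep = Surface(truth.true_bm_surface.z_um + 5000.0)
        with pytest.raises(CcFlowError, match="exits"):
            extract_cc_slab(volume, deep)

    def test_invalid_slab_spec_rejected(self):
        with pytest.raises(CcFlowError):
            CcSlabSpec(thickness_um=0.0)


class TestCompensateFlow:
    def test_uniform_structure_preserves_rank_order(self):
        rng = np.random.default_rng(0)
        flow = Raster(rng.uniform(10, 200, (50, 50)), 12.0)
        structure = Raster(np.full((50, 50), 80.0), 12.0)
        comp = compensate_flow(flow, structure)
        order_in = np.argsort(flow.values.ravel())
        order_out = np.argsort(comp.values.ravel())
        assert np.array_equal(order_in, order_out)

    def test_pure_shadow_recovered(self):
        # flow and structure both halved under a (minority) shadow patch:
        # compensation restores the flow level there to within 10%
        flow_v = np.full((60, 60), 100.0)
        struct_v = np.full((60, 60), 80.0)
        flow_v[:, 45:] *= 0.5
        struct_v[:, 45:] *= 0.5
        comp = compensate_flow(Raster(flow_v, 12.0), Raster(struct_v, 12.0))
        # away from the shadow edge
        assert comp.values[:, 55:].mean() == pytest.approx(100.0, rel=0.10)
        assert comp.values[:, :40].mean() == pytest.approx(100.0, rel=0.05)

    def test_gain_capped_at_inverse_floor(self):
        flow_v = np.full((40, 40), 50.0)
        struct_v = np.full((40, 40), 100.0)
        struct_v[:10, :10] = 0.01            # collapses below the floor
        comp = compensate_flow(Raster(flow_v, 12.0), Raster(struct_v, 12.0),
                               floor_fraction=0.1, smooth_sigma_px=0.0)
        assert comp.values.max() <= flow_v.max() + 1e-9   # clipped to range

    def test_zero_structure_rejected(self):
        with pytest.raises(CcFlowError):
            compensate_flow(Raster(np.ones((10, 10)), 12.0),
                            Raster(np.zeros((10, 10)), 12.0))


class TestPhansalkarBinarize:
    def test_constant_half_closed_form(self):
        # T = 0.5*(1 + 2e^-5 - 0.25) = 0.38174; 0.5 > T so no deficits
        img = np.full((32, 32), 0.5)
        assert not phansalkar_binarize(img).any()

    def test_all_zero_closed_form(self):
        assert phansalkar_binarize(np.zeros((16, 16))).all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.random((24, 24))
        assert np.array_equal(phansalkar_binarize(img),
                              phansalkar_bruteforce(img))

    def test_uint8_input_normalized_by_dtype(self):
        rng = np.random.default_rng(2)
        img8 = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        assert np.array_equal(phansalkar_binarize(img8),
                              phansalkar_bruteforce(img8 / 255.0))

    def test_constant_nonzero_outside_unit_rejected(self):
        with pytest.raises(CcFlowError):
            phansalkar_binarize(np.full((10, 10), 7.3))


class TestRemoveSmallDeficits:
    def test_pixel_count_cutoff_at_native_pitch(self):
        # at 12 um pitch: 3 px = 432 um^2 (equiv 23.4 um) removed,
        # 4 px = 576 um^2 (equiv 27.1 um) kept
        mask = np.zeros((20, 20), bool)
        mask[2, 2:5] = True                  # 3-pixel component
        mask[10, 10:14] = True               # 4-pixel component
        out = remove_small_deficits(mask, 12.0)
        assert not out[2, 2:5].any()
        assert out[10, 10:14].all()

    def test_disk_below_and_above_cutoff(self):
        # equivalent diameter 20 um removed, 30 um retained (3 um pitch
        # grid so the disks are well resolved)
        pitch = 3.0
        yy, xx = np.mgrid[0:40, 0:80].astype(float) * pitch
        small = np.hypot(yy - 60, xx - 60) <= 10.0      # diam 20 um
        big = np.hypot(yy - 60, xx - 180) <= 15.0       # diam 30 um
        out = remove_small_deficits(small | big, pitch)
        assert not (out & small).any()
        assert np.array_equal(out & big, big)

    def test_never_increases_and_matches_area_cutoff(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.2
        out = remove_small_deficits(mask, 12.0)
        assert not (out & ~mask).any()
        # brute-force area filter oracle
        from skimage import measure
        labels = measure.label(mask, connectivity=2)
        keep = np.zeros_like(mask)
        for lab in range(1, labels.max() + 1):
            comp = labels == lab
            if 2 * np.sqrt(comp.sum() * 144.0 / np.pi) >= 24.0:
                keep |= comp
        assert np.array_equal(out, keep)


class TestFdMetrics:
    def test_full_and_empty_masks(self):
        mask = np.ones((20, 20), bool)
        m = fd_metrics(mask, mask, 12.0)
        assert m.fd_percent == 100.0
        m0 = fd_metrics(np.zeros((20, 20), bool), mask, 12.0)
        assert m0.fd_percent == 0.0 and m0.fd_count == 0
        assert np.isnan(m0.fd_mean_size_um2)

    def test_component_arithmetic(self):
        deficits = np.zeros((30, 30), bool)
        deficits[2, 2:7] = True              # 5 px
        deficits[10:12, 10:15] = True        # 10 px
        analysis = np.ones((30, 30), bool)
        m = fd_metrics(deficits, analysis, 12.0)
        assert m.fd_count == 2
        assert m.fd_percent == pytest.approx(100.0 * 15 / 900)
        assert m.fd_mean_size_um2 == pytest.approx(7.5 * 144.0)

    def test_empty_analysis_mask_rejected(self):
        with pytest.raises(CcFlowError):
            fd_metrics(np.zeros((5, 5), bool), np.zeros((5, 5), bool), 12.0)

    def test_partition_consistency_exact(self):
        rng = np.random.default_rng(4)
        deficits = rng.random((80, 80)) < 0.25
        roi = np.hypot(*np.mgrid[0:80, 0:80] - 39.5) <= 35
        drusen = roi & (rng.random((80, 80)) < 0.3)
        free = roi & ~drusen
        fd_roi = fd_metrics(deficits, roi, 12.0).fd_percent
        fd_d = fd_metrics(deficits, drusen, 12.0).fd_percent
        fd_f = fd_metrics(deficits, free, 12.0).fd_percent
        w = drusen.sum() / roi.sum()
        assert fd_roi == pytest.approx(w * fd_d + (1 - w) * fd_f, abs=1e-10)


class TestRemoveProjectionArtifacts:
    def test_empty_mask_is_identity(self):
        roi = np.ones((10, 10), bool)
        assert np.array_equal(remove_projection_artifacts(roi, None), roi)
        assert np.array_equal(
            remove_projection_artifacts(roi, np.zeros((10, 10), bool)), roi)

    def test_analyzed_area_shrinks_by_mask_intersection(self):
        roi = np.zeros((20, 20), bool)
        roi[5:15, 5:15] = True
        vessels = np.zeros((20, 20), bool)
        vessels[5:15, 5:7] = True            # 20 px inside the ROI
        out = remove_projection_artifacts(roi, vessels)
        assert out.sum() == roi.sum() - 20

    def test_fd_percent_unchanged_for_representative_vessels(self):
        # vessels over a region whose deficit fraction equals the global one
        deficits = np.zeros((20, 20), bool)
        deficits[:, ::4] = True              # 25% everywhere, column stripes
        roi = np.ones((20, 20), bool)
        vessels = np.zeros((20, 20), bool)
        vessels[:4] = True                   # rows: same 25% stripe pattern
        before = fd_metrics(deficits, roi, 12.0).fd_percent
        after = fd_metrics(deficits,
                           remove_projection_artifacts(roi, vessels),
                           12.0).fd_percent
        assert before == pytest.approx(after)
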