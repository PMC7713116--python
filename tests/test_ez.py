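"""EZ slab extraction and normalized reflectivity."""

import numpy as np
import pytest

from maculaflow.ez import (EzError, SlabSpec, extract_ez_enface,
                           normalize_reflectivity, regional_reflectivity,
                           sample_reference)
from maculaflow.geometry import (OctVolume, Raster, RegionMasks, RoiSpec,
                                 circular_roi_mask, segment_rpe)
from maculaflow.phantom import PhantomConfig, generate_volume


class TestExtractEzEnface:
    def test_noiseless_band_recovered_exactly(self, noiseless_volume):
        volume, truth = noiseless_volume
        rpe = segment_rpe(volume)
        enface = extract_ez_enface(volume, rpe)
        assert np.allclose(enface.values, 200.0, rtol=1e-6)

    def test_attenuation_field_scales_enface(self):
        att = np.ones((96, 96))
        att[:, 48:] = 0.5
        cfg = PhantomConfig(grid_rows=96, grid_cols=96, lateral_pitch_um=62.5,
                            ez_attenuation_field=att, seed=4)
        ratios = []
        for seed in range(3):
            volume, truth = generate_volume(
                PhantomConfig(grid_rows=96, grid_cols=96,
                              lateral_pitch_um=62.5,
                              ez_attenuation_field=att, seed=seed))
            rpe = segment_rpe(volume)
            enface = extract_ez_enface(volume, rpe)
            # stay clear of the attenuation step edge
            ratios.append(enface.values[:, 50:].mean()
                          / enface.values[:, :46].mean())
        assert 0.45 < np.mean(ratios) < 0.55

    def test_zero_thickness_slab_rejected(self):
        with pytest.raises(EzError):
            SlabSpec(thickness_um=0.0)

    def test_slab_exiting_volume_rejected(self, noiseless_volume):
        volume, _ = noiseless_volume
        shallow = segment_rpe(volume)
        with pytest.raises(EzError, match="exits"):
            extract_ez_enface(volume, shallow,
                              SlabSpec(offset_above_rpe_um=5000.0,
                                       thickness_um=21.0))


class TestSampleReference:
    def test_constant_region_returns_value(self):
        vol = OctVolume(np.full((20, 8, 8), 42.0), 5.0, 12.0)
        mask3d = np.zeros((20, 8, 8), bool)
        mask3d[2:5] = True
        assert sample_reference(vol, mask3d) == 42.0

    def test_single_voxel_mask(self):
        v = np.zeros((10, 4, 4))
        v[3, 1, 2] = 17.0
        vol = OctVolume(v, 5.0, 12.0)
        mask = np.zeros((10, 4, 4), bool)
        mask[3, 1, 2] = True
        assert sample_reference(vol, mask) == 17.0

    def test_phantom_vitreous_darker_than_rnfl(self, noiseless_volume):
        volume, truth = noiseless_volume
        refs = truth.reference_masks
        mu_v = sample_reference(volume, refs.vitreous_mask,
                                z_range_um=refs.vitreous_z_um)
        mu_r = sample_reference(volume, refs.rnfl_mask,
                                z_range_um=refs.rnfl_z_um)
        assert mu_v < mu_r

    def test_empty_mask_rejected(self, noiseless_volume):
        volume, _ = noiseless_volume
        with pytest.raises(EzError, match="empty"):
            sample_reference(volume, np.zeros(volume.values.shape, bool))


class TestNormalizeReflectivity:
    @pytest.mark.parametrize("mu_ez,expected", [
        (10.0, 0.0),      # at the dark reference
        (110.0, 1.0),     # at the bright reference
        (86.0, 0.76),     # linear interior point
    ])
    def test_two_point_rescaling(self, mu_ez, expected):
        assert normalize_reflectivity(mu_ez, 10.0, 110.0) == pytest.approx(
            expected)

    def test_inverted_references_rejected(self):
        with pytest.raises(EzError, match="inverted"):
            normalize_reflectivity(50.0, 110.0, 10.0)


class TestRegionalReflectivity:
    @staticmethod
    def _masks(shape, split=None, vessels=None):
        roi = np.ones(shape, bool)
        drusen = np.zeros(shape, bool)
        if split is not None:
            drusen[:, :split] = True
        m = RegionMasks(roi=roi, drusen=drusen, drusen_free=roi & ~drusen)
        if vessels is not None:
            m.vessel_excluded = vessels
        return m

    def test_uniform_image_at_bright_reference_reports_one(self):
        enface = Raster(np.full((30, 30), 110.0), 12.0)
        res = regional_reflectivity(enface, self._masks((30, 30), split=10),
                                    mu_vitreous=10.0, mu_rnfl=110.0)
        assert res.normalized_whole_roi == pytest.approx(1.0)
        assert res.normalized_drusen_free == pytest.approx(1.0)
        assert res.normalized_drusen == pytest.approx(1.0)

    def test_attenuation_under_drusen_orders_regions(self):
        vals = np.full((30, 30), 100.0)
        vals[:, :10] = 80.0              # darker under drusen
        enface = Raster(vals, 12.0)
        res = regional_reflectivity(enface, self._masks((30, 30), split=10),
                                    mu_vitreous=10.0, mu_rnfl=110.0)
        assert res.normalized_drusen < res.normalized_drusen_free

    def test_vessels_covering_roi_reported_missing(self):
        enface = Raster(np.full((20, 20), 50.0), 12.0)
        vessels = np.ones((20, 20), bool)
        with pytest.warns(UserWarning, match="vessel"):
            res = regional_reflectivity(enface, self._masks((20, 20),
                                                            vessels=vessels),
                                        mu_vitreous=10.0, mu_rnfl=110.0)
        assert np.isnan(res.normalized_whole_roi)

    def test_region_aggregation_identity(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(20, 200, (40, 40))
        enface = Raster(vals, 12.0)
        masks = self._masks((40, 40), split=13)
        mu_roi = vals[masks.roi].mean()
        w_d = masks.drusen.sum() / masks.roi.sum()
        agg = (w_d * vals[masks.drusen].mean()
               + (1 - w_d) * vals[masks.drusen_free].mean())
        assert mu_roi == pytest.approx(agg, abs=1e-12)

    def test_affine_invariance_of_normalization(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(20, 200, (30, 30))
        masks = self._masks((30, 30), split=9)
        r1 = regional_reflectivity(Raster(vals, 12.0), masks, 10.0, 110.0)
        a, b = 3.7, 25.0
        r2 = regional_reflectivity(Raster(a * vals + b, 12.0), masks,
                                   a * 10.0 + b, a * 110.0 + b)
        for v1, v2 in zip((r1.normalized_whole_roi, r1.normalized_drusen_free,
                           r1.normalized_drusen),
                          (r2.normalized_whole_roi, r2.normalized_drusen_free,
                           r2.normalized_drusen)):
            assert abs(v1 - v2) < 1e-9
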