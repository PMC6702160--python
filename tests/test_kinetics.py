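"""Kinetic features, FTV segmentation, PRMs and aggregate analogues."""

import numpy as np
import pytest

import dcetrack as dt


class TestKineticMaps:
    def test_washout_curve_plugin(self, make_curve_study):
        kin = dt.kinetic_maps(make_curve_study(100, 200, 150))
        v = (0, 0, 0)
        assert kin.PE.values[v] == pytest.approx(1.0)
        assert kin.t_PE[v] == pytest.approx(2.5)
        assert kin.WIS.values[v] == pytest.approx(0.4)
        assert kin.WOS.values[v] == pytest.approx(-10.0)
        assert kin.SER.values[v] == pytest.approx(0.5)

    def test_persistent_curve_exercises_late_peak_branches(self, make_curve_study):
        kin = dt.kinetic_maps(make_curve_study(100, 150, 200))
        v = (0, 0, 0)
        assert kin.PE.values[v] == pytest.approx(1.0)
        assert kin.t_PE[v] == pytest.approx(7.5)
        assert kin.WIS.values[v] == pytest.approx(1.0 / 7.5)
        assert kin.WOS.values[v] == 0.0  # t2 == t_PE branch
        assert kin.SER.values[v] == pytest.approx(2.0)

    def test_flat_curve_guarded(self, make_curve_study):
        kin = dt.kinetic_maps(make_curve_study(100, 100, 100))
        v = (0, 0, 0)
        assert kin.PE.values[v] == 0.0
        assert kin.WIS.values[v] == 0.0
        assert kin.SER.values[v] == 0.0
        assert kin.SER.flags["ser_guarded"][v]
        assert kin.PE.flags["no_enhancement"][v]
        assert kin.t_PE[v] == dt.kinetics.T_PE_NONE

    def test_nonpositive_baseline_flagged(self, make_curve_study):
        study = make_curve_study(0, 50, 80)
        kin = dt.kinetic_maps(study)
        assert not kin.PE.valid.any()
        assert (kin.PE.values == 0).all()

    def test_ser_one_when_late_equals_early(self, make_curve_study):
        kin = dt.kinetic_maps(make_curve_study(100, 180, 180))
        assert kin.SER.values[0, 0, 0] == pytest.approx(1.0)

    def test_wos_alternative_denominator(self, make_curve_study):
        kin = dt.kinetic_maps(make_curve_study(100, 200, 150), wos_denominator="t2_minus_t1")
        assert kin.WOS.values[0, 0, 0] == pytest.approx(-10.0)  # same here: t_PE = t1


def _blob_study(centers, radius=4.0, n=32, pe_inside=1.2, pe_outside=0.05):
    g = dt.VolumeGrid(np.full((n, n, n), 100.0), np.ones(3))
    pts = g.world_coordinates()
    inside = np.zeros((n, n, n), bool)
    for c in centers:
        inside |= np.linalg.norm(pts - np.asarray(c, float), axis=-1) <= radius
    i1 = np.where(inside, 100 * (1 + pe_inside), 100 * (1 + pe_outside))
    i2 = np.where(inside, 100 * (1 + 0.8 * pe_inside), 100 * (1 + 0.8 * pe_outside))
    return dt.DCEStudy(g, g.like(i1), g.like(i2)), inside


class TestSegmentFTV:
    def test_enhancing_ellipsoid_segmented_exactly(self):
        study, inside = _blob_study([(16, 16, 16)])
        mask, vol_cm3 = dt.segment_ftv(study, pe_min=0.7)
        np.testing.assert_array_equal(mask, inside)
        assert vol_cm3 == pytest.approx(inside.sum() / 1000.0)

    def test_threshold_above_max_gives_empty_mask_with_warning(self):
        study, _ = _blob_study([(16, 16, 16)])
        with pytest.warns(RuntimeWarning, match="empty"):
            mask, vol = dt.segment_ftv(study, pe_min=10.0)
        assert not mask.any() and vol == 0.0

    def test_keep_largest_component(self):
        study, _ = _blob_study([(10, 10, 10), (24, 24, 24)], radius=3.0)
        big, _ = _blob_study([(10, 10, 10)], radius=5.0)
        # merge: a big blob and a small blob
        study2, _ = _blob_study([(10, 10, 10)], radius=5.0)
        vals1 = np.maximum(study2.vol_t1.values, study.vol_t1.values)
        vals2 = np.maximum(study2.vol_t2.values, study.vol_t2.values)
        merged = dt.DCEStudy(study.vol_t0, study.vol_t0.like(vals1), study.vol_t0.like(vals2))
        mask, _ = dt.segment_ftv(merged, pe_min=0.7)
        pts = study.vol_t0.world_coordinates()
        assert mask[10, 10, 10] and not mask[24, 24, 24]


class TestPRM:
    def test_null_case_identity_transform_identical_studies(self, make_curve_study):
        study = make_curve_study(100, 200, 150, n=8)
        mask = np.ones((8, 8, 8), bool)
        kin = dt.kinetic_maps(study, mask)
        T = dt.DisplacementField.identity(study.grid)
        jac = dt.FeatureMap("Jacobian", np.ones((8, 8, 8)), mask)
        for name in dt.kinetics.KINETIC_NAMES:
            early_vol = study.grid.like(dt.kinetic_maps(study)[name].values)
            prm = dt.prm_map(kin[name], early_vol, T, jac)
            np.testing.assert_allclose(prm.values[prm.valid], 0.0, atol=1e-12)

    @pytest.mark.parametrize("j, f_early, f_pre, expected", [(1.0, 1.5, 1.0, 0.5),
                                                             (0.5, 2.0, 1.0, 0.0)])
    def test_plugin_values(self, j, f_early, f_pre, expected):
        n = 4
        g = dt.VolumeGrid(np.zeros((n, n, n)), np.ones(3))
        mask = np.ones((n, n, n), bool)
        pre_map = dt.FeatureMap("PE", np.full((n, n, n), f_pre), mask)
        early_vol = g.like(np.full((n, n, n), f_early))
        jac = dt.FeatureMap("Jacobian", np.full((n, n, n), j), mask)
        prm = dt.prm_map(pre_map, early_vol, dt.DisplacementField.identity(g), jac)
        np.testing.assert_allclose(prm.values[prm.valid], expected, atol=1e-12)

    def test_mapped_outside_early_flagged(self):
        n = 4
        g = dt.VolumeGrid(np.zeros((n, n, n)), np.ones(3))
        mask = np.ones((n, n, n), bool)
        pre_map = dt.FeatureMap("PE", np.ones((n, n, n)), mask)
        jac = dt.FeatureMap("Jacobian", np.ones((n, n, n)), mask)
        u = np.zeros((n, n, n, 3))
        u[..., 0] = 100.0  # maps far outside
        prm = dt.prm_map(pre_map, g.like(np.ones((n, n, n))),
                         dt.DisplacementField(u, np.ones(3)), jac)
        assert not prm.valid.any()
        assert prm.flags["outside_early"].all()


class TestAggregates:
    def _kin(self, value, n=4):
        g = dt.VolumeGrid(np.full((n, n, n), 100.0), np.ones(3))
        study = dt.DCEStudy(g, g.like(np.full((n, n, n), 100.0 * (1 + value))),
                            g.like(np.full((n, n, n), 100.0 * (1 + 0.5 * value))))
        return dt.kinetic_maps(study)

    def test_delta_plugin(self):
        # PE means: pre 2, early 4 -> delta = (4-2)/4 = 0.5
        agg = dt.aggregate_features(self._kin(2.0), self._kin(4.0), 10.0, 8.0)
        assert agg["d_PE"] == pytest.approx(0.5)
        assert agg["ftv_ratio"] == pytest.approx(0.8)

    def test_identical_visits_all_zero(self):
        kin = self._kin(1.5)
        agg = dt.aggregate_features(kin, kin, 5.0, 5.0)
        assert agg["ftv_ratio"] == pytest.approx(1.0)
        for name in ("d_PE", "d_WIS", "d_WOS", "d_SER"):
            assert agg[name] == pytest.approx(0.0) or np.isnan(agg[name])

    def test_exactly_five_values(self):
        agg = dt.aggregate_features(self._kin(1.0), self._kin(2.0), 4.0, 4.0)
        assert len(agg) == 5
        assert set(agg) == set(dt.AGGREGATE_FEATURES)

    def test_empty_ftv1_rejected(self):
        kin = self._kin(1.0)
        with pytest.raises(ValueError, match="ftv1"):
            dt.aggregate_features(kin, kin, 0.0, 1.0)

    def test_mean_prm_pe_recovers_uniform_delta(self):
        """A uniform +delta PE change with identity transform appears as
        mean PRM_PE = delta over the tumor."""
        spec = dt.PhantomSpec(
            grid_shape=(24, 24, 24), noise_sd=0.0, bias_amplitude=0.0,
            boundary_width_mm=0.5,
            tumor_enhancement=(100.0, 200.0, 150.0),
            tumor_enhancement_early=(100.0, 230.0, 150.0),
        )
        pre, early, truth = dt.make_study_pair(spec)
        core = truth.tumor_fraction > 0.99
        assert core.sum() > 0
        kin_pre = dt.kinetic_maps(pre, core)
        early_pe = early.grid.like(dt.kinetic_maps(early).PE.values)
        T = dt.DisplacementField.identity(pre.grid)
        jac = dt.FeatureMap("Jacobian", np.ones(spec.grid_shape), core)
        prm = dt.prm_map(kin_pre.PE, early_pe, T, jac)
        assert prm.masked_values().mean() == pytest.approx(0.3, rel=0.02)
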