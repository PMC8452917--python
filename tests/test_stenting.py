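import numpy as np
import pytest

import coroflow as cf
from conftest import distal_ffr, stenosed_case
from coroflow.stenting import _interior_stations


def uniform_tube(r=1.5, L=40.0):
    b = cf.build_branch("v0", L, r)
    return cf.CoronaryTree(branches={"v0": b}, root_id="v0")


class TestDeployStent:
    def test_interior_station_count_26mm(self):
        # 26 mm span at 3 mm spacing -> 8 interior sections
        assert len(_interior_stations(0.0, 26.0, 3.0)) == 8

    def test_station_on_distal_boundary_excluded(self):
        assert len(_interior_stations(0.0, 12.0, 3.0)) == 3

    def test_identity_when_stent_matches_lumen(self):
        tree = uniform_tube(r=1.5)
        spec = cf.StentSpec("v0", s_proximal=5.0, s_distal=31.0, diameter=3.0)
        out = cf.deploy_stent(tree, spec)
        r0 = np.array([p.r for p in tree.branches["v0"].samples])
        r1 = np.array([p.r for p in out.branches["v0"].samples])
        assert np.max(np.abs(r1 - r0)) <= 0.01 * 1.5

    def test_severe_lesion_restored_to_stent_diameter(self):
        tree = cf.apply_stenosis(uniform_tube(r=1.5),
                                 cf.StenosisSpec("v0", 20.0, 14.0, 80.0))
        spec = cf.StentSpec("v0", s_proximal=12.0, s_distal=28.0, diameter=3.0)
        out = cf.deploy_stent(tree, spec)
        span = [p.r for p in out.branches["v0"].samples if 12.0 <= p.s <= 28.0]
        assert 2 * min(span) >= 0.95 * 3.0

    def test_untouched_outside_span(self):
        tree = cf.apply_stenosis(uniform_tube(), cf.StenosisSpec("v0", 20.0, 14.0, 60.0))
        spec = cf.StentSpec("v0", s_proximal=12.0, s_distal=28.0, diameter=3.0)
        out = cf.deploy_stent(tree, spec)
        for pa, pb in zip(tree.branches["v0"].samples, out.branches["v0"].samples):
            if pa.s < 12.0 or pa.s > 28.0:
                assert pa.r == pb.r
        # input untouched
        assert min(p.r for p in tree.branches["v0"].samples) < 0.7

    def test_span_outside_branch_rejected(self):
        with pytest.raises(cf.GeometryError):
            cf.deploy_stent(uniform_tube(L=20.0),
                            cf.StentSpec("v0", 10.0, 25.0, 3.0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            cf.StentSpec("v0", 10.0, 5.0, 3.0)
        with pytest.raises(ValueError):
            cf.StentSpec("v0", 5.0, 10.0, -1.0)


class TestAutoSizeStent:
    def test_recovers_cosine_lesion_extent_and_diameter(self):
        # 50 %DS dip spanning [10, 22] in an otherwise uniform 3 mm vessel
        tree = cf.apply_stenosis(uniform_tube(r=1.5),
                                 cf.StenosisSpec("v0", 16.0, 12.0, 50.0))
        spec = cf.auto_size_stent(tree, "v0", search_window=(4.0, 28.0))
        assert spec.s_proximal == pytest.approx(10.0, abs=0.5)
        assert spec.s_distal == pytest.approx(22.0, abs=0.5)
        assert spec.length == pytest.approx(12.0, abs=1.0)
        assert spec.diameter == pytest.approx(3.0, rel=0.02)

    def test_uniform_vessel_is_no_lesion(self):
        with pytest.raises(cf.NoLesionError):
            cf.auto_size_stent(uniform_tube(), "v0")

    def test_two_dips_brackets_the_deeper(self):
        tree = uniform_tube(L=44.0)
        tree = cf.apply_stenosis(tree, cf.StenosisSpec("v0", 12.0, 8.0, 40.0))
        tree = cf.apply_stenosis(tree, cf.StenosisSpec("v0", 30.0, 8.0, 60.0))
        spec = cf.auto_size_stent(tree, "v0", search_window=(2.0, 42.0))
        assert spec.s_proximal >= 16.0  # clear of the shallower dip
        assert spec.s_proximal <= 27.0 and spec.s_distal >= 33.0

    @pytest.mark.parametrize("severity", [40.0, 60.0, 80.0])
    def test_roundtrip_recovery_from_apply_stenosis(self, severity):
        tree = cf.apply_stenosis(uniform_tube(r=1.6, L=50.0),
                                 cf.StenosisSpec("v0", 25.0, 16.0, severity))
        spec = cf.auto_size_stent(tree, "v0")
        assert spec.s_proximal == pytest.approx(17.0, abs=0.5)
        assert spec.s_distal == pytest.approx(33.0, abs=0.5)
        assert spec.diameter == pytest.approx(3.2, rel=0.02)


class TestClassifyLesions:
    def _tree(self):
        root = cf.build_branch("v0", 30.0, 2.0)
        child = cf.build_branch("v1", 20.0, 1.5, parent_id="v0", attach_s=15.0)
        return cf.CoronaryTree(branches={"v0": root, "v1": child}, root_id="v0")

    def _lesion(self, bid, lo, hi, ds):
        return cf.LesionRecord(branch_id=bid, s_range=(lo, hi), min_diameter=1.0,
                               reference_diameter=4.0, percent_ds=ds)

    def test_focal_mid_branch(self):
        out = cf.classify_lesions(self._tree(), [self._lesion("v0", 20.0, 26.0, 60.0)])
        assert out[0].type == "focal"

    def test_bifurcation_spans_takeoff(self):
        out = cf.classify_lesions(self._tree(), [self._lesion("v0", 13.0, 17.0, 60.0)])
        assert out[0].type == "bifurcation"

    def test_ostial_near_origin(self):
        out = cf.classify_lesions(self._tree(), [self._lesion("v1", 1.0, 6.0, 60.0)])
        assert out[0].type == "ostial"

    def test_tandem_two_significant_on_one_path(self):
        lesions = [self._lesion("v0", 20.0, 24.0, 55.0),
                   self._lesion("v1", 6.0, 10.0, 55.0)]
        out = cf.classify_lesions(self._tree(), lesions)
        assert [l.type for l in out] == ["tandem-member", "tandem-member"]

    def test_sub_50_pair_not_tandem(self):
        lesions = [self._lesion("v0", 20.0, 24.0, 45.0),
                   self._lesion("v1", 6.0, 10.0, 55.0)]
        out = cf.classify_lesions(self._tree(), lesions)
        assert [l.type for l in out] == ["focal", "focal"]

    def test_ostial_precedence_over_bifurcation(self):
        out = cf.classify_lesions(self._tree(), [self._lesion("v0", 1.0, 17.0, 60.0)])
        assert out[0].type == "ostial"

    def test_off_tree_lesion_rejected(self):
        with pytest.raises(KeyError):
            cf.classify_lesions(self._tree(), [self._lesion("zz", 1.0, 2.0, 50.0)])


class TestStentingHemodynamics:
    @pytest.mark.parametrize("seed,severity", [(0, 45.0), (1, 65.0), (2, 85.0)])
    def test_stenting_never_lowers_distal_ffr(self, patient, seed, severity):
        tree, bid, s_site = stenosed_case(seed, severity)
        pre = distal_ffr(tree, bid, s_site, patient)
        spec = cf.auto_size_stent(tree, bid)
        post = distal_ffr(cf.deploy_stent(tree, spec), bid, s_site, patient)
        assert post >= pre - 1e-9

    def test_stenting_healthy_segment_is_neutral(self, patient):
        tree = cf.generate_tree(7, generations=2)
        from coroflow.synthetic import lesion_target_branch

        bid = lesion_target_branch(tree)
        br = tree.branches[bid]
        s_site = br.samples[-1].s - 1.0
        pre = distal_ffr(tree, bid, s_site, patient)
        spec = cf.StentSpec(bid, 5.0, br.length - 5.0, diameter=2 * br.samples[0].r)
        post = distal_ffr(cf.deploy_stent(tree, spec), bid, s_site, patient)
        assert abs(post - pre) < 0.005
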