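import math

import numpy as np
import pytest

import coroflow as cf
from conftest import stenosed_case
from coroflow.units import MLMIN_TO_M3S, MMHG_TO_PA


def poiseuille_resistance(length_mm, radius_mm, mu=0.0035):
    """Closed-form 8*mu*L/(pi r^4), returned in mmHg min/mL."""
    r_pa = 8 * mu * (length_mm * 1e-3) / (math.pi * (radius_mm * 1e-3) ** 4)
    return r_pa / MMHG_TO_PA * MLMIN_TO_M3S


LINEAR = cf.HemoParams(rho=1e-12)  # suppresses expansion losses


class TestSegmentPressureDrop:
    def test_poiseuille_closed_form(self):
        prof = np.column_stack([np.linspace(0, 30, 61), np.full(61, 1.5)])
        q = 120.0  # 2 mL/s
        expected = poiseuille_resistance(30, 1.5) * q  # ~0.792 mmHg
        assert expected == pytest.approx(0.792, abs=0.002)
        assert cf.segment_pressure_drop(prof, q) == pytest.approx(expected, rel=1e-3)

    def test_zero_flow_zero_drop(self):
        prof = [(0, 1.5), (10, 1.0), (20, 1.5)]
        assert cf.segment_pressure_drop(prof, 0.0) == 0.0

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            cf.segment_pressure_drop([(0, 1.5), (10, 1.5)], -1.0)

    @pytest.mark.parametrize("q", [30.0, 120.0, 300.0])
    def test_stenosis_exceeds_uniform_tube(self, q):
        s = np.linspace(0, 30, 121)
        r_uniform = np.full_like(s, 1.5)
        factor = np.where(np.abs(s - 15) <= 5,
                          1 - 0.75 * 0.5 * (1 + np.cos(2 * np.pi * (s - 15) / 10)), 1.0)
        dp_sten = cf.segment_pressure_drop(np.column_stack([s, r_uniform * factor]), q)
        dp_unif = cf.segment_pressure_drop(np.column_stack([s, r_uniform]), q)
        assert dp_sten > dp_unif

    def test_drop_strictly_increasing_in_flow(self):
        s = np.linspace(0, 30, 121)
        r = np.where(np.abs(s - 15) <= 5, 0.8, 1.5)
        drops = [cf.segment_pressure_drop(np.column_stack([s, r]), q)
                 for q in np.linspace(10, 300, 12)]
        assert np.all(np.diff(drops) > 0)


class TestSolveFlow:
    def test_single_tube_series_circuit(self, tube_tree):
        # linear losses: Q = P_in / (R_v + R)
        R = 0.5
        p_in = 85.0
        bcs = [cf.OutletBC(outlet_id="v0", resistance=R, p0=0.0)]
        sol = cf.solve_flow(tube_tree, p_in, bcs, params=LINEAR)
        rv = poiseuille_resistance(30, 1.5)
        assert sol.inlet_flow == pytest.approx(p_in / (rv + R), rel=1e-6)
        assert sol.converged

    def test_two_outlet_linear_matches_resistor_network(self, two_outlet_tree):
        p_in = 85.0
        R1, R2 = 0.9, 1.7
        bcs = [cf.OutletBC("v1", R1), cf.OutletBC("v2", R2)]
        sol = cf.solve_flow(two_outlet_tree, p_in, bcs, params=LINEAR)
        # independent oracle: solve the 2x2 lumped resistor network
        r0 = poiseuille_resistance(20, 2.0)
        rv1 = poiseuille_resistance(25, 1.5)
        rv2 = poiseuille_resistance(25, 1.0)
        A = np.array([[r0 + rv1 + R1, r0], [r0, r0 + rv2 + R2]])
        q = np.linalg.solve(A, np.array([p_in, p_in]))
        assert sol.outlet_flows["v1"] == pytest.approx(q[0], rel=1e-6)
        assert sol.outlet_flows["v2"] == pytest.approx(q[1], rel=1e-6)

    def test_symmetric_outlets_get_equal_flow(self):
        root = cf.build_branch("v0", 20.0, 2.0)
        kids = {f"v{i}": cf.build_branch(f"v{i}", 25.0, 1.4, parent_id="v0",
                                         attach_s=20.0) for i in (1, 2)}
        tree = cf.CoronaryTree(branches={"v0": root, **kids}, root_id="v0")
        bcs = [cf.OutletBC("v1", 1.0), cf.OutletBC("v2", 1.0)]
        sol = cf.solve_flow(tree, 85.0, bcs)
        assert sol.outlet_flows["v1"] == pytest.approx(sol.outlet_flows["v2"], rel=1e-9)

    def test_mass_conservation(self, patient):
        for seed in range(3):
            tree, bid, _ = stenosed_case(seed, 60.0)
            p_in, bcs, _ = cf.build_outlet_bcs(tree, patient)
            sol = cf.solve_flow(tree, p_in, bcs)
            assert sol.inlet_flow == pytest.approx(
                sum(sol.outlet_flows.values()), rel=1e-9)

    def test_monotone_pressure_along_branches(self, patient):
        tree, bid, _ = stenosed_case(1, 70.0)
        p_in, bcs, _ = cf.build_outlet_bcs(tree, patient)
        sol = cf.solve_flow(tree, p_in, bcs)
        for b, p in sol.sample_pressures.items():
            assert np.all(np.diff(p) <= 1e-12)
            assert np.all(p <= p_in + 1e-9)

    def test_relaxation_factors_reach_same_fixed_point(self, patient):
        tree, bid, s = stenosed_case(2, 75.0)
        p_in, bcs, _ = cf.build_outlet_bcs(tree, patient)
        sols = [cf.solve_flow(tree, p_in, bcs,
                              cf.SolverSettings(relaxation=a)) for a in (0.25, 0.5, 1.0)]
        for o in tree.outlet_ids():
            flows = [s_.outlet_flows[o] for s_ in sols]
            assert max(flows) - min(flows) == pytest.approx(0.0, abs=1e-4 * flows[0] + 1e-9)

    def test_flow_homogeneous_in_driving_pressure_linear_limit(self, tube_tree):
        bcs = [cf.OutletBC("v0", 0.7)]
        s1 = cf.solve_flow(tube_tree, 40.0, bcs, params=LINEAR)
        s2 = cf.solve_flow(tube_tree, 80.0, bcs, params=LINEAR)
        assert s2.inlet_flow == pytest.approx(2 * s1.inlet_flow, rel=1e-9)

    def test_scaling_pressure_and_resistance_together(self):
        # with a fat (negligible-loss) tube, doubling P_in and R leaves Q fixed
        b = cf.build_branch("v0", 10.0, 4.0)
        tree = cf.CoronaryTree(branches={"v0": b}, root_id="v0")
        s1 = cf.solve_flow(tree, 40.0, [cf.OutletBC("v0", 0.5)], params=LINEAR)
        s2 = cf.solve_flow(tree, 80.0, [cf.OutletBC("v0", 1.0)], params=LINEAR)
        assert s2.inlet_flow == pytest.approx(s1.inlet_flow, rel=1e-3)

    def test_bcs_must_cover_outlets(self, two_outlet_tree):
        with pytest.raises(cf.TopologyError):
            cf.solve_flow(two_outlet_tree, 85.0, [cf.OutletBC("v1", 1.0)])


class TestCalibration:
    def test_healthy_tube_hits_target(self, tube_tree):
        bcs = [cf.OutletBC("v0", 0.85)]
        _, sol = cf.calibrate_total_flow(tube_tree, 85.0, bcs, target=100.0)
        assert abs(sol.inlet_flow - 100.0) / 100.0 <= 1e-3

    def test_stenosis_lowers_distal_pressure_at_matched_flow(self, patient):
        healthy = cf.generate_tree(3, generations=2)
        from coroflow.synthetic import lesion_target_branch
        bid = lesion_target_branch(healthy)
        stenosed, _, s_site = stenosed_case(3, 80.0)
        out = {}
        for name, tree in (("healthy", healthy), ("stenosed", stenosed)):
            p_in, bcs, target = cf.build_outlet_bcs(tree, patient)
            _, sol = cf.calibrate_total_flow(tree, p_in, bcs, target)
            assert abs(sol.inlet_flow - target) / target <= 1e-3
            out[name] = sol.pressure_at(bid, s_site)
        assert out["stenosed"] < out["healthy"]

    def test_calibrated_resistances_independent_of_relaxation(self, patient):
        tree, _, _ = stenosed_case(4, 65.0)
        p_in, bcs, target = cf.build_outlet_bcs(tree, patient)
        results = []
        for a in (0.25, 0.5, 1.0):
            cal, sol = cf.calibrate_total_flow(
                tree, p_in, bcs, target, cf.SolverSettings(relaxation=a))
            results.append(np.array([b.resistance for b in cal]))
            assert abs(sol.inlet_flow - target) / target <= 1e-3
        for r in results[1:]:
            assert np.allclose(r, results[0], rtol=5e-3)

    def test_unattainable_target_raises(self, tube_tree):
        # a 1.5 mm tube cannot pass 20 L/min at 85 mmHg
        bcs = [cf.OutletBC("v0", 0.85)]
        with pytest.raises(cf.ConvergenceError):
            cf.calibrate_total_flow(tube_tree, 85.0, bcs, target=20000.0)

    def test_convergence_error_carries_history(self, tube_tree):
        bcs = [cf.OutletBC("v0", 0.85)]
        try:
            cf.calibrate_total_flow(tube_tree, 85.0, bcs, target=20000.0)
        except cf.ConvergenceError as exc:
            assert len(exc.residual_history) > 0
        else:  # pragma: no cover
            pytest.fail("expected ConvergenceError")
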