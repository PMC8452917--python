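import pytest

import coroflow as cf


@pytest.fixture
def patient():
    """Typical intermediate-CAD patient: 127/74 mmHg, LV mass 114 g."""
    return cf.PatientRecord(sbp=127.0, dbp=74.0, lv_mass=114.0)


@pytest.fixture
def tube_tree():
    """Single straight 30 mm tube, radius 1.5 mm."""
    b = cf.build_branch("v0", 30.0, 1.5)
    return cf.CoronaryTree(branches={"v0": b}, root_id="v0")


@pytest.fixture
def two_outlet_tree():
    """Root trunk with two daughters (3 mm and 2 mm diameter) at its tip."""
    root = cf.build_branch("v0", 20.0, 2.0)
    tip = root.samples[-1].s
    c1 = cf.build_branch("v1", 25.0, 1.5, parent_id="v0", attach_s=tip)
    c2 = cf.build_branch("v2", 25.0, 1.0, parent_id="v0", attach_s=tip)
    return cf.CoronaryTree(branches={"v0": root, "v1": c1, "v2": c2}, root_id="v0")


def stenosed_case(seed: int, severity: float):
    """A seeded Murray tree with one lesion on the LAD-equivalent daughter.

    Returns (tree, lesioned branch id, distal measurement s).
    """
    from coroflow.synthetic import lesion_target_branch

    tree = cf.generate_tree(seed, generations=2)
    bid = lesion_target_branch(tree)
    br = tree.branches[bid]
    center = round(br.length / 2.0)
    length = min(20.0, 2.0 * min(center, br.length - center) - 1.0)
    st = cf.apply_stenosis(
        tree, cf.StenosisSpec(branch_id=bid, s_center=center,
                              length=length, severity=severity))
    return st, bid, br.samples[-1].s - 1.0


def distal_ffr(tree, branch_id, s, patient, settings=None, hemo=None):
    """Calibrate + solve + read FFR at one site (shared helper)."""
    hemo = hemo or cf.HemoParams()
    settings = settings or cf.SolverSettings()
    p_in, bcs, target = cf.build_outlet_bcs(tree, patient, hemo)
    _, sol = cf.calibrate_total_flow(tree, p_in, bcs, target, settings, hemo)
    return sol.pressure_at(branch_id, s) / p_in
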