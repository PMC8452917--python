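"""Seeded generators for synthetic coronary anatomy and validation cohorts.

Real coronary geometries behind clinical FFR studies are rarely released, so
every downstream module is exercised on synthetic epicardial trees: binary
bifurcating networks obeying Murray's law (d_parent^g = sum d_child^g,
g = 3 by default), truncated where daughter diameters fall below a clinical
segmentation floor (1.5 mm diameter), with parametric cosine-shaped stenoses.
A validation cohort pairs each synthetic patient's simulated FFR with a
"pseudo-invasive" FFR equal to the simulated value plus a configurable bias
and additive Gaussian noise, for exercising the agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GeometryError
from .physiology import HemoParams, PatientRecord, build_outlet_bcs
from .solver import SolverSettings, calibrate_total_flow
from .tree import Branch, CenterlineSample, CoronaryTree, MeasurementSite, build_branch

DEFAULT_DIAMETER_FLOOR_MM = 1.5
SAMPLE_SPACING_MM = 0.5


@dataclass(frozen=True)
class StenosisSpec:
    """A cosine-tapered focal narrowing.

    severity is % diameter stenosis: the radius at s_center is scaled by
    (1 - severity/100); the taper has compact support of width ``length``.
    """

    branch_id: str
    s_center: float
    length: float
    severity: float
    shape: str = "cosine"

    def __post_init__(self):
        if not (0 < self.severity < 100):
            raise ValueError("severity must lie strictly between 0 and 100 %DS")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")
        if self.shape != "cosine":
            raise ValueError(f"unknown stenosis shape {self.shape!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic validation cohort.

    bias and noise_sd act on the FFR scale: pseudo-invasive FFR =
    simulated FFR + bias + N(0, noise_sd), truncated to (0, 1].
    Default physiological ranges span mean +/- SD of a typical intermediate
    coronary-disease cohort (SBP 127+/-14, DBP 74+/-11 mmHg, LV mass
    114+/-32 g); severities cover the 30-90 %DS band referred for invasive
    FFR.
    """

    n_patients: int
    seed: int
    bias: float = 0.0
    noise_sd: float = 0.0
    severity_range: tuple[float, float] = (30.0, 90.0)
    mass_range: tuple[float, float] = (82.0, 146.0)
    sbp_range: tuple[float, float] = (113.0, 141.0)
    dbp_range: tuple[float, float] = (63.0, 85.0)

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in (self.severity_range, self.mass_range,
                       self.sbp_range, self.dbp_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo, hi)")


def generate_tree(
    seed: int,
    generations: int = 3,
    root_diameter: float = 3.5,
    murray_exponent: float = 3.0,
    branch_length_range: tuple[float, float] = (15.0, 40.0),
    asymmetry_range: tuple[float, float] = (0.6, 1.0),
    diameter_floor: float = DEFAULT_DIAMETER_FLOOR_MM,
) -> CoronaryTree:
    """Generate a binary bifurcating tree honouring Murray's law.

    At each bifurcation the daughter asymmetry ratio a = d_small/d_large is
    drawn uniformly from ``asymmetry_range`` and diameters solve
    d_parent^g = d_1^g + d_2^g exactly.  Branches whose daughters would fall
    below ``diameter_floor`` stay terminal, emulating segmentation truncation
    at ~1.5 mm vessel diameter.  ``generations = 0`` yields a single straight
    branch.  Deterministic in ``seed``.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if root_diameter < diameter_floor:
        raise ValueError(
            f"root_diameter {root_diameter} mm is below the floor {diameter_floor} mm"
        )
    rng = np.random.default_rng(seed)
    branches: dict[str, Branch] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"v{counter[0] - 1}"

    def grow(parent_id: Optional[str], attach_s: float, diameter: float,
             gen_left: int, origin: np.ndarray, angle: float) -> None:
        length = float(rng.uniform(*branch_length_range))
        direction = np.array([math.cos(angle), math.sin(angle), 0.0])
        bid = new_id()
        branches[bid] = build_branch(
            bid, length, diameter / 2.0, parent_id=parent_id, attach_s=attach_s,
            spacing=SAMPLE_SPACING_MM, origin=origin, direction=direction,
        )
        if gen_left <= 0:
            return
        a = float(rng.uniform(*asymmetry_range))
        g = murray_exponent
        d_large = diameter / (1.0 + a**g) ** (1.0 / g)
        d_small = a * d_large
        if d_small < diameter_floor:
            return
        tip = origin + length * direction
        tip_s = branches[bid].samples[-1].s
        spread = float(rng.uniform(math.radians(20), math.radians(40)))
        grow(bid, tip_s, d_large, gen_left - 1, tip, angle + spread / 2.0)
        grow(bid, tip_s, d_small, gen_left - 1, tip, angle - spread / 2.0)

    grow(None, 0.0, root_diameter, generations, np.zeros(3), 0.0)
    return CoronaryTree(branches=branches, root_id="v0",
                        metadata={"seed": int(seed), "generations": int(generations)})


def apply_stenosis(tree: CoronaryTree, spec: StenosisSpec) -> CoronaryTree:
    """Return a copy of the tree with a cosine-tapered stenosis applied.

    The radius multiplier at arc position s within the extent is
    1 - (severity/100) * 0.5 * (1 + cos(2 pi (s - s_center)/length)); it
    reaches 1 - severity/100 at s_center and 1 at the extent boundaries.
    """
    b = tree.branch(spec.branch_id)
    lo = spec.s_center - spec.length / 2.0
    hi = spec.s_center + spec.length / 2.0
    if lo < b.samples[0].s - 1e-9 or hi > b.samples[-1].s + 1e-9:
        raise GeometryError(
            f"stenosis extent [{lo}, {hi}] exceeds branch {b.id!r} arc range"
        )
    new = tree.copy()
    nb = new.branches[spec.branch_id]
    sev = spec.severity / 100.0
    samples = []
    for p in nb.samples:
        if lo <= p.s <= hi:
            theta = 2.0 * math.pi * (p.s - spec.s_center) / spec.length
            factor = 1.0 - sev * 0.5 * (1.0 + math.cos(theta))
            samples.append(CenterlineSample(s=p.s, r=p.r * factor, xyz=p.xyz))
        else:
            samples.append(p)
    nb.samples = samples
    return new


# ---------------------------------------------------------------------------
# validation cohorts
# ---------------------------------------------------------------------------


def lesion_target_branch(tree: CoronaryTree) -> str:
    """Branch a synthetic lesion lands on: the largest daughter of the root
    trunk (an LAD equivalent), or the root itself for a single-branch tree."""
    kids = tree.children_of(tree.root_id)
    if not kids:
        return tree.root_id
    return max(kids, key=lambda b: float(np.mean(b.r))).id


@dataclass
class CohortCase:
    """One synthetic patient: anatomy, physiology, lesion, and paired FFRs."""

    patient_id: str
    tree: CoronaryTree
    stented_tree: CoronaryTree
    patient: PatientRecord
    stenosis: StenosisSpec
    site: MeasurementSite
    ffr_pre: float
    ffr_post: float
    invasive_pre: float
    invasive_post: float


def _stent_lesion(tree: CoronaryTree, spec: StenosisSpec) -> CoronaryTree:
    """Restore the lesion extent to its reference radius (idealized stent)."""
    healthy = tree.copy()
    b = healthy.branches[spec.branch_id]
    lo = spec.s_center - spec.length / 2.0
    hi = spec.s_center + spec.length / 2.0
    sev = spec.severity / 100.0
    samples = []
    for p in b.samples:
        if lo <= p.s <= hi:
            theta = 2.0 * math.pi * (p.s - spec.s_center) / spec.length
            factor = 1.0 - sev * 0.5 * (1.0 + math.cos(theta))
            samples.append(CenterlineSample(s=p.s, r=p.r / factor, xyz=p.xyz))
        else:
            samples.append(p)
    b.samples = samples
    return healthy


def generate_validation_cohort(
    spec: CohortSpec,
    generations: int = 2,
    params: HemoParams = HemoParams(),
    settings: SolverSettings = SolverSettings(),
) -> tuple[list[CohortCase], pd.DataFrame]:
    """Generate a cohort of stenosed trees with paired simulated and
    pseudo-invasive FFR, before and after (idealized) stenting.

    Each patient gets a seeded Murray tree rooted at a left-main-equivalent
    trunk; one stenosis with severity drawn from ``severity_range`` is placed
    mid-way along the trunk's larger daughter (the LAD-equivalent), and the
    measurement site sits just proximal to that daughter's own bifurcation.
    Placing the lesion on one vessel of a larger perfusion network mirrors
    clinical anatomy and keeps the total-outflow calibration well posed: the
    healthy subtrees absorb the resistance rescale while flow through the
    lesioned vessel sags physiologically.  The paired table follows the
    agreement-statistics schema with columns vessel_id, phase, ffr_invasive,
    ffr_sim.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_patients)
    cases: list[CohortCase] = []
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = generate_tree(tree_seed, generations=generations)
        target_branch = lesion_target_branch(tree)
        tb = tree.branches[target_branch]
        sev = float(rng.uniform(*spec.severity_range))
        center = round((tb.length / 2.0) / SAMPLE_SPACING_MM) * SAMPLE_SPACING_MM
        # treated lesion lengths cluster around 20-26 mm clinically; fit the
        # taper inside the branch when the vessel is shorter
        length = min(20.0, 2.0 * min(center, tb.length - center) - 1.0)
        sten = StenosisSpec(branch_id=target_branch, s_center=center,
                            length=length, severity=sev)
        stenosed = apply_stenosis(tree, sten)
        sbp = float(rng.uniform(*spec.sbp_range))
        dbp = float(rng.uniform(*spec.dbp_range))
        mass = float(rng.uniform(*spec.mass_range))
        patient = PatientRecord(sbp=sbp, dbp=dbp, lv_mass=mass,
                                patient_id=f"SP{i + 1:03d}")
        site = MeasurementSite(branch_id=target_branch,
                               s=tb.samples[-1].s - 2.0 * SAMPLE_SPACING_MM)

        def _ffr(model: CoronaryTree) -> float:
            p_in, bcs, target = build_outlet_bcs(model, patient, params)
            _, sol = calibrate_total_flow(model, p_in, bcs, target, settings, params)
            return sol.pressure_at(site.branch_id, site.s) / p_in

        ffr_pre = _ffr(stenosed)
        stented = _stent_lesion(stenosed, sten)
        ffr_post = _ffr(stented)
        inv_pre = float(np.clip(ffr_pre + spec.bias + rng.normal(0.0, spec.noise_sd)
                                if spec.noise_sd > 0 else ffr_pre + spec.bias,
                                1e-6, 1.0))
        inv_post = float(np.clip(ffr_post + spec.bias + rng.normal(0.0, spec.noise_sd)
                                 if spec.noise_sd > 0 else ffr_post + spec.bias,
                                 1e-6, 1.0))
        cases.append(CohortCase(
            patient_id=patient.patient_id, tree=stenosed, stented_tree=stented,
            patient=patient, stenosis=sten, site=site,
            ffr_pre=ffr_pre, ffr_post=ffr_post,
            invasive_pre=inv_pre, invasive_post=inv_post,
        ))
        rows.append(dict(vessel_id=patient.patient_id, phase="pre",
                         ffr_invasive=inv_pre, ffr_sim=ffr_pre))
        rows.append(dict(vessel_id=patient.patient_id, phase="post",
                         ffr_invasive=inv_post, ffr_sim=ffr_post))
    return cases, pd.DataFrame(rows)


def write_cohort(cases: list[CohortCase], paired: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Persist a cohort: one tree JSON per patient, a patients CSV, and the
    paired-FFR CSV."""
    from .tree import write_tree

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = []
    for c in cases:
        write_tree(c.tree, out / f"{c.patient_id}_tree.json")
        patients.append(dict(patient_id=c.patient_id, sbp=c.patient.sbp,
                             dbp=c.patient.dbp, lv_mass=c.patient.lv_mass,
                             severity=c.stenosis.severity))
    pd.DataFrame(patients).to_csv(out / "patients.csv", index=False)
    paired.to_csv(out / "paired_ffr.csv", index=False)
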