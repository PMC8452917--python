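"""End-to-end orchestration: single-case and cohort workflows.

A case runs the full chain: load tree -> patient boundary conditions ->
calibrate outlet resistances to the hyperemic inflow target -> steady solve
-> FFR at the measurement sites -> (optionally) deploy stents, recalibrate
and resolve for the post-stent FFR.  A cohort run generates a seeded
synthetic validation cohort, runs every case pre/post, and evaluates the
agreement statistics against the pseudo-invasive reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .assessment import ISCHEMIA_THRESHOLD, compute_ffr
from .physiology import HemoParams, PatientRecord, build_outlet_bcs
from .solver import SolverSettings, calibrate_total_flow
from .stats import agreement_report
from .stenting import StentSpec, auto_size_stent, deploy_stents
from .synthetic import CohortSpec, generate_validation_cohort, write_cohort
from .tree import CoronaryTree, MeasurementSite, read_tree

log = logging.getLogger("coroflow")


@dataclass
class CaseConfig:
    """Everything needed to run one pre/post-stent simulation."""

    tree: Union[str, Path, CoronaryTree]
    patient: PatientRecord
    sites: Sequence[MeasurementSite]
    stents: Sequence[StentSpec] = ()
    auto_stent_branches: Sequence[str] = ()  # size stents from the area curve
    hemo: HemoParams = field(default_factory=HemoParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    calibration_mode: str = "as_imaged"  # or "reference_healthy"
    reference_tree: Optional[CoronaryTree] = None
    threshold: float = ISCHEMIA_THRESHOLD
    out_dir: Optional[Union[str, Path]] = None
    seed: int = 0


def _simulate(tree: CoronaryTree, config: CaseConfig):
    """Calibrate and solve one model; returns (inlet pressure, solution, bcs)."""
    p_in, bcs, target = build_outlet_bcs(tree, config.patient, config.hemo)
    if config.calibration_mode == "reference_healthy":
        ref = config.reference_tree
        if ref is None:
            raise ValueError("reference_healthy calibration needs reference_tree")
        from .solver import solve_flow

        cal_bcs, _ = calibrate_total_flow(ref, p_in, bcs, target,
                                          config.solver, config.hemo)
        sol = solve_flow(tree, p_in, cal_bcs, config.solver, config.hemo)
        return p_in, sol, cal_bcs
    cal_bcs, sol = calibrate_total_flow(tree, p_in, bcs, target,
                                        config.solver, config.hemo)
    return p_in, sol, cal_bcs


def run_case(config: CaseConfig) -> dict:
    """Run one case end to end; returns (and optionally writes) the report."""
    tree = config.tree if isinstance(config.tree, CoronaryTree) else read_tree(config.tree)
    p_in, sol_pre, _ = _simulate(tree, config)
    log.info("pre-stent solve: %d iterations, residual %.2e",
             sol_pre.iterations, sol_pre.residual)
    report = {
        "seed": config.seed,
        "patient": asdict(config.patient),
        "inlet_pressure_mmHg": p_in,
        "hyperemic_inflow_mL_min": sol_pre.inlet_flow,
        "calibration_mode": config.calibration_mode,
        "pre": {"iterations": sol_pre.iterations, "residual": sol_pre.residual,
                "sites": []},
    }
    for site in config.sites:
        res = compute_ffr(sol_pre, p_in, site, phase="pre", threshold=config.threshold)
        report["pre"]["sites"].append(
            {"branch_id": site.branch_id, "s": site.s,
             "ffr": res.ffr, "ischemic": res.ischemic})
    stents = list(config.stents)
    for bid in config.auto_stent_branches:
        stents.append(auto_size_stent(tree, bid))
    if stents:
        stented = deploy_stents(tree, stents)
        p_in2, sol_post, _ = _simulate(stented, config)
        report["stents"] = [
            {"branch_id": sp.branch_id, "s_proximal": sp.s_proximal,
             "s_distal": sp.s_distal, "length": sp.length, "diameter": sp.diameter}
            for sp in stents
        ]
        report["post"] = {"iterations": sol_post.iterations,
                          "residual": sol_post.residual, "sites": []}
        for site in config.sites:
            res = compute_ffr(sol_post, p_in2, site, phase="post",
                              threshold=config.threshold)
            report["post"]["sites"].append(
                {"branch_id": site.branch_id, "s": site.s,
                 "ffr": res.ffr, "ischemic": res.ischemic})
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "case_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        sol_pre.to_frame().to_csv(out / "solution_pre.csv", index=False)
        if stents:
            sol_post.to_frame().to_csv(out / "solution_post.csv", index=False)
    return report


def run_cohort(
    spec: CohortSpec,
    out_dir: Optional[Union[str, Path]] = None,
    hemo: HemoParams = HemoParams(),
    solver: SolverSettings = SolverSettings(),
    threshold: float = ISCHEMIA_THRESHOLD,
    make_plots: bool = True,
) -> dict:
    """Generate and evaluate a synthetic validation cohort.

    Returns a report with per-phase agreement statistics and the paired
    table; when ``out_dir`` is given, writes the cohort, the report JSON,
    and scatter/Bland-Altman plots.
    """
    cases, paired = generate_validation_cohort(spec, params=hemo, settings=solver)
    stats = agreement_report(paired, threshold=threshold)
    report = {
        "spec": asdict(spec),
        "n_cases": len(cases),
        "stats": stats,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cases, paired, out / "cohort")
        (out / "cohort_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        if make_plots:
            from .plots import agreement_plots

            agreement_plots(paired, out)
    report["paired"] = paired
    return report


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------


def load_params(path: Optional[Union[str, Path]] = None,
                **overrides) -> tuple[HemoParams, SolverSettings]:
    """Hemodynamic and solver settings from a YAML/JSON config file plus
    keyword overrides (flat keys; solver keys prefixed ``solver_``)."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})
    solver_keys = {"relaxation", "flow_tolerance", "inner_tolerance", "max_iterations"}
    hemo_kwargs = {k: v for k, v in doc.items()
                   if k in HemoParams.__dataclass_fields__}
    solver_kwargs = {k.removeprefix("solver_"): v for k, v in doc.items()
                     if k.removeprefix("solver_") in solver_keys}
    return HemoParams(**hemo_kwargs), SolverSettings(**solver_kwargs)
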