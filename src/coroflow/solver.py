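"""Steady-state reduced-order flow solver on a centerline tree.

The pressure drop along a vessel combines a fully developed viscous
(Poiseuille) term integrated over the sampled radius profile,

    dP_visc = integral 8 mu / (pi r(s)^4) * Q ds,

with Bernoulli-type irreversible expansion (Borda-Carnot) losses collected
over maximal lumen-area expansion events,

    dP_exp = sum (rho / 2) * Q^2 * (1/A_min - 1/A_down)^2,

where A_min is the throat area opening an expansion run and A_down the area
at its downstream end.  Both terms are positive and monotone increasing in Q,
so the network has a unique steady solution for positive outlet resistances.

``solve_flow`` finds outlet flows such that along every root-to-outlet path
P_in - sum(dP) = P0 + R_i * Q_i, using a damped (under-relaxed) fixed-point
update on the outlet flows; ``calibrate_total_flow`` wraps it in the outer
under-relaxed rescaling of all outlet resistances until total outflow matches
the hyperemic inflow target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, TopologyError
from .physiology import HemoParams, OutletBC
from .tree import CoronaryTree
from .units import M3S_TO_MLMIN, MLMIN_TO_M3S, MM_TO_M, MMHG_TO_PA, PA_TO_MMHG


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the flow solve and calibration.

    relaxation : under-relaxation factor applied to both the inner flow
        update and the outer resistance rescale exponent
    flow_tolerance : relative tolerance on |total outflow - target|
    inner_tolerance : relative pressure-residual tolerance of the flow solve
    max_iterations : cap for either loop
    """

    relaxation: float = 0.5
    flow_tolerance: float = 1e-3
    inner_tolerance: float = 1e-8
    max_iterations: int = 500

    def __post_init__(self):
        if not (0 < self.relaxation <= 1):
            raise ValueError("relaxation must lie in (0, 1]")
        if self.flow_tolerance <= 0 or self.inner_tolerance <= 0:
            raise ValueError("tolerances must be positive")

    def with_overrides(self, **kwargs) -> "SolverSettings":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# geometry pre-processing
# ---------------------------------------------------------------------------


def _expansion_events(A: np.ndarray, rho: float) -> list[tuple[int, int, float]]:
    """Maximal strictly-increasing runs of area -> (i_throat, i_end, coef).

    coef has units Pa / (m^3/s)^2; the loss of one event is coef * Q^2 with Q
    the flow through the throat interval.
    """
    events = []
    n = len(A)
    i = 0
    while i < n - 1:
        if A[i + 1] > A[i]:
            j = i
            while j < n - 1 and A[j + 1] >= A[j]:
                j += 1
            if A[j] > A[i]:
                coef = 0.5 * rho * (1.0 / A[i] - 1.0 / A[j]) ** 2
                events.append((i, j, coef))
            i = j
        else:
            i += 1
    return events


class _CompiledBranch:
    """Per-branch geometry factors in SI units."""

    __slots__ = ("id", "n", "g", "cumG", "events", "children", "s_mm")

    def __init__(self, branch, params: HemoParams):
        self.id = branch.id
        s = branch.s * MM_TO_M
        r = branch.r * MM_TO_M
        self.s_mm = branch.s
        self.n = len(s)
        dens = 8.0 * params.mu / (math.pi * r**4)  # Pa per (m^3/s) per m
        self.g = 0.5 * (dens[:-1] + dens[1:]) * np.diff(s)
        self.cumG = np.concatenate([[0.0], np.cumsum(self.g)])
        A = math.pi * r**2
        self.events = _expansion_events(A, params.rho)
        self.children: list[tuple[str, int]] = []  # (child_id, attach sample index)


class _Network:
    """Compiled tree: topological order, outlet paths, per-branch factors."""

    def __init__(self, tree: CoronaryTree, params: HemoParams):
        self.tree = tree
        self.params = params
        self.branches = {bid: _CompiledBranch(b, params) for bid, b in tree.branches.items()}
        for bid in self.branches:
            cb = self.branches[bid]
            s_mm = cb.s_mm
            for child in tree.children_of(bid):
                # flows split at the sample nearest the attachment point
                idx = int(np.argmin(np.abs(s_mm - child.attach_s)))
                cb.children.append((child.id, idx))
        # topological order root -> leaves
        self.order: list[str] = []
        stack = [tree.root_id]
        while stack:
            bid = stack.pop()
            self.order.append(bid)
            stack.extend(c.id for c in tree.children_of(bid))
        self.outlets = tree.outlet_ids()
        # outlet path: list of (branch_id, end sample index) from root to tip
        self.paths: dict[str, list[tuple[str, int]]] = {}
        for o in self.outlets:
            chain = tree.path_to_root(o)
            segs = []
            for k, bid in enumerate(chain):
                cb = self.branches[bid]
                if k + 1 < len(chain):
                    nxt = chain[k + 1]
                    end = next(idx for cid, idx in cb.children if cid == nxt)
                else:
                    end = cb.n - 1
                segs.append((bid, end))
            self.paths[o] = segs
        # shared path prefix of every outlet pair, for the coupling Jacobian
        self.shared: dict[tuple[str, str], list[tuple[str, int]]] = {}
        for i, oi in enumerate(self.outlets):
            for oj in self.outlets[i:]:
                pi, pj = self.paths[oi], self.paths[oj]
                segs = []
                for (bi, ei), (bj, ej) in zip(pi, pj):
                    if bi != bj:
                        break
                    e = min(ei, ej)
                    if e > 0:
                        segs.append((bi, e))
                    if ei != ej:
                        break
                self.shared[(oi, oj)] = segs
                self.shared[(oj, oi)] = segs


# ---------------------------------------------------------------------------
# pressure-drop primitive
# ---------------------------------------------------------------------------


def segment_pressure_drop(
    profile: Sequence[tuple[float, float]] | np.ndarray,
    Q: float,
    params: HemoParams = HemoParams(),
) -> float:
    """Pressure drop (mmHg) across one radius profile carrying flow Q (mL/min).

    ``profile`` is an ordered sequence of (s, r) pairs in mm.  Combines the
    trapezoidal Poiseuille integral with Borda-Carnot expansion losses; both
    vanish at Q = 0.  Flow reversal (Q < 0) is not supported.
    """
    if Q < 0:
        raise ValueError("negative flow (reversal) is not supported")
    if Q == 0:
        return 0.0
    prof = np.asarray(profile, dtype=float)
    s = prof[:, 0] * MM_TO_M
    r = prof[:, 1] * MM_TO_M
    q = Q * MLMIN_TO_M3S
    dens = 8.0 * params.mu / (math.pi * r**4)
    visc = float(np.sum(0.5 * (dens[:-1] + dens[1:]) * np.diff(s))) * q
    A = math.pi * r**2
    exp_loss = sum(coef for _, _, coef in _expansion_events(A, params.rho)) * q**2
    return (visc + exp_loss) * PA_TO_MMHG


# ---------------------------------------------------------------------------
# flow solution container
# ---------------------------------------------------------------------------


@dataclass
class FlowSolution:
    """Converged steady flow field on the tree.

    branch_flows : proximal (entry) flow of each branch, mL/min
    outlet_flows : flow leaving each outlet, mL/min
    sample_pressures : per-branch pressure arrays on the branch sample grid, mmHg
    """

    branch_flows: dict[str, float]
    outlet_flows: dict[str, float]
    sample_pressures: dict[str, np.ndarray]
    sample_s: dict[str, np.ndarray]
    inlet_pressure: float
    inlet_flow: float
    converged: bool
    iterations: int
    residual: float

    def pressure_at(self, branch_id: str, s: float) -> float:
        """Pressure (mmHg) at arc position s, linearly interpolated."""
        return float(np.interp(s, self.sample_s[branch_id], self.sample_pressures[branch_id]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bid in sorted(self.sample_pressures):
            s = self.sample_s[bid]
            p = self.sample_pressures[bid]
            q = self.branch_flows[bid]
            for si, pi in zip(s, p):
                rows.append(dict(branch_id=bid, s=si, P_mmHg=pi, Q_mL_min=q))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _evaluate(net: _Network, p_in_pa: float, q_out: dict[str, float]):
    """Branch flows, interval flows, and sample pressures for given outlet flows.

    Returns (totals, pressures, q_intervals) in SI.
    """
    totals: dict[str, float] = {}
    for bid in reversed(net.order):
        cb = net.branches[bid]
        q = q_out.get(bid, 0.0)
        q += sum(totals[cid] for cid, _ in cb.children)
        totals[bid] = q
    pressures: dict[str, np.ndarray] = {}
    q_ints: dict[str, np.ndarray] = {}
    for bid in net.order:
        cb = net.branches[bid]
        removed = np.zeros(cb.n)
        for cid, idx in cb.children:
            removed[idx] += totals[cid]
        removed = np.cumsum(removed)
        q_int = totals[bid] - removed[: cb.n - 1]
        q_ints[bid] = q_int
        drops = np.zeros(cb.n)
        drops[1:] = cb.g * q_int
        for i0, i1, coef in cb.events:
            qe = q_int[min(i0, cb.n - 2)]
            drops[i1] += coef * qe * qe
        branch = net.tree.branches[bid]
        if branch.parent_id is None:
            p_entry = p_in_pa
        else:
            parent = pressures[branch.parent_id]
            p_entry = float(
                np.interp(branch.attach_s, net.branches[branch.parent_id].s_mm, parent)
            )
        pressures[bid] = p_entry - np.cumsum(drops)
    return totals, pressures, q_ints


def _segs_stiffness(net: _Network, segs, q_ints: dict[str, np.ndarray]) -> float:
    """d(pressure drop over segments)/d(downstream flow), Pa per (m^3/s)."""
    d = 0.0
    for bid, end in segs:
        cb = net.branches[bid]
        d += cb.cumG[end]
        q_int = q_ints[bid]
        for i0, i1, coef in cb.events:
            if i1 <= end:
                d += 2.0 * coef * q_int[min(i0, cb.n - 2)]
    return d


_QMIN = 1e-15  # m^3/s floor keeping outlet flows positive


def solve_flow(
    tree: CoronaryTree,
    inlet_pressure: float,
    bcs: Sequence[OutletBC],
    settings: SolverSettings = SolverSettings(),
    params: HemoParams = HemoParams(),
    _network: Optional[_Network] = None,
    _warm_start: Optional[dict[str, float]] = None,
) -> FlowSolution:
    """Solve steady flow for given inlet pressure (mmHg) and outlet BCs.

    Outlet flows are iterated with an under-relaxed Newton update on the
    pressure-balance residuals f_i = P_tip,i - P0 - R_i Q_i, with the exact
    (small, symmetric) Jacobian built from path stiffnesses; the relaxation
    factor damps each step.  Because the epicardial losses are strictly
    increasing in flow, the pressure balance has a unique solution, which is
    independent of the iteration scheme and of the relaxation factor.
    """
    net = _network or _Network(tree, params)
    bc_map = {bc.outlet_id: bc for bc in bcs}
    if set(bc_map) != set(net.outlets):
        raise TopologyError(
            f"boundary conditions must cover exactly the outlets {sorted(net.outlets)}, "
            f"got {sorted(bc_map)}"
        )
    if not net.outlets:
        raise TopologyError("tree has no outlets")
    p_in_pa = inlet_pressure * MMHG_TO_PA
    p0_pa = {o: bc_map[o].p0 * MMHG_TO_PA for o in net.outlets}
    # resistance mmHg min/mL -> Pa s/m^3
    R = {o: bc_map[o].resistance * MMHG_TO_PA / MLMIN_TO_M3S for o in net.outlets}
    if _warm_start:
        q_out = {o: max(_warm_start[o], _QMIN) for o in net.outlets}
    else:
        q_out = {o: (p_in_pa - p0_pa[o]) / R[o] for o in net.outlets}
    alpha = settings.relaxation
    scale = max(p_in_pa - min(p0_pa.values()), 1.0)
    outlets = net.outlets
    n_out = len(outlets)
    history = []
    residual = math.inf
    for it in range(1, settings.max_iterations + 1):
        totals, pressures, q_ints = _evaluate(net, p_in_pa, q_out)
        f = np.array([pressures[o][-1] - p0_pa[o] - R[o] * q_out[o] for o in outlets])
        residual = float(np.max(np.abs(f)) / scale)
        history.append(residual)
        if residual <= settings.inner_tolerance:
            break
        # damped Newton on the outlet pressure balances; J couples outlets
        # through the stiffness of their shared path prefix
        J = np.empty((n_out, n_out))
        for i, oi in enumerate(outlets):
            for j in range(i, n_out):
                k = _segs_stiffness(net, net.shared[(oi, outlets[j])], q_ints)
                J[i, j] = J[j, i] = k
        J[np.diag_indices(n_out)] += np.array([R[o] for o in outlets])
        dq = np.linalg.solve(J, f)
        for i, o in enumerate(outlets):
            q_out[o] = max(q_out[o] + alpha * dq[i], _QMIN)
    else:
        raise ConvergenceError(
            f"flow solve did not converge in {settings.max_iterations} iterations "
            f"(residual {residual:.3e})",
            residual_history=history,
        )
    totals, pressures, _ = _evaluate(net, p_in_pa, q_out)
    return FlowSolution(
        branch_flows={b: q * M3S_TO_MLMIN for b, q in totals.items()},
        outlet_flows={o: q * M3S_TO_MLMIN for o, q in q_out.items()},
        sample_pressures={b: p * PA_TO_MMHG for b, p in pressures.items()},
        sample_s={b: net.branches[b].s_mm.copy() for b in net.branches},
        inlet_pressure=inlet_pressure,
        inlet_flow=totals[tree.root_id] * M3S_TO_MLMIN,
        converged=True,
        iterations=it,
        residual=residual,
    )


def calibrate_total_flow(
    tree: CoronaryTree,
    inlet_pressure: float,
    bcs: Sequence[OutletBC],
    target: float,
    settings: SolverSettings = SolverSettings(),
    params: HemoParams = HemoParams(),
) -> tuple[list[OutletBC], FlowSolution]:
    """Uniformly rescale outlet resistances until total outflow hits ``target``.

    The scale factor beta follows the under-relaxed multiplicative update
    beta <- beta * (Q_total / target)^alpha; total outflow is monotone
    decreasing in beta, so the fixed point is unique.  Returns the calibrated
    BC list and the final converged solution.
    """
    if target <= 0:
        raise ValueError("target flow must be positive")
    net = _Network(tree, params)
    beta = 1.0
    warm = None
    history = []
    for _ in range(settings.max_iterations):
        scaled = [replace(bc, resistance=bc.resistance * beta) for bc in bcs]
        sol = solve_flow(tree, inlet_pressure, scaled, settings, params,
                         _network=net, _warm_start=warm)
        warm = {o: q * MLMIN_TO_M3S for o, q in sol.outlet_flows.items()}
        ratio = sol.inlet_flow / target
        history.append(abs(ratio - 1.0))
        if abs(ratio - 1.0) <= settings.flow_tolerance:
            return scaled, sol
        beta *= ratio**settings.relaxation
        if beta < 1e-10:
            raise ConvergenceError(
                "flow target unattainable: epicardial losses alone exceed the "
                "driving pressure at the target flow (outlet resistances would "
                "have to vanish)", residual_history=history)
    raise ConvergenceError(
        f"flow calibration did not reach target within {settings.max_iterations} "
        f"outer iterations (relative error {history[-1]:.3e})",
        residual_history=history,
    )
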