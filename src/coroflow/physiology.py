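"""Patient physiology and boundary-condition construction.

The simulated FFR pipeline drives a steady hyperemic flow through the
coronary tree.  The inlet is held at a static pressure equal to the
patient's mean brachial pressure minus a fixed adenosine offset (6.8 mmHg).
Each outlet carries a lumped resistance to a shared venous reference
pressure P0.  Resting total coronary flow scales allometrically with left
ventricular mass, Q_rest = c * m^0.75; hyperemia is modelled as microvascular
resistance falling to 0.21x its resting value, i.e. a target hyperemic inflow
of Q_rest / 0.21 at the fixed inlet pressure.  Flow (and hence conductance)
is apportioned among outlets by a Murray-type power of the local outlet
diameter, d^k with k = 3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import TopologyError
from .tree import CoronaryTree


@dataclass(frozen=True)
class PatientRecord:
    """Brachial pressures (mmHg) and left-ventricular mass (g)."""

    sbp: float
    dbp: float
    lv_mass: float
    patient_id: Optional[str] = None

    def __post_init__(self):
        if not (self.sbp > self.dbp > 0):
            raise ValueError(f"require sbp > dbp > 0, got {self.sbp}/{self.dbp}")
        if self.lv_mass <= 0:
            raise ValueError("lv_mass must be positive")

    @property
    def mbp(self) -> float:
        return mean_blood_pressure(self.sbp, self.dbp)


@dataclass(frozen=True)
class HemoParams:
    """Hemodynamic model parameters.

    rho : blood density, kg/m^3
    mu : dynamic viscosity, Pa s (Newtonian blood)
    flow_coeff : allometric coefficient c, mL/min per g^0.75 (default 2.6,
        giving ~0.8 mL/min/g resting perfusion at a 114 g left ventricle)
    flow_exponent : allometric exponent (3/4 scaling law)
    hyperemia_factor : hyperemic-to-resting microvascular resistance ratio
    inlet_offset : adenosine pressure offset subtracted from MBP, mmHg
    murray_exponent : diameter power k used to apportion outlet flow
    p0 : shared outlet reference pressure, mmHg (venous, default 0)
    """

    rho: float = 1050.0
    mu: float = 0.0035
    flow_coeff: float = 2.6
    flow_exponent: float = 0.75
    hyperemia_factor: float = 0.21
    inlet_offset: float = 6.8
    murray_exponent: float = 3.0
    p0: float = 0.0

    def __post_init__(self):
        if min(self.rho, self.mu, self.flow_coeff, self.flow_exponent) <= 0:
            raise ValueError("rho, mu, flow_coeff, flow_exponent must be positive")
        if not (0 < self.hyperemia_factor <= 1):
            raise ValueError("hyperemia_factor must lie in (0, 1]")
        if self.p0 < 0:
            raise ValueError("p0 must be non-negative")

    def with_overrides(self, **kwargs) -> "HemoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OutletBC:
    """Lumped resistance boundary condition at one outlet.

    resistance : mmHg min / mL
    p0 : reference pressure, mmHg (shared across outlets)
    """

    outlet_id: str
    resistance: float
    p0: float = 0.0

    def __post_init__(self):
        if self.resistance <= 0:
            raise ValueError("resistance must be positive")


def mean_blood_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from brachial cuff pressures (mmHg):
    MBP = DBP + (SBP - DBP) / 3."""
    if sbp <= dbp:
        raise ValueError(f"sbp must exceed dbp, got {sbp} <= {dbp}")
    return dbp + (sbp - dbp) / 3.0


def resting_flow(lv_mass: float, params: HemoParams = HemoParams()) -> float:
    """Resting total coronary flow (mL/min) from LV mass (g):
    Q_rest = c * m^e with the 3/4-power allometric default."""
    if lv_mass <= 0:
        raise ValueError("lv_mass must be positive")
    return params.flow_coeff * lv_mass**params.flow_exponent


def outlet_diameter(tree: CoronaryTree, outlet_id: str, n_tail: int = 3) -> float:
    """Representative outlet diameter (mm): mean lumen diameter over the
    branch's last ``n_tail`` samples."""
    b = tree.branch(outlet_id)
    r = b.r[-n_tail:]
    return float(2.0 * np.mean(r))


def outlet_flow_weights(tree: CoronaryTree, params: HemoParams = HemoParams()) -> dict[str, float]:
    """Murray-type flow split: w_i = d_i^k / sum_j d_j^k over outlet diameters."""
    outlets = tree.outlet_ids()
    if not outlets:
        raise TopologyError("tree has no outlets")
    d = np.array([outlet_diameter(tree, o) for o in outlets])
    w = d**params.murray_exponent
    w = w / w.sum()
    return dict(zip(outlets, w.tolist()))


def build_outlet_bcs(
    tree: CoronaryTree,
    patient: PatientRecord,
    params: HemoParams = HemoParams(),
) -> tuple[float, list[OutletBC], float]:
    """Inlet pressure, per-outlet resistance BCs, and hyperemic flow target.

    Returns ``(p_in, bcs, q_target)`` where p_in = MBP - inlet_offset (mmHg),
    q_target = Q_rest / hyperemia_factor (mL/min), and each outlet's initial
    resistance is R_i = (p_in - p0) / (w_i * q_target) so that, absent
    epicardial losses, the outlet would draw exactly its share of the target.
    The solver's calibration loop rescales all R_i uniformly so total outflow
    matches q_target through the actual (possibly stenosed) tree.
    """
    p_in = patient.mbp - params.inlet_offset
    if p_in <= params.p0:
        raise ValueError("inlet pressure must exceed the outlet reference pressure")
    q_target = resting_flow(patient.lv_mass, params) / params.hyperemia_factor
    weights = outlet_flow_weights(tree, params)
    bcs = [
        OutletBC(outlet_id=o, resistance=(p_in - params.p0) / (w * q_target), p0=params.p0)
        for o, w in sorted(weights.items())
    ]
    return p_in, bcs, q_target
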