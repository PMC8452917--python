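"""Simulated-FFR readout, ischemia classification, and diameter stenosis.

FFR is the ratio of distal coronary pressure to aortic pressure under
maximal hyperemia; here the denominator is the model inlet pressure
(MBP - 6.8 mmHg, the simulated hyperemic aortic pressure) and the numerator
the solved pressure at the measurement site.  FFR <= 0.80 is read as
hemodynamically significant (ischemia), with the boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoLesionError
from .solver import FlowSolution
from .stenting import LesionRecord, find_shoulders
from .tree import CoronaryTree, MeasurementSite, lumen_area_curve

ISCHEMIA_THRESHOLD = 0.80


@dataclass(frozen=True)
class FfrResult:
    """Simulated FFR at one measurement site."""

    site: MeasurementSite
    ffr: float
    phase: str  # pre | post
    ischemic: bool


def classify_ischemia(ffr: float, threshold: float = ISCHEMIA_THRESHOLD) -> bool:
    """True when the FFR indicates ischemia (ffr <= threshold, inclusive)."""
    if not (0 < ffr <= 1.05):
        raise ValueError(f"ffr {ffr} outside the plausible range (0, 1.05]")
    return ffr <= threshold


def compute_ffr(
    solution: FlowSolution,
    inlet_pressure: float,
    site: MeasurementSite,
    phase: str = "pre",
    threshold: float = ISCHEMIA_THRESHOLD,
) -> FfrResult:
    """Read simulated FFR off a converged flow solution.

    The site pressure is linearly interpolated on the branch sample grid.
    Values exceeding 1 by more than 1e-6 (possible only through numerical
    noise) are clipped with a warning.
    """
    if not solution.converged:
        raise RuntimeError("flow solution is not converged; FFR undefined")
    p = solution.pressure_at(site.branch_id, site.s)
    ffr = p / inlet_pressure
    if ffr > 1.0 + 1e-6:
        warnings.warn(f"FFR {ffr:.6f} exceeds 1; clipping", stacklevel=2)
    ffr = min(ffr, 1.0)
    return FfrResult(site=site, ffr=ffr, phase=phase,
                     ischemic=classify_ischemia(ffr, threshold))


def diameter_stenosis(
    tree: CoronaryTree, branch_id: str, s_range: tuple[float, float]
) -> tuple[float, LesionRecord]:
    """Percent diameter stenosis of the worst narrowing in ``s_range``.

    The reference diameter at the throat is interpolated linearly between
    the lumen diameters at the proximal and distal shoulders (located from
    the curvature of the lumen-area curve); %DS = (1 - d_min/d_ref) * 100.
    Raises :class:`NoLesionError` for a monotone or flat area curve.
    """
    s, A = lumen_area_curve(tree, branch_id)
    i_P, i_S, i_D = find_shoulders(s, A, s_range)
    d = 2.0 * tree.branch(branch_id).r
    d_ref = float(np.interp(s[i_S], [s[i_P], s[i_D]], [d[i_P], d[i_D]]))
    d_min = float(d[i_S])
    pct = (1.0 - d_min / d_ref) * 100.0
    lesion = LesionRecord(
        branch_id=branch_id, s_range=(float(s[i_P]), float(s[i_D])),
        min_diameter=d_min, reference_diameter=d_ref, percent_ds=max(pct, 0.0),
    )
    return max(pct, 0.0), lesion
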