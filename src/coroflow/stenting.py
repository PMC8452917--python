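"""Virtual stent deployment, automatic stent sizing, and lesion typing.

Stent deployment is a pure geometry edit on the centerline model: the
diseased span between a proximal (P*) and distal (D*) location is replaced
by a cubic B-spline radius profile through circular control sections — the
original lumen radii at P* and D*, and stent-radius sections at regular
stations (3 mm apart by default) strictly inside the span.

Automatic sizing follows the lumen-area curve A(s): the stenotic site S is
the interior area minimum; the landing points P and D are the locations of
maximal absolute change of slope (discrete second difference of A) on either
side of S; stent length is D - P and stent diameter the mean of the lumen
diameters at P and D.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import GeometryError, NoLesionError
from .tree import CenterlineSample, CoronaryTree, lumen_area_curve

DEFAULT_SECTION_SPACING_MM = 3.0
DEFAULT_OSTIAL_MARGIN_MM = 3.0
TANDEM_DS_THRESHOLD = 50.0


@dataclass(frozen=True)
class StentSpec:
    """A stent placement: branch, landing points P*/D* (mm), diameter (mm)."""

    branch_id: str
    s_proximal: float
    s_distal: float
    diameter: float

    def __post_init__(self):
        if self.s_distal <= self.s_proximal:
            raise ValueError("s_distal must exceed s_proximal")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def length(self) -> float:
        return self.s_distal - self.s_proximal


@dataclass
class LesionRecord:
    """A localized narrowing with its quantitative and categorical typing."""

    branch_id: str
    s_range: tuple[float, float]
    min_diameter: float
    reference_diameter: float
    percent_ds: float
    type: Optional[str] = None  # focal | bifurcation | ostial | tandem-member

    def __post_init__(self):
        if not (0 <= self.percent_ds < 100):
            raise ValueError("percent_ds must lie in [0, 100)")
        if self.min_diameter > self.reference_diameter + 1e-12:
            raise ValueError("min_diameter cannot exceed reference_diameter")


def _interior_stations(s_proximal: float, s_distal: float, spacing: float) -> list[float]:
    """Stations at integer multiples of ``spacing`` strictly inside (P*, D*);
    a station landing exactly on D* is excluded."""
    stations = []
    k = 1
    while True:
        s = s_proximal + k * spacing
        if s >= s_distal - 1e-9:
            break
        stations.append(s)
        k += 1
    return stations


def deploy_stent(
    tree: CoronaryTree,
    spec: StentSpec,
    section_spacing: float = DEFAULT_SECTION_SPACING_MM,
) -> CoronaryTree:
    """Return a copy of the tree with the stent geometry applied.

    Control radii: the original lumen radii at P* and D* (so the profile
    blends into the untouched vessel) and the stent radius D/2 at each
    interior station.  The radius profile over [P*, D*] is the interpolating
    cubic B-spline through these controls, resampled onto the branch's
    existing s grid; geometry outside [P*, D*] is untouched.
    """
    if section_spacing <= 0:
        raise GeometryError("section_spacing must be positive")
    b = tree.branch(spec.branch_id)
    s0, s1 = b.samples[0].s, b.samples[-1].s
    if spec.s_proximal < s0 - 1e-9 or spec.s_distal > s1 + 1e-9:
        raise GeometryError(
            f"stent span [{spec.s_proximal}, {spec.s_distal}] outside branch "
            f"{b.id!r} arc range [{s0}, {s1}]"
        )
    ctrl_s = [spec.s_proximal] + _interior_stations(
        spec.s_proximal, spec.s_distal, section_spacing) + [spec.s_distal]
    ctrl_r = ([b.radius_at(spec.s_proximal)]
              + [spec.diameter / 2.0] * (len(ctrl_s) - 2)
              + [b.radius_at(spec.s_distal)])
    k = min(3, len(ctrl_s) - 1)
    if k >= 1:
        spline = make_interp_spline(ctrl_s, ctrl_r, k=k)
    else:  # degenerate single control; constant profile
        spline = lambda s: np.full_like(np.asarray(s, dtype=float), ctrl_r[0])
    new = tree.copy()
    nb = new.branches[spec.branch_id]
    samples = []
    for p in nb.samples:
        if spec.s_proximal <= p.s <= spec.s_distal:
            r = float(spline(p.s))
            if r <= 0:
                raise GeometryError("stent spline produced non-positive radius")
            samples.append(CenterlineSample(s=p.s, r=r, xyz=p.xyz))
        else:
            samples.append(p)
    nb.samples = samples
    return new


def deploy_stents(tree: CoronaryTree, specs: Sequence[StentSpec],
                  section_spacing: float = DEFAULT_SECTION_SPACING_MM) -> CoronaryTree:
    """Apply several stents sequentially in proximal-to-distal order."""
    out = tree
    for spec in sorted(specs, key=lambda sp: (sp.branch_id, sp.s_proximal)):
        out = deploy_stent(out, spec, section_spacing)
    return out


# ---------------------------------------------------------------------------
# sizing from the lumen-area curve
# ---------------------------------------------------------------------------


def _second_difference(s: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Three-point second difference of A(s) on a possibly non-uniform grid;
    end points are set to zero."""
    d2 = np.zeros_like(A)
    h0 = s[1:-1] - s[:-2]
    h1 = s[2:] - s[1:-1]
    d2[1:-1] = 2.0 * (A[:-2] / (h0 * (h0 + h1))
                      - A[1:-1] / (h0 * h1)
                      + A[2:] / (h1 * (h0 + h1)))
    return d2


def find_shoulders(
    s: np.ndarray, A: np.ndarray, window: tuple[float, float]
) -> tuple[int, int, int]:
    """Indices (i_P, i_S, i_D) of the lesion shoulders and throat in a window.

    i_S is the interior area minimum; i_P and i_D maximize the absolute
    discrete second difference of A proximal and distal to i_S.
    Raises :class:`NoLesionError` when no interior minimum exists (monotone or
    flat area curve).
    """
    lo, hi = window
    mask = (s >= lo - 1e-9) & (s <= hi + 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size < 5:
        raise NoLesionError("window too narrow to locate a lesion")
    Aw = A[idx]
    i_min_local = int(np.argmin(Aw))
    span = Aw.max() - Aw.min()
    if i_min_local in (0, idx.size - 1) or span <= 1e-9 * max(Aw.max(), 1.0):
        raise NoLesionError("no interior lumen-area minimum in window")
    i_S = int(idx[i_min_local])
    d2 = np.abs(_second_difference(s, A))
    prox = idx[idx < i_S]
    dist = idx[idx > i_S]
    if prox.size == 0 or dist.size == 0:
        raise NoLesionError("lesion throat lies at the window boundary")
    i_P = int(prox[np.argmax(d2[prox])])
    i_D = int(dist[np.argmax(d2[dist])])
    return i_P, i_S, i_D


def auto_size_stent(
    tree: CoronaryTree,
    branch_id: str,
    search_window: Optional[tuple[float, float]] = None,
) -> StentSpec:
    """Derive a stent length and diameter from the lumen-area curve.

    Stent length = s(D) - s(P); diameter = mean lumen diameter at P and D.
    When two dips lie in the window, the deeper one's throat is bracketed.
    """
    s, A = lumen_area_curve(tree, branch_id)
    window = search_window or (float(s[0]), float(s[-1]))
    i_P, _, i_D = find_shoulders(s, A, window)
    r = tree.branch(branch_id).r
    diameter = float(r[i_P] + r[i_D])  # mean of the two diameters = sum of radii
    return StentSpec(branch_id=branch_id, s_proximal=float(s[i_P]),
                     s_distal=float(s[i_D]), diameter=diameter)


# ---------------------------------------------------------------------------
# lesion classification
# ---------------------------------------------------------------------------


def _on_same_path(tree: CoronaryTree, a: str, b: str) -> bool:
    """True when branches a and b lie on a common root-to-outlet lineage."""
    pa, pb = tree.path_to_root(a), tree.path_to_root(b)
    return a in pb or b in pa


def classify_lesions(
    tree: CoronaryTree,
    lesions: Sequence[LesionRecord],
    ostial_margin: float = DEFAULT_OSTIAL_MARGIN_MM,
    tandem_threshold: float = TANDEM_DS_THRESHOLD,
) -> list[LesionRecord]:
    """Type each lesion as ostial, bifurcation, tandem-member, or focal.

    ostial : starts within ``ostial_margin`` of the branch origin (the aortic
        ostium for the root vessel, the take-off for a daughter branch)
    bifurcation : spans a child's attachment point
    tandem-member : at least two lesions with %DS >= ``tandem_threshold``
        share a root-to-outlet path
    Precedence: ostial > bifurcation > tandem-member > focal.
    """
    for les in lesions:
        b = tree.branch(les.branch_id)  # raises BranchNotFoundError off-tree
        lo, hi = les.s_range
        if lo < b.samples[0].s - 1e-9 or hi > b.samples[-1].s + 1e-9:
            raise GeometryError(
                f"lesion range {les.s_range} outside branch {les.branch_id!r}"
            )
    significant = [l for l in lesions if l.percent_ds >= tandem_threshold]
    typed = []
    for les in lesions:
        b = tree.branch(les.branch_id)
        if les.s_range[0] - b.samples[0].s <= ostial_margin:
            kind = "ostial"
        elif any(les.s_range[0] - 1e-9 <= c.attach_s <= les.s_range[1] + 1e-9
                 for c in tree.children_of(les.branch_id)):
            kind = "bifurcation"
        elif (les.percent_ds >= tandem_threshold and any(
                other is not les and _on_same_path(tree, les.branch_id, other.branch_id)
                for other in significant)):
            kind = "tandem-member"
        else:
            kind = "focal"
        typed.append(replace(les, type=kind))
    return typed
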