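"""Centerline + lumen-radius coronary tree model and I/O.

A coronary tree is represented as a rooted collection of branches.  Each
branch is an ordered sequence of centerline samples ``(s, r[, xyz])`` where
``s`` is arc length from the branch's proximal end in mm and ``r`` the local
lumen radius in mm (circular cross-section).  Child branches attach to their
parent at an arc position ``attach_s`` on the parent.  A branch end that has
no child attached at it is an outflow boundary (outlet).

Two bit-compatible on-disk dialects are supported (JSON and flat CSV), plus a
one-way legacy-VTK polyline export for visualisation.
"""

from __future__ import annotations

import copy
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BranchNotFoundError, ParseError, TopologyError

#: Radii below this floor (mm) trigger a warning on read/validation.  Clinical
#: CT segmentation typically stops at 1.5 mm lumen diameter.
DEFAULT_RADIUS_FLOOR_MM = 0.75

#: Tolerance (mm) for deciding whether a child attaches at its parent's tip.
ATTACH_TOL_MM = 1e-6


@dataclass(frozen=True)
class CenterlineSample:
    """One centerline station: arc length ``s`` (mm), lumen radius ``r`` (mm),
    optional 3-D position ``xyz`` (mm)."""

    s: float
    r: float
    xyz: Optional[tuple[float, float, float]] = None


@dataclass
class Branch:
    """An ordered run of centerline samples forming one vessel segment."""

    id: str
    parent_id: Optional[str]
    attach_s: float
    samples: list[CenterlineSample]
    label: Optional[str] = None

    @property
    def s(self) -> np.ndarray:
        return np.array([p.s for p in self.samples], dtype=float)

    @property
    def r(self) -> np.ndarray:
        return np.array([p.r for p in self.samples], dtype=float)

    @property
    def length(self) -> float:
        return self.samples[-1].s - self.samples[0].s

    def radius_at(self, s: float) -> float:
        """Lumen radius at arc position ``s``, linearly interpolated."""
        return float(np.interp(s, self.s, self.r))

    def validate(self) -> None:
        if len(self.samples) < 2:
            raise TopologyError(f"branch {self.id!r}: needs >= 2 samples")
        s = self.s
        if s[0] < 0:
            raise TopologyError(f"branch {self.id!r}: negative arc length")
        if not np.all(np.diff(s) > 0):
            raise TopologyError(
                f"branch {self.id!r}: arc lengths must be strictly increasing"
            )
        if not np.all(self.r > 0):
            raise TopologyError(f"branch {self.id!r}: radii must be positive")


@dataclass(frozen=True)
class MeasurementSite:
    """A location on the tree where pressure/FFR is read off."""

    branch_id: str
    s: float


@dataclass
class CoronaryTree:
    """Rooted tree of :class:`Branch` objects."""

    branches: dict[str, Branch]
    root_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure -------------------------------------------------------

    def branch(self, branch_id: str) -> Branch:
        try:
            return self.branches[branch_id]
        except KeyError:
            raise BranchNotFoundError(branch_id) from None

    def children_of(self, branch_id: str) -> list[Branch]:
        kids = [b for b in self.branches.values() if b.parent_id == branch_id]
        kids.sort(key=lambda b: (b.attach_s, b.id))
        return kids

    def outlet_ids(self) -> list[str]:
        """Branches whose distal tip is an open outflow boundary.

        A branch tip is an outlet unless a child attaches at (within
        tolerance of) its distal end; side branches attached strictly
        mid-branch leave the parent's own tip open.
        """
        out = []
        for b in sorted(self.branches.values(), key=lambda b: b.id):
            tip = b.samples[-1].s
            capped = any(
                abs(c.attach_s - tip) <= ATTACH_TOL_MM for c in self.children_of(b.id)
            )
            if not capped:
                out.append(b.id)
        return out

    def path_to_root(self, branch_id: str) -> list[str]:
        """Branch ids from the root down to (and including) ``branch_id``."""
        path = [branch_id]
        b = self.branch(branch_id)
        while b.parent_id is not None:
            path.append(b.parent_id)
            b = self.branch(b.parent_id)
        return path[::-1]

    def copy(self) -> "CoronaryTree":
        return copy.deepcopy(self)

    # -- validation ------------------------------------------------------

    def validate(self, radius_floor: float = DEFAULT_RADIUS_FLOOR_MM) -> None:
        if not self.branches:
            raise TopologyError("tree has no branches")
        roots = [b.id for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(f"tree must have exactly one root, found {roots}")
        if roots[0] != self.root_id:
            raise TopologyError(
                f"root_id {self.root_id!r} does not match parentless branch {roots[0]!r}"
            )
        for b in self.branches.values():
            if b.id != self.root_id:
                if b.parent_id not in self.branches:
                    raise TopologyError(
                        f"branch {b.id!r} references missing parent {b.parent_id!r}"
                    )
            b.validate()
        # cycle check: walk each branch's ancestry
        for b in self.branches.values():
            seen = {b.id}
            cur = b
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise TopologyError(f"cycle detected through branch {b.id!r}")
                seen.add(cur.parent_id)
                cur = self.branches[cur.parent_id]
        # attachment positions must lie on the parent
        for b in self.branches.values():
            if b.parent_id is not None:
                parent = self.branches[b.parent_id]
                lo, hi = parent.samples[0].s, parent.samples[-1].s
                if not (lo - ATTACH_TOL_MM <= b.attach_s <= hi + ATTACH_TOL_MM):
                    raise TopologyError(
                        f"branch {b.id!r}: attach_s={b.attach_s} outside parent arc "
                        f"range [{lo}, {hi}]"
                    )
        small = [b.id for b in self.branches.values() if float(np.min(b.r)) < radius_floor]
        if small:
            warnings.warn(
                f"branches {small} contain radii below {radius_floor} mm "
                f"({2 * radius_floor} mm diameter), below the usual segmentation floor",
                stacklevel=2,
            )


def lumen_area_curve(tree: CoronaryTree, branch_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Lumen cross-sectional area A(s) = pi r(s)^2 along a branch.

    Returns ``(s, A)`` in mm and mm^2 on the branch's own sample grid.
    """
    b = tree.branch(branch_id)
    s = b.s
    return s, math.pi * b.r**2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["branch_id", "parent_id", "attach_s", "label", "s", "r", "x", "y", "z"]


def _branch_from_record(rec: dict) -> Branch:
    try:
        samples = [
            CenterlineSample(
                s=float(p["s"]),
                r=float(p["r"]),
                xyz=tuple(float(v) for v in p["xyz"]) if p.get("xyz") else None,
            )
            for p in rec["samples"]
        ]
        return Branch(
            id=str(rec["id"]),
            parent_id=None if rec.get("parent_id") is None else str(rec["parent_id"]),
            attach_s=float(rec.get("attach_s", 0.0)),
            samples=samples,
            label=rec.get("label"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed branch record {rec.get('id', '<no id>')!r}: {exc}") from exc


def read_tree(path: str | Path, format: Optional[str] = None) -> CoronaryTree:
    """Read a coronary tree from JSON or CSV.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "branches" not in doc or "root_id" not in doc:
            raise ParseError(f"{path}: expected object with 'root_id' and 'branches'")
        branches = {}
        for rec in doc["branches"]:
            b = _branch_from_record(rec)
            branches[b.id] = b
        return CoronaryTree(branches=branches, root_id=str(doc["root_id"]),
                            metadata=doc.get("metadata", {}))
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"branch_id": str, "parent_id": str, "label": str})
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing CSV columns {sorted(missing)}")
        branches: dict[str, Branch] = {}
        for bid, grp in df.groupby("branch_id", sort=False):
            parent = grp["parent_id"].iloc[0]
            parent = None if pd.isna(parent) else str(parent)
            label = grp["label"].iloc[0]
            label = None if pd.isna(label) else str(label)
            samples = []
            for row in grp.itertuples(index=False):
                xyz = None
                if not (pd.isna(row.x) or pd.isna(row.y) or pd.isna(row.z)):
                    xyz = (float(row.x), float(row.y), float(row.z))
                samples.append(CenterlineSample(s=float(row.s), r=float(row.r), xyz=xyz))
            branches[str(bid)] = Branch(
                id=str(bid), parent_id=parent,
                attach_s=float(grp["attach_s"].iloc[0]),
                samples=samples, label=label,
            )
        roots = [b for b in branches.values() if b.parent_id is None]
        if not roots:
            raise ParseError(f"{path}: no root branch (empty parent_id) found")
        return CoronaryTree(branches=branches, root_id=roots[0].id)
    raise ParseError(f"unsupported tree format {fmt!r}")


def _tree_to_doc(tree: CoronaryTree) -> dict:
    return {
        "root_id": tree.root_id,
        "branches": [
            {
                "id": b.id,
                "parent_id": b.parent_id,
                "attach_s": b.attach_s,
                "label": b.label,
                "samples": [
                    {"s": p.s, "r": p.r, "xyz": list(p.xyz) if p.xyz else None}
                    for p in b.samples
                ],
            }
            for b in sorted(tree.branches.values(), key=lambda b: b.id)
        ],
        "metadata": tree.metadata,
    }


def write_tree(tree: CoronaryTree, path: str | Path, format: Optional[str] = None) -> None:
    """Write a tree as JSON, CSV, or legacy-VTK polylines (export only)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        path.write_text(json.dumps(_tree_to_doc(tree), indent=1))
        return
    if fmt == "csv":
        rows = []
        for b in sorted(tree.branches.values(), key=lambda b: b.id):
            for p in b.samples:
                x, y, z = p.xyz if p.xyz else (np.nan, np.nan, np.nan)
                rows.append(
                    dict(branch_id=b.id, parent_id=b.parent_id, attach_s=b.attach_s,
                         label=b.label, s=p.s, r=p.r, x=x, y=y, z=z)
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        return
    if fmt in ("vtk", "vtk-polyline"):
        _write_vtk_polylines(tree, path)
        return
    raise ParseError(f"unsupported tree format {fmt!r}")


def _write_vtk_polylines(tree: CoronaryTree, path: Path) -> None:
    """Legacy ASCII VTK polydata export: one polyline per branch, radius as a
    point scalar.  Branches without xyz coordinates are laid out along s."""
    points: list[tuple[float, float, float]] = []
    radii: list[float] = []
    lines: list[list[int]] = []
    for b in sorted(tree.branches.values(), key=lambda b: b.id):
        idx = []
        for p in b.samples:
            xyz = p.xyz if p.xyz else (p.s, 0.0, 0.0)
            idx.append(len(points))
            points.append(xyz)
            radii.append(p.r)
        lines.append(idx)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoroflow centerline tree\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for x, y, z in points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        fh.write(f"POINT_DATA {len(points)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6f}\n")


def build_branch(
    branch_id: str,
    length: float,
    radius: float | Sequence[float],
    parent_id: Optional[str] = None,
    attach_s: float = 0.0,
    spacing: float = 0.5,
    label: Optional[str] = None,
    origin: Optional[np.ndarray] = None,
    direction: Optional[np.ndarray] = None,
) -> Branch:
    """Convenience constructor for a straight branch sampled every ``spacing`` mm.

    ``radius`` may be a scalar (uniform) or a per-sample sequence matching the
    generated grid.
    """
    n = max(2, int(round(length / spacing)) + 1)
    s = np.linspace(0.0, length, n)
    r = np.broadcast_to(np.asarray(radius, dtype=float), s.shape)
    xyz = None
    if origin is not None and direction is not None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        xyz = np.asarray(origin, dtype=float)[None, :] + s[:, None] * d[None, :]
    samples = [
        CenterlineSample(
            s=float(si), r=float(ri),
            xyz=tuple(xyz[i]) if xyz is not None else None,
        )
        for i, (si, ri) in enumerate(zip(s, r))
    ]
    return Branch(id=branch_id, parent_id=parent_id, attach_s=attach_s,
                  samples=samples, label=label)
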