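"""Parametric planar model of an aortic conduit with a protruding branch stent.

The model is the symmetry plane of a branched stent-graft: a straight aortic
channel of width ``D1`` with a branch conduit of width ``D2`` leaving through
the near (bottom) wall at tilt angle ``theta``.  ``theta`` is measured from
the upstream (proximal) aortic axis direction to the branch outward axis, so
``theta < 90`` points the stent tip against the aortic flow and
``theta > 90`` with it.  When a stent is present, the branch tube protrudes
into the aortic lumen by ``entry_depth`` (measured along the branch axis from
the near wall to the tip plane), carrying solid walls of finite thickness.
The beveled variant removes the upstream-facing protruding wall down to the
aortic wall plane so the tip lumen opens toward the oncoming flow.

Geometries are rasterized onto a uniform Cartesian grid by cell-center
point-in-region predicates, producing a :class:`DomainMask` consumed by the
flow solver.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import vtkio

__all__ = [
    "FLUID", "SOLID", "WALL", "INLET", "AORTIC_OUTLET", "BRANCH_OUTLET",
    "LABEL_NAMES", "GeometryError", "GridError",
    "StentGeometry", "GridSpec", "DomainMask",
    "make_geometry", "make_channel", "bevel_cut", "rasterize",
    "fluid_predicate", "solid_predicate", "effective_wall_thickness",
    "load_geometry_config", "save_geometry_config",
]

# cell labels
FLUID = 0
SOLID = 1          # stent wall material inside the lumen
WALL = 2           # rigid no-slip boundary / exterior
INLET = 3
AORTIC_OUTLET = 4
BRANCH_OUTLET = 5

LABEL_NAMES = {
    FLUID: "fluid", SOLID: "solid", WALL: "wall",
    INLET: "inlet", AORTIC_OUTLET: "aortic_outlet", BRANCH_OUTLET: "branch_outlet",
}


class GeometryError(ValueError):
    """A geometric parameter violates a model invariant."""


class GridError(ValueError):
    """The grid cannot resolve the geometry."""


@dataclass(frozen=True)
class StentGeometry:
    """Validated parameters of the planar branched-stent scene (mm, degrees).

    ``branch_present=False`` is a degenerate builder flag producing a plain
    straight channel (used for validation against closed-form channel flow);
    all branch parameters are then ignored by :func:`rasterize`.
    """

    D1: float                 # aortic lumen width, mm
    D2: float                 # branch stent lumen width, mm
    L1: float                 # aortic conduit length, mm
    L2: float                 # branch conduit length, mm
    theta: float              # tilt angle, degrees, from upstream aortic axis
    entry_depth: float        # protrusion depth into the aortic lumen, mm
    wall_thickness: float = 0.5
    stent_present: bool = True
    bevel: bool = False
    branch_present: bool = True

    def __post_init__(self):
        if not self.D1 > 0:
            raise GeometryError(f"invariant D1 > 0 violated (D1={self.D1})")
        if not self.branch_present:
            if not self.L1 >= 5 * self.D1:
                raise GeometryError(
                    f"invariant L1 >= 5*D1 violated (L1={self.L1}, D1={self.D1})")
            return
        if not 0 < self.D2 < self.D1:
            raise GeometryError(
                f"invariant 0 < D2 < D1 violated (D2={self.D2}, D1={self.D1})")
        if not 0 < self.theta < 180:
            raise GeometryError(
                f"invariant 0 < theta < 180 violated (theta={self.theta})")
        if not 0 <= self.entry_depth < self.D1:
            raise GeometryError(
                f"invariant 0 <= entry_depth < D1 violated "
                f"(entry_depth={self.entry_depth}, D1={self.D1})")
        if not self.L1 >= 5 * self.D1:
            raise GeometryError(
                f"invariant L1 >= 5*D1 violated (L1={self.L1}, D1={self.D1})")
        if not self.L2 >= 5 * self.D2:
            raise GeometryError(
                f"invariant L2 >= 5*D2 violated (L2={self.L2}, D2={self.D2})")
        if self.stent_present and not self.wall_thickness > 0:
            raise GeometryError(
                "invariant wall_thickness > 0 (with stent_present) violated "
                f"(wall_thickness={self.wall_thickness})")

    # branch axis frame ------------------------------------------------
    @property
    def branch_anchor_x(self) -> float:
        """x where the branch axis crosses the near (bottom) aortic wall, mm."""
        return self.L1 / 2.0

    @property
    def branch_axis(self):
        """Unit vector of the branch outward axis (points out of the aorta)."""
        th = math.radians(self.theta)
        return (-math.cos(th), -math.sin(th))

    @property
    def branch_normal(self):
        """Unit vector across the branch; +normal is the downstream side."""
        th = math.radians(self.theta)
        return (math.sin(th), -math.cos(th))


def make_geometry(D1, D2, L1, L2, theta, entry_depth,
                  stent_present=True, bevel=False,
                  wall_thickness=0.5) -> StentGeometry:
    """Build and validate a branched-stent geometry (mm, degrees)."""
    return StentGeometry(D1=D1, D2=D2, L1=L1, L2=L2, theta=theta,
                         entry_depth=entry_depth, wall_thickness=wall_thickness,
                         stent_present=stent_present, bevel=bevel)


def make_channel(D1, L1) -> StentGeometry:
    """Degenerate straight-channel geometry (no branch at all)."""
    return StentGeometry(D1=D1, D2=D1 / 2, L1=L1, L2=5 * D1 / 2, theta=90.0,
                         entry_depth=0.0, stent_present=False,
                         branch_present=False)


def bevel_cut(geometry: StentGeometry) -> StentGeometry:
    """Cut the protruding tip so its lumen opens toward the oncoming flow.

    The upstream-facing protruding wall is excised down to the aortic wall
    plane (a cut parallel to the aortic axis); the downstream wall keeps its
    full protrusion.  Idempotent.
    """
    if not geometry.stent_present:
        raise GeometryError("bevel_cut requires a protruding stent "
                            "(stent_present is False)")
    if not geometry.entry_depth > 0:
        raise GeometryError("bevel_cut requires entry_depth > 0 "
                            "(nothing protrudes, nothing to cut)")
    return dataclasses.replace(geometry, bevel=True)


@dataclass(frozen=True)
class GridSpec:
    """Uniform rasterization grid.

    ``h`` is the cell size in mm.  ``min_cells_across`` is the minimum number
    of cells across the branch lumen the grid must resolve (8 by default; the
    coarse profile used for quick sweeps relaxes this deliberately).
    """

    h: float
    min_cells_across: int = 8

    def __post_init__(self):
        if not self.h > 0:
            raise GridError(f"cell size must be positive (h={self.h})")


@dataclass
class DomainMask:
    """Rasterized classification of the flow domain on a uniform grid.

    ``labels[j, i]`` is the label of the cell whose center is
    ``(origin + (i + 0.5) h, origin_y + (j + 0.5) h)`` in mm.  ``s`` and ``r``
    hold each cell center's along-axis / across-axis branch coordinates (mm),
    kept for post-processing (wall naming, recirculation windows).
    """

    labels: np.ndarray          # (ny, nx) int8
    h: float                    # mm
    origin: tuple               # (x0, y0) of the grid lower-left corner, mm
    geometry: StentGeometry
    s: np.ndarray | None = None
    r: np.ndarray | None = None

    @property
    def shape(self):
        return self.labels.shape

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {LABEL_NAMES[int(v)]: int(c) for v, c in zip(vals, counts)}

    def cell_centers(self):
        ny, nx = self.labels.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.h
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.h
        return np.meshgrid(x, y)

    def area(self, label: int) -> float:
        """Total area of cells carrying ``label``, mm^2."""
        return float(np.count_nonzero(self.labels == label)) * self.h ** 2

    def to_csv(self, path):
        import pandas as pd
        ny, nx = self.labels.shape
        jj, ii = np.mgrid[0:ny, 0:nx]
        pd.DataFrame({
            "x_index": ii.ravel(), "y_index": jj.ravel(),
            "label": [LABEL_NAMES[int(v)] for v in self.labels.ravel()],
        }).to_csv(path, index=False)
        return path

    def to_vtk(self, path):
        return vtkio.write_structured_points(
            path, {"label": self.labels.astype(np.int32)}, self.h, self.origin)


def _branch_frame(geom: StentGeometry, X, Y):
    """Along-axis (s) and across-axis (r) coordinates of cell centers."""
    bx, by = geom.branch_axis
    nx_, ny_ = geom.branch_normal
    dx = X - geom.branch_anchor_x
    s = dx * bx + Y * by
    r = dx * nx_ + Y * ny_
    return s, r


def effective_wall_thickness(geom: StentGeometry, h: float) -> float:
    """Rendered stent wall thickness: at least one grid cell."""
    return max(geom.wall_thickness, h * 1.0001)


def solid_predicate(geom: StentGeometry, X, Y, tw_eff: float):
    """True where a point sits inside stent wall material."""
    if not (geom.branch_present and geom.stent_present
            and geom.entry_depth > 0):
        return np.zeros(np.shape(X), dtype=bool)
    s, r = _branch_frame(geom, X, Y)
    band = (np.abs(r) >= geom.D2 / 2) & (np.abs(r) <= geom.D2 / 2 + tw_eff)
    solid = band & (s >= -geom.entry_depth) & (Y > 0) & (Y < geom.D1) \
        & (X > 0) & (X < geom.L1)
    if geom.bevel:
        solid &= r >= 0
    return solid


def fluid_predicate(geom: StentGeometry, X, Y, tw_eff: float):
    """True where a point sits in flowing lumen (aorta or branch, not in
    stent wall material).  The same predicate rasterization samples at cell
    centers; the solver samples it at sub-cell points to place no-slip
    surfaces at their true positions."""
    fluid = (X > 0) & (X < geom.L1) & (Y > 0) & (Y < geom.D1)
    if geom.branch_present:
        s, r = _branch_frame(geom, X, Y)
        s_min = -geom.entry_depth if geom.stent_present else 0.0
        fluid |= (np.abs(r) < geom.D2 / 2) & (s > s_min) & (s <= geom.L2)
        fluid &= ~solid_predicate(geom, X, Y, tw_eff)
    return fluid


def rasterize(geometry: StentGeometry, grid: GridSpec) -> DomainMask:
    """Rasterize the geometry by cell-center point-in-region predicates.

    Stent walls are rendered at least one cell thick.  Fluid pockets that are
    not face-connected to the inlet are pruned to wall cells, so every fluid
    cell is reachable from the inlet.
    """
    g, h = geometry, grid.h
    if g.branch_present and h > g.D2 / grid.min_cells_across + 1e-12:
        raise GridError(
            f"grid too coarse to resolve the branch lumen: h={h} mm but "
            f"D2/{grid.min_cells_across} = {g.D2 / grid.min_cells_across:.4g} mm")

    tw_eff = effective_wall_thickness(g, h)  # walls at least one cell thick
    outlet_margin = 2 * h

    # vertical extent below the aortic wall occupied by branch + outlet band
    if g.branch_present:
        bx, by = g.branch_axis
        nx_, ny_ = g.branch_normal
        s_end = g.L2 + outlet_margin
        half = g.D2 / 2 + tw_eff
        corner_y = [s_end * by + sgn * half * ny_ for sgn in (-1.0, 1.0)]
        y_min_geom = min(corner_y + [0.0])
    else:
        y_min_geom = 0.0

    n_below = int(math.ceil(-y_min_geom / h)) + 1 if y_min_geom < 0 else 0
    # one rim row/column beyond every boundary
    x0 = -h
    y0 = -(n_below + 1) * h
    nx = int(round(g.L1 / h)) + 2
    ny = int(round(g.D1 / h)) + n_below + 2

    X, Y = np.meshgrid(x0 + (np.arange(nx) + 0.5) * h,
                       y0 + (np.arange(ny) + 0.5) * h)

    labels = np.full((ny, nx), WALL, dtype=np.int8)
    in_aorta_y = (Y > 0) & (Y < g.D1)
    labels[fluid_predicate(g, X, Y, tw_eff)] = FLUID

    s = r = None
    if g.branch_present:
        s, r = _branch_frame(g, X, Y)
        labels[solid_predicate(g, X, Y, tw_eff)] = SOLID
        lumen = np.abs(r) < g.D2 / 2
        labels[lumen & (s > g.L2) & (s <= g.L2 + outlet_margin)] = BRANCH_OUTLET

    labels[(X < 0) & in_aorta_y] = INLET
    labels[(X > g.L1) & in_aorta_y] = AORTIC_OUTLET

    # prune fluid not face-connected to the inlet
    fluid = labels == FLUID
    comp, ncomp = ndimage.label(fluid, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if ncomp:
        inlet_adjacent = np.zeros_like(fluid)
        inlet_adjacent[:, 1:] = labels[:, :-1] == INLET
        keep = np.unique(comp[inlet_adjacent & fluid])
        keep = keep[keep > 0]
        labels[fluid & ~np.isin(comp, keep)] = WALL

    # drop boundary cells that lost their fluid neighbor to pruning
    fluid = labels == FLUID
    adj = np.zeros_like(fluid)
    adj[:, :-1] |= fluid[:, 1:]
    adj[:, 1:] |= fluid[:, :-1]
    adj[:-1, :] |= fluid[1:, :]
    adj[1:, :] |= fluid[:-1, :]
    for lab in (INLET, AORTIC_OUTLET, BRANCH_OUTLET):
        labels[(labels == lab) & ~adj] = WALL

    mask = DomainMask(labels=labels, h=h, origin=(x0, y0), geometry=g, s=s, r=r)
    counts = mask.label_counts()
    if counts.get("inlet", 0) == 0 or counts.get("aortic_outlet", 0) == 0:
        raise GridError("rasterization produced no inlet/aortic outlet cells")
    if g.branch_present and counts.get("branch_outlet", 0) == 0:
        raise GridError("rasterization produced no branch outlet cells")
    return mask


# ---------------------------------------------------------------------------
# flat key-value geometry config files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = ("D1_mm", "D2_mm", "L1_mm", "L2_mm", "theta_deg",
                "entry_depth_mm", "wall_thickness_mm", "stent_present", "bevel")


def save_geometry_config(geometry: StentGeometry, path):
    vals = {
        "D1_mm": geometry.D1, "D2_mm": geometry.D2,
        "L1_mm": geometry.L1, "L2_mm": geometry.L2,
        "theta_deg": geometry.theta, "entry_depth_mm": geometry.entry_depth,
        "wall_thickness_mm": geometry.wall_thickness,
        "stent_present": geometry.stent_present, "bevel": geometry.bevel,
    }
    Path(path).write_text(
        "".join(f"{k} = {vals[k]}\n" for k in _CONFIG_KEYS))
    return path


def load_geometry_config(path) -> StentGeometry:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    missing = set(_CONFIG_KEYS) - set(kv)
    if missing:
        raise GeometryError(f"geometry config missing keys: {sorted(missing)}")

    def as_bool(v):
        return v.lower() in ("1", "true", "yes")

    return make_geometry(
        D1=float(kv["D1_mm"]), D2=float(kv["D2_mm"]),
        L1=float(kv["L1_mm"]), L2=float(kv["L2_mm"]),
        theta=float(kv["theta_deg"]), entry_depth=float(kv["entry_depth_mm"]),
        wall_thickness=float(kv["wall_thickness_mm"]),
        stent_present=as_bool(kv["stent_present"]), bevel=as_bool(kv["bevel"]))
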