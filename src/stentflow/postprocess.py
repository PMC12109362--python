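"""Flow-field observables: branch mass flow, reflux classification, wall
shear stress profiles and recirculation-region size.

Sign convention for the branch: positive mass flux means blood leaving the
domain through the branch outlet (outflow toward the renal artery); negative
means reflux, i.e. flow drawn back from the branch into the aorta.  Fluxes
are per unit depth of the planar model, kg/(m s); an optional pseudo-3D
conversion (multiply by pi*D2/4) is provided for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (AORTIC_OUTLET, BRANCH_OUTLET, FLUID, INLET, SOLID,
                       WALL, DomainMask)
from .solver import FlowField

__all__ = [
    "BranchFlowResult", "WSSProfile", "RecirculationMetrics",
    "boundary_flux", "classify_branch_flow", "branch_flow_result",
    "wall_shear_stress", "recirculation_metrics", "pseudo3d_flux",
    "run_record",
]

_BOUNDARY_LABELS = {"inlet": INLET, "aortic_outlet": AORTIC_OUTLET,
                    "branch_outlet": BRANCH_OUTLET}


@dataclass(frozen=True)
class BranchFlowResult:
    mass_flux: float          # signed, kg/(m s), positive = out of the branch
    classification: str       # outflow | reflux | stagnant
    normalized_flux: float    # mass_flux / inlet mass flux


@dataclass
class WSSProfile:
    wall_id: str
    positions: np.ndarray     # arc-length coordinate along the wall, mm
    tau_w: np.ndarray         # Pa, non-negative
    summary: dict = field(default_factory=dict)

    def to_csv(self, path):
        import pandas as pd
        pd.DataFrame({"position_mm": self.positions,
                      "tau_w_pa": self.tau_w}).to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class RecirculationMetrics:
    vortex_area: float        # mm^2 of counter-flowing fluid in the window
    area_fraction: float      # vortex_area / fluid area of the window


def boundary_flux(field: FlowField, mask: DomainMask, boundary_id: str) -> float:
    """Signed mass flux through a named boundary, kg/(m s).

    Outlets are signed positive for flow leaving the domain; the inlet is
    signed positive for flow entering it (so a plug inlet of speed U over a
    width D1 gives +rho U D1/1000 per unit depth).
    """
    if boundary_id not in _BOUNDARY_LABELS:
        raise KeyError(f"unknown boundary_id {boundary_id!r}; expected one of "
                       f"{sorted(_BOUNDARY_LABELS)}")
    lab = _BOUNDARY_LABELS[boundary_id]
    labels = mask.labels
    h = mask.h / 1000.0
    rho = field.fluid.rho
    bd = labels == lab
    fl = labels == FLUID
    total = 0.0
    # u faces: boundary cell left of fluid -> outward normal -x, etc.
    left = bd[:, :-1] & fl[:, 1:]     # face between (j,i) boundary, (j,i+1) fluid
    jj, ii = np.nonzero(left)
    total += np.sum(-field.u[jj, ii + 1])
    right = fl[:, :-1] & bd[:, 1:]
    jj, ii = np.nonzero(right)
    total += np.sum(field.u[jj, ii + 1])
    below = bd[:-1, :] & fl[1:, :]
    jj, ii = np.nonzero(below)
    total += np.sum(-field.v[jj + 1, ii])
    above = fl[:-1, :] & bd[1:, :]
    jj, ii = np.nonzero(above)
    total += np.sum(field.v[jj + 1, ii])
    flux = rho * h * total
    return float(-flux) if boundary_id == "inlet" else float(flux)


def classify_branch_flow(mass_flux: float, inlet_flux: float,
                         stagnation_frac: float = 1e-3) -> str:
    """Classify branch flow against a dead band around zero.

    Discrete solutions never produce an exact zero, so flows within
    ``stagnation_frac`` of the inlet flux are called stagnant.
    """
    if not inlet_flux > 0:
        raise ValueError("inlet_flux must be positive")
    band = stagnation_frac * inlet_flux
    if mass_flux > band:
        return "outflow"
    if mass_flux < -band:
        return "reflux"
    return "stagnant"


def branch_flow_result(field: FlowField, mask: DomainMask,
                       stagnation_frac: float = 1e-3) -> BranchFlowResult:
    q_b = boundary_flux(field, mask, "branch_outlet")
    q_in = boundary_flux(field, mask, "inlet")
    return BranchFlowResult(mass_flux=q_b,
                            classification=classify_branch_flow(
                                q_b, q_in, stagnation_frac),
                            normalized_flux=q_b / q_in)


def _wall_faces(mask: DomainMask, wall_id: str):
    """(fluid_j, fluid_i, orientation) for faces of the named wall segment.

    orientation: 'x' if the wall normal is horizontal (tangential velocity v),
    'y' if vertical (tangential velocity u).
    """
    labels = mask.labels
    g = mask.geometry
    blocked = (labels == WALL) | (labels == SOLID)
    fl = labels == FLUID
    X, Y = mask.cell_centers()

    if wall_id == "branch_wall":
        if not g.branch_present:
            raise ValueError("geometry has no branch; no branch wall exists")
        # fluid cells of the branch lumen: the conduit below the aortic wall
        # plus, when a stent protrudes, the in-lumen stented segment
        s_min = -g.entry_depth if g.stent_present else 0.0
        region = fl & (np.abs(mask.r) < g.D2 / 2) & (mask.s > s_min) \
            & (mask.s <= g.L2)
        if not g.stent_present:
            region &= Y <= 0
    elif wall_id == "aortic_top":
        region = fl & (Y > 0) & (Y < g.D1) & \
            (Y > g.D1 - 1.5 * mask.h)
    elif wall_id == "aortic_bottom":
        region = fl & (Y > 0) & (Y < 1.5 * mask.h)
    else:
        raise ValueError(f"unknown wall_id {wall_id!r}")

    faces = []
    jj, ii = np.nonzero(region)
    for dj, di, orient in ((0, 1, "x"), (0, -1, "x"), (1, 0, "y"), (-1, 0, "y")):
        nb_j, nb_i = jj + dj, ii + di
        ok = blocked[nb_j, nb_i]
        faces.append((jj[ok], ii[ok], orient))
    if sum(len(f[0]) for f in faces) == 0:
        raise ValueError(f"wall {wall_id!r} has no adjacent fluid cells")
    return faces


def wall_shear_stress(field: FlowField, mask: DomainMask,
                      wall_id: str) -> WSSProfile:
    """WSS magnitude tau_w = mu |du_t/dn| along a named wall.

    One-sided first-order difference: the tangential cell-center velocity of
    the wall-adjacent fluid cell over the half-cell distance to the
    interface.  Profile positions are the along-wall coordinate in mm
    (branch-axis coordinate ``s`` for the branch wall, ``x`` for the aortic
    walls), sorted ascending.
    """
    mu = field.fluid.mu
    h_m = mask.h / 1000.0
    uc, vc = field.cell_velocity()
    X, Y = mask.cell_centers()
    pos_arr = mask.s if wall_id == "branch_wall" else X

    positions, taus = [], []
    for jj, ii, orient in _wall_faces(mask, wall_id):
        if len(jj) == 0:
            continue
        ut = vc[jj, ii] if orient == "x" else uc[jj, ii]
        taus.append(mu * np.abs(ut) / (h_m / 2.0))
        positions.append(pos_arr[jj, ii])
    positions = np.concatenate(positions)
    taus = np.concatenate(taus)
    order = np.argsort(positions, kind="stable")
    positions, taus = positions[order], taus[order]
    return WSSProfile(wall_id=wall_id, positions=positions, tau_w=taus,
                      summary={"mean": float(taus.mean()),
                               "max": float(taus.max())})


def recirculation_metrics(field: FlowField, mask: DomainMask,
                          window=None) -> RecirculationMetrics:
    """Counter-flow area near the branch ostium.

    Counts fluid cells inside the window whose axial (x) velocity opposes
    the inlet direction.  Default window: axial extent +/- 2 D2 around the
    branch-axis/wall intersection, full aortic width.
    """
    g = mask.geometry
    X, Y = mask.cell_centers()
    if window is None:
        if not g.branch_present:
            raise ValueError("default window needs a branch; pass one explicitly")
        x0 = g.branch_anchor_x - 2 * g.D2
        x1 = g.branch_anchor_x + 2 * g.D2
        y0, y1 = 0.0, g.D1
    else:
        x0, x1, y0, y1 = window
    sel = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
    if not sel.any():
        raise ValueError("window does not intersect the grid")
    influid = sel & (mask.labels == FLUID)
    n_fluid = int(np.count_nonzero(influid))
    if n_fluid == 0:
        raise ValueError("window contains no fluid cells")
    uc, _ = field.cell_velocity()
    n_rev = int(np.count_nonzero(influid & (uc < 0.0)))
    return RecirculationMetrics(vortex_area=n_rev * mask.h ** 2,
                                area_fraction=n_rev / n_fluid)


def pseudo3d_flux(flux_per_depth: float, D2_mm: float) -> float:
    """Convert a per-unit-depth 2D flux to a nominal tube flux, kg/s.

    Multiplies by pi D2/4 (the mean-chord depth of a circular lumen of
    diameter D2).  Reporting convenience only; all classification and
    acceptance logic stays on the 2D flux.
    """
    return flux_per_depth * np.pi * (D2_mm / 1000.0) / 4.0


def run_record(field: FlowField, mask: DomainMask,
               stagnation_frac: float = 1e-3) -> dict:
    """One tidy results row for a solved configuration."""
    g = mask.geometry
    res = branch_flow_result(field, mask, stagnation_frac) \
        if g.branch_present else None
    rec = {
        "theta": g.theta, "entry_depth": g.entry_depth, "D2": g.D2,
        "bevel": g.bevel, "stent_present": g.stent_present,
        "v_inlet": field.bcs.v_inlet, "h_mm": mask.h,
        "Re": field.fluid.rho * field.bcs.v_inlet * (g.D1 / 1000.0)
              / field.fluid.mu,
        "converged": field.converged, "iterations": field.iterations,
        "cycle_averaged": field.cycle_averaged,
    }
    if res is not None:
        rec.update({"mass_flux": res.mass_flux,
                    "normalized_flux": res.normalized_flux,
                    "classification": res.classification})
        wss = wall_shear_stress(field, mask, "branch_wall")
        rec.update({"wss_mean": wss.summary["mean"],
                    "wss_max": wss.summary["max"]})
        rm = recirculation_metrics(field, mask)
        rec.update({"vortex_area": rm.vortex_area,
                    "vortex_fraction": rm.area_fraction})
    return rec
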