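"""Reproducible parameter sweeps over the branched-stent scene.

Four experiments drive the solver over the clinically relevant geometry
ranges: tilt-angle response without a protruding stent, the joint
angle x entry-depth map with a stent, branch-diameter response at a fixed
right-angle deep-entry configuration, and the paired comparison of a
reflux configuration against its beveled-tip modification.  A bisection
driver locates the reflux-to-outflow transition angle.

All runs are laminar at a reduced channel Reynolds number (default 200;
the physiological value near 7.2e3 is transitional and magnitudes at that
Re are not the target — flow direction and monotone trends are).  Sweep
tables are deterministic, cached per configuration within a session, and
carry a provenance hash of every effective parameter.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import postprocess
from .geometry import GridSpec, make_geometry, rasterize, bevel_cut
from .solver import (BoundaryConditions, FluidProperties,
                     SolverDivergenceError, SolverSettings, scale_reynolds,
                     solve_steady)

__all__ = [
    "RunProfile", "SweepResult", "TransitionReport", "fast_profile",
    "run_single", "run_no_stent_angle_sweep", "run_angle_depth_sweep",
    "run_diameter_sweep", "compare_bevel", "find_transition_angle",
    "clear_cache",
]

DEFAULT_THETAS = (45.0, 60.0, 75.0, 90.0, 105.0, 120.0, 135.0)
DEFAULT_DEPTHS = (5.0, 10.0, 15.0)
DEFAULT_DIAMETERS = (6.0, 8.0, 10.0, 12.0)


@dataclass(frozen=True)
class RunProfile:
    """Everything that fixes one solver run besides the swept parameters.

    ``h=None`` resolves to D2/8 (eight cells across the branch lumen).
    ``L2=None`` resolves to the profile's conduit length or, if that is
    shorter than five branch widths, to 5 D2.
    """

    D1: float = 30.0
    L1: float = 200.0
    L2: float | None = 100.0
    h: float | None = None
    min_cells_across: int = 8
    target_Re: float = 200.0
    settings: SolverSettings = field(default_factory=lambda: SolverSettings(
        tol=1e-5, max_iter=8000))
    rho: float = 1055.0
    mu: float = 0.0035

    def grid_h(self, D2: float) -> float:
        return self.h if self.h is not None else D2 / self.min_cells_across

    def conduit_L2(self, D2: float) -> float:
        base = self.L2 if self.L2 is not None else 5 * D2
        return max(base, 5 * D2)


def fast_profile() -> RunProfile:
    """Coarse quick-turnaround profile: conduits shortened to the minimum
    developed-flow lengths (5 diameters), same cross-branch resolution."""
    return RunProfile(L1=150.0, L2=None)


@dataclass
class SweepResult:
    table: pd.DataFrame
    provenance: str

    def to_csv(self, path):
        self.table.to_csv(path, index=False)
        return path


@dataclass
class TransitionReport:
    """Smallest angle (to the requested resolution) with branch outflow."""

    depth: float
    theta_star: float | None     # None when no transition in the bracket
    bracket: tuple               # (largest reflux angle, smallest outflow angle)
    resolution: float
    lo_classification: str
    hi_classification: str

    @property
    def present(self) -> bool:
        return self.theta_star is not None


_CACHE: dict = {}


def clear_cache():
    _CACHE.clear()


def _provenance(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_single(theta, entry_depth, D2=8.0, stent_present=True, bevel=False,
               v_inlet=0.8, profile: RunProfile | None = None,
               return_field: bool = False):
    """Solve one configuration and return its tidy results row."""
    profile = profile or RunProfile()
    L2 = profile.conduit_L2(D2)
    h = profile.grid_h(D2)
    key = (profile, theta, entry_depth, D2, stent_present, bevel, v_inlet)
    if key in _CACHE:
        row, field_, mask = _CACHE[key]
        return (row, field_, mask) if return_field else row
    geom = make_geometry(profile.D1, D2, profile.L1, L2, theta, entry_depth,
                         stent_present=stent_present, bevel=bevel)
    mask = rasterize(geom, GridSpec(h=h,
                                    min_cells_across=profile.min_cells_across))
    bcs = BoundaryConditions(v_inlet=v_inlet)
    fluid = scale_reynolds(FluidProperties(rho=profile.rho, mu=profile.mu),
                           bcs, geom, profile.target_Re)
    settings = profile.settings
    field_ = None
    for attempt in range(3):
        try:
            field_ = solve_steady(mask, fluid, bcs, settings)
            break
        except SolverDivergenceError:
            if attempt == 2:
                raise
            # deterministic fallback: stronger under-relaxation
            settings = replace(settings,
                               relax_momentum=settings.relax_momentum * 0.6,
                               relax_pressure=settings.relax_pressure * 0.6,
                               max_iter=settings.max_iter * 2)
    row = postprocess.run_record(field_, mask)
    row["L1"], row["L2"] = profile.L1, L2
    _CACHE[key] = (row, field_, mask)
    if return_field:
        return row, field_, mask
    return row


def _sweep(rows_cfg, profile, label) -> SweepResult:
    seen = set()
    rows = []
    for cfg in rows_cfg:
        key = tuple(sorted(cfg.items()))
        if key in seen:
            continue  # one row per requested configuration
        seen.add(key)
        rows.append(run_single(profile=profile, **cfg))
    table = pd.DataFrame(rows)
    prov = _provenance({"experiment": label, "profile": repr(profile),
                        "configs": sorted(map(str, seen))})
    return SweepResult(table=table, provenance=prov)


def run_no_stent_angle_sweep(theta_list=None,
                             profile: RunProfile | None = None) -> SweepResult:
    """Branch flow vs tilt angle with a flush ostium (no protruding stent)."""
    thetas = tuple(theta_list) if theta_list is not None else DEFAULT_THETAS
    if any(not 0 < t < 180 for t in thetas):
        raise ValueError("theta values must lie in (0, 180)")
    cfgs = [dict(theta=t, entry_depth=0.0, stent_present=False) for t in thetas]
    return _sweep(cfgs, profile or RunProfile(), "no_stent_angle")


def run_angle_depth_sweep(theta_list=None, depth_list=None,
                          profile: RunProfile | None = None) -> SweepResult:
    """Joint tilt-angle x entry-depth map with a protruding stent."""
    thetas = tuple(theta_list) if theta_list is not None else DEFAULT_THETAS
    depths = tuple(depth_list) if depth_list is not None else DEFAULT_DEPTHS
    cfgs = [dict(theta=t, entry_depth=d) for t in thetas for d in depths]
    return _sweep(cfgs, profile or RunProfile(), "angle_depth")


def run_diameter_sweep(D2_list=None,
                       profile: RunProfile | None = None) -> SweepResult:
    """Branch-diameter response at theta=90, entry depth 15 mm, 0.4 m/s.

    Recirculation areas are additionally evaluated in one window common to
    the whole sweep (axial extent +/- 2 max(D2) around the ostium), so the
    vortex sizes of different diameters are compared on equal footing; the
    default per-run window scales with D2 and would conflate window growth
    with vortex growth.
    """
    D2s = tuple(D2_list) if D2_list is not None else DEFAULT_DIAMETERS
    profile = profile or RunProfile()
    cfgs = [dict(theta=90.0, entry_depth=15.0, D2=d, v_inlet=0.4) for d in D2s]
    result = _sweep(cfgs, profile, "diameter")
    span = 2 * max(D2s)
    common = []
    for cfg in cfgs:
        _, field_, mask = run_single(profile=profile, return_field=True, **cfg)
        g = mask.geometry
        m = postprocess.recirculation_metrics(
            field_, mask, window=(g.branch_anchor_x - span,
                                  g.branch_anchor_x + span, 0.0, g.D1))
        common.append(m.vortex_area)
    table = result.table.set_index("D2")
    table.loc[list(D2s), "vortex_area_common_window"] = common
    result.table = table.reset_index()
    return result


def compare_bevel(theta=90.0, depth=15.0, D2=8.0,
                  profile: RunProfile | None = None) -> SweepResult:
    """Paired original-vs-beveled runs of one configuration.

    The default is the canonical reflux case (right-angle, deep entry).
    If the original configuration is not actually in reflux a warning is
    issued and the comparison is still returned.
    """
    profile = profile or RunProfile()
    orig = run_single(theta, depth, D2=D2, profile=profile)
    if orig["classification"] != "reflux":
        warnings.warn(f"original configuration is {orig['classification']}, "
                      "not reflux; bevel comparison may not be informative",
                      RuntimeWarning)
    bev = run_single(theta, depth, D2=D2, bevel=True, profile=profile)
    table = pd.DataFrame([dict(orig, variant="original"),
                          dict(bev, variant="beveled")])
    prov = _provenance({"experiment": "bevel", "profile": repr(profile),
                        "theta": theta, "depth": depth, "D2": D2})
    return SweepResult(table=table, provenance=prov)


def find_transition_angle(depth, theta_lo=45.0, theta_hi=135.0,
                          resolution=2.5,
                          profile: RunProfile | None = None,
                          ) -> TransitionReport:
    """Bisect the reflux-to-outflow transition angle at a fixed entry depth.

    Uses the branch-flow classification as the predicate.  Both bracket
    ends must classify differently (reflux below, outflow above); otherwise
    a no-transition report is returned.
    """
    profile = profile or RunProfile()
    lo_row = run_single(theta_lo, depth, profile=profile)
    hi_row = run_single(theta_hi, depth, profile=profile)
    lo_cls, hi_cls = lo_row["classification"], hi_row["classification"]
    if not (lo_cls == "reflux" and hi_cls == "outflow"):
        return TransitionReport(depth=depth, theta_star=None,
                                bracket=(theta_lo, theta_hi),
                                resolution=resolution,
                                lo_classification=lo_cls,
                                hi_classification=hi_cls)
    lo, hi = theta_lo, theta_hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        cls = run_single(mid, depth, profile=profile)["classification"]
        if cls == "outflow":
            hi = mid
        else:  # reflux or stagnant: not yet flowing out
            lo = mid
    return TransitionReport(depth=depth, theta_star=hi, bracket=(lo, hi),
                            resolution=resolution,
                            lo_classification=lo_cls,
                            hi_classification=hi_cls)
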