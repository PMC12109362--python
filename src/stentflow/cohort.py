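"""Case fixtures and synthetic cohorts for the statistics stage.

Two sources of :class:`~stentflow.casestats.ArteryRecord` lists:

* :func:`load_clinical_cases` — the twelve renal arteries of the six-patient
  clinical cohort (stent tilt angle, entry depth, branch and aortic
  diameter, follow-up patency), packaged as a CSV fixture.  Per-artery flow
  is not part of the cohort record; :func:`assign_reconstructed_flows`
  fills in synthetic placeholder flows that realize the reported low/high
  flow-group membership (the four occluded arteries plus the two
  smallest-angle patent arteries fall below the median).

* :func:`generate_cohort` — fully synthetic cohorts with a controllable
  tilt-angle effect, used to calibrate and power-check the analysis
  pipeline.  Flow follows a monotone response in angle (with weaker depth
  and diameter modifiers) plus Gaussian noise; arteries with negative flow
  are marked occluded.

:func:`surrogate_flow` is a reduced-order stand-in for the flow solver,
calibrated on a sweep table so its sign structure (reflux below the
transition angle, outflow above) matches the solver on every calibration
configuration.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .casestats import ArteryRecord

__all__ = [
    "CohortSpec", "SurrogateCoeffs", "FixtureError",
    "load_clinical_cases", "assign_reconstructed_flows", "generate_cohort",
    "fit_surrogate", "surrogate_flow", "cases_to_csv", "cases_from_csv",
]

_FIXTURE = "renal_artery_cases.csv"
_FIXTURE_SHA256 = "fb0b9e10093dbd35283eb7218d2f9a8ca94610d7ebab7b5104238ad8a4e570a3"

# arteries below the median flow in the reported grouping: the four
# occluded arteries plus the two patent arteries with the smallest angles
_LOW_GROUP = {("D", "left"), ("D", "right"), ("E", "left"), ("F", "left"),
              ("A", "left"), ("C", "right")}


class FixtureError(RuntimeError):
    """Packaged case table failed its integrity check."""


def load_clinical_cases():
    """The twelve-artery clinical case table; flow left unset.

    Raises :class:`FixtureError` on a checksum mismatch of the packaged CSV.
    """
    ref = resources.files("stentflow").joinpath("data", _FIXTURE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(f"case fixture checksum mismatch: {digest}")
    records = []
    lines = raw.decode().strip().splitlines()
    header = lines[0].split(",")
    for line in lines[1:]:
        row = dict(zip(header, line.split(",")))
        records.append(ArteryRecord(
            patient_id=row["patient_id"], side=row["side"],
            tilt_angle=float(row["tilt_angle"]),
            entry_depth=float(row["entry_depth"]),
            branch_diameter=float(row["branch_diameter"]),
            aortic_diameter=float(row["aortic_diameter"]),
            flow=None, patency=row["patency"]))
    return records


def assign_reconstructed_flows(records):
    """Fill synthetic placeholder flows realizing the reported grouping.

    The reference analysis splits the twelve arteries at the median flow
    (0.005 kg/s); per-artery flows themselves are not printed.  These
    synthetic values put occluded arteries in a reflux state (negative
    flow) and order the rest so the low/high membership matches the
    reported group medians.  Only the induced ordering carries meaning;
    the magnitudes are cosmetic, on the printed kg/s scale.
    """
    recs = [ArteryRecord(**r.__dict__) for r in records]
    low = sorted((r for r in recs if (r.patient_id, r.side) in _LOW_GROUP),
                 key=lambda r: (r.patency == "patent", r.tilt_angle))
    high = sorted((r for r in recs if (r.patient_id, r.side) not in _LOW_GROUP),
                  key=lambda r: r.tilt_angle)
    for k, r in enumerate(low):
        r.flow = (-0.004 + 0.001 * k) if r.patency == "occluded" \
            else 0.002 + 0.001 * (k - 4)
    for k, r in enumerate(high):
        r.flow = 0.006 + 0.001 * k
    return recs


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a synthetic case cohort.

    Angles are drawn half-and-half from two normal groups (centers near the
    clinical low/high angle medians of about 90 and 125 degrees, common SD);
    entry depth and branch diameter are drawn from common distributions in
    both groups.  Flow is a strictly increasing saturating response in the
    tilt angle, weakly modulated by depth and diameter, plus Gaussian
    noise on the kg/s scale of the clinical medians; negative flow marks an
    artery as occluded.
    """

    n_arteries: int = 12
    angle_low_mean: float = 90.0
    angle_high_mean: float = 125.0
    angle_sd: float = 12.0
    depth_mean: float = 7.0         # mm
    depth_sd: float = 2.0
    diameter_mean: float = 5.0      # mm
    diameter_sd: float = 0.7
    flow_gain: float = 0.006        # kg/s scale of the response
    angle_center: float = 97.5      # response zero crossing, degrees
    angle_width: float = 12.0       # response saturation width, degrees
    depth_coeff: float = -0.02      # per mm, relative
    diameter_coeff: float = 0.08    # per mm, relative
    noise_sd: float = 0.001         # kg/s
    seed: int = 0

    def __post_init__(self):
        if self.n_arteries % 2:
            raise ValueError("n_arteries must be even")
        for name in ("angle_sd", "depth_sd", "diameter_sd", "noise_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.flow_gain < 0 or self.angle_width <= 0:
            raise ValueError("flow_gain must be >= 0 and angle_width > 0")

    @classmethod
    def null(cls, seed: int = 0) -> "CohortSpec":
        """No structure: one angle population and flow that is pure noise."""
        return cls(angle_low_mean=105.0, angle_high_mean=105.0,
                   flow_gain=0.0, seed=seed)

    def response(self, angle, depth, diameter):
        """Noise-free flow response, strictly increasing in angle."""
        mod = (1 + self.depth_coeff * (np.asarray(depth) - self.depth_mean)) \
            * (1 + self.diameter_coeff * (np.asarray(diameter)
                                          - self.diameter_mean))
        mod = np.clip(mod, 0.05, None)  # keep the angle monotonicity intact
        return self.flow_gain * np.tanh(
            (np.asarray(angle) - self.angle_center) / self.angle_width) * mod


def generate_cohort(spec: CohortSpec):
    """Draw one synthetic cohort; reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_arteries
    nlow = n // 2
    angles = np.concatenate([
        rng.normal(spec.angle_low_mean, spec.angle_sd, nlow),
        rng.normal(spec.angle_high_mean, spec.angle_sd, n - nlow)])
    angles = np.clip(angles, 1.0, 179.0)
    depths = np.clip(rng.normal(spec.depth_mean, spec.depth_sd, n), 0.5, None)
    diams = np.clip(rng.normal(spec.diameter_mean, spec.diameter_sd, n),
                    1.0, None)
    flow = spec.response(angles, depths, diams) \
        + rng.normal(0.0, spec.noise_sd, n)
    records = []
    for k in range(n):
        records.append(ArteryRecord(
            patient_id=f"S{k // 2 + 1:02d}",
            side="left" if k % 2 == 0 else "right",
            tilt_angle=float(angles[k]), entry_depth=float(depths[k]),
            branch_diameter=float(diams[k]),
            aortic_diameter=float(np.clip(rng.normal(24.0, 4.0), 12.0, None)),
            flow=float(flow[k]),
            patency="occluded" if flow[k] < 0 else "patent"))
    return records


# ---------------------------------------------------------------------------
# reduced-order surrogate calibrated on solver sweep tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateCoeffs:
    """flow = exp(c0 + c1 depth + c2 diameter)
              * tanh((theta - (theta_star + depth_slope * depth)) / width).

    The reflux-to-outflow transition angle grows with entry depth (deeper
    tips need a larger conforming tilt before the branch flows out), so the
    zero crossing is affine in depth.
    """

    theta_star: float            # transition angle at zero depth, degrees
    depth_slope: float           # degrees per mm of entry depth
    width: float
    c0: float
    c1: float
    c2: float
    theta_range: tuple
    depth_range: tuple
    diameter_range: tuple

    def transition_angle(self, depth) -> float:
        return self.theta_star + self.depth_slope * np.asarray(depth)


def fit_surrogate(sweep_table) -> SurrogateCoeffs:
    """Calibrate the surrogate on a stented sweep table.

    ``sweep_table`` needs columns theta, entry_depth, D2, mass_flux (rows
    with a stent present).  After fitting, the surrogate's sign is checked
    against the solver classification on every calibration row; a mismatch
    raises, since sign structure is the whole point of the surrogate.
    """
    from scipy.optimize import least_squares

    df = sweep_table[sweep_table["stent_present"]].reset_index(drop=True)
    if df.empty:
        raise ValueError("no stented rows to calibrate on")
    th = df["theta"].to_numpy(float)
    dep = df["entry_depth"].to_numpy(float)
    dia = df["D2"].to_numpy(float)
    q = df["mass_flux"].to_numpy(float)
    scale = max(np.abs(q).max(), 1e-12)

    # stage 1: the transition boundary theta = a + b*depth is fitted to the
    # classifications directly.  For each candidate slope the feasible
    # intercept interval is exact: every reflux row needs a > theta - b*dep,
    # every outflow row a < theta - b*dep.  Taking the midpoint of the
    # widest feasible interval makes the later sign check hold by
    # construction.
    cls = df["classification"].to_numpy()
    reflux = cls == "reflux"
    outflow = cls == "outflow"
    best = None
    for b in np.arange(0.0, 3.001, 0.05):
        margin = th - b * dep
        a_lo = margin[reflux].max() if reflux.any() else -np.inf
        a_hi = margin[outflow].min() if outflow.any() else np.inf
        if a_hi - a_lo > 0 and (best is None or a_hi - a_lo > best[0]):
            best = (a_hi - a_lo, 0.5 * (a_lo + a_hi), b)
    if best is None:
        raise ValueError("no affine-in-depth transition boundary separates "
                         "the calibration classifications; the surrogate "
                         "form cannot represent this sweep")
    _, th_star, slope = best

    # stage 2: magnitudes, with the boundary frozen
    def model(p):
        lw, c0, c1, c2 = p
        return np.exp(c0 + c1 * dep + c2 * dia) \
            * np.tanh((th - th_star - slope * dep) / np.exp(lw))

    res = least_squares(lambda p: model(p) - q,
                        x0=[math.log(15.0), math.log(scale), 0.0, 0.0],
                        bounds=([math.log(1.0), -60, -2, -2],
                                [math.log(80.0), 10, 2, 2]))
    lw, c0, c1, c2 = res.x
    coeffs = SurrogateCoeffs(
        theta_star=float(th_star), depth_slope=float(slope),
        width=float(math.exp(lw)),
        c0=float(c0), c1=float(c1), c2=float(c2),
        theta_range=(float(th.min()), float(th.max())),
        depth_range=(float(dep.min()), float(dep.max())),
        diameter_range=(float(dia.min()), float(dia.max())))
    pred = surrogate_flow(th, dep, dia, coeffs)
    cls = df["classification"].to_numpy()
    decided = cls != "stagnant"
    if np.any(np.sign(pred[decided]) != np.where(cls[decided] == "outflow",
                                                 1.0, -1.0)):
        raise ValueError("surrogate sign disagrees with the solver on a "
                         "calibration row; refusing a miscalibrated fit")
    return coeffs


def surrogate_flow(angle, depth, diameter, coeffs: SurrogateCoeffs):
    """Reduced-order branch flow; warns outside the calibrated ranges."""
    angle = np.asarray(angle, dtype=float)
    depth = np.asarray(depth, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    for val, rng, name in ((angle, coeffs.theta_range, "angle"),
                           (depth, coeffs.depth_range, "depth"),
                           (diameter, coeffs.diameter_range, "diameter")):
        if np.any(val < rng[0]) or np.any(val > rng[1]):
            warnings.warn(f"surrogate extrapolating beyond calibrated "
                          f"{name} range {rng}", RuntimeWarning)
    out = np.exp(coeffs.c0 + coeffs.c1 * depth + coeffs.c2 * diameter) \
        * np.tanh((angle - coeffs.transition_angle(depth)) / coeffs.width)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# CSV round trip for case tables
# ---------------------------------------------------------------------------

def cases_to_csv(records, path):
    import pandas as pd
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
    return path


def cases_from_csv(path):
    import pandas as pd
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if "flow" in d and pd.isna(d["flow"]):
            d["flow"] = None
        recs.append(ArteryRecord(**d))
    return recs
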