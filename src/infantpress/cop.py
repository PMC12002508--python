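"""Centre-of-pressure trajectory construction in a common reference system.

Per loaded frame the CoP is the pressure-weighted centroid of the pixel
centres.  Trajectories are time-normalized to 101 stance nodes by cubic
spline, then re-referenced into a cohort-wide frame built from two scalar
references per step: K, the most posterior contact coordinate of the
step's maximum pressure picture, and J, the ML coordinate of its
longitudinal axis (the pressure-weighted centroid after vertical
rotation).  K and J are aggregated hierarchically — within infant
(per visit), then between infants — and the between-infant aggregates
K_BS / J_BS are subtracted from every trajectory:

    AP_it = AP_t - K_BS        ML_it = ML_t - J_BS

ML is signed so that positive values are medial CoP applications.
Finally trajectories are normalised to percent of foot length / width.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline

from .grid import PITCH_CM
from .io import InputError, MaxPressurePicture, StepRecord


@dataclasses.dataclass
class CoPPath:
    """Raw CoP path over the loaded frames of one step (cm)."""

    ap: np.ndarray
    ml: np.ndarray
    stance_fraction: np.ndarray

    def __post_init__(self):
        self.ap = np.asarray(self.ap, float)
        self.ml = np.asarray(self.ml, float)
        self.stance_fraction = np.asarray(self.stance_fraction, float)
        n = self.ap.size
        if not (self.ml.size == n == self.stance_fraction.size) or n < 2:
            raise InputError("ap, ml, stance_fraction must share length >= 2")
        d = np.diff(self.stance_fraction)
        if np.any(d <= 0) or self.stance_fraction[0] != 0.0 or self.stance_fraction[-1] != 1.0:
            raise InputError("stance_fraction must increase strictly from 0 to 1")


@dataclasses.dataclass
class ReferenceSystem:
    """Common reference values: per-step K/J, within-infant (per visit)
    aggregates, and the between-infant grand aggregates."""

    K_per_step: dict  # (infant_id, stage, step index) -> cm
    J_per_step: dict
    K_WS: dict  # (infant_id, stage) -> cm
    J_WS: dict
    K_BS: float
    J_BS: float


@dataclasses.dataclass
class CoPTrajectory:
    """101-node re-referenced trajectory; ML positive = medial."""

    ap_101: np.ndarray
    ml_101: np.ndarray
    units: str = "cm"  # or "percent"
    infant_id: str = ""
    stage: str = ""
    side: str = ""

    def __post_init__(self):
        self.ap_101 = np.asarray(self.ap_101, float)
        self.ml_101 = np.asarray(self.ml_101, float)
        if self.ap_101.size != 101 or self.ml_101.size != 101:
            raise InputError("trajectory components must have exactly 101 nodes")


def compute_cop_path(step: StepRecord, load_threshold: float = 1.0) -> CoPPath:
    """Pressure-weighted centroid per loaded frame of a rotated step.

    Frames whose total load is <= ``load_threshold`` (kPa) are excluded;
    stance_fraction spans the loaded frames uniformly.
    """
    totals = step.frames.sum(axis=(1, 2))
    loaded = np.nonzero(totals > load_threshold)[0]
    if loaded.size < 2:
        raise InputError("fewer than 2 loaded frames")
    rows = np.arange(step.frames.shape[1]) * step.pitch_cm
    cols = np.arange(step.frames.shape[2]) * step.pitch_cm
    f = step.frames[loaded]
    tot = totals[loaded]
    ap = (f.sum(axis=2) @ rows) / tot
    ml = (f.sum(axis=1) @ cols) / tot
    return CoPPath(ap=ap, ml=ml, stance_fraction=np.linspace(0.0, 1.0, loaded.size))


def resample_101(path: CoPPath) -> CoPPath:
    """Cubic-spline resampling to the 101 stance nodes 0, 0.01, ..., 1."""
    t = path.stance_fraction
    if np.any(np.diff(t) == 0):
        raise InputError("duplicate stance_fraction values")
    nodes = np.linspace(0.0, 1.0, 101)
    if t.size < 4:  # cubic needs 4 support points; fall back to lower order
        ap = np.interp(nodes, t, path.ap)
        ml = np.interp(nodes, t, path.ml)
    else:
        ap = CubicSpline(t, path.ap)(nodes)
        ml = CubicSpline(t, path.ml)(nodes)
    ap[0], ap[-1] = path.ap[0], path.ap[-1]
    ml[0], ml[-1] = path.ml[0], path.ml[-1]
    return CoPPath(ap=ap, ml=ml, stance_fraction=nodes)


def compute_K(mpp: MaxPressurePicture, load_threshold: float = 1.0) -> float:
    """Most posterior contact coordinate (cm): minimum AP coordinate over
    MPP pixels with pressure above threshold."""
    rows, _ = np.nonzero(mpp.grid > load_threshold)
    if rows.size == 0:
        raise InputError("MPP has no pixel above threshold")
    return float(rows.min() * mpp.pitch_cm)


def compute_J(mpp: MaxPressurePicture) -> float:
    """ML coordinate (cm) of the longitudinal axis: the pressure-weighted
    centroid column of the (rotated) MPP."""
    tot = mpp.grid.sum()
    if tot <= 0:
        raise InputError("MPP entirely zero")
    cols = np.arange(mpp.grid.shape[1]) * mpp.pitch_cm
    return float((mpp.grid.sum(axis=0) @ cols) / tot)


def aggregate_reference(
    per_step: list[tuple[str, str, float, float]],
    statistic=np.mean,
) -> ReferenceSystem:
    """Hierarchical aggregation of per-step (infant_id, stage, K, J).

    Within-infant aggregates are taken per visit; the between-infant
    values are the aggregate of those within-infant values across infants
    and visits.  The statistic defaults to the arithmetic mean.
    """
    if not per_step:
        raise InputError("no per-step reference values")
    K_per, J_per = {}, {}
    groups: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for idx, (iid, stage, K, J) in enumerate(per_step):
        K_per[(iid, stage, idx)] = K
        J_per[(iid, stage, idx)] = J
        groups.setdefault((iid, stage), []).append((K, J))
    K_WS = {g: float(statistic([k for k, _ in v])) for g, v in groups.items()}
    J_WS = {g: float(statistic([j for _, j in v])) for g, v in groups.items()}
    K_BS = float(statistic(list(K_WS.values())))
    J_BS = float(statistic(list(J_WS.values())))
    return ReferenceSystem(K_per, J_per, K_WS, J_WS, K_BS, J_BS)


def rereference(
    path_101: CoPPath,
    refs: ReferenceSystem,
    side: str = "right",
    mirrored: bool = True,
    infant_id: str = "",
    stage: str = "",
) -> CoPTrajectory:
    """Subtract the between-infant references and orient the ML sign so
    positive = medial.

    Trajectories computed from steps mirrored onto the right-foot
    convention already have the medial side at increasing ML coordinate;
    unmirrored left steps have their ML sign flipped instead.
    """
    if refs is None:
        raise InputError("missing reference system")
    ap = path_101.ap - refs.K_BS
    ml = path_101.ml - refs.J_BS
    if side == "left" and not mirrored:
        ml = -ml
    return CoPTrajectory(ap_101=ap, ml_101=ml, units="cm", infant_id=infant_id, stage=stage, side=side)


def normalise_trajectory(
    traj: CoPTrajectory, foot_length_cm: float, foot_width_cm: float
) -> CoPTrajectory:
    """Express AP in % of foot length and ML in % of foot width."""
    if foot_length_cm <= 0 or foot_width_cm <= 0:
        raise InputError("foot dimensions must be positive")
    if traj.units == "percent":
        return traj
    return CoPTrajectory(
        ap_101=traj.ap_101 * 100.0 / foot_length_cm,
        ml_101=traj.ml_101 * 100.0 / foot_width_cm,
        units="percent",
        infant_id=traj.infant_id,
        stage=traj.stage,
        side=traj.side,
    )


def ap_origin_percent(traj: CoPTrajectory) -> float:
    """AP trajectory origin: the value at stance node 0, in % of foot
    length from the most posterior contact of the grand reference."""
    if traj.units != "percent":
        raise InputError("trajectory must be normalised to percent")
    return float(traj.ap_101[0])


def trajectories_to_frame(trajs: list[CoPTrajectory]):
    """Export trajectories as a long-format table (CSV-ready)."""
    import pandas as pd

    rows = []
    for tr in trajs:
        for node in range(101):
            rows.append(
                dict(
                    infant_id=tr.infant_id,
                    stage=tr.stage,
                    side=tr.side,
                    node=node,
                    ap_value=tr.ap_101[node],
                    ml_value=tr.ml_101[node],
                    units=tr.units,
                )
            )
    return pd.DataFrame(rows)
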