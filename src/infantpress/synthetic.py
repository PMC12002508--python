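"""Synthetic cohort and footstep-pressure generator.

Generates infant cohorts whose anthropometrics match the study's per-stage
summary table (means, SDs, ranges, and the reported pairwise correlations),
and per-step 36 x 25 pressure-frame sequences with known ground truth: a
two-lobed foot silhouette, a stage-dependent rollover whose initial contact
sits at a configurable fraction of foot length from the heel (defaults:
50% when new to walking, 30% when walking confidently), a medially biased
centre-of-pressure path, and a random in-plane pose on the platform grid.

Every generated quantity is deterministic given (config, seed), and every
step carries its generator truth (CoP path, pose, contact onset) so the
downstream pipeline can be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from . import io as pio
from .grid import N_COLS_ML, N_ROWS_AP, PITCH_CM

MONTH_DAYS = 30.44

STAGES = ("new", "confident")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """A step could not be generated (e.g. foot too large for the grid)."""


# ---------------------------------------------------------------------------
# Cohort configuration (defaults encode the study's participant table)
# ---------------------------------------------------------------------------

#: (min, mean, sd, max) per measure and stage.
DEFAULT_ANTHROPOMETRICS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "new": {
        "mass_kg": (8.0, 10.3, 1.3, 13.8),
        "height_cm": (68.5, 74.7, 3.1, 81.8),
        "foot_length_cm": (9.7, 11.4, 0.7, 12.6),
        "foot_width_cm": (4.4, 5.1, 0.4, 6.0),
        "age_months": (9.1, 13.3, 1.6, 16.6),
        "days_since_milestone": (7.0, 14.5, 5.1, 21.0),
    },
    "confident": {
        "mass_kg": (8.5, 11.0, 1.3, 14.0),
        "height_cm": (71.9, 78.4, 3.5, 85.0),
        "foot_length_cm": (10.5, 11.9, 0.8, 13.6),
        "foot_width_cm": (4.3, 5.2, 0.4, 6.2),
        "age_months": (12.3, 15.6, 1.8, 20.2),
        "days_since_milestone": (3.0, 15.2, 5.5, 21.0),
    },
}

#: Pairwise Pearson targets reported for the cohort (all other pairs 0).
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("height_cm", "age_months"): 0.53,
    ("height_cm", "mass_kg"): 0.63,
    ("mass_kg", "foot_length_cm"): 0.50,
    ("days_since_milestone", "age_months"): 0.59,
}

_VARS = ("mass_kg", "height_cm", "foot_length_cm", "foot_width_cm", "age_months", "days_since_milestone")


@dataclasses.dataclass
class CohortConfig:
    """Cohort structure and anthropometric distribution parameters."""

    n_infants: int = 39
    stages: tuple[str, ...] = STAGES
    steps_per_foot_per_stage: int = 3
    anthropometrics: dict = dataclasses.field(
        default_factory=lambda: {s: dict(DEFAULT_ANTHROPOMETRICS[s]) for s in STAGES}
    )
    correlation_targets: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    experience_mode: str = "cumulative"  # or "since_milestone"
    seed: int = 0

    def validate(self) -> None:
        if self.n_infants < 0 or self.steps_per_foot_per_stage < 0:
            raise ConfigurationError("counts must be >= 0")
        for stage, table in self.anthropometrics.items():
            for name, (lo, mean, sd, hi) in table.items():
                if sd < 0:
                    raise ConfigurationError(f"{stage}/{name}: SD < 0")
                if not (lo <= mean <= hi):
                    raise ConfigurationError(f"{stage}/{name}: min <= mean <= max violated")
        for pair, r in self.correlation_targets.items():
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"correlation target {pair} outside [-1, 1]")
        if self.experience_mode not in ("cumulative", "since_milestone"):
            raise ConfigurationError(f"unknown experience_mode {self.experience_mode!r}")


@dataclasses.dataclass(frozen=True)
class StageRecord:
    mass_kg: float
    height_cm: float
    foot_length_cm: float
    foot_width_cm: float
    age_months: float
    days_since_milestone: float
    experience_days: float


@dataclasses.dataclass(frozen=True)
class InfantProfile:
    infant_id: str
    stages: dict  # stage label -> StageRecord

    def __post_init__(self):
        for rec in self.stages.values():
            if not rec.foot_length_cm > rec.foot_width_cm > 0:
                raise ConfigurationError("foot length > foot width > 0 violated")
        if "new" in self.stages and "confident" in self.stages:
            if self.stages["confident"].age_months < self.stages["new"].age_months:
                raise ConfigurationError("confident-stage age < new-stage age")


# ---------------------------------------------------------------------------
# Truncated multivariate-normal cohort sampling
# ---------------------------------------------------------------------------


def _nearest_pd_corr(C: np.ndarray) -> np.ndarray:
    """Nearest positive-definite correlation matrix (eigenvalue clipping +
    unit-diagonal rescaling)."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-6, None)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _target_corr_matrix(targets: dict) -> np.ndarray:
    C = np.eye(len(_VARS))
    idx = {v: i for i, v in enumerate(_VARS)}
    for (a, b), r in targets.items():
        if a in idx and b in idx:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return _nearest_pd_corr(C)


def _z_bounds(table: dict) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([(table[v][0] - table[v][1]) / max(table[v][2], 1e-12) for v in _VARS])
    hi = np.array([(table[v][3] - table[v][1]) / max(table[v][2], 1e-12) for v in _VARS])
    return lo, hi


def _sample_truncated_z(C: np.ndarray, lo: np.ndarray, hi: np.ndarray, n: int, rng) -> np.ndarray:
    """Rejection-sample n rows of standard-normal z with correlation C,
    truncated componentwise to [lo, hi]."""
    L = np.linalg.cholesky(C)
    out = np.empty((n, len(_VARS)))
    got = 0
    while got < n:
        batch = max(64, 2 * (n - got))
        z = rng.standard_normal((batch, len(_VARS))) @ L.T
        ok = np.all((z >= lo) & (z <= hi), axis=1)
        take = z[ok][: n - got]
        out[got : got + take.shape[0]] = take
        got += take.shape[0]
    return out


_CALIBRATION_CACHE: dict = {}


def _calibrated_latent_corr(targets: dict, table: dict) -> np.ndarray:
    """Latent correlation matrix such that the componentwise-truncated
    sample reproduces the target correlations.

    Truncation attenuates correlations; a short fixed-seed Monte-Carlo
    fixed-point iteration inflates the latent entries to compensate.
    """
    key = (tuple(sorted((a, b, r) for (a, b), r in targets.items())),
           tuple(sorted((v, table[v]) for v in _VARS)))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    idx = {v: i for i, v in enumerate(_VARS)}
    lo, hi = _z_bounds(table)
    latent = {pair: r for pair, r in targets.items()}
    C = _target_corr_matrix(latent)
    rng = np.random.default_rng(90210)
    for _ in range(3):
        z = _sample_truncated_z(C, lo, hi, 8000, rng)
        R = np.corrcoef(z, rowvar=False)
        for (a, b), r in targets.items():
            realized = R[idx[a], idx[b]]
            latent[(a, b)] = float(np.clip(latent[(a, b)] + (r - realized), -0.97, 0.97))
        C = _target_corr_matrix(latent)
    _CALIBRATION_CACHE[key] = C
    return C


def sample_cohort(config: CohortConfig) -> list[InfantProfile]:
    """Draw a cohort of infant profiles from the configured truncated
    multivariate normal; deterministic given ``config.seed``.

    Stage-to-stage consistency is obtained by reusing each infant's latent
    z-score at both stages for the growth variables (comonotone visits), so
    confident-stage age/mass/height/foot size always exceed the new-stage
    values while each stage keeps its own configured marginals.
    """
    config.validate()
    if config.n_infants == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 1]))
    new_t = config.anthropometrics["new"]
    C = _calibrated_latent_corr(config.correlation_targets, new_t)
    lo, hi = _z_bounds(new_t)
    z = _sample_truncated_z(C, lo, hi, config.n_infants, rng)

    profiles = []
    for i in range(config.n_infants):
        recs = {}
        values = {}
        for stage in config.stages:
            table = config.anthropometrics[stage]
            vals = {}
            for j, v in enumerate(_VARS):
                lo_v, mean, sd, hi_v = table[v]
                if v == "days_since_milestone" and stage != "new":
                    # per-visit recency is not a growth variable: fresh draw
                    zz = rng.standard_normal()
                    zlo = (lo_v - mean) / max(sd, 1e-12)
                    zhi = (hi_v - mean) / max(sd, 1e-12)
                    while not (zlo <= zz <= zhi):
                        zz = rng.standard_normal()
                    vals[v] = mean + sd * zz
                else:
                    vals[v] = float(np.clip(mean + sd * z[i, j], lo_v, hi_v))
            values[stage] = vals
        milestone_age_new = None
        if "new" in values:
            milestone_age_new = values["new"]["age_months"] - values["new"]["days_since_milestone"] / MONTH_DAYS
        for stage in config.stages:
            vals = values[stage]
            if config.experience_mode == "cumulative" and milestone_age_new is not None:
                exp = (vals["age_months"] - milestone_age_new) * MONTH_DAYS
            else:
                exp = vals["days_since_milestone"]
            recs[stage] = StageRecord(
                mass_kg=vals["mass_kg"],
                height_cm=vals["height_cm"],
                foot_length_cm=vals["foot_length_cm"],
                foot_width_cm=vals["foot_width_cm"],
                age_months=vals["age_months"],
                days_since_milestone=vals["days_since_milestone"],
                experience_days=float(exp),
            )
        profiles.append(InfantProfile(infant_id=f"inf{i:03d}", stages=recs))
    return profiles


def cohort_table(profiles: list[InfantProfile]):
    """Long-format cohort table (one row per infant per stage)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for stage, r in p.stages.items():
            rows.append(
                dict(
                    infant_id=p.infant_id,
                    stage=stage,
                    mass_kg=r.mass_kg,
                    height_cm=r.height_cm,
                    foot_length_cm=r.foot_length_cm,
                    foot_width_cm=r.foot_width_cm,
                    age_months=r.age_months,
                    experience_days=r.experience_days,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rollover / pressure-field model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RolloverParams:
    """Parameters of the synthetic rollover pressure field.

    contact_onset_frac: fraction of foot length (from the heel) where the
    first loaded frame's pressure centroid lies.  medial_offset_profile:
    medial offset of the CoP activation path vs the foot axis, as a
    fraction of foot width, sampled over stance.  regional_peak_pressures:
    peak pressure (kPa) per anatomical zone.
    """

    contact_onset_frac: float = 0.50
    stance_frames: int = 30
    medial_offset_profile: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(11, 0.22)
    )
    medial_ridge_amp: float = 0.25
    medial_ridge_width_frac: float = 0.30
    regional_peak_pressures: dict = dataclasses.field(
        default_factory=lambda: {"heel": 160.0, "midfoot": 60.0, "forefoot": 140.0, "toes": 90.0}
    )
    noise_sd: float = 3.0
    contact_floor: float = 5.0  # kPa: light whole-sole contact pressure
    toe_off_frac: float = 0.82
    convergence_time: float = 0.38  # stance fraction where rollovers merge
    convergence_frac: float = 0.62  # foot-length fraction at the merge point
    ridge_gate_onset: float = 0.40  # stage-independent gate reference onset
    load_cutoff: float = 0.5
    max_rotation_deg: float = 20.0
    #: scale of natural rollover variability (0 disables it).  Visit-level
    #: perturbations emulate how an infant's rollover style differs
    #: between sessions months apart; step-level jitter is smaller.
    #: The contact onset itself is never jittered (it is the calibrated
    #: stage signature).
    variability: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.contact_onset_frac <= 1.0:
            raise ConfigurationError("contact_onset_frac outside [0, 1]")
        if self.stance_frames < 2:
            raise ConfigurationError("stance_frames must be >= 2")
        if any(v < 0 for v in self.regional_peak_pressures.values()):
            raise ConfigurationError("regional peak pressures must be >= 0")

    def medial_offset(self, t: np.ndarray | float) -> np.ndarray:
        prof = np.asarray(self.medial_offset_profile, float)
        return np.interp(t, np.linspace(0, 1, prof.size), prof)


def default_rollover(stage: str) -> RolloverParams:
    """Stage defaults: initial contact at 50% (new) / 30% (confident) of
    foot length."""
    return RolloverParams(contact_onset_frac=0.50 if stage == "new" else 0.30)


_HW_TAU = np.array([0.0, 0.03, 0.15, 0.32, 0.47, 0.62, 0.75, 0.88, 1.0])
_HW_S = np.array([0.0, 0.70, 0.82, 0.62, 0.52, 0.88, 1.00, 0.72, 0.0])
_halfwidth_frac = PchipInterpolator(_HW_TAU, _HW_S)


def _zone_gain(tau: np.ndarray, peaks: dict) -> np.ndarray:
    h, m, f, t = (peaks["heel"], peaks["midfoot"], peaks["forefoot"], peaks["toes"])
    xp = [0.0, 0.15, 0.30, 0.45, 0.60, 0.72, 0.85, 0.93, 1.0]
    fp = [0.7 * h, h, 0.6 * h + 0.4 * m, m, 0.5 * m + 0.5 * f, f, f, t, 0.6 * t]
    return np.interp(tau, xp, fp)


def _wave_center(t, rp: RolloverParams, onset_adjust: float = 0.0):
    """Contact-wave centre as a fraction of foot length: piecewise linear
    through (0, onset), (convergence_time, convergence_frac),
    (1, toe_off).  After the convergence knot the path is identical for
    every onset, mirroring how different walking stages' AP trajectories
    merge in mid-stance."""
    onset = min(rp.contact_onset_frac + onset_adjust, rp.convergence_frac - 1e-3)
    return np.interp(
        np.asarray(t, float),
        [0.0, rp.convergence_time, 1.0],
        [onset, rp.convergence_frac, rp.toe_off_frac],
    )


def _pressure_field(u, v, t, L, W, rp: RolloverParams, onset_adjust: float = 0.0):
    """Noise-free pressure (kPa) of the rollover field at foot-frame
    coordinates (u medial+, v from heel) and normalized stance time t."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    tau = v / L
    inside = (tau >= 0.0) & (tau <= 1.0)
    hw = np.where(inside, 0.5 * W * np.clip(_halfwidth_frac(np.clip(tau, 0, 1)), 0, None), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi2 = np.where(hw > 0, (u / np.where(hw > 0, hw, 1.0)) ** 2, np.inf)
    cross = np.clip(1.0 - xi2, 0.0, None)
    # the contact wave starts at the stage's onset but merges onto a common
    # rollover by ~45% of stance (different stages' paths converge there,
    # as infant AP trajectories do), then progresses to toe-off
    c = _wave_center(t, rp, onset_adjust) * L
    wv = L * (0.055 + 0.10 * math.sin(math.pi * t))
    act_v = np.exp(-((v - c) ** 2) / (2.0 * wv**2))
    # medial bias: a sustained low-amplitude ridge (the silhouette profile
    # shifted medially) rides along with the contact wave.  Because the
    # ridge peak stays below the base peak, it barely moves the pixelwise
    # maximum image, while it pulls every frame's centroid medially -- so
    # the instantaneous CoP sits medial to the MPP's longitudinal axis.
    # the ridge shift scales with the local half-width (nominal value
    # medial_offset * W at the widest section) so each row carries the
    # same relative medial mass and the principal axis stays untilted
    d0 = 2.0 * float(rp.medial_offset(t))
    with np.errstate(divide="ignore", invalid="ignore"):
        xi2_r = np.where(hw > 0, (u / np.where(hw > 0, hw, 1.0) - d0) ** 2, np.inf)
    cross_r = np.where(cross > 0, np.clip(1.0 - xi2_r, 0.0, None), 0.0)
    wr = rp.medial_ridge_width_frac * L
    act_r = np.exp(-((v - c) ** 2) / (2.0 * wr**2))
    # gate the ridge by a reference wave's maximum load envelope per row:
    # rows the rollover never loads strongly carry no extra medial mass
    # (otherwise faint rows would tilt the image's principal axis).  The
    # gate uses a fixed stage-independent reference onset so that the
    # post-convergence CoP does not depend on the stage's contact onset.
    tt = np.linspace(1e-3, 1.0 - 1e-3, 41)
    cc = np.interp(
        tt,
        [0.0, rp.convergence_time, 1.0],
        [min(rp.ridge_gate_onset, rp.convergence_frac - 1e-3), rp.convergence_frac, rp.toe_off_frac],
    ) * L
    ww = L * (0.055 + 0.10 * np.sin(np.pi * tt))
    ee = np.sin(np.pi * tt) ** 0.7
    gate = (np.exp(-((v[..., None] - cc) ** 2) / (2.0 * ww**2)) * ee).max(axis=-1)
    env = math.sin(math.pi * t) ** 0.7
    g = _zone_gain(np.clip(tau, 0, 1), rp.regional_peak_pressures)
    p = (
        g * (cross * act_v + rp.medial_ridge_amp * cross_r * act_r * gate)
        + rp.contact_floor * cross
    ) * env
    p = np.where(p >= rp.load_cutoff, p, 0.0)
    return p


def _perturbed_rollover(rp: RolloverParams, visit_rng, step_rng) -> RolloverParams:
    """Visit- and step-level rollover variability.

    Toe-off position, the convergence knot, regional gains and the medial
    offset get zero-mean perturbations; all steps of one infant at one
    visit share the visit-level component.  Without this, synthetic
    trajectories are implausibly repeatable and any systematic offset --
    however tiny -- dominates paired statistics.
    """
    v = rp.variability
    if v == 0.0:
        return rp
    toe = float(np.clip(
        rp.toe_off_frac + v * (visit_rng.normal(0.0, 0.05) + step_rng.normal(0.0, 0.015)),
        0.70, 0.92,
    ))
    conv_f = float(np.clip(
        rp.convergence_frac + v * (visit_rng.normal(0.0, 0.03) + step_rng.normal(0.0, 0.015)),
        max(rp.contact_onset_frac + 0.05, 0.45), toe - 0.08,
    ))
    conv_t = float(np.clip(rp.convergence_time + v * visit_rng.normal(0.0, 0.05), 0.25, 0.50))
    gains = {
        k: val * math.exp(v * (visit_rng.normal(0.0, 0.12) + step_rng.normal(0.0, 0.05)))
        for k, val in rp.regional_peak_pressures.items()
    }
    medial = np.asarray(rp.medial_offset_profile, float) + v * visit_rng.normal(0.0, 0.03)
    return dataclasses.replace(
        rp,
        toe_off_frac=toe,
        convergence_frac=conv_f,
        convergence_time=conv_t,
        regional_peak_pressures=gains,
        medial_offset_profile=np.clip(medial, 0.0, 0.45),
    )


@dataclasses.dataclass
class SyntheticStep:
    """A generated step plus its ground truth."""

    step: pio.StepRecord
    truth_cop_xy: np.ndarray  # (n_loaded, 2) platform (x_ml, y_ap) cm
    truth_pose: tuple[float, float, float]  # rotation rad, tx, ty cm
    truth_contact_onset_frac: float
    foot_length_cm: float
    foot_width_cm: float


def _sample_pose(L, W, rng, max_rot_deg, pitch=PITCH_CM):
    """Random in-plane pose keeping every nonzero pixel >= 1 pixel inside
    the platform border."""
    margin = 0.75 * pitch
    xmax_plat = (N_COLS_ML - 1) * pitch
    ymax_plat = (N_ROWS_AP - 1) * pitch
    corners = np.array([[-0.5 * W, 0.0], [0.5 * W, 0.0], [-0.5 * W, L], [0.5 * W, L]])
    max_rot = math.radians(max_rot_deg)
    for attempt in range(60):
        shrink = 0.85 ** (attempt // 10)
        theta = rng.uniform(-max_rot, max_rot) * shrink
        ca, sa = math.cos(theta), math.sin(theta)
        R = np.array([[ca, -sa], [sa, ca]])
        rc = corners @ R.T
        xlo, ylo = rc.min(axis=0)
        xhi, yhi = rc.max(axis=0)
        tx_lo, tx_hi = margin + pitch - xlo, xmax_plat - margin - pitch - xhi
        ty_lo, ty_hi = margin + pitch - ylo, ymax_plat - margin - pitch - yhi
        if tx_lo <= tx_hi and ty_lo <= ty_hi:
            return theta, rng.uniform(tx_lo, tx_hi), rng.uniform(ty_lo, ty_hi)
    raise GenerationError(f"foot {L:.1f} x {W:.1f} cm does not fit the platform grid")


def synthesize_step(
    profile: InfantProfile,
    stage: str,
    rollover: RolloverParams | None = None,
    seed: int = 0,
    side: str = "right",
    pose: tuple[float, float, float] | None = None,
    compute_truth: bool = True,
    visit_seed: int | None = None,
) -> SyntheticStep:
    """Generate one footstep: a full loading cycle of pressure frames on
    the platform grid, at a random (or given) in-plane pose, with ground
    truth recorded.  Deterministic given (arguments, seed).

    ``visit_seed`` controls the visit-level rollover perturbation shared
    by all of an infant's steps at one visit; by default it is derived
    from (infant_id, stage) so repeated direct calls stay consistent.
    """
    rp = rollover if rollover is not None else default_rollover(stage)
    rp.validate()
    if visit_seed is None:
        visit_seed = zlib.crc32(f"{profile.infant_id}|{stage}".encode()) & 0x7FFFFFFF
    rng_step_jitter = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 5]))
    rp = _perturbed_rollover(rp, np.random.default_rng(visit_seed), rng_step_jitter)
    rec = profile.stages[stage]
    L, W = rec.foot_length_cm, rec.foot_width_cm
    if L > N_ROWS_AP * PITCH_CM:
        raise GenerationError(f"foot length {L} cm exceeds the {N_ROWS_AP * PITCH_CM} cm grid")
    rng = np.random.default_rng(seed)
    if pose is None:
        pose = _sample_pose(L, W, rng, rp.max_rotation_deg)
    theta, tx, ty = pose
    s = 1.0 if side == "right" else -1.0

    n = rp.stance_frames
    n_inner = n - 2  # frames 0 and n-1 are unloaded by construction
    t_norm = (np.arange(n_inner) + 1.0) / (n_inner + 1.0)

    # calibrate the onset knot of the activation path so the first loaded
    # frame's centroid sits exactly at contact_onset_frac * L (generator
    # contract); only the pre-convergence part of the path moves, so
    # mid/late-stance behaviour stays identical across onsets
    fine_u = np.linspace(-0.5 * W, 0.5 * W, max(24, int(W / 0.15)))
    fine_v = np.linspace(0.0, L, max(48, int(L / 0.15)))
    UU, VV = np.meshgrid(fine_u, fine_v, indexing="xy")
    onset_adjust = 0.0
    for _ in range(2):
        p0 = _pressure_field(UU, VV, float(t_norm[0]), L, W, rp, onset_adjust)
        tot = p0.sum()
        if tot <= 0:
            break
        v_c = float((p0 * VV).sum() / tot)
        onset_adjust += (rp.contact_onset_frac * L - v_c) / L

    # render frames at pixel centres (X: ML, Y: AP, both (36, 25))
    X = np.arange(N_COLS_ML)[None, :] * PITCH_CM * np.ones((N_ROWS_AP, 1))
    Y = np.arange(N_ROWS_AP)[:, None] * PITCH_CM * np.ones((1, N_COLS_ML))
    ca, sa = math.cos(theta), math.sin(theta)
    xr = ca * (X - tx) + sa * (Y - ty)
    yr = -sa * (X - tx) + ca * (Y - ty)
    u_pix = s * xr
    v_pix = yr

    frames = np.zeros((n, N_ROWS_AP, N_COLS_ML))
    clean = np.zeros_like(frames)
    for k, t in enumerate(t_norm):
        clean[k + 1] = _pressure_field(u_pix, v_pix, float(t), L, W, rp, onset_adjust)
    if rp.noise_sd > 0:
        noise = rng.normal(0.0, rp.noise_sd, size=clean.shape)
        frames = np.clip(np.where(clean > 0, clean + noise, 0.0), 0.0, None)
    else:
        frames = clean.copy()

    loaded = np.nonzero(frames.sum(axis=(1, 2)) > 0)[0]
    truth_xy = np.empty((0, 2))
    if compute_truth and loaded.size:
        pts = []
        for k in loaded:
            t = float(t_norm[k - 1])
            p = _pressure_field(UU, VV, t, L, W, rp, onset_adjust)
            tot = p.sum()
            if tot <= 0:  # sub-pixel support mismatch: fall back to the frame
                g = clean[k]
                tot = g.sum()
                u_c = float((g * u_pix).sum() / tot)
                v_c = float((g * v_pix).sum() / tot)
            else:
                u_c = float((p * UU).sum() / tot)
                v_c = float((p * VV).sum() / tot)
            xf, yf = s * u_c, v_c
            pts.append([ca * xf - sa * yf + tx, sa * xf + ca * yf + ty])
        truth_xy = np.array(pts)

    step = pio.StepRecord(
        frames,
        infant_id=profile.infant_id,
        stage=stage,
        side=side,
        pitch_cm=PITCH_CM,
        rate_hz=100.0,
    )
    return SyntheticStep(
        step=step,
        truth_cop_xy=truth_xy,
        truth_pose=(theta, tx, ty),
        truth_contact_onset_frac=rp.contact_onset_frac,
        foot_length_cm=L,
        foot_width_cm=W,
    )


def generate_dataset(
    config: CohortConfig,
    rollovers: dict[str, RolloverParams] | None = None,
    outdir: str | Path | None = None,
    compute_truth: bool = True,
) -> list[SyntheticStep]:
    """Generate the full cohort dataset: ``n_infants x |stages| x 2 sides x
    steps_per_foot_per_stage`` steps, optionally written to ``outdir`` in
    the ASCII dialect together with the cohort table and config."""
    config.validate()
    profiles = sample_cohort(config)
    rollovers = rollovers or {s: default_rollover(s) for s in config.stages}
    steps: list[SyntheticStep] = []
    for i, profile in enumerate(profiles):
        for j, stage in enumerate(config.stages):
            visit_seed = int(
                np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 3, i, j]).generate_state(1)[0]
                % (2**31)
            )
            for k, side in enumerate(("left", "right")):
                for l in range(config.steps_per_foot_per_stage):
                    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 2, i, j, k, l])
                    step_seed = int(ss.generate_state(1)[0])
                    steps.append(
                        synthesize_step(
                            profile,
                            stage,
                            rollover=rollovers[stage],
                            seed=step_seed,
                            side=side,
                            compute_truth=compute_truth,
                            visit_seed=visit_seed,
                        )
                    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for idx, s in enumerate(steps):
            st = s.step
            pio.write_step_ascii(
                st, outdir / f"{st.infant_id}_{st.stage}_{st.side}_{idx % max(config.steps_per_foot_per_stage, 1)}.txt"
            )
        cohort_table(profiles).to_csv(outdir / "cohort.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(
                dict(
                    n_infants=config.n_infants,
                    stages=list(config.stages),
                    steps_per_foot_per_stage=config.steps_per_foot_per_stage,
                    experience_mode=config.experience_mode,
                    seed=config.seed,
                ),
                fh,
            )
    return steps
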