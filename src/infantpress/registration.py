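"""Point-cloud registration of maximum pressure pictures.

MPPs are converted to pressure-bearing point clouds (one point per
suprathreshold pixel centre).  Within an infant, step clouds are rigidly
aligned with iterative closest point (ICP) and coordinate-averaged into a
mean cloud; across infants, mean clouds are non-rigidly aligned to an
unbiased (medoid) template with coherent point drift (CPD), a Gaussian-
mixture EM with a motion-coherence prior.  Pressures travel with point
identity: registration moves coordinates, never deforms pressures.

The aligned clouds are finally resampled onto the template's pixel
lattice, producing pixelwise-comparable pressure images for 2D field
statistics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.interpolate import griddata
from scipy.spatial import cKDTree

from .grid import N_COLS_ML, N_ROWS_AP, PITCH_CM
from .io import InputError, MaxPressurePicture


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class PressureCloud:
    """2D pixel-centre coordinates (cm) with matching pressures (kPa)."""

    points: np.ndarray  # (n, 2) as (x_ml, y_ap)
    pressures: np.ndarray  # (n,)
    infant_id: str = ""
    stage: str = ""
    side: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        self.pressures = np.asarray(self.pressures, float).ravel()
        if self.points.shape[0] != self.pressures.size or self.points.shape[0] < 3:
            raise InputError("cloud needs >= 3 points with matching pressures")
        if np.any(self.pressures <= 0):
            raise InputError("cloud pressures must be > 0")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def replace(self, **kw) -> "PressureCloud":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R(angle) x + t."""

    angle_rad: float
    translation: tuple[float, float]

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.angle_rad), math.sin(self.angle_rad)
        return np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix().T + np.asarray(self.translation)


@dataclasses.dataclass
class DeformationResult:
    """Outcome of a non-rigid registration."""

    displaced: np.ndarray  # (n, 2)
    displacement: np.ndarray  # (n, 2)
    iterations: int
    final_objective: float
    converged: bool
    objective_trace: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))


@dataclasses.dataclass
class AlignedPressureImage:
    """Pressures resampled on the template's 36 x 25 lattice."""

    grid: np.ndarray
    mask: np.ndarray
    infant_id: str = ""
    stage: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.mask = np.asarray(self.mask, bool)
        if self.grid.shape != self.mask.shape:
            raise InputError("grid and mask shapes differ")
        self.grid = np.where(self.mask, np.clip(self.grid, 0.0, None), 0.0)


# ---------------------------------------------------------------------------
# Cloud construction and error metric
# ---------------------------------------------------------------------------


def mpp_to_cloud(mpp: MaxPressurePicture, load_threshold: float = 1.0) -> PressureCloud:
    """One point per suprathreshold MPP pixel, carrying its pressure."""
    rows, cols = np.nonzero(mpp.grid > load_threshold)
    if rows.size < 3:
        raise InputError("fewer than 3 pixels above threshold")
    pts = np.column_stack([cols * mpp.pitch_cm, rows * mpp.pitch_cm])
    return PressureCloud(
        pts, mpp.grid[rows, cols], infant_id=mpp.infant_id, stage=mpp.stage, side=mpp.side
    )


def registration_error(a: PressureCloud, b: PressureCloud) -> float:
    """Mean symmetric nearest-neighbour distance between two clouds, mm."""
    ta, tb = cKDTree(a.points), cKDTree(b.points)
    d_ab = tb.query(a.points)[0]
    d_ba = ta.query(b.points)[0]
    return float(10.0 * 0.5 * (d_ab.mean() + d_ba.mean()))


def _symmetric_nn_cm(pa: np.ndarray, pb: np.ndarray) -> float:
    ta, tb = cKDTree(pa), cKDTree(pb)
    return 0.5 * (tb.query(pa)[0].mean() + ta.query(pb)[0].mean())


# ---------------------------------------------------------------------------
# Rigid ICP
# ---------------------------------------------------------------------------


def _procrustes_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform(math.atan2(R[1, 0], R[0, 0]), (float(t[0]), float(t[1])))


def _principal_angle(pts: np.ndarray) -> float:
    """Angle of the dominant covariance eigenvector, in (-pi/2, pi/2]."""
    q = pts - pts.mean(axis=0)
    cov = q.T @ q
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    ang = math.atan2(u[1], u[0])
    if ang <= -math.pi / 2:
        ang += math.pi
    elif ang > math.pi / 2:
        ang -= math.pi
    return ang


def _icp_core(source_pts, target_pts, tree, init: RigidTransform, max_iter, tol):
    pts = init.apply(source_pts)
    total = init
    prev = np.inf
    history = []
    converged = False
    for _ in range(max_iter):
        dist, idx = tree.query(pts)
        mean_d = float(dist.mean())
        history.append(mean_d)
        if prev - mean_d < tol:
            converged = True
            break
        prev = mean_d
        step = _procrustes_rigid(pts, target_pts[idx])
        pts = step.apply(pts)
        total = RigidTransform(
            total.angle_rad + step.angle_rad,
            tuple(step.apply(np.asarray(total.translation)[None, :])[0]),
        )
    return total, pts, history, converged


def icp_align(
    source: PressureCloud,
    target: PressureCloud,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[RigidTransform, PressureCloud, dict]:
    """Iterative closest point: alternate nearest-neighbour correspondence
    with a least-squares rigid update until the mean correspondence
    distance improves by less than ``tol``.

    Started from two initializations -- centroid alignment, and centroid
    plus principal-axis alignment -- keeping the better basin, which makes
    recovery of in-plane rotations up to the axis ambiguity reliable.
    Non-convergence within ``max_iter`` returns the best transform with a
    warning diagnostic rather than raising.
    """
    tree = cKDTree(target.points)
    mu_s = source.points.mean(axis=0)
    mu_t = target.points.mean(axis=0)
    inits = [RigidTransform(0.0, tuple(mu_t - mu_s))]
    d_ang = _principal_angle(target.points) - _principal_angle(source.points)
    d_ang = (d_ang + math.pi / 2) % math.pi - math.pi / 2  # axis is 180-ambiguous
    if abs(d_ang) > 1e-12:
        c, s = math.cos(d_ang), math.sin(d_ang)
        R = np.array([[c, -s], [s, c]])
        inits.append(RigidTransform(d_ang, tuple(mu_t - R @ mu_s)))
    best = None
    for init in inits:
        total, pts, history, converged = _icp_core(
            source.points, target.points, tree, init, max_iter, tol
        )
        if best is None or history[-1] < best[2][-1]:
            best = (total, pts, history, converged)
    total, pts, history, converged = best
    diag = {"iterations": len(history), "mean_distance": history[-1],
            "history": np.array(history), "converged": converged}
    if not converged:
        warnings.warn("ICP did not converge within max_iter", RuntimeWarning)
    return total, source.replace(points=pts), diag


# ---------------------------------------------------------------------------
# Within-subject averaging and template selection
# ---------------------------------------------------------------------------


def _medoid_index(clouds: list[PressureCloud]) -> int:
    """Index of the cloud minimizing summed symmetric NN distance to all
    others, after centering each cloud (order-free objective)."""
    centered = [c.points - c.points.mean(axis=0) for c in clouds]
    n = len(clouds)
    cost = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                cost[i] += _symmetric_nn_cm(centered[i], centered[j])
    return int(np.argmin(cost))


def within_subject_mean(
    clouds: list[PressureCloud], unmatched_radius_cm: float = 2 * PITCH_CM
) -> PressureCloud:
    """ICP-register an infant's step clouds to their medoid reference and
    average matched coordinates and pressures.

    For each reference point the nearest neighbour in every registered
    cloud is located; coordinates and pressures are averaged over these
    correspondences.  A warning diagnostic is emitted when more than half
    of a cloud's correspondences exceed ``unmatched_radius_cm``.
    """
    if not clouds:
        raise InputError("no clouds to average")
    if len(clouds) == 1:
        return clouds[0]
    ref = clouds[_medoid_index(clouds)]
    coords = [ref.points.copy()]
    press = [ref.pressures.copy()]
    for c in clouds:
        if c is ref:
            continue
        _, aligned, _ = icp_align(c, ref)
        tree = cKDTree(aligned.points)
        dist, idx = tree.query(ref.points)
        if np.mean(dist > unmatched_radius_cm) > 0.5:
            warnings.warn(
                f"cloud {c.infant_id}/{c.stage}/{c.side}: >50% correspondences unmatched",
                RuntimeWarning,
            )
        coords.append(aligned.points[idx])
        press.append(aligned.pressures[idx])
    return PressureCloud(
        np.mean(coords, axis=0),
        np.mean(press, axis=0),
        infant_id=ref.infant_id,
        stage=ref.stage,
        side=ref.side,
    )


def select_template(mean_clouds: list[PressureCloud]) -> PressureCloud:
    """Unbiased template: the medoid mean cloud (minimum summed symmetric
    NN distance to all others after centering)."""
    if not mean_clouds:
        raise InputError("no clouds")
    if len(mean_clouds) == 1:
        return mean_clouds[0]
    return mean_clouds[_medoid_index(mean_clouds)]


# ---------------------------------------------------------------------------
# Non-rigid coherent point drift
# ---------------------------------------------------------------------------


def cpd_nonrigid(
    source: PressureCloud,
    template: PressureCloud,
    beta: float = 0.75,
    lam: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> DeformationResult:
    """Non-rigid coherent point drift of ``source`` toward ``template``.

    The source is a Gaussian mixture displaced by a motion-coherent field
    v(y) = G w with Gaussian kernel width ``beta`` (cm) and regularization
    weight ``lam``; EM alternates soft assignment with a regularized
    least-squares field update, and the objective is non-increasing per
    step.  Stops when the relative objective change falls below ``tol``.
    """
    if beta <= 0:
        raise ConfigurationError("beta must be > 0")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    Y0 = source.points
    X = template.points
    M, N, D = Y0.shape[0], X.shape[0], 2

    d2 = ((Y0[:, None, :] - Y0[None, :, :]) ** 2).sum(-1)
    G = np.exp(-d2 / (2.0 * beta**2))
    W = np.zeros((M, D))
    T = Y0.copy()
    sigma2 = ((X[None, :, :] - Y0[:, None, :]) ** 2).sum() / (D * M * N)

    prev_q = np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diff2 = ((X[None, :, :] - T[:, None, :]) ** 2).sum(-1)  # (M, N)
        P = np.exp(-diff2 / (2.0 * sigma2))
        denom = P.sum(axis=0, keepdims=True)
        denom[denom < 1e-300] = 1e-300
        P = P / denom
        P1 = P.sum(axis=1)  # (M,)
        Pt1 = P.sum(axis=0)  # (N,)
        Np = P1.sum()
        PX = P @ X

        A = G * P1[:, None] + lam * sigma2 * np.eye(M)
        rhs = PX - P1[:, None] * Y0
        W = np.linalg.solve(A, rhs)
        T = Y0 + G @ W

        xPx = (Pt1 * (X**2).sum(axis=1)).sum()
        trPT = (PX * T).sum()
        tPt = (P1 * (T**2).sum(axis=1)).sum()
        err = max(xPx - 2.0 * trPT + tPt, 0.0)
        sigma2 = max(err / (Np * D), 1e-10)

        q = err / (2.0 * sigma2) + Np * D / 2.0 * math.log(sigma2) + 0.5 * lam * (W * (G @ W)).sum()
        trace.append(q)
        if prev_q != np.inf and abs(prev_q - q) < tol * (abs(prev_q) + 1e-12):
            converged = True
            break
        prev_q = q

    return DeformationResult(
        displaced=T,
        displacement=T - Y0,
        iterations=it,
        final_objective=float(trace[-1]) if trace else np.nan,
        converged=converged,
        objective_trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# Resampling onto the template lattice
# ---------------------------------------------------------------------------


def resample_to_template_grid(
    deformed_points: np.ndarray,
    pressures: np.ndarray,
    pitch_cm: float = PITCH_CM,
    shape: tuple[int, int] = (N_ROWS_AP, N_COLS_ML),
    infant_id: str = "",
    stage: str = "",
) -> AlignedPressureImage:
    """Interpolate pressures from displaced points onto the pixel lattice.

    Linear scattered-data interpolation inside the cloud's convex hull
    (which defines the valid-data mask), with nearest-neighbour fallback
    for lattice points on the hull boundary where the linear interpolant
    is undefined.
    """
    rows, cols = shape
    gx = np.arange(cols) * pitch_cm
    gy = np.arange(rows) * pitch_cm
    GX, GY = np.meshgrid(gx, gy)
    pts = np.asarray(deformed_points, float)
    vals = np.asarray(pressures, float)
    lin = griddata(pts, vals, (GX, GY), method="linear")
    mask = ~np.isnan(lin)
    if mask.any():
        nearest = griddata(pts, vals, (GX, GY), method="nearest")
        lin = np.where(mask, lin, nearest)
    grid = np.where(mask, np.clip(lin, 0.0, None), 0.0)
    return AlignedPressureImage(grid, mask, infant_id=infant_id, stage=stage)


# ---------------------------------------------------------------------------
# Smooth synthetic warps (for registration benchmarks)
# ---------------------------------------------------------------------------


def apply_smooth_warp(
    points: np.ndarray, amplitude_frac: float, seed: int, extent_cm: float | None = None
) -> np.ndarray:
    """Apply a smooth low-order warp (random affine shear/scale plus one
    sinusoidal mode) with maximum displacement ``amplitude_frac`` of the
    cloud extent.  Used to emulate between-infant shape differences."""
    rng = np.random.default_rng(seed)
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    q = pts - c
    ext = extent_cm if extent_cm is not None else float(np.abs(q).max())
    A = rng.normal(0.0, 1.0, (2, 2))
    phase = rng.uniform(0, 2 * math.pi, 2)
    disp = q @ A.T / max(ext, 1e-9) * ext
    disp = disp + np.sin(math.pi * q / max(ext, 1e-9) + phase) * ext
    m = np.abs(disp).max()
    if m > 0:
        disp *= amplitude_frac * ext / m
    return pts + disp
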