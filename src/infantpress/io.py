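"""Pressure-frame I/O, step-inclusion filters, maximum pressure pictures and
PCA vertical rotation.

Footsteps are sequences of 36 x 25 pressure frames (kPa) exported as plain
ASCII text.  The dialect understood here mirrors the platform's ASCII
export: optional ``# key=value`` header lines carrying identity metadata,
followed by the frames as 36 whitespace-delimited rows of 25 decimal
values, frames separated by a blank line.

The visual step-selection criteria used when curating real recordings
(within platform borders, full step cycle, no omission of anatomical
parts) are replaced by the programmatic proxies in :func:`validate_step`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import GRID_SHAPE, N_COLS_ML, N_ROWS_AP, PITCH_CM


class ParseError(ValueError):
    """Malformed ASCII step file (carries the offending line number)."""


class InputError(ValueError):
    """Structurally invalid input to an operation."""


@dataclasses.dataclass(frozen=True)
class PressureFrame:
    """One 36 x 25 pressure frame (kPa) at a given frame ordinal."""

    grid: np.ndarray
    pitch_cm: float = PITCH_CM
    timestamp_index: int = 0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.shape != GRID_SHAPE:
            raise InputError(f"frame must be {GRID_SHAPE}, got {g.shape}")
        if np.any(g < 0):
            raise InputError("negative pressure in frame")
        object.__setattr__(self, "grid", g)


@dataclasses.dataclass
class StepRecord:
    """Ordered pressure frames for one footstep plus identity metadata.

    ``frames`` is a (T, 36, 25) float array, T >= 2.
    """

    frames: np.ndarray
    infant_id: str = ""
    stage: str = ""
    side: str = "right"
    pitch_cm: float = PITCH_CM
    rate_hz: float = 100.0
    mirrored: bool = False

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[1:] != GRID_SHAPE:
            raise InputError(f"frames must be (T, {N_ROWS_AP}, {N_COLS_ML}), got {f.shape}")
        if f.shape[0] < 1:
            raise InputError("a step needs at least 1 frame")
        if np.any(f < 0):
            raise InputError("negative pressure in step frames")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> PressureFrame:
        return PressureFrame(self.frames[i], self.pitch_cm, i)

    def replace(self, **kw) -> "StepRecord":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class MaxPressurePicture:
    """Pixelwise maximum pressure (kPa) over the frames of one step."""

    grid: np.ndarray
    infant_id: str = ""
    stage: str = ""
    side: str = "right"
    pitch_cm: float = PITCH_CM

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.shape != GRID_SHAPE:
            raise InputError(f"MPP must be {GRID_SHAPE}, got {g.shape}")
        object.__setattr__(self, "grid", g)


@dataclasses.dataclass(frozen=True)
class ValidityReport:
    """Programmatic proxies for the visual step-inclusion filters."""

    within_borders: bool
    full_cycle: bool
    no_omission: bool

    @property
    def is_valid(self) -> bool:
        return self.within_borders and self.full_cycle and self.no_omission


# ---------------------------------------------------------------------------
# ASCII dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("infant_id", "stage", "side", "pitch_cm", "rate_hz")


def write_step_ascii(step: StepRecord, path: str | Path) -> None:
    """Write a step in the ASCII frame dialect (2 decimal places)."""
    lines = []
    lines.append(f"# infant_id={step.infant_id}")
    lines.append(f"# stage={step.stage}")
    lines.append(f"# side={step.side}")
    lines.append(f"# pitch_cm={step.pitch_cm:g}")
    lines.append(f"# rate_hz={step.rate_hz:g}")
    for t in range(step.n_frames):
        if t:
            lines.append("")
        for row in step.frames[t]:
            lines.append(" ".join(f"{v:.2f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_step_ascii(path: str | Path) -> StepRecord:
    """Read a step from the ASCII frame dialect.

    Raises :class:`ParseError` (naming the line number) on ragged rows,
    non-numeric tokens, negative pressures, or frames that are not 36 x 25.
    """
    meta: dict[str, str] = {}
    frames: list[np.ndarray] = []
    rows: list[list[float]] = []
    row_line0 = 0

    def flush(lineno):
        nonlocal rows
        if not rows:
            return
        if len(rows) != N_ROWS_AP:
            raise ParseError(
                f"line {lineno}: frame has {len(rows)} rows, expected {N_ROWS_AP}"
            )
        frames.append(np.array(rows, dtype=float))
        rows = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if not line:
                flush(lineno)
                continue
            toks = line.split()
            if len(toks) != N_COLS_ML:
                raise ParseError(
                    f"line {lineno}: row has {len(toks)} columns, expected {N_COLS_ML}"
                )
            try:
                vals = [float(t) for t in toks]
            except ValueError as e:
                raise ParseError(f"line {lineno}: non-numeric token ({e})") from None
            if any(v < 0 for v in vals):
                raise ParseError(f"line {lineno}: negative pressure value")
            if not rows:
                row_line0 = lineno
            rows.append(vals)
    flush(row_line0 + N_ROWS_AP)
    if not frames:
        raise ParseError("file contains no frames")
    return StepRecord(
        np.stack(frames),
        infant_id=meta.get("infant_id", ""),
        stage=meta.get("stage", ""),
        side=meta.get("side", "right"),
        pitch_cm=float(meta.get("pitch_cm", PITCH_CM)),
        rate_hz=float(meta.get("rate_hz", 100.0)),
    )


def write_grid_ascii(grid: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Write a single 2D pressure grid in the same ASCII dialect."""
    lines = [f"# {k}={v}" for k, v in (meta or {}).items()]
    for row in np.asarray(grid, float):
        lines.append(" ".join(f"{v:.2f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_mpp(step: StepRecord) -> MaxPressurePicture:
    """Maximum pressure picture: pixelwise max over the step's frames."""
    if step.n_frames == 0:  # unreachable through StepRecord, kept for safety
        raise InputError("empty frame list")
    return MaxPressurePicture(
        step.frames.max(axis=0),
        infant_id=step.infant_id,
        stage=step.stage,
        side=step.side,
        pitch_cm=step.pitch_cm,
    )


def validate_step(
    step: StepRecord,
    area_ratio_min: float = 0.5,
    foot_length_cm: float | None = None,
    foot_width_cm: float | None = None,
    load_threshold: float = 1.0,
) -> ValidityReport:
    """Programmatic step-inclusion filters (report only; never mutates).

    within_borders
        no nonzero pixel on any edge row/column of the MPP.
    full_cycle
        first and last frames carry zero total load while some interior
        frame is loaded above ``load_threshold``.
    no_omission
        MPP contact area >= ``area_ratio_min`` x (foot length x width);
        skipped (True) when foot dimensions are unknown.
    """
    mpp = compute_mpp(step).grid
    edges = np.concatenate([mpp[0, :], mpp[-1, :], mpp[:, 0], mpp[:, -1]])
    within_borders = not np.any(edges > 0)

    totals = step.frames.sum(axis=(1, 2))
    full_cycle = (
        totals[0] == 0.0 and totals[-1] == 0.0 and bool(np.any(totals[1:-1] > load_threshold))
    )

    if foot_length_cm is None or foot_width_cm is None:
        no_omission = True
    else:
        contact_area = np.count_nonzero(mpp > load_threshold) * step.pitch_cm**2
        no_omission = contact_area >= area_ratio_min * foot_length_cm * foot_width_cm
    return ValidityReport(within_borders, full_cycle, no_omission)


def _weighted_pca_angle(mpp: np.ndarray, pitch: float) -> tuple[float, np.ndarray]:
    """Angle (rad) of the pressure-weighted principal axis from the AP (+y)
    axis, in (-pi/2, pi/2], and the weighted centroid (x_ml, y_ap) in cm."""
    rows, cols = np.nonzero(mpp > 0)
    if rows.size == 0:
        raise InputError("MPP entirely zero")
    w = mpp[rows, cols]
    x = cols * pitch
    y = rows * pitch
    cx = np.average(x, weights=w)
    cy = np.average(y, weights=w)
    dx, dy = x - cx, y - cy
    cov = np.array(
        [
            [np.average(dx * dx, weights=w), np.average(dx * dy, weights=w)],
            [np.average(dx * dy, weights=w), np.average(dy * dy, weights=w)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]  # (ux, uy), dominant direction
    if u[1] < 0:
        u = -u
    angle = math.atan2(u[0], u[1])  # signed angle from +y toward +x
    return angle, np.array([cx, cy])


def _affine_resample(
    frames: np.ndarray, angle: float, center_in: np.ndarray, center_out: np.ndarray, pitch: float
) -> np.ndarray:
    """Rotate image content by ``angle`` (counterclockwise in the (x, y)
    plane) mapping ``center_in`` to ``center_out``, bilinear, negatives
    clipped to zero."""
    rr, cc = np.meshgrid(np.arange(N_ROWS_AP), np.arange(N_COLS_ML), indexing="ij")
    xo = cc * pitch - center_out[0]
    yo = rr * pitch - center_out[1]
    ca, sa = math.cos(angle), math.sin(angle)
    # inverse rotation: output point -> input point
    xi = ca * xo + sa * yo + center_in[0]
    yi = -sa * xo + ca * yo + center_in[1]
    coords = np.stack([yi / pitch, xi / pitch])
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        out[t] = ndimage.map_coordinates(frames[t], coords, order=1, mode="constant", cval=0.0)
    np.clip(out, 0.0, None, out=out)
    # a rigid motion of a pressure field conserves total load exactly;
    # renormalize away the bilinear-resampling mass error per frame
    before = frames.sum(axis=(1, 2))
    after = out.sum(axis=(1, 2))
    scale = np.where(after > 0, before / np.where(after > 0, after, 1.0), 0.0)
    out *= scale[:, None, None]
    return out


def pca_vertical_rotate(
    step: StepRecord, load_threshold: float = 1.0, recenter: bool = True
) -> tuple[StepRecord, float]:
    """Rotate a step so the pressure-weighted principal axis of its MPP is
    vertical (AP), heel at the low-index AP end.

    The heel end is disambiguated as the AP half containing the pressure
    centroid of the earliest loaded 20% of frames.  The content is also
    recentred on the grid centre (single bilinear resample) so the rotation
    cannot push pressure outside the 36 x 25 grid; the induced translation
    is absorbed downstream by the common reference system.

    Returns the rotated step and the applied rotation angle in radians.
    """
    mpp = compute_mpp(step).grid
    axis_angle, _ = _weighted_pca_angle(mpp, step.pitch_cm)
    # _weighted_pca_angle measures from +y toward +x (clockwise); rotating
    # the content counterclockwise by that same signed value verticalizes it
    angle = axis_angle

    # recentring uses the occupancy (support) centroid: unlike the pressure
    # centroid it does not depend on how load is distributed within the
    # footprint, so the posterior-contact reference K stays comparable
    # across steps with different rollover patterns
    rows, cols = np.nonzero(mpp > 0)
    support_centroid = np.array(
        [cols.mean() * step.pitch_cm, rows.mean() * step.pitch_cm]
    )

    # heel disambiguation: the rollover progresses heel -> toe, so the
    # centroid of the earliest loaded frames must end up below (lower AP
    # index than) the centroid of the latest loaded frames
    totals = step.frames.sum(axis=(1, 2))
    loaded = np.nonzero(totals > load_threshold)[0]
    if loaded.size:
        k = max(1, int(math.ceil(0.2 * loaded.size)))

        def _centroid(img):
            rr, cc = np.nonzero(img > 0)
            w = img[rr, cc]
            return (
                np.average(cc * step.pitch_cm, weights=w),
                np.average(rr * step.pitch_cm, weights=w),
            )

        ex, ey = _centroid(step.frames[loaded[:k]].sum(axis=0))
        lx, ly = _centroid(step.frames[loaded[-k:]].sum(axis=0))
        y_early = math.sin(angle) * ex + math.cos(angle) * ey
        y_late = math.sin(angle) * lx + math.cos(angle) * ly
        if y_early > y_late:
            angle += math.pi
    angle = math.atan2(math.sin(angle), math.cos(angle))

    center_out = (
        np.array([(N_COLS_ML - 1) / 2 * step.pitch_cm, (N_ROWS_AP - 1) / 2 * step.pitch_cm])
        if recenter
        else support_centroid
    )
    rotated = _affine_resample(step.frames, angle, support_centroid, center_out, step.pitch_cm)
    return step.replace(frames=rotated), angle


def mirror_to_common_side(step: StepRecord) -> StepRecord:
    """Reflect left steps about the vertical axis onto the right-foot
    convention (column index increasing medially).  Right steps pass
    through unchanged; applying the operation twice to a left step is the
    identity."""
    if step.side != "left":
        return step
    return step.replace(frames=step.frames[:, :, ::-1].copy(), mirrored=not step.mirrored)
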