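"""Platform grid conventions shared across the package.

The pressure platform exports frames on a fixed 36 x 25 sensor grid at
0.5 cm pitch (4 sensors per cm^2).  Rows index the anterior-posterior
(AP) axis, with the row index increasing toward the toes after vertical
rotation; columns index the medio-lateral (ML) axis, with the column
index increasing medially once left steps have been mirrored onto the
right-foot convention.  Physical coordinates are 0-based pixel centres:
``coordinate_cm = index * pitch_cm``.
"""

from __future__ import annotations

import numpy as np

N_ROWS_AP = 36
N_COLS_ML = 25
PITCH_CM = 0.5

GRID_SHAPE = (N_ROWS_AP, N_COLS_ML)


def ap_coords(pitch_cm: float = PITCH_CM) -> np.ndarray:
    """AP (row) pixel-centre coordinates in cm, shape (36,)."""
    return np.arange(N_ROWS_AP) * pitch_cm


def ml_coords(pitch_cm: float = PITCH_CM) -> np.ndarray:
    """ML (column) pixel-centre coordinates in cm, shape (25,)."""
    return np.arange(N_COLS_ML) * pitch_cm


def pixel_centers(pitch_cm: float = PITCH_CM) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of (AP, ML) pixel-centre coordinates, each shape (36, 25)."""
    return np.meshgrid(ap_coords(pitch_cm), ml_coords(pitch_cm), indexing="ij")
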