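"""Pearson correlation screening of candidate regression predictors.

Growth indicators (age, height, weight, foot dimensions, experience) are
mutually correlated; predictors are screened pairwise and, for every pair
with |r| >= 0.5 at p < 0.001, the lower-priority member is dropped.  The
default priority keeps walking experience, weight and the foot-width
variables and drops age and height first (age is a chronological rather
than developmental variable; height is redundant with weight).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from ..io import InputError

DEFAULT_PRIORITY = [
    "experience_days",
    "mass_kg",
    "foot_width_cm",
    "normalised_foot_width",
    "foot_length_cm",
    "height_cm",
    "age_months",
]


@dataclasses.dataclass
class CorrelationScreen:
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    flagged_pairs: list  # (col_a, col_b, r, p)
    retained: list

    def summary(self) -> str:
        lines = ["Predictor correlation screen (|r| >= threshold, p < threshold)"]
        for a, b, r, p in self.flagged_pairs:
            lines.append(f"  flagged: {a} ~ {b}: r = {r:.2f}, p = {p:.2g}")
        lines.append(f"  retained: {', '.join(self.retained)}")
        return "\n".join(lines)


def correlation_screen(
    table: pd.DataFrame,
    r_thresh: float = 0.5,
    p_thresh: float = 0.001,
    priority: list[str] | None = None,
) -> CorrelationScreen:
    """Full Pearson r/p matrices plus a greedy retained-predictor set.

    Constant columns have undefined correlations (NaN) and are excluded
    from flagging.  ``priority`` lists columns from most to least
    important to keep; unlisted columns rank below listed ones.
    """
    if len(table) < 3:
        raise InputError("need at least 3 rows")
    cols = list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        x = table[cols[i]].to_numpy(float)
        y = table[cols[j]].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = stats.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue

    prio = priority if priority is not None else DEFAULT_PRIORITY
    rank = {c: (prio.index(c) if c in prio else len(prio) + n) for n, c in enumerate(cols)}

    flagged = []
    for i, j in itertools.combinations(range(k), 2):
        if np.isfinite(r[i, j]) and abs(r[i, j]) >= r_thresh and p[i, j] < p_thresh:
            flagged.append((cols[i], cols[j], float(r[i, j]), float(p[i, j])))

    retained = set(cols)
    for a, b, _, _ in sorted(flagged, key=lambda f: -abs(f[2])):
        if a in retained and b in retained:
            retained.discard(a if rank[a] > rank[b] else b)
    retained_list = [c for c in cols if c in retained]
    return CorrelationScreen(
        r_matrix=pd.DataFrame(r, index=cols, columns=cols),
        p_matrix=pd.DataFrame(p, index=cols, columns=cols),
        flagged_pairs=flagged,
        retained=retained_list,
    )


def normalised_foot_width(width_cm: float, length_cm: float) -> float:
    """Foot width as percent of foot length (width/length x 100)."""
    if np.any(np.asarray(length_cm) <= 0):
        raise InputError("foot length must be positive")
    return width_cm / length_cm * 100.0
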