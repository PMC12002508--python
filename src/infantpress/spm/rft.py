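"""Random-field-theory utilities for 1D statistic fields.

Smoothness of the residual field is summarized by the FWHM (in nodes) of
an equivalent Gaussian kernel, estimated from the gradients of the
unit-variance-normalized residuals.  Family-wise critical thresholds come
from the expected-Euler-characteristic approximation for smooth t and
chi-square fields over ``resels = (n_nodes - 1) / fwhm`` resolution
elements, clamped between the single-comparison and Bonferroni quantiles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

_4LOG2 = 4.0 * math.log(2.0)


class ConfigurationError(ValueError):
    pass


def estimate_fwhm(residuals: np.ndarray) -> float:
    """FWHM (nodes) of the residual smoothness.

    ``residuals``: (n_curves, n_nodes).  The field is normalized to unit
    variance per node; the mean squared gradient of the normalized field
    gives resels per node and hence the FWHM.
    """
    R = np.asarray(residuals, float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("residuals must be (n_curves >= 2, n_nodes)")
    ssq = (R**2).sum(axis=0)
    dR = np.diff(R, axis=1)
    denom = np.sqrt(ssq[:-1] * ssq[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (dR**2).sum(axis=0) / denom
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        return float(R.shape[1]) * 10.0  # flat residuals: effectively one resel
    resels_per_node = np.sqrt(v / _4LOG2)
    return float(1.0 / resels_per_node.mean())


def _ec_density_t(t: float, df: float) -> float:
    """1D EC density of a t field (per resel, unit-FWHM scaling)."""
    return math.sqrt(_4LOG2) / (2.0 * math.pi) * (1.0 + t * t / df) ** (-(df - 1.0) / 2.0)


def _ec_density_chi2(u: float, k: int) -> float:
    """1D EC density of a chi-square field with k df."""
    if u <= 0:
        return math.inf
    return (
        math.sqrt(_4LOG2)
        / (2.0 * math.pi)
        * u ** ((k - 1) / 2.0)
        * math.exp(-u / 2.0)
        / (2.0 ** ((k - 2) / 2.0) * math.gamma(k / 2.0))
    )


def rft_threshold_1d(
    df: float,
    fwhm: float,
    n_nodes: int = 101,
    alpha: float = 0.05,
    two_tailed: bool = True,
) -> float:
    """Smallest t whose expected-EC tail probability over the field is
    <= alpha (two-tailed by halving alpha).

    Bracketed by construction: never below the single-comparison quantile,
    never above the Bonferroni quantile over ``n_nodes`` nodes.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    if df < 1 or fwhm <= 0 or n_nodes < 2:
        raise ConfigurationError("need df >= 1, fwhm > 0, n_nodes >= 2")
    a = alpha / 2.0 if two_tailed else alpha
    resels = (n_nodes - 1.0) / fwhm
    lo = float(stats.t.isf(a, df))
    hi = float(stats.t.isf(a / n_nodes, df))

    def excess(t):
        return stats.t.sf(t, df) + resels * _ec_density_t(t, df) - a

    if excess(lo) <= 0:
        return lo
    if excess(hi) >= 0:
        return hi
    return float(optimize.brentq(excess, lo, hi, xtol=1e-10))


def rft_threshold_chi2(
    k: int, fwhm: float, n_nodes: int = 101, alpha: float = 0.05
) -> float:
    """RFT-corrected chi-square critical value (one-tailed)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    resels = (n_nodes - 1.0) / fwhm
    lo = float(stats.chi2.isf(alpha, k))
    hi = float(stats.chi2.isf(alpha / n_nodes, k))

    def excess(u):
        return stats.chi2.sf(u, k) + resels * _ec_density_chi2(u, k) - alpha

    if excess(lo) <= 0:
        return lo
    if excess(hi) >= 0:
        return hi
    return float(optimize.brentq(excess, lo, hi, xtol=1e-10))


def cluster_intervals(stat: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of nodes with |stat| > threshold, as inclusive
    (start, end) node intervals."""
    supra = np.abs(np.asarray(stat, float)) > threshold
    out = []
    i = 0
    n = supra.size
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def cluster_tail_p(t_peak: float, df: float, resels: float) -> float:
    """Expected-EC tail probability at a cluster's peak |t| (two-tailed),
    reported as an interval-level descriptor (no extent calibration)."""
    p = 2.0 * (stats.t.sf(t_peak, df) + resels * _ec_density_t(t_peak, df))
    return float(min(1.0, p))
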