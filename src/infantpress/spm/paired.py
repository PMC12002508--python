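"""Paired field tests: parametric 1D (RFT) and nonparametric 2D
(sign-flip permutation), in a model/results idiom.

``PairedSPM1D`` compares matched sets of 101-node curves node-by-node
with a paired t statistic; the family-wise critical threshold comes from
random field theory using the estimated residual smoothness.
``PairedPermutationSPM2D`` compares matched sets of template-aligned
pressure images pixel-by-pixel; the critical threshold is the
(1 - alpha) quantile of the max-|t| distribution over random sign flips
of the per-pair difference images (exhaustively enumerated when
feasible).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from ..io import InputError
from . import rft


class ConfigurationError(ValueError):
    pass


def paired_t_statistic(diff: np.ndarray) -> np.ndarray:
    """Classical one-sample t of the differences, per node/pixel.

    diff: (n, k).  Zero-variance entries with zero mean give t = 0.
    """
    d = np.asarray(diff, float)
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.sign(mean) * np.inf, t)
    return np.where((sd == 0) & (mean == 0), 0.0, t)


@dataclasses.dataclass
class SPM1DResults:
    """Node-wise t field with its RFT critical threshold."""

    t: np.ndarray
    df: float
    fwhm: float
    t_critical: float
    clusters: list  # (start_node, end_node, peak_tail_p)
    alpha: float
    n_pairs: int

    @property
    def h0_rejected(self) -> bool:
        return len(self.clusters) > 0

    @property
    def suprathreshold(self) -> np.ndarray:
        return np.abs(self.t) > self.t_critical

    def summary(self) -> str:
        lines = [
            "Paired SPM t-test (1D, random field theory)",
            f"  pairs:          {self.n_pairs}",
            f"  df:             {self.df:g}",
            f"  residual FWHM:  {self.fwhm:.2f} nodes",
            f"  alpha:          {self.alpha:g} (two-tailed)",
            f"  t* (critical):  {self.t_critical:.3f}",
            f"  max |t|:        {np.abs(self.t).max():.3f}",
        ]
        if self.clusters:
            for (i0, i1, p) in self.clusters:
                lines.append(f"  cluster: nodes {i0}-{i1} ({i0}%-{i1}% stance), p ~ {p:.4f}")
        else:
            lines.append("  no suprathreshold clusters")
        return "\n".join(lines)


class PairedSPM1D:
    """Parametric paired t-test over matched sets of 1D curves."""

    def __init__(self, curves_a: np.ndarray, curves_b: np.ndarray, alpha: float = 0.05):
        a = np.asarray(curves_a, float)
        b = np.asarray(curves_b, float)
        if a.shape != b.shape or a.ndim != 2:
            raise InputError("curve sets must be matched 2D arrays of equal shape")
        if a.shape[0] < 3:
            raise InputError("need at least 3 pairs")
        self.diff = a - b
        self.alpha = alpha

    def fit(self) -> SPM1DResults:
        d = self.diff
        n, q = d.shape
        t = paired_t_statistic(d)
        residuals = d - d.mean(axis=0)
        fwhm = rft.estimate_fwhm(residuals)
        tcrit = rft.rft_threshold_1d(df=n - 1, fwhm=fwhm, n_nodes=q, alpha=self.alpha)
        resels = (q - 1.0) / fwhm
        clusters = [
            (i0, i1, rft.cluster_tail_p(float(np.abs(t[i0 : i1 + 1]).max()), n - 1, resels))
            for (i0, i1) in rft.cluster_intervals(t, tcrit)
        ]
        return SPM1DResults(
            t=t, df=n - 1, fwhm=fwhm, t_critical=tcrit, clusters=clusters,
            alpha=self.alpha, n_pairs=n,
        )


def paired_t_1d(curves_a, curves_b, alpha: float = 0.05) -> SPM1DResults:
    """Functional wrapper around :class:`PairedSPM1D`."""
    return PairedSPM1D(curves_a, curves_b, alpha=alpha).fit()


# ---------------------------------------------------------------------------
# 1D normality
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Normality1DResults:
    k2: np.ndarray
    k2_critical: float
    fwhm: float
    alpha: float

    @property
    def h0_rejected(self) -> bool:
        return bool(np.any(self.k2 > self.k2_critical))

    @property
    def suprathreshold(self) -> np.ndarray:
        return self.k2 > self.k2_critical


def normality_test_1d(curves: np.ndarray, alpha: float = 0.05) -> Normality1DResults:
    """Node-wise D'Agostino-Pearson K2 test on the residuals of a set of
    curves, thresholded with an RFT-corrected chi-square critical value.

    Requires >= 8 curves (the omnibus statistic needs that many
    observations); constant (zero-variance) curves are rejected as input.
    """
    from scipy import stats

    c = np.asarray(curves, float)
    if c.ndim != 2 or c.shape[0] < 8:
        raise InputError("need >= 8 curves")
    residuals = c - c.mean(axis=0)
    if np.any(residuals.std(axis=0) == 0):
        raise InputError("zero-variance node: normality undefined")
    k2 = stats.normaltest(residuals, axis=0).statistic
    fwhm = rft.estimate_fwhm(residuals)
    crit = rft.rft_threshold_chi2(k=2, fwhm=fwhm, n_nodes=c.shape[1], alpha=alpha)
    return Normality1DResults(k2=k2, k2_critical=crit, fwhm=fwhm, alpha=alpha)


# ---------------------------------------------------------------------------
# 2D permutation paired test
# ---------------------------------------------------------------------------


def build_common_mask(image_masks: np.ndarray, min_coverage: float = 0.9) -> np.ndarray:
    """Pixels with valid data in at least ``min_coverage`` of the images."""
    m = np.asarray(image_masks, bool)
    return m.mean(axis=0) >= min_coverage


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Sign-flip patterns: exhaustive when 2**n <= n_perm, else sampled."""
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return signs, True
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    signs[0] = 1.0  # include the observed labelling
    return signs, False


@dataclasses.dataclass
class SPM2DResults:
    """Pixel-wise t image with its permutation max-|t| threshold."""

    t_image: np.ndarray
    t_critical: float
    suprathreshold: np.ndarray
    mask: np.ndarray
    n_permutations: int
    exhaustive: bool
    p_fwe: float
    alpha: float
    seed: int | None

    @property
    def n_significant(self) -> int:
        return int(self.suprathreshold.sum())

    def summary(self) -> str:
        return "\n".join(
            [
                "Paired permutation SPM t-test (2D, max-|t|)",
                f"  permutations:   {self.n_permutations}"
                + (" (exhaustive)" if self.exhaustive else ""),
                f"  alpha:          {self.alpha:g} (two-tailed)",
                f"  t* (critical):  {self.t_critical:.3f}",
                f"  max |t|:        {np.abs(self.t_image[self.mask]).max():.3f}"
                if self.mask.any()
                else "  empty mask",
                f"  significant px: {self.n_significant}",
                f"  FWE p (global): {self.p_fwe:.4f}",
            ]
        )


class PairedPermutationSPM2D:
    """Nonparametric paired t-test over matched 2D pressure images.

    The null is built by random sign flips of the per-pair difference
    images; the critical threshold is the (1 - alpha) quantile of the
    max-|t| distribution over the common mask.
    """

    def __init__(
        self,
        images_a: np.ndarray,
        images_b: np.ndarray,
        alpha: float = 0.05,
        n_perm: int = 10000,
        seed: int | None = 0,
        masks_a: np.ndarray | None = None,
        masks_b: np.ndarray | None = None,
        min_coverage: float = 0.9,
    ):
        A = np.asarray(images_a, float)
        B = np.asarray(images_b, float)
        if A.shape != B.shape or A.ndim != 3:
            raise InputError("image sets must be matched (n, rows, cols) arrays")
        if A.shape[0] < 5:
            raise InputError("need at least 5 pairs")
        if n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if masks_a is None:
            masks_a = A > 0
        if masks_b is None:
            masks_b = B > 0
        mask = build_common_mask(np.concatenate([masks_a, masks_b]), min_coverage)
        if not mask.any():
            raise InputError("disjoint masks: no common pixels")
        self.mask = mask
        self.diff = np.where(mask, A, 0.0) - np.where(mask, B, 0.0)
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    def fit(self) -> SPM2DResults:
        n = self.diff.shape[0]
        D = self.diff[:, self.mask]  # (n, npix)
        rng = np.random.default_rng(self.seed)
        signs, exhaustive = _sign_matrix(n, self.n_perm, rng)
        t_obs = paired_t_statistic(D)
        max_t = np.empty(signs.shape[0])
        for i, s in enumerate(signs):
            max_t[i] = np.abs(paired_t_statistic(s[:, None] * D)).max()
        tcrit = float(np.quantile(max_t, 1.0 - self.alpha))
        p_fwe = float(np.mean(max_t >= np.abs(t_obs).max()))
        t_image = np.zeros(self.mask.shape)
        t_image[self.mask] = t_obs
        supra = np.zeros(self.mask.shape, bool)
        supra[self.mask] = np.abs(t_obs) > tcrit
        return SPM2DResults(
            t_image=t_image,
            t_critical=tcrit,
            suprathreshold=supra,
            mask=self.mask,
            n_permutations=signs.shape[0],
            exhaustive=exhaustive,
            p_fwe=p_fwe,
            alpha=self.alpha,
            seed=self.seed,
        )


def perm_paired_t_2d(images_a, images_b, alpha=0.05, n_perm=10000, seed=0, **kw) -> SPM2DResults:
    """Functional wrapper around :class:`PairedPermutationSPM2D`."""
    return PairedPermutationSPM2D(
        images_a, images_b, alpha=alpha, n_perm=n_perm, seed=seed, **kw
    ).fit()
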