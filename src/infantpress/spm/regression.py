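"""Pixel-level nonparametric linear regression of pressure on
developmental predictors, with Freedman-Lane permutation inference.

Per pixel, an ordinary least-squares fit of pressure on all predictors
plus intercept; per predictor, a t statistic.  Family-wise significance
is assessed by permuting the residuals of the reduced model (the design
without the predictor under test) and taking the max-|t| over the mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ..io import InputError


class ConfigurationError(ValueError):
    pass


def _ols_t(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistics of every coefficient for every column of Y.

    X: (n, p) including intercept, full rank.  Y: (n, k).
    Returns (p, k).
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (p, k)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof  # (k,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # (p, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return np.where(se == 0, 0.0, t)


@dataclasses.dataclass
class RegressionMapsResults:
    """Per-predictor t images and permutation thresholds."""

    predictors: list
    t_images: dict  # name -> 2D array
    t_critical: dict  # name -> float
    suprathreshold: dict  # name -> bool 2D array
    mask: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None

    def n_significant(self, name: str) -> int:
        return int(self.suprathreshold[name].sum())

    def summary(self) -> str:
        lines = [
            "Pixel-level permutation regression (Freedman-Lane, max-|t|)",
            f"  permutations: {self.n_permutations}, alpha: {self.alpha:g}",
        ]
        for name in self.predictors:
            tmax = np.abs(self.t_images[name][self.mask]).max() if self.mask.any() else 0.0
            lines.append(
                f"  {name}: t* = {self.t_critical[name]:.3f}, max |t| = {tmax:.3f}, "
                f"significant px = {self.n_significant(name)}"
            )
        return "\n".join(lines)


class PixelRegression:
    """OLS of pixel pressures on a predictor table, permutation-corrected."""

    def __init__(
        self,
        images: np.ndarray,
        design: pd.DataFrame,
        alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int | None = 0,
        mask: np.ndarray | None = None,
        min_coverage: float = 0.9,
    ):
        imgs = np.asarray(images, float)
        if imgs.ndim != 3:
            raise InputError("images must be (n, rows, cols)")
        if len(design) != imgs.shape[0]:
            raise InputError("design rows must match images")
        if mask is None:
            mask = (imgs > 0).mean(axis=0) >= min_coverage
        if not mask.any():
            raise InputError("empty mask")
        self.names = list(design.columns)
        X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # name the offending columns for the error message
            bad = []
            for j, name in enumerate(self.names, start=1):
                Xr = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(Xr) == np.linalg.matrix_rank(X):
                    bad.append(name)
            raise ConfigurationError(f"rank-deficient design; collinear columns: {bad or self.names}")
        self.X = X
        self.Y = imgs[:, mask]
        self.mask = mask
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    def fit(self) -> RegressionMapsResults:
        X, Y = self.X, self.Y
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        t_full = _ols_t(X, Y)  # (p, k); row 0 is the intercept

        t_images, t_crit, supra = {}, {}, {}
        shape = self.mask.shape
        for j, name in enumerate(self.names, start=1):
            Xr = np.delete(X, j, axis=1)  # reduced model
            Hr = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T
            fitted = Hr @ Y
            resid = Y - fitted
            max_t = np.empty(self.n_perm)
            for i in range(self.n_perm):
                perm = np.arange(n) if i == 0 else rng.permutation(n)
                Ystar = fitted + resid[perm]
                max_t[i] = np.abs(_ols_t(X, Ystar)[j]).max()
            crit = float(np.quantile(max_t, 1.0 - self.alpha))
            timg = np.zeros(shape)
            timg[self.mask] = t_full[j]
            t_images[name] = timg
            t_crit[name] = crit
            sup = np.zeros(shape, bool)
            sup[self.mask] = np.abs(t_full[j]) > crit
            supra[name] = sup
        return RegressionMapsResults(
            predictors=self.names,
            t_images=t_images,
            t_critical=t_crit,
            suprathreshold=supra,
            mask=self.mask,
            n_permutations=self.n_perm,
            alpha=self.alpha,
            seed=self.seed,
        )


def perm_regression_2d(images, design, alpha=0.05, n_perm=1000, seed=0, **kw) -> RegressionMapsResults:
    """Functional wrapper around :class:`PixelRegression`."""
    return PixelRegression(images, design, alpha=alpha, n_perm=n_perm, seed=seed, **kw).fit()
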