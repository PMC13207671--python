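"""Log2 transform, median centering, global-distribution parameter
estimation, and left-censored imputation from a downshifted normal
(mu_imp = mu_obs - shift * sigma_obs, sigma_imp = width * sigma_obs)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import IntensityMatrix

__all__ = [
    "ImputationParams",
    "log2_and_center",
    "estimate_global_params",
    "impute_left_censored",
]


@dataclass(frozen=True)
class ImputationParams:
    """Pooled observed-distribution parameters and the downshift rule."""

    mu_obs: float
    sigma_obs: float
    shift: float = 1.8
    width: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_obs):
            raise ValueError("mu_obs must be finite")
        if not (self.sigma_obs > 0):
            raise ValueError("sigma_obs must be > 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if not (self.width > 0):
            raise ValueError("width must be > 0")

    @property
    def mu_imp(self) -> float:
        return self.mu_obs - self.shift * self.sigma_obs

    @property
    def sigma_imp(self) -> float:
        return self.width * self.sigma_obs


def log2_and_center(m: IntensityMatrix) -> pd.DataFrame:
    """log2-transform, then shift each sample so its median equals the
    global median of per-sample medians. Missingness is unchanged."""
    vals = m.data.to_numpy(dtype=float)
    bad = np.argwhere(vals <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at protein {m.data.index[i]!r}, "
            f"sample {m.data.columns[j]!r}"
        )
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        sid = m.data.columns[np.argmax(all_missing)]
        raise ValueError(f"sample {sid!r} has no observed values")
    log2 = np.log2(vals)
    medians = np.nanmedian(log2, axis=0)
    target = np.median(medians)
    log2 = log2 + (target - medians)[None, :]
    return pd.DataFrame(log2, index=m.data.index, columns=m.data.columns)


def estimate_global_params(
    log2_matrix: pd.DataFrame, shift: float = 1.8, width: float = 0.3
) -> ImputationParams:
    """Pooled mean/SD of all observed log2 values (SD with n-1 denominator)."""
    pool = log2_matrix.to_numpy(dtype=float)
    pool = pool[np.isfinite(pool)]
    if pool.size < 2:
        raise ValueError("need at least 2 observed values to estimate params")
    mu = float(pool.mean())
    sigma = float(pool.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("observed values are constant; sigma_obs = 0")
    return ImputationParams(mu, sigma, shift, width)


def impute_left_censored(
    log2_matrix: pd.DataFrame, params: ImputationParams, seed: int
) -> pd.DataFrame:
    """Replace every missing entry with an independent draw from
    Normal(mu_imp, sigma_imp^2).

    Draws are generated in protein-major (row-major) traversal order from
    one seeded generator, so results do not depend on storage layout.
    Observed entries are bit-identical before and after.
    """
    vals = log2_matrix.to_numpy(dtype=float).copy()
    mask = ~np.isfinite(vals)
    n_missing = int(mask.sum())
    if n_missing:
        rng = np.random.default_rng(seed)
        draws = rng.normal(params.mu_imp, params.sigma_imp, size=n_missing)
        vals[mask] = draws  # boolean fancy-indexing assigns in C (row-major) order
    return pd.DataFrame(vals, index=log2_matrix.index, columns=log2_matrix.columns)
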