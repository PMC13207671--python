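"""Parametric empirical-Bayes batch correction (location-scale model)
with the biological condition preserved via a covariate in the
standardization design."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import SampleMetadata

__all__ = ["BatchModelParams", "combat_adjust", "ConvergenceError"]

_VAR_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BatchModelParams:
    batches: list[str]
    n_per_batch: dict[str, int]
    alpha: np.ndarray  # per-protein grand mean
    beta: np.ndarray  # covariate coefficients (proteins x n_cov)
    gamma_hat: dict[str, np.ndarray]
    gamma_star: dict[str, np.ndarray]
    delta_hat_sq: dict[str, np.ndarray]
    delta_star_sq: dict[str, np.ndarray]
    gamma_bar: dict[str, float]
    tau_sq: dict[str, float]
    a_prior: dict[str, float]
    b_prior: dict[str, float]
    n_iter: dict[str, int]
    shrunk: dict[str, bool] = field(default_factory=dict)


def _eb_iterate(
    Zb: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau_sq: float,
    a: float,
    b: float,
    tolerance: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Simultaneous posterior updates for gamma* and delta*^2."""
    nb = Zb.shape[1]
    g = gamma_hat.copy()
    d = delta_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (tau_sq * nb * gamma_hat + d * gamma_bar) / (tau_sq * nb + d)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b + 0.5 * sum2) / (nb / 2 + a - 1)
        if np.max(np.abs(g_new - g)) < tolerance and np.max(np.abs(d_new - d)) < tolerance:
            return g_new, d_new, it
        g, d = g_new, d_new
    raise ConvergenceError(
        f"EB updates did not converge within {max_iter} iterations"
    )


def combat_adjust(
    matrix: pd.DataFrame,
    meta: SampleMetadata,
    tolerance: float = 1e-8,
    max_iter: int = 500,
    prior_mode: str = "eb",
) -> tuple[pd.DataFrame, BatchModelParams]:
    """Remove additive/multiplicative batch effects from a complete log2
    matrix by the parametric location-scale empirical-Bayes procedure.

    Steps: (1) per-protein OLS fit with batch indicators plus the
    condition covariate; (2) standardize residuals by the pooled variance;
    (3) per-batch moment estimates gamma_hat / delta_hat^2 and
    method-of-moments priors; (4) iterate the EB posterior updates to
    convergence; (5) back-adjust and restore the batch-free fit.

    ``prior_mode="identity"`` forces gamma* = 0, delta*^2 = 1 (a
    diagnostic limit under which adjustment returns the input). Batches
    with degenerate priors (zero across-protein spread) fall back to the
    unshrunk estimates.
    """
    if prior_mode not in ("eb", "identity"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    cells = [s for s in matrix.columns if s in set(meta.cell_ids)]
    Y = matrix[cells].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("matrix must be complete (impute before correction)")
    batch = meta.batch_of().reindex(cells).to_numpy()
    cond = meta.group_of().reindex(cells).to_numpy()
    batches = sorted(pd.unique(batch))
    if len(batches) < 2:
        raise ValueError(
            "only one acquisition batch present; skip batch correction"
        )
    for b_lab in batches:
        if (batch == b_lab).sum() < 2:
            raise ValueError(f"batch {b_lab!r} has fewer than 2 samples")

    n = len(cells)
    n_b = {b_lab: int((batch == b_lab).sum()) for b_lab in batches}
    B = len(batches)
    X_batch = np.column_stack([(batch == b_lab).astype(float) for b_lab in batches])
    cond_levels = sorted(pd.unique(cond))
    X_cov = np.column_stack(
        [(cond == lev).astype(float) for lev in cond_levels[1:]]
    ) if len(cond_levels) > 1 else np.empty((n, 0))
    X = np.hstack([X_batch, X_cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design is rank deficient: batch is confounded with the "
            f"condition (batches {batches}, conditions {cond_levels})"
        )

    # per-protein OLS fit; coefficients are (p x G)
    coef = np.linalg.solve(X.T @ X, X.T @ Y.T)
    weights = np.array([n_b[b_lab] / n for b_lab in batches])
    alpha = weights @ coef[:B]  # grand mean per protein
    beta = coef[B:].T  # proteins x n_cov
    if X_cov.shape[1]:
        stand_mean = alpha[:, None] + (X_cov @ coef[B:]).T
    else:
        stand_mean = np.repeat(alpha[:, None], n, axis=1)
    resid = Y - (X @ coef).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, _VAR_FLOOR)
    sd_pooled = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / sd_pooled[:, None]

    gamma_hat, gamma_star = {}, {}
    delta_hat_sq, delta_star_sq = {}, {}
    gamma_bar_d, tau_sq_d, a_d, b_d, iters, shrunk = {}, {}, {}, {}, {}, {}
    for b_lab in batches:
        idx = batch == b_lab
        Zb = Z[:, idx]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        gamma_hat[b_lab] = g_hat
        delta_hat_sq[b_lab] = d_hat
        g_bar = float(g_hat.mean())
        t2 = float(g_hat.var(ddof=1))
        m = float(d_hat.mean())
        s2 = float(d_hat.var(ddof=1))
        gamma_bar_d[b_lab] = g_bar
        tau_sq_d[b_lab] = t2
        if s2 > _VAR_FLOOR:
            a_d[b_lab] = (2 * s2 + m**2) / s2
            b_d[b_lab] = (m * s2 + m**3) / s2
        else:
            a_d[b_lab] = float("nan")
            b_d[b_lab] = float("nan")
        if prior_mode == "identity":
            gamma_star[b_lab] = np.zeros_like(g_hat)
            delta_star_sq[b_lab] = np.ones_like(d_hat)
            iters[b_lab] = 0
            shrunk[b_lab] = False
        elif t2 <= _VAR_FLOOR or s2 <= _VAR_FLOOR:
            # degenerate priors: no information to shrink with
            gamma_star[b_lab] = g_hat.copy()
            delta_star_sq[b_lab] = np.maximum(d_hat, _VAR_FLOOR)
            iters[b_lab] = 0
            shrunk[b_lab] = False
        else:
            g_st, d_st, it = _eb_iterate(
                Zb, g_hat, d_hat, g_bar, t2, a_d[b_lab], b_d[b_lab],
                tolerance, max_iter,
            )
            gamma_star[b_lab] = g_st
            delta_star_sq[b_lab] = np.maximum(d_st, _VAR_FLOOR)
            iters[b_lab] = it
            shrunk[b_lab] = True

    adjusted = np.empty_like(Z)
    for b_lab in batches:
        idx = batch == b_lab
        adjusted[:, idx] = (
            Z[:, idx] - gamma_star[b_lab][:, None]
        ) / np.sqrt(delta_star_sq[b_lab])[:, None]
    adjusted = adjusted * sd_pooled[:, None] + stand_mean

    out = pd.DataFrame(adjusted, index=matrix.index, columns=cells)
    params = BatchModelParams(
        batches=list(batches),
        n_per_batch=n_b,
        alpha=alpha,
        beta=beta,
        gamma_hat=gamma_hat,
        gamma_star=gamma_star,
        delta_hat_sq=delta_hat_sq,
        delta_star_sq=delta_star_sq,
        gamma_bar=gamma_bar_d,
        tau_sq=tau_sq_d,
        a_prior=a_d,
        b_prior=b_d,
        n_iter=iters,
        shrunk=shrunk,
    )
    return out, params
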