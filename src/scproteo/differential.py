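"""Differential-abundance calling: pooled-variance t-tests, BH adjustment,
class assignment at FDR/fold-change thresholds, top-k z-score clustering,
and a PCA-silhouette group-separation score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .io_qc import SampleMetadata

__all__ = [
    "DifferentialTable",
    "students_t_test",
    "bh_adjust",
    "differential_table",
    "zscore_top_k",
    "group_separation",
]

_FC_EPS = 1e-12  # float tolerance at the inclusive |FC| boundary


@dataclass
class DifferentialTable:
    """Per-protein differential results.

    ``table`` columns: protein_id, mean_<ref>, mean_<other>, log2fc,
    fc_linear, t, p, q, class. log2fc = mean(other) - mean(reference).
    """

    table: pd.DataFrame
    reference: str
    other: str
    fdr_threshold: float
    fc_threshold: float

    def classified(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["class"] == cls, "protein_id"])

    @property
    def up(self) -> list[str]:
        return self.classified("up")

    @property
    def down(self) -> list[str]:
        return self.classified("down")


def students_t_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test (pooled variance by default).

    Returns (t, p); p is NaN (with a warning) when the pooled variance is
    zero, in which case the protein is reported but unclassifiable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if not welch and (sx2 + sy2) == 0.0:
        warnings.warn("zero pooled variance; p undefined", stacklevel=2)
        return 0.0, float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Values are capped at 1. NaNs pass through as NaN and do not count
    toward m. p outside [0, 1] is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m == 0:
        return q
    pf = p[finite]
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    qf = np.empty(m)
    qf[order] = ranked
    q[finite] = qf
    return q


def _group_t_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled t statistic per row, other-vs-reference with
    groups taken in sorted label order (used for GSEA phenotype nulls)."""
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two group labels required")
    a = values[:, labels == groups[0]]
    b = values[:, labels == groups[1]]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def differential_table(
    matrix: pd.DataFrame,
    meta: SampleMetadata,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    reference: str | None = None,
    welch: bool = False,
) -> DifferentialTable:
    """Per-protein t/p/q and up/down/ns classes on a complete log2 matrix.

    log2fc = mean(other group) - mean(reference group); by default the
    lexicographically first group label is the reference. Classes: up iff
    q < fdr_threshold and FC >= fc_threshold (inclusive boundary); down
    symmetric; otherwise ns; proteins with undefined p (zero pooled
    variance) are "unclassifiable".
    """
    groups = meta.groups
    if len(groups) != 2:
        raise ValueError(f"two groups required, found {groups}")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    other = groups[1] if reference == groups[0] else groups[0]
    in_matrix = set(matrix.columns)
    ref_cols = [s for s in meta.samples_in_group(reference) if s in in_matrix]
    oth_cols = [s for s in meta.samples_in_group(other) if s in in_matrix]
    if len(ref_cols) < 2 or len(oth_cols) < 2:
        raise ValueError("each group needs at least 2 samples in the matrix")
    a = matrix[ref_cols].to_numpy(float)
    b = matrix[oth_cols].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix must be complete (impute before testing)")

    mean_ref = a.mean(axis=1)
    mean_oth = b.mean(axis=1)
    log2fc = mean_oth - mean_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    degenerate = sp2 == 0.0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, np.nan, p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} proteins have zero pooled variance; "
            "reported but unclassifiable",
            stacklevel=2,
        )
    q = bh_adjust(p)

    log2_thr = np.log2(fc_threshold)
    sig = q < fdr_threshold  # strict: q == threshold fails
    up = sig & (log2fc >= log2_thr - _FC_EPS)
    down = sig & (log2fc <= -log2_thr + _FC_EPS)
    cls = np.where(up, "up", np.where(down, "down", "ns"))
    cls = np.where(np.isnan(p), "unclassifiable", cls)

    table = pd.DataFrame(
        {
            "protein_id": matrix.index,
            f"mean_{reference}": mean_ref,
            f"mean_{other}": mean_oth,
            "log2fc": log2fc,
            "fc_linear": np.exp2(log2fc),
            "t": t,
            "p": p,
            "q": q,
            "class": cls,
        }
    ).reset_index(drop=True)
    return DifferentialTable(table, reference, other, fdr_threshold, fc_threshold)


def zscore_top_k(
    matrix: pd.DataFrame, table: DifferentialTable, k: int = 60
) -> tuple[pd.DataFrame, list[int]]:
    """Row-standardized submatrix of the k most significant proteins,
    ordered by average-linkage hierarchical clustering on correlation
    distance.

    Selection key: q ascending, |log2fc| descending, protein id ascending.
    Returns (reordered z-score DataFrame, row order as positions into the
    selected-by-significance list).
    """
    t = table.table
    eligible = t[np.isfinite(t["q"])].copy()
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} proteins with finite q; k={k}")
    eligible["_abs_fc"] = eligible["log2fc"].abs()
    sel = eligible.sort_values(
        ["q", "_abs_fc", "protein_id"], ascending=[True, False, True]
    ).head(k)["protein_id"].tolist()
    sub = matrix.loc[sel].to_numpy(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance row cannot be z-scored")
    z = (sub - mu) / sd
    if k == 1:
        order = [0]
    else:
        lk = linkage(z, method="average", metric="correlation")
        order = [int(i) for i in leaves_list(lk)]
    zdf = pd.DataFrame(z, index=sel, columns=matrix.columns).iloc[order]
    return zdf, order


def group_separation(matrix: pd.DataFrame, meta: SampleMetadata) -> float:
    """Mean silhouette of the two group labels in the top-2 PC plane.

    Cells are observations; the matrix must be complete. Deterministic
    stand-in for a 2-D embedding when quantifying group segregation.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    groups = meta.groups
    if len(groups) != 2:
        raise ValueError(f"two groups required, found {groups}")
    cells = [s for s in matrix.columns if s in set(meta.cell_ids)]
    labels = meta.group_of().reindex(cells).to_numpy()
    X = matrix[cells].to_numpy(float).T
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance matrix; separation undefined")
    emb = PCA(n_components=2, svd_solver="full").fit_transform(Xc)
    return float(silhouette_score(emb, labels))
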