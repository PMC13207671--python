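"""Over-representation analysis, permutation GSEA, and annotation tallies.

ORA uses the exact hypergeometric upper tail; GSEA uses the classical
weighted Kolmogorov-Smirnov running sum with gene-set (default) or
phenotype permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "GseaResult",
    "read_gmt",
    "write_gmt",
    "ora_hypergeometric",
    "gsea_enrichment_score",
    "gsea_run",
    "category_tally",
]


@dataclass
class GeneSetCollection:
    """Named, ordered protein sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def filter_names(self, substring: str) -> "GeneSetCollection":
        """Subset to sets whose name contains ``substring`` (case-insensitive)."""
        sub = substring.lower()
        keep = {n: m for n, m in self.sets.items() if sub in n.lower()}
        return GeneSetCollection(
            keep, {n: d for n, d in self.descriptions.items() if n in keep}
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...).

    Duplicate members within a set are deduplicated with a warning;
    duplicate set names and short lines are rejected.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            seen: set[str] = set()
            uniq: list[str] = []
            for m in members:
                if m in seen:
                    warnings.warn(
                        f"set {name!r}: duplicate member {m!r} dropped",
                        stacklevel=2,
                    )
                    continue
                seen.add(m)
                uniq.append(m)
            if not uniq:
                raise ValueError(f"line {lineno}: set {name!r} has no members")
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# ORA


@dataclass
class EnrichmentRecord:
    term: str
    N: int  # population size
    K: int  # annotated in population
    n: int  # study-set size
    k: int  # annotated in study set
    fold_enrichment: float
    p: float
    q: float = float("nan")
    significant: bool = False


def ora_hypergeometric(
    study,
    population,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each set in the study list.

    ``study`` must be a subset of ``population``; K and k are counted after
    intersecting each set with the population. p is the exact upper tail
    P(X >= k). Records carry a BH-adjusted q but the significance flag uses
    raw p < ``p_threshold``. Sorted by (p, term).
    """
    study = set(study)
    population = set(population)
    if not population:
        raise ValueError("population is empty")
    stray = sorted(study - population)
    if stray:
        raise ValueError(f"study proteins not in population: {stray[:10]}")
    N = len(population)
    n = len(study)
    records = []
    for term in sets.names:
        members = set(sets[term]) & population
        K = len(members)
        k = len(members & study)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        if n > 0 and K > 0:
            fold = (k / n) / (K / N)
        else:
            fold = 0.0
        records.append(EnrichmentRecord(term, N, K, n, k, fold, p))
    from .differential import bh_adjust

    qs = bh_adjust(np.array([r.p for r in records])) if records else []
    for r, q in zip(records, qs):
        r.q = float(q)
        r.significant = r.p < p_threshold
    records.sort(key=lambda r: (r.p, r.term))
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# GSEA


def _rank_order(protein_ids, scores):
    ids = np.asarray(protein_ids, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if ids.shape != scores.shape:
        raise ValueError("protein_ids and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    # descending score; ties broken by id for determinism
    order = np.lexsort((ids, -scores))
    return ids[order], scores[order]


def gsea_enrichment_score(
    protein_ids,
    scores,
    members,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running-sum enrichment score for one set.

    ``protein_ids``/``scores`` define the ranked list (sorted internally
    by descending score). Hits add |score|^weight normalised by the total
    hit weight; misses subtract 1/(N - N_hits). Returns (ES, running-sum
    profile, leading-edge members). For ES >= 0 the leading edge is the
    hits at or before the extremum; for ES < 0, at or after it.
    """
    ids, sc = _rank_order(protein_ids, scores)
    N = len(ids)
    member_set = set(members)
    hit = np.array([g in member_set for g in ids], dtype=bool)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("set has no members in the ranked list")
    if n_hits == N:
        raise ValueError("set covers the entire ranked list (degenerate)")
    w = np.abs(sc) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0.0:  # all hit scores zero: fall back to unweighted steps
        hit_w = hit.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~hit) / (N - n_hits)
    run = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(run)))
    es = float(run[i_ext])
    if es >= 0:
        leading = [g for j, g in enumerate(ids) if hit[j] and j <= i_ext]
    else:
        leading = [g for j, g in enumerate(ids) if hit[j] and j >= i_ext]
    return es, run, leading


def _es_from_positions(pos: np.ndarray, w: np.ndarray, N: int) -> float:
    """ES given sorted hit positions and their weights (O(set size))."""
    n_hits = len(pos)
    total = w.sum()
    if total == 0.0:
        w = np.ones(n_hits)
        total = float(n_hits)
    cum = np.cumsum(w) / total
    miss_rate = 1.0 / (N - n_hits)
    before = (pos - np.arange(n_hits)) * miss_rate
    at_hit = cum - before  # value just after each hit
    cum_prev = np.concatenate(([0.0], cum[:-1]))
    pre_hit = cum_prev - before  # value just before each hit
    hi = at_hit.max()
    lo = min(pre_hit.min(), 0.0)
    return float(hi) if hi >= -lo else float(lo)


@dataclass
class GseaResult:
    term: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr: float
    significant: bool
    leading_edge: list[str]
    warning: str = ""


def gsea_run(
    protein_ids,
    scores,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    perm_type: str = "gene_set",
    seed: int | None = None,
    weight: float = 1.0,
    fdr_threshold: float = 0.25,
    matrix: pd.DataFrame | None = None,
    meta=None,
) -> list[GseaResult]:
    """GSEA over a collection with permutation-based NES / p / FDR.

    gene_set mode (default): null ES from ``n_perm`` random same-size
    member sets. phenotype mode: group labels are permuted and the t-based
    ranking recomputed (requires ``matrix`` and ``meta``). p-values carry
    an add-one correction; NES = ES / mean(|null ES| of matching sign);
    FDR is the sign-stratified permutation FDR.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if perm_type not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown perm_type {perm_type!r}")
    rng = np.random.default_rng(seed)
    ids, sc = _rank_order(protein_ids, scores)
    N = len(ids)
    abs_w = np.abs(sc) ** weight
    pos_of = {g: i for i, g in enumerate(ids)}

    terms, sizes, es_obs, leading_edges, warns = [], [], [], [], []
    for term in sets.names:
        inter = [g for g in sets[term] if g in pos_of]
        if len(inter) == 0 or len(inter) == N:
            terms.append(term)
            sizes.append(len(inter))
            es_obs.append(np.nan)
            leading_edges.append([])
            warns.append("degenerate after intersection with ranked list")
            continue
        es, _, le = gsea_enrichment_score(ids, sc, inter, weight=weight)
        terms.append(term)
        sizes.append(len(inter))
        es_obs.append(es)
        leading_edges.append(le)
        warns.append("")

    # null ES, one matrix row per term
    null_es = np.full((len(terms), n_perm), np.nan)
    if perm_type == "gene_set":
        for ti, s in enumerate(sizes):
            if warns[ti]:
                continue
            for j in range(n_perm):
                pos = np.sort(rng.choice(N, size=s, replace=False))
                null_es[ti, j] = _es_from_positions(pos, abs_w[pos], N)
    else:
        if matrix is None or meta is None:
            raise ValueError("phenotype permutation requires matrix and meta")
        from .differential import _group_t_scores

        labels = meta.group_of().reindex(matrix.columns).to_numpy()
        for j in range(n_perm):
            perm = rng.permutation(labels)
            t_perm = _group_t_scores(matrix.to_numpy(float), perm)
            pids, psc = _rank_order(matrix.index.to_numpy(object), t_perm)
            ppos = {g: i for i, g in enumerate(pids)}
            pw = np.abs(psc) ** weight
            for ti, term in enumerate(terms):
                if warns[ti]:
                    continue
                pos = np.sort([ppos[g] for g in sets[term] if g in ppos])
                null_es[ti, j] = _es_from_positions(pos, pw[pos], N)

    results = []
    nes_obs = np.full(len(terms), np.nan)
    null_nes_pool_pos: list[np.ndarray] = []
    null_nes_pool_neg: list[np.ndarray] = []
    for ti, term in enumerate(terms):
        es = es_obs[ti]
        if warns[ti]:
            continue
        nulls = null_es[ti]
        same = nulls[nulls >= 0] if es >= 0 else nulls[nulls < 0]
        if same.size == 0:
            warns[ti] = "no null ES of matching sign; term unscored"
            continue
        mean_abs = np.abs(same).mean()
        nes_obs[ti] = es / mean_abs if mean_abs > 0 else np.nan
        pos_nulls = nulls[nulls >= 0]
        neg_nulls = nulls[nulls < 0]
        if pos_nulls.size:
            null_nes_pool_pos.append(pos_nulls / np.abs(pos_nulls).mean())
        if neg_nulls.size:
            null_nes_pool_neg.append(neg_nulls / np.abs(neg_nulls).mean())

    pool_pos = np.concatenate(null_nes_pool_pos) if null_nes_pool_pos else np.array([])
    pool_neg = np.concatenate(null_nes_pool_neg) if null_nes_pool_neg else np.array([])
    obs_pos = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
    obs_neg = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]

    for ti, term in enumerate(terms):
        es = es_obs[ti]
        if warns[ti]:
            results.append(
                GseaResult(term, sizes[ti], float(es) if np.isfinite(es) else np.nan,
                           np.nan, np.nan, np.nan, False, leading_edges[ti],
                           warning=warns[ti])
            )
            continue
        nulls = null_es[ti]
        nes = float(nes_obs[ti])
        # add-one two-sided permutation p: calibrated and bounded in
        # [1/(n_perm+1), 1]
        count = int((np.abs(nulls) >= abs(es)).sum())
        if es >= 0:
            if pool_pos.size and obs_pos.size:
                frac_null = (pool_pos >= nes).mean()
                frac_obs = max((obs_pos >= nes).mean(), 1.0 / max(obs_pos.size, 1))
                fdr = min(1.0, float(frac_null / frac_obs))
            else:
                fdr = np.nan
        else:
            if pool_neg.size and obs_neg.size:
                frac_null = (pool_neg <= nes).mean()
                frac_obs = max((obs_neg <= nes).mean(), 1.0 / max(obs_neg.size, 1))
                fdr = min(1.0, float(frac_null / frac_obs))
            else:
                fdr = np.nan
        p = (1 + count) / (n_perm + 1)
        results.append(
            GseaResult(
                term,
                sizes[ti],
                float(es),
                nes,
                float(p),
                float(fdr),
                bool(np.isfinite(fdr) and fdr < fdr_threshold),
                leading_edges[ti],
            )
        )
    return results


def gsea_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_perm": r.p_perm,
                "fdr": r.fdr,
                "significant": r.significant,
                "leading_edge": ",".join(r.leading_edge),
                "warning": r.warning,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Annotation tallies


def category_tally(study, annotations: pd.DataFrame) -> pd.DataFrame:
    """Count annotation categories over a study set.

    ``annotations`` has columns (protein_id, category); a protein may carry
    several categories and contributes one count to each. Proteins without
    any annotation row are tallied as "unannotated". Fractions are over
    total assignments, not proteins.
    """
    if not {"protein_id", "category"}.issubset(annotations.columns):
        raise ValueError("annotations need columns protein_id, category")
    study = list(dict.fromkeys(study))
    ann = annotations[annotations["protein_id"].isin(set(study))]
    counts: dict[str, int] = {}
    annotated = set(ann["protein_id"])
    for cat, sub in ann.groupby("category"):
        counts[str(cat)] = sub["protein_id"].nunique()
    n_unann = len([p for p in study if p not in annotated])
    if n_unann:
        counts["unannotated"] = counts.get("unannotated", 0) + n_unann
    total = sum(counts.values())
    rows = [
        {"category": c, "count": n, "fraction": (n / total if total else 0.0)}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])
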