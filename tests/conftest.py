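"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from scproteo import SampleMetadata, SynthConfig, generate_dataset


def make_meta(groups, batches=None, blanks=()):
    """Build SampleMetadata from {sample_id: group} plus optional batches."""
    rows = []
    for sid, grp in groups.items():
        rows.append(
            {
                "sample_id": sid,
                "group": grp,
                "batch": batches.get(sid, "b1") if batches else "b1",
                "is_blank": False,
            }
        )
    for sid in blanks:
        rows.append({"sample_id": sid, "group": "", "batch": "", "is_blank": True})
    return SampleMetadata(pd.DataFrame(rows))


def two_group_meta(n_per_group=12, n_batches=1, prefix=("a", "b")):
    groups = {}
    batches = {}
    for g in prefix:
        for i in range(n_per_group):
            sid = f"{g}{i:02d}"
            groups[sid] = g
            batches[sid] = f"batch{i % n_batches}"
    return make_meta(groups, batches)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SynthConfig(n_proteins=500, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """No missingness, no contaminants, no blanks: complete matrix."""
    cfg = SynthConfig(
        n_proteins=600,
        seed=7,
        detect_x0=-100.0,
        blank_frac=0.0,
        n_blanks=0,
    )
    return generate_dataset(cfg)


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_maximal_cliques(g):
    """Exhaustive 2^n-subset maximal-clique oracle (n <= ~16).

    Vectorized over all non-empty vertex subsets using adjacency bitmasks.
    Returns cliques as sorted tuples of node labels, lexicographically
    ordered — independent of any clique-enumeration algorithm.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return []
    pos = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros(n, dtype=np.int64)
    for u, v in g.edges:
        adj[pos[u]] |= 1 << pos[v]
        adj[pos[v]] |= 1 << pos[u]
    masks = np.arange(1, 1 << n, dtype=np.int64)
    is_clique = np.ones(masks.size, dtype=bool)
    for v in range(n):
        has_v = ((masks >> v) & 1) == 1
        others = masks & ~np.int64(1 << v)
        covered = (adj[v] & others) == others
        is_clique &= ~has_v | covered
    cliques = masks[is_clique]
    maximal = np.ones(cliques.size, dtype=bool)
    for v in range(n):
        outside = ((cliques >> v) & 1) == 0
        extends = (adj[v] & cliques) == cliques
        maximal &= ~(outside & extends)
    out = []
    for m in cliques[maximal]:
        out.append(tuple(nodes[i] for i in range(n) if (int(m) >> i) & 1))
    out.sort()
    return out


def brute_force_mcc(g):
    """MCC via the exhaustive-subset clique oracle."""
    scores = {v: 0 for v in g.nodes}
    for clique in brute_force_maximal_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def brute_force_bh(p):
    """Literal step-up definition of Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def brute_force_hypergeom_upper(N, K, n, k):
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total
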