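"""PPI edge-list I/O, maximal-clique enumeration, and Maximal Clique
Centrality (MCC) hub ranking.

MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!. An
isolated node forms a singleton maximal clique and scores (1-1)! = 1.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import pandas as pd

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "enumerate_maximal_cliques",
    "mcc_scores",
    "top_hubs",
]


def read_edge_list(path, min_score: float = 0.0) -> nx.Graph:
    """Read a STRING-style TSV edge list (node1, node2[, combined_score]).

    Edges below ``min_score`` are dropped; duplicate/reversed duplicates
    are collapsed; self-loops are dropped with a warning. A header line
    whose third field is not numeric is skipped.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"line {lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            score = 1.0
            if len(fields) == 3:
                try:
                    score = float(fields[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise ValueError(
                        f"line {lineno}: unparseable score {fields[2]!r}"
                    ) from None
            if u == v:
                warnings.warn(f"line {lineno}: self-loop {u!r} dropped", stacklevel=2)
                g.add_node(u)
                continue
            if score < min_score:
                continue
            g.add_edge(u, v, score=score)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node1\tnode2\tscore\n")
        for u, v, data in sorted(
            ((min(a, b), max(a, b), d) for a, b, d in g.edges(data=True))
        ):
            fh.write(f"{u}\t{v}\t{data.get('score', 1.0)}\n")


def enumerate_maximal_cliques(g: nx.Graph) -> list[list[str]]:
    """All maximal cliques, each sorted, in lexicographic list order.

    Uses pivoting Bron-Kerbosch (networkx). Isolated nodes yield
    singleton cliques; the empty graph yields an empty list.
    """
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort()
    return cliques


def mcc_scores(g: nx.Graph) -> pd.DataFrame:
    """Per-node MCC table (node, mcc, degree, rank).

    Sorted by mcc descending, then degree descending, then node id
    ascending; rank is 1-based in that order.
    """
    scores = {v: 0 for v in g.nodes}
    for clique in enumerate_maximal_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    rows = sorted(
        (
            {"node": v, "mcc": s, "degree": g.degree(v)}
            for v, s in scores.items()
        ),
        key=lambda r: (-r["mcc"], -r["degree"], str(r["node"])),
    )
    table = pd.DataFrame(rows, columns=["node", "mcc", "degree"])
    table["rank"] = range(1, len(rows) + 1)
    return table


def top_hubs(table: pd.DataFrame, k: int = 10) -> list[str]:
    """The k highest-MCC nodes under the documented tie-break."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(
            f"k={k} exceeds node count {len(table)}; returning all nodes",
            stacklevel=2,
        )
        k = len(table)
    return list(table["node"].iloc[:k])
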