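"""Synthetic single-cell proteome generator.

Produces protein x sample intensity matrices with a two-group, two-batch
design, intensity-dependent (left-censored) missingness, planted
fold-changes, procedural blanks carrying contaminant background, plus
companion gene-set, PPI and annotation fixtures — together with the
ground truth needed for parameter-recovery tests.

Model, per protein i and cell j (group g, batch b):

    x_ij = mu_i + fc_i * [g == treatment] + gamma_{b,i}
           + delta_{b,i} * eps_ij,            eps_ij ~ N(0, sigma_cell^2)

A cell's signal is detected with probability logistic((x - x0)/s) in the
realized log2 intensity; detected signal contributes 2^x on the linear
scale. Contaminant proteins additionally contribute lognormal background
(mean log2 level ``blank_level``) in blanks AND in cell samples, additive
on the linear scale, so blank subtraction has something real to remove.

All randomness flows from a single seed through independent spawned
streams (baseline, classes, fold-changes, batch effects, cell noise,
detection, contamination, blanks), so e.g. changing ``n_blanks`` does not
perturb the cell draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import GeneSetCollection
from .io_qc import IntensityMatrix, SampleMetadata

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_gene_sets",
    "generate_ppi",
    "generate_annotations",
    "write_ground_truth",
]

_LOG2_15 = float(np.log2(1.5))


@dataclass(frozen=True)
class SynthConfig:
    n_per_group: int = 12
    n_blanks: int = 3
    n_proteins: int = 2500
    frac_up: float = 0.08
    frac_down: float = 0.02
    fc_log2_range: tuple[float, float] = (_LOG2_15, 3.0)
    mu0: float = 20.0
    sigma0: float = 2.0
    sigma_cell: float = 0.5
    batch_gamma_sd: float = 0.4
    batch_delta_range: tuple[float, float] = (0.8, 1.25)
    detect_x0: float = 17.5
    detect_s: float = 1.2
    blank_frac: float = 0.05
    blank_level: float = 16.0
    group_labels: tuple[str, str] = ("control", "storage")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("invariant violated: n_per_group >= 2")
        if self.n_blanks < 0:
            raise ValueError("invariant violated: n_blanks >= 0")
        if self.n_proteins < 1:
            raise ValueError("invariant violated: n_proteins >= 1")
        if not (0 <= self.frac_up and 0 <= self.frac_down):
            raise ValueError("invariant violated: frac_up, frac_down >= 0")
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("invariant violated: frac_up + frac_down < 1")
        if self.fc_log2_range[0] < 0 or self.fc_log2_range[1] < self.fc_log2_range[0]:
            raise ValueError(
                "invariant violated: fc_log2_range lower bound >= 0 and ordered"
            )
        if not (self.detect_s > 0):
            raise ValueError("invariant violated: detect_s > 0")
        for name in ("sigma0", "sigma_cell", "batch_gamma_sd"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"invariant violated: {name} > 0")
        lo, hi = self.batch_delta_range
        if not (0 < lo <= hi):
            raise ValueError("invariant violated: batch_delta_range positive, ordered")
        if not (0 <= self.blank_frac <= 1):
            raise ValueError("invariant violated: blank_frac in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    protein_ids: list[str]
    true_class: np.ndarray  # 'up' | 'down' | 'null' per protein
    true_log2fc: np.ndarray
    batches: list[str]
    gamma: np.ndarray  # (n_batches, n_proteins) additive shifts
    delta: np.ndarray  # (n_batches, n_proteins) residual scales
    contaminant: np.ndarray  # bool per protein
    true_log2: pd.DataFrame  # realized signal log2 abundance, proteins x cells
    detect_prob: pd.DataFrame  # logistic detection probability per entry
    planted_set: list[str] | None = None
    planted_clique: list[str] | None = None

    def __post_init__(self) -> None:
        null = self.true_class == "null"
        if not np.all(self.true_log2fc[null] == 0.0):
            raise ValueError("null proteins must have true_log2fc exactly 0")

    @property
    def up_proteins(self) -> list[str]:
        return [p for p, c in zip(self.protein_ids, self.true_class) if c == "up"]

    @property
    def down_proteins(self) -> list[str]:
        return [p for p, c in zip(self.protein_ids, self.true_class) if c == "down"]

    @property
    def null_proteins(self) -> list[str]:
        return [p for p, c in zip(self.protein_ids, self.true_class) if c == "null"]


def generate_dataset(
    config: SynthConfig,
) -> tuple[IntensityMatrix, SampleMetadata, GroundTruth]:
    """Simulate the full matrix + metadata + ground truth.

    Cells are assigned to the two batches by interleaving within each
    group (cell 1 -> b1, cell 2 -> b2, ...), so batch and group are not
    confounded. Columns are ordered: group-A cells, group-B cells, blanks.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (
        s_base, s_class, s_fc, s_batch, s_noise, s_detect, s_contam, s_blank
    ) = ss.spawn(8)
    rng_base = np.random.default_rng(s_base)
    rng_class = np.random.default_rng(s_class)
    rng_fc = np.random.default_rng(s_fc)
    rng_batch = np.random.default_rng(s_batch)
    rng_noise = np.random.default_rng(s_noise)
    rng_detect = np.random.default_rng(s_detect)
    rng_contam = np.random.default_rng(s_contam)
    rng_blank = np.random.default_rng(s_blank)

    P = cfg.n_proteins
    width = len(str(P))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(P)]

    mu = rng_base.normal(cfg.mu0, cfg.sigma0, P)

    n_up = int(round(cfg.frac_up * P))
    n_down = int(round(cfg.frac_down * P))
    perm = rng_class.permutation(P)
    true_class = np.full(P, "null", dtype=object)
    true_class[perm[:n_up]] = "up"
    true_class[perm[n_up : n_up + n_down]] = "down"
    lo, hi = cfg.fc_log2_range
    fc = np.zeros(P)
    fc[perm[:n_up]] = rng_fc.uniform(lo, hi, n_up)
    fc[perm[n_up : n_up + n_down]] = -rng_fc.uniform(lo, hi, n_down)

    batches = ["b1", "b2"]
    gamma = rng_batch.normal(0.0, cfg.batch_gamma_sd, (2, P))
    dlo, dhi = cfg.batch_delta_range
    delta = rng_batch.uniform(dlo, dhi, (2, P))

    n_cells = 2 * cfg.n_per_group
    gA, gB = cfg.group_labels
    cell_ids = [f"{gA}_{i + 1:02d}" for i in range(cfg.n_per_group)] + [
        f"{gB}_{i + 1:02d}" for i in range(cfg.n_per_group)
    ]
    groups = np.array([gA] * cfg.n_per_group + [gB] * cfg.n_per_group, dtype=object)
    # interleaved batch assignment within each group
    batch_idx = np.array(
        [i % 2 for i in range(cfg.n_per_group)] * 2, dtype=int
    )
    batch_labels = np.array([batches[i] for i in batch_idx], dtype=object)
    is_treated = (groups == gB).astype(float)

    eps = rng_noise.normal(0.0, cfg.sigma_cell, (P, n_cells))
    x = (
        mu[:, None]
        + fc[:, None] * is_treated[None, :]
        + gamma[batch_idx, :].T
        + delta[batch_idx, :].T * eps
    )

    p_detect = expit((x - cfg.detect_x0) / cfg.detect_s)
    detected = rng_detect.random((P, n_cells)) < p_detect

    n_contam = int(round(cfg.blank_frac * P))
    contaminant = np.zeros(P, dtype=bool)
    if n_contam:
        contaminant[rng_contam.choice(P, size=n_contam, replace=False)] = True

    linear = np.where(detected, np.exp2(x), 0.0)
    if n_contam:
        bg_cells = np.exp2(
            rng_contam.normal(cfg.blank_level, cfg.sigma_cell, (n_contam, n_cells))
        )
        linear[contaminant, :] += bg_cells
    cell_values = np.where(linear > 0.0, linear, np.nan)

    blank_ids = [f"blank_{i + 1:02d}" for i in range(cfg.n_blanks)]
    blank_values = np.full((P, cfg.n_blanks), np.nan)
    if cfg.n_blanks and n_contam:
        bg_blanks = np.exp2(
            rng_blank.normal(cfg.blank_level, cfg.sigma_cell, (n_contam, cfg.n_blanks))
        )
        blank_values[contaminant, :] = bg_blanks

    data = pd.DataFrame(
        np.hstack([cell_values, blank_values]),
        index=pd.Index(protein_ids, name="protein_id"),
        columns=cell_ids + blank_ids,
    )
    matrix = IntensityMatrix(data)

    meta_rows = [
        {"sample_id": sid, "group": grp, "batch": bat, "is_blank": False}
        for sid, grp, bat in zip(cell_ids, groups, batch_labels)
    ] + [
        {"sample_id": sid, "group": "", "batch": "", "is_blank": True}
        for sid in blank_ids
    ]
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    truth = GroundTruth(
        protein_ids=protein_ids,
        true_class=true_class,
        true_log2fc=fc,
        batches=batches,
        gamma=gamma,
        delta=delta,
        contaminant=contaminant,
        true_log2=pd.DataFrame(x, index=data.index, columns=cell_ids),
        detect_prob=pd.DataFrame(p_detect, index=data.index, columns=cell_ids),
    )
    return matrix, meta, truth


def generate_gene_sets(
    truth: GroundTruth,
    n_decoys: int = 10,
    set_size: int = 50,
    enrich_frac: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """One planted set enriched for up-class proteins plus uniform decoys.

    The planted set draws ``round(enrich_frac * set_size)`` members from
    up-class proteins and the remainder from nulls; decoys are sampled
    uniformly from all proteins. The planted membership is recorded on
    ``truth.planted_set``.
    """
    if not (0 <= enrich_frac <= 1):
        raise ValueError("enrich_frac must be in [0, 1]")
    if set_size > len(truth.protein_ids):
        raise ValueError(
            f"set_size={set_size} exceeds {len(truth.protein_ids)} proteins"
        )
    rng = np.random.default_rng(seed)
    n_up = int(round(enrich_frac * set_size))
    ups = truth.up_proteins
    nulls = truth.null_proteins
    if n_up > len(ups):
        raise ValueError(f"need {n_up} up-class proteins, only {len(ups)} available")
    if set_size - n_up > len(nulls):
        raise ValueError("not enough null proteins for the planted set remainder")
    planted = list(rng.choice(ups, size=n_up, replace=False)) + list(
        rng.choice(nulls, size=set_size - n_up, replace=False)
    )
    sets = {"PLANTED": planted}
    descriptions = {"PLANTED": f"enrich_frac={enrich_frac}"}
    all_ids = np.asarray(truth.protein_ids, dtype=object)
    for d in range(n_decoys):
        name = f"DECOY_{d + 1:03d}"
        sets[name] = list(rng.choice(all_ids, size=set_size, replace=False))
        descriptions[name] = "uniform decoy"
    truth.planted_set = list(planted)
    return GeneSetCollection(sets, descriptions)


def generate_ppi(
    truth: GroundTruth,
    clique_size: int = 6,
    n_nodes: int = 60,
    edge_prob: float = 0.02,
    seed: int = 0,
) -> nx.Graph:
    """Erdos-Renyi background plus one planted complete subgraph.

    Nodes are the first ``n_nodes`` protein ids; the planted clique's
    nodes are recorded on ``truth.planted_clique``.
    """
    if clique_size < 2:
        raise ValueError("clique_size must be >= 2")
    if clique_size > n_nodes:
        raise ValueError("clique_size must be <= n_nodes")
    if not (0 <= edge_prob <= 1):
        raise ValueError("edge_prob must be in [0, 1]")
    if n_nodes > len(truth.protein_ids):
        raise ValueError("n_nodes exceeds number of simulated proteins")
    rng = np.random.default_rng(seed)
    nodes = truth.protein_ids[:n_nodes]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if edge_prob > 0:
        n = len(nodes)
        for i in range(n):
            draws = rng.random(n - i - 1)
            for off, r in enumerate(draws):
                if r < edge_prob:
                    g.add_edge(nodes[i], nodes[i + 1 + off], score=1.0)
    clique_nodes = [nodes[i] for i in rng.choice(n_nodes, clique_size, replace=False)]
    for i, u in enumerate(clique_nodes):
        for v in clique_nodes[i + 1 :]:
            g.add_edge(u, v, score=1.0)
    truth.planted_clique = sorted(clique_nodes)
    return g


_DEFAULT_CATEGORIES = (
    "lysosome",
    "endoplasmic reticulum",
    "mitochondrion",
    "cytosol",
    "nucleus",
    "plasma membrane",
)


def generate_annotations(
    truth: GroundTruth,
    categories: tuple[str, ...] = _DEFAULT_CATEGORIES,
    unannotated_frac: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Random protein -> compartment table (1-2 categories per protein,
    a fraction left unannotated). Plumbing for category tallies."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in truth.protein_ids:
        if rng.random() < unannotated_frac:
            continue
        k = 2 if rng.random() < 0.2 else 1
        for cat in rng.choice(categories, size=k, replace=False):
            rows.append({"protein_id": pid, "category": str(cat)})
    return pd.DataFrame(rows, columns=["protein_id", "category"])


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "protein_id\ttrue_class\ttrue_log2fc\tcontaminant\t"
            "gamma_b1\tgamma_b2\tdelta_b1\tdelta_b2\n"
        )
        for i, pid in enumerate(truth.protein_ids):
            fh.write(
                f"{pid}\t{truth.true_class[i]}\t{truth.true_log2fc[i]!r}\t"
                f"{int(truth.contaminant[i])}\t"
                f"{truth.gamma[0, i]!r}\t{truth.gamma[1, i]!r}\t"
                f"{truth.delta[0, i]!r}\t{truth.delta[1, i]!r}\n"
            )


def write_annotations(annotations: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tcategory\n")
        for _, r in annotations.iterrows():
            fh.write(f"{r['protein_id']}\t{r['category']}\n")
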