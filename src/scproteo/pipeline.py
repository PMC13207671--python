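"""End-to-end orchestration: enforces the fixed stage order
(read -> blank subtraction -> depth filter -> detection filter -> log2 +
median-center -> impute -> batch-correct -> differential -> QC -> ORA ->
GSEA -> hubs -> tally), writes every intermediate table, and emits a
manifest with parameter values and artifact digests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .batch import combat_adjust
from .differential import differential_table, group_separation, zscore_top_k
from .enrichment import (
    category_tally,
    enrichment_to_frame,
    gsea_run,
    gsea_to_frame,
    ora_hypergeometric,
    read_gmt,
)
from .io_qc import (
    correlation_matrix,
    filter_proteins_by_detection,
    filter_samples_by_depth,
    overlap_counts,
    read_protein_matrix,
    read_sample_metadata,
    subtract_blank_background,
    validate_matrix_metadata,
    write_protein_matrix,
)
from .network import mcc_scores, read_edge_list, top_hubs
from .normalize import estimate_global_params, impute_left_censored, log2_and_center

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("scproteo")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    matrix: str = ""
    metadata: str = ""
    gene_sets: str = ""
    edge_list: str = ""
    annotations: str = ""
    out_dir: str = "run"
    # stage toggles
    do_blank_subtraction: bool = True
    do_batch_correction: bool = True
    do_ora: bool = True
    do_gsea: bool = True
    do_hubs: bool = True
    # thresholds
    min_proteins: int = 900
    min_reps: int = 4
    fdr: float = 0.05
    fc: float = 1.5
    ora_p: float = 0.05
    gsea_fdr: float = 0.25
    gsea_n_perm: int = 1000
    gsea_set_filter: str = ""  # optional term-name substring filter
    shift: float = 1.8
    width: float = 0.3
    hub_k: int = 10
    hub_direction: str = "up"  # which DEP class feeds ORA/hubs
    min_score: float = 0.0  # PPI edge score threshold
    seed: int | None = None

    def validate(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.fc < 1:
            raise ValueError("fc must be >= 1")
        if not (0 < self.ora_p < 1):
            raise ValueError("ora_p must be in (0, 1)")
        if not (0 < self.gsea_fdr < 1):
            raise ValueError("gsea_fdr must be in (0, 1)")
        if self.min_proteins < 0 or self.min_reps < 0:
            raise ValueError("min_proteins and min_reps must be >= 0")
        if self.shift < 0 or self.width <= 0:
            raise ValueError("shift >= 0 and width > 0 required")
        if self.hub_k < 1:
            raise ValueError("hub_k must be >= 1")
        if self.hub_direction not in ("up", "down"):
            raise ValueError("hub_direction must be 'up' or 'down'")
        stochastic = self.do_gsea or True  # imputation is always stochastic
        if stochastic and self.seed is None:
            raise ValueError(
                "seed is required when a stochastic stage (imputation/GSEA) "
                "is enabled"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in _fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "PipelineConfig":
        d = asdict(self)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**d)


def _fields(cls):
    import dataclasses

    return dataclasses.fields(cls)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stage order is fixed; any stage error aborts with a stage-named
    message, leaving partial outputs plus a FAILED marker in place.
    Identical config + inputs yield identical artifact digests.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "read"
        matrix = read_protein_matrix(config.matrix)
        meta = read_sample_metadata(config.metadata)
        validate_matrix_metadata(matrix, meta)
        log.info("read %d proteins x %d samples", matrix.n_proteins, matrix.n_samples)

        stage = "blank_subtraction"
        if config.do_blank_subtraction:
            matrix = subtract_blank_background(matrix, meta)
            log.info("blank subtraction: %d proteins retain signal", matrix.n_proteins)
        else:
            keep = [s for s in matrix.sample_ids if s in set(meta.cell_ids)]
            matrix = type(matrix)(matrix.data[keep])
            log.info("blank subtraction skipped; blank columns dropped")

        stage = "depth_filter"
        matrix, sample_counts = filter_samples_by_depth(matrix, config.min_proteins)
        artifacts["qc_sample_counts.tsv"] = out / "qc_sample_counts.tsv"
        _write_tsv(sample_counts, artifacts["qc_sample_counts.tsv"])
        meta_kept = meta.subset(matrix.sample_ids + meta.blank_ids)
        log.info("depth filter (>= %d): %d samples kept", config.min_proteins,
                 matrix.n_samples)

        stage = "detection_filter"
        matrix = filter_proteins_by_detection(matrix, meta_kept, config.min_reps)
        artifacts["matrix_filtered.tsv"] = out / "matrix_filtered.tsv"
        write_protein_matrix(matrix, artifacts["matrix_filtered.tsv"])
        log.info("detection filter (>= %d reps): %d proteins kept",
                 config.min_reps, matrix.n_proteins)

        stage = "qc_overlap"
        shared, only_a, only_b = overlap_counts(matrix, meta_kept)
        groups = meta_kept.groups
        artifacts["qc_overlap.tsv"] = out / "qc_overlap.tsv"
        _write_tsv(
            pd.DataFrame(
                [{"shared": shared, f"only_{groups[0]}": only_a,
                  f"only_{groups[1]}": only_b}]
            ),
            artifacts["qc_overlap.tsv"],
        )

        stage = "log2_center"
        log2m = log2_and_center(matrix)

        stage = "impute"
        params = estimate_global_params(log2m, config.shift, config.width)
        log.info(
            "imputation params: mu_obs=%.5f sigma_obs=%.5f mu_imp=%.5f sigma_imp=%.5f",
            params.mu_obs, params.sigma_obs, params.mu_imp, params.sigma_imp,
        )
        complete = impute_left_censored(log2m, params, seed=config.seed)
        artifacts["matrix_imputed.tsv"] = out / "matrix_imputed.tsv"
        complete.to_csv(artifacts["matrix_imputed.tsv"], sep="\t",
                        lineterminator="\n")

        stage = "batch_correction"
        if config.do_batch_correction:
            complete, bparams = combat_adjust(complete, meta_kept)
            log.info("batch correction: batches %s, iterations %s",
                     bparams.batches, bparams.n_iter)
        else:
            log.info("batch correction skipped")
        artifacts["matrix_corrected.tsv"] = out / "matrix_corrected.tsv"
        complete.to_csv(artifacts["matrix_corrected.tsv"], sep="\t",
                        lineterminator="\n")

        stage = "qc_correlation"
        corr = correlation_matrix(complete)
        artifacts["qc_correlation.tsv"] = out / "qc_correlation.tsv"
        corr.to_csv(artifacts["qc_correlation.tsv"], sep="\t", lineterminator="\n")

        stage = "differential"
        table = differential_table(
            complete, meta_kept, fdr_threshold=config.fdr, fc_threshold=config.fc
        )
        artifacts["differential_table.tsv"] = out / "differential_table.tsv"
        _write_tsv(table.table, artifacts["differential_table.tsv"])
        n_up, n_down = len(table.up), len(table.down)
        log.info("DEPs at FDR<%g, |FC|>=%g: %d up, %d down",
                 config.fdr, config.fc, n_up, n_down)

        stage = "top_k_zscore"
        k = min(60, int((table.table["q"].notna()).sum()))
        zdf, _ = zscore_top_k(complete, table, k=k)
        artifacts["top_proteins_zscore.tsv"] = out / "top_proteins_zscore.tsv"
        zdf.to_csv(artifacts["top_proteins_zscore.tsv"], sep="\t",
                   lineterminator="\n")

        stage = "group_separation"
        sep = group_separation(complete, meta_kept)
        log.info("PCA-silhouette group separation: %.4f", sep)

        stage = "ora"
        study = table.up if config.hub_direction == "up" else table.down
        population = list(complete.index)
        if config.do_ora and config.gene_sets:
            sets = read_gmt(config.gene_sets)
            records = ora_hypergeometric(study, population, sets, config.ora_p)
            ora_df = enrichment_to_frame(records)
        else:
            ora_df = pd.DataFrame(
                columns=["term", "N", "K", "n", "k", "fold_enrichment",
                         "p", "q", "significant"]
            )
        artifacts["ora_results.tsv"] = out / "ora_results.tsv"
        _write_tsv(ora_df, artifacts["ora_results.tsv"])

        stage = "gsea"
        if config.do_gsea and config.gene_sets:
            sets = read_gmt(config.gene_sets)
            if config.gsea_set_filter:
                sets = sets.filter_names(config.gsea_set_filter)
                log.info("GSEA set filter %r: %d sets retained",
                         config.gsea_set_filter, len(sets))
            ranked = table.table
            results = gsea_run(
                ranked["protein_id"].tolist(),
                ranked["t"].tolist(),
                sets,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
                fdr_threshold=config.gsea_fdr,
            )
            gsea_df = gsea_to_frame(results)
        else:
            gsea_df = pd.DataFrame(
                columns=["term", "size", "es", "nes", "p_perm", "fdr",
                         "significant", "leading_edge", "warning"]
            )
        artifacts["gsea_results.tsv"] = out / "gsea_results.tsv"
        _write_tsv(gsea_df, artifacts["gsea_results.tsv"])

        stage = "hubs"
        if config.do_hubs and config.edge_list:
            g = read_edge_list(config.edge_list, min_score=config.min_score)
            sub = g.subgraph([p for p in study if p in g]).copy()
            hub_table = mcc_scores(sub)
            hubs = top_hubs(hub_table, min(config.hub_k, max(len(hub_table), 1))) \
                if len(hub_table) else []
            log.info("hub subnetwork: %d nodes, top hubs %s",
                     sub.number_of_nodes(), hubs)
        else:
            hub_table = pd.DataFrame(columns=["node", "mcc", "degree", "rank"])
        artifacts["hub_table.tsv"] = out / "hub_table.tsv"
        _write_tsv(hub_table, artifacts["hub_table.tsv"])

        stage = "category_tally"
        if config.annotations:
            ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
            tally = category_tally(study, ann)
        else:
            tally = pd.DataFrame(columns=["category", "count", "fraction"])
        artifacts["category_tally.tsv"] = out / "category_tally.tsv"
        _write_tsv(tally, artifacts["category_tally.tsv"])

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "imputation_params": {
                "mu_obs": params.mu_obs,
                "sigma_obs": params.sigma_obs,
                "mu_imp": params.mu_imp,
                "sigma_imp": params.sigma_imp,
            },
            "group_separation_silhouette": sep,
            "n_up": n_up,
            "n_down": n_down,
            "stage_order": [
                "read", "blank_subtraction", "depth_filter", "detection_filter",
                "log2_center", "impute", "batch_correction", "differential",
                "qc", "ora", "gsea", "hubs", "category_tally",
            ],
            "digests": {name: _sha256(p) for name, p in sorted(artifacts.items())},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("run complete: %d artifacts", len(artifacts))
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        log.error("stage %s failed: %s", stage, exc)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
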