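"""Protein matrix / metadata I/O, blank subtraction, depth and detection
filters, and sample-level QC summaries.

Matrices are proteins x samples on the linear intensity scale; missing
values are ``NaN``. Zeros and empty fields in input files are converted to
missing at read time. All writers emit UTF-8 text with Unix newlines and
use ``repr(float)`` so that write -> read -> write round-trips are
byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "SampleMetadata",
    "QCReport",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "subtract_blank_background",
    "filter_samples_by_depth",
    "filter_proteins_by_detection",
    "overlap_counts",
    "correlation_matrix",
]


def _format_value(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return repr(float(v))


@dataclass
class IntensityMatrix:
    """Linear-scale protein intensities with explicit missingness.

    ``data`` is a proteins x samples DataFrame; index holds protein ids,
    columns hold sample ids, NaN marks missing. Every stored value is
    strictly positive or missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        bad = np.argwhere(vals <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive intensity at protein {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where a value is observed)."""
        return self.data.notna()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy())


@dataclass
class SampleMetadata:
    """Per-sample design table: group, acquisition batch, blank flag."""

    table: pd.DataFrame  # columns: sample_id, group, batch, is_blank

    REQUIRED = ("sample_id", "group", "batch", "is_blank")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        nonblank = t[~t["is_blank"]]
        if (nonblank["group"].astype(str).str.len() == 0).any():
            bad = nonblank.loc[
                nonblank["group"].astype(str).str.len() == 0, "sample_id"
            ].iloc[0]
            raise ValueError(f"non-blank sample {bad!r} has no group label")
        if (nonblank["batch"].astype(str).str.len() == 0).any():
            bad = nonblank.loc[
                nonblank["batch"].astype(str).str.len() == 0, "sample_id"
            ].iloc[0]
            raise ValueError(f"non-blank sample {bad!r} has no batch label")
        groups = sorted(nonblank["group"].unique())
        if len(groups) > 2:
            raise ValueError(
                f"two-group design required; found groups {groups}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["is_blank"], "sample_id"])

    @property
    def blank_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_blank"], "sample_id"])

    @property
    def groups(self) -> list[str]:
        """Sorted distinct group labels among non-blank samples."""
        return sorted(self.table.loc[~self.table["is_blank"], "group"].unique())

    def group_of(self) -> pd.Series:
        nb = self.table[~self.table["is_blank"]]
        return pd.Series(nb["group"].values, index=nb["sample_id"].values)

    def batch_of(self) -> pd.Series:
        nb = self.table[~self.table["is_blank"]]
        return pd.Series(nb["batch"].values, index=nb["sample_id"].values)

    def samples_in_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.loc[(~t["is_blank"]) & (t["group"] == group), "sample_id"])

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return SampleMetadata(self.table[keep].reset_index(drop=True))


@dataclass
class QCReport:
    """Container for the QC summaries: per-sample identification counts,
    retained/excluded flags, group overlap counts, and a pairwise Pearson
    correlation matrix."""

    sample_counts: pd.DataFrame | None = None  # sample_id, n_proteins, retained, reason
    overlap: tuple[int, int, int] | None = None  # (shared, only_a, only_b)
    correlation: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers / writers


def read_protein_matrix(path) -> IntensityMatrix:
    """Read a tab-separated protein x sample matrix.

    First column: protein ids; header row: sample ids. Empty fields and
    zeros become missing. Negative values are rejected with coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "protein_id"
    # Python float() is correctly rounded, so repr-formatted files
    # round-trip bit-exactly (pandas' fast parser does not guarantee this)
    vals = df.apply(
        lambda c: c.map(lambda s: np.nan if pd.isna(s) or s == "" else float(s))
    ).astype(float)
    neg = np.argwhere(vals.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative intensity at protein {vals.index[i]!r}, "
            f"sample {vals.columns[j]!r}"
        )
    vals = vals.mask(vals == 0.0)
    return IntensityMatrix(vals)


def write_protein_matrix(m: IntensityMatrix, path) -> None:
    df = m.data
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\t" + "\t".join(map(str, df.columns)) + "\n")
        arr = df.to_numpy(dtype=float)
        for pid, row in zip(df.index, arr):
            fh.write(str(pid) + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no", ""}


def read_sample_metadata(path) -> SampleMetadata:
    """Read the sample metadata TSV (sample_id, group, batch, is_blank)."""
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SampleMetadata.REQUIRED if c not in t.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")

    def _to_bool(v: str) -> bool:
        if v in _TRUE:
            return True
        if v in _FALSE:
            return False
        raise ValueError(f"unrecognised is_blank value: {v!r}")

    t["is_blank"] = t["is_blank"].map(_to_bool)
    return SampleMetadata(t)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\tbatch\tis_blank\n")
        for _, r in meta.table.iterrows():
            fh.write(
                f"{r['sample_id']}\t{r['group']}\t{r['batch']}\t{int(r['is_blank'])}\n"
            )


def validate_matrix_metadata(m: IntensityMatrix, meta: SampleMetadata) -> None:
    """Every matrix sample must appear in the metadata."""
    known = set(meta.sample_ids)
    absent = [s for s in m.sample_ids if s not in known]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")


# ---------------------------------------------------------------------------
# Filtering pipeline


def subtract_blank_background(
    m: IntensityMatrix, meta: SampleMetadata
) -> IntensityMatrix:
    """Subtract the per-protein mean procedural-blank intensity.

    For each protein the mean linear intensity across blank samples
    (missing treated as 0) is subtracted from every cell sample; results
    <= 0 become missing. Blank columns are dropped from the output.
    """
    validate_matrix_metadata(m, meta)
    blanks = [s for s in meta.blank_ids if s in m.data.columns]
    if not blanks:
        raise ValueError(
            "no blank samples present; skip blank subtraction explicitly "
            "instead of calling it"
        )
    cells = [s for s in m.sample_ids if s not in set(blanks)]
    blank_mean = m.data[blanks].fillna(0.0).mean(axis=1)
    out = m.data[cells].sub(blank_mean, axis=0)
    out = out.mask(out <= 0.0)
    return IntensityMatrix(out)


def filter_samples_by_depth(
    m: IntensityMatrix, min_proteins: int = 900
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Drop samples with fewer than ``min_proteins`` protein identifications.

    A sample with exactly ``min_proteins`` identifications is retained
    (the rule excludes strictly "fewer than"). Returns the filtered matrix
    and a per-sample report fragment.
    """
    if min_proteins < 0:
        raise ValueError("min_proteins must be >= 0")
    counts = m.data.notna().sum(axis=0)
    retained = counts >= min_proteins
    report = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "n_proteins": counts.values,
            "retained": retained.values,
            "reason": [
                "" if ok else f"fewer than {min_proteins} protein identifications"
                for ok in retained.values
            ],
        }
    )
    keep = [s for s, ok in zip(m.sample_ids, retained.values) if ok]
    if not keep:
        raise ValueError(
            f"all samples excluded at min_proteins={min_proteins}; "
            "no sample survives the depth filter"
        )
    return IntensityMatrix(m.data[keep]), report


def filter_proteins_by_detection(
    m: IntensityMatrix, meta: SampleMetadata, min_reps: int = 4
) -> IntensityMatrix:
    """Keep proteins detected in >= ``min_reps`` replicates of at least one
    biological group."""
    groups = meta.groups
    if len(groups) != 2:
        raise ValueError(f"two groups required, found {groups}")
    in_matrix = set(m.sample_ids)
    ga = [s for s in meta.samples_in_group(groups[0]) if s in in_matrix]
    gb = [s for s in meta.samples_in_group(groups[1]) if s in in_matrix]
    if min_reps > len(ga) and min_reps > len(gb):
        raise ValueError(
            f"min_reps={min_reps} exceeds both group sizes "
            f"({len(ga)}, {len(gb)}); no protein can pass"
        )
    na = m.data[ga].notna().sum(axis=1)
    nb = m.data[gb].notna().sum(axis=1)
    keep = (na >= min_reps) | (nb >= min_reps)
    return IntensityMatrix(m.data[keep])


def overlap_counts(
    m: IntensityMatrix, meta: SampleMetadata
) -> tuple[int, int, int]:
    """(shared, only_a, only_b) detection overlap between the two groups.

    A protein counts as detected in a group if observed in >= 1 of its
    samples. Groups are taken in sorted label order.
    """
    groups = meta.groups
    if len(groups) != 2:
        raise ValueError(f"two groups required, found {groups}")
    in_matrix = set(m.sample_ids)
    ga = [s for s in meta.samples_in_group(groups[0]) if s in in_matrix]
    gb = [s for s in meta.samples_in_group(groups[1]) if s in in_matrix]
    det_a = set(m.data.index[m.data[ga].notna().any(axis=1)])
    det_b = set(m.data.index[m.data[gb].notna().any(axis=1)])
    return (
        len(det_a & det_b),
        len(det_a - det_b),
        len(det_b - det_a),
    )


def correlation_matrix(
    log2_matrix: pd.DataFrame, min_overlap: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples of a log2-scale matrix.

    Correlations are computed over proteins observed in both samples of a
    pair (pairwise-complete). Pairs with fewer than ``min_overlap``
    mutually observed proteins get NaN with a warning. On a complete
    (post-imputation) matrix this reduces to the all-protein correlation.
    """
    if log2_matrix.shape[1] < 2:
        raise ValueError("at least two samples required")
    corr = log2_matrix.corr(method="pearson", min_periods=min_overlap)
    n_obs = log2_matrix.notna().astype(int)
    overlap = n_obs.T @ n_obs
    thin = (overlap < min_overlap).to_numpy()
    np.fill_diagonal(thin, False)
    if thin.any():
        warnings.warn(
            "some sample pairs share fewer than "
            f"{min_overlap} observed proteins; their correlation is missing",
            stacklevel=2,
        )
    np.fill_diagonal(corr.values, 1.0)
    return corr
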