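"""Readers and writers for expression matrices, IHC core tables, clinical
tables, and loaders for the bundled reference fixtures.

Expression matrices are tab-delimited text with genes in rows and samples in
columns; the first row holds sample identifiers and the first column gene
symbols.  Values are assumed to be on log2 scale already — no transformation
is applied on read or write.  IHC core-level scores and clinical outcome
tables travel as CSV with the column names documented on the respective
reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The marker panel used on tissue microarray cores.  Ki67 travels in a
#: separate percent channel and is not an Allred-scored marker.
ALLRED_MARKERS = (
    "ER", "PR", "HER2", "CK5", "EGFR",
    "CLDN3", "CLDN4", "CLDN7", "ECAD",
    "CD24", "CD44", "ALDH1",
)

#: Allred raw scores are intensity (0-3) plus proportion category (0-5);
#: a raw score of 1 cannot occur (intensity >= 1 forces proportion >= 1).
VALID_ALLRED_RAW = frozenset({0, 2, 3, 4, 5, 6, 7, 8})


class ParseError(ValueError):
    """A cell in an input file could not be interpreted."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression matrix with optional annotations.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample identifiers as
        columns.  All entries must be finite.
    batch_labels
        Optional per-sample batch category, indexed by sample id.
    subtype_labels
        Optional per-sample molecular-subtype label, indexed by sample id.
        Samples without a label carry NaN.
    """

    values: pd.DataFrame
    batch_labels: pd.Series | None = None
    subtype_labels: pd.Series | None = None
    housekeeping_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:10]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:10]}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        for name in ("batch_labels", "subtype_labels"):
            lab = getattr(self, name)
            if lab is not None and not lab.index.equals(v.columns):
                lab = lab.reindex(v.columns)
                setattr(self, name, lab)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[ids].copy(),
            batch_labels=None if self.batch_labels is None else self.batch_labels[ids].copy(),
            subtype_labels=None if self.subtype_labels is None else self.subtype_labels[ids].copy(),
            housekeeping_genes=list(self.housekeeping_genes),
        )


@dataclass(frozen=True)
class SignatureGene:
    """One gene of the claudin-low signature with its direction of change
    (``up`` or ``down``) in claudin-low tumors relative to all other
    molecular subtypes."""

    symbol: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited genes-by-samples expression file.

    Duplicate gene symbols are collapsed by taking the per-sample maximum
    (the same convention used for replicate IHC cores); the number of
    collapsed rows is logged.  Duplicate sample ids and non-numeric body
    cells are errors.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = pd.Index(header[1:])
    if sample_ids.has_duplicates:
        dupes = sample_ids[sample_ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate sample ids in {path}: {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & ~raw[col].isna()
        if bad.any() or converted.isna().any():
            gene = raw.index[(bad | converted.isna()).to_numpy().argmax()]
            cell = raw.loc[gene, col]
            raise ParseError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: {cell!r}"
            )
        numeric[col] = converted
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        numeric = numeric.groupby(level=0, sort=False).max()
        logger.info(
            "collapsed %d duplicate gene rows by per-sample maximum",
            n_before - len(numeric),
        )
    return ExpressionMatrix(values=numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a tab-delimited genes-by-samples file (inverse of the reader)."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# IHC core-level scores

CORE_COLUMNS = ["tumor_id", "core_index", "marker", "allred_raw", "ki67_percent", "fish_ratio"]


def read_core_scores(path: str | Path) -> pd.DataFrame:
    """Read a core-level IHC score CSV.

    Expected columns: ``tumor_id``, ``core_index`` (1-3), ``marker`` (one of
    the Allred panel or ``KI67``), ``allred_raw`` (0 or 2-8, empty when the
    core is a Ki67 count), ``ki67_percent`` (0-100, only for KI67 rows),
    ``fish_ratio`` (positive, HER2/CEP17, only meaningful for HER2 rows).
    Missing cores are absent rows, never zero scores.
    """
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"core score file missing columns: {missing}")
    df = df[CORE_COLUMNS].copy()
    df["tumor_id"] = df["tumor_id"].astype(str)
    df["core_index"] = df["core_index"].astype(int)
    if not df["core_index"].between(1, 3).all():
        raise ParseError("core_index must be in 1..3")
    bad_marker = ~df["marker"].isin(list(ALLRED_MARKERS) + ["KI67"])
    if bad_marker.any():
        raise ParseError(f"unknown markers: {sorted(df.loc[bad_marker, 'marker'].unique())}")
    scored = df["allred_raw"].notna()
    if not df.loc[scored, "allred_raw"].isin(list(VALID_ALLRED_RAW)).all():
        bad = sorted(set(df.loc[scored, "allred_raw"]) - set(VALID_ALLRED_RAW))
        raise ParseError(f"invalid Allred raw scores (1 is unrepresentable): {bad}")
    return df


def write_core_scores(df: pd.DataFrame, path: str | Path) -> None:
    df[CORE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clinical records

CLINICAL_COLUMNS = [
    "tumor_id", "age_years", "tumor_size_cm", "grade", "lvi",
    "lymphocytic_infiltrate", "circumscribed_margin", "adjuvant",
    "os_time", "os_event", "dfs_time", "dfs_event", "lr_time", "lr_event",
]

GRADES = ("I", "II", "III")
INFILTRATE_LEVELS = ("none", "minimal", "moderate", "extensive")
ADJUVANT_ARMS = ("tamoxifen", "chemotherapy", "none")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical/outcome CSV (one row per tumor).

    Time columns are in years; event columns are 0/1.  Grade is I/II/III,
    lymphocytic infiltrate one of none/minimal/moderate/extensive, adjuvant
    one of tamoxifen/chemotherapy/none.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"clinical file missing columns: {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    df["tumor_id"] = df["tumor_id"].astype(str)
    if df["tumor_id"].duplicated().any():
        raise ParseError("duplicate tumor_id in clinical table")
    for col in ("os_time", "dfs_time", "lr_time"):
        if (df[col] < 0).any():
            raise ParseError(f"negative follow-up time in {col}")
    for col in ("os_event", "dfs_event", "lr_event", "lvi", "circumscribed_margin"):
        df[col] = df[col].astype(bool)
    if not df["grade"].isin(GRADES).all():
        raise ParseError("grade must be I, II or III")
    if not df["lymphocytic_infiltrate"].isin(INFILTRATE_LEVELS).all():
        raise ParseError(f"lymphocytic_infiltrate must be one of {INFILTRATE_LEVELS}")
    if not df["adjuvant"].isin(ADJUVANT_ARMS).all():
        raise ParseError(f"adjuvant must be one of {ADJUVANT_ARMS}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Signature read/write and bundled fixtures


def read_signature(path: str | Path) -> list[SignatureGene]:
    """Read a two-column ``symbol,direction`` CSV into signature genes."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["symbol", "direction"]:
        raise ParseError("signature file must have columns symbol,direction")
    if df["symbol"].duplicated().any():
        raise ParseError("duplicate symbols in signature file")
    return [SignatureGene(row.symbol, row.direction) for row in df.itertuples()]


def write_signature(genes: Iterable[SignatureGene], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.symbol, g.direction) for g in genes], columns=["symbol", "direction"]
    )
    df.to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("claudinlow.data").joinpath(name)


def load_cl_signature() -> list[SignatureGene]:
    """The published 60-gene claudin-low signature (bundled fixture).

    23 genes up-regulated and 37 down-regulated in claudin-low tumors
    relative to all other molecular subtypes.
    """
    with resources.as_file(_data_path("cl_signature_60gene.csv")) as p:
        return read_signature(p)


def load_cell_line_profiles() -> Mapping[str, dict]:
    """Allred profiles of the nine reference breast cancer cell lines.

    Returns a mapping from cell-line name to a dict with keys
    ``declared_subtype`` (the subtype each line is known to model) and
    ``scores`` (marker -> Allred raw score over the 10-marker panel).
    """
    with resources.as_file(_data_path("cell_line_allred.csv")) as p:
        df = pd.read_csv(p)
    out: dict[str, dict] = {}
    markers = [c for c in df.columns if c not in ("cell_line", "declared_subtype")]
    for row in df.itertuples():
        out[row.cell_line] = {
            "declared_subtype": row.declared_subtype,
            "scores": {m: int(getattr(row, m)) for m in markers},
        }
    return out
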