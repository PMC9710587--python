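"""Data model and file I/O for connectivity-mapping inputs and outputs.

Three input objects drive a stratified connectivity analysis:

* a :class:`QueryMatrix` of log fold-changes (genes x contrasts),
* a :class:`ReferenceDatabase` of perturbation profiles (genes x experiments)
  whose column headers encode the perturbagen as a prefix
  (``drug@profileID`` or ``drug_profileID``),
* an :class:`AnnotationTable` mapping drugs to mechanism-of-action (MoA)
  labels and target genes.

Matrices are read from tab-delimited text (gene identifiers in the first
column) or GCT v1.2 (the ``#1.2`` two-line-header dialect). Results are
written as a flat tab-delimited table, one row per (level, contrast, name).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "QueryMatrix",
    "ReferenceDatabase",
    "AnnotationTable",
    "parse_profile_id",
    "read_query",
    "read_reference",
    "read_annotation",
    "write_query",
    "write_reference",
    "write_result_table",
    "read_result_table",
]

#: Column order of the result table on disk.
RESULT_COLUMNS = [
    "level",
    "contrast",
    "name",
    "set_size",
    "es",
    "nes",
    "pval",
    "qval",
    "leading_edge",
]


@dataclass
class QueryMatrix:
    """A genes x contrasts matrix of real-valued fold changes (the query *y*).

    Parameters
    ----------
    gene_ids
        Row identifiers; unique after whitespace trimming.
    values
        Array of shape ``(len(gene_ids), len(contrast_names))``. NaN marks
        a missing measurement.
    contrast_names
        One name per column.
    """

    gene_ids: list[str]
    values: np.ndarray
    contrast_names: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.contrast_names = [str(c) for c in self.contrast_names]
        if self.values.shape != (len(self.gene_ids), len(self.contrast_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.contrast_names)} contrasts"
            )
        if len(self.contrast_names) < 1:
            raise ValueError("a query needs at least one contrast")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers in query")
        if np.isinf(self.values).any():
            raise ValueError("query values must be finite or NaN")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.contrast_names)

    def negated(self) -> "QueryMatrix":
        """Sign-flipped copy (the signature-reversal direction)."""
        return QueryMatrix(list(self.gene_ids), -self.values, list(self.contrast_names))


@dataclass
class ReferenceDatabase:
    """A genes x experiments perturbation matrix with perturbagen grouping.

    ``experiment_ids`` keeps the full original column headers; ``drug_of``
    maps each header to the perturbagen name recovered by
    :func:`parse_profile_id`.
    """

    gene_ids: list[str]
    values: np.ndarray
    experiment_ids: list[str]
    drug_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.experiment_ids = [str(e) for e in self.experiment_ids]
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        if len(set(self.experiment_ids)) != len(self.experiment_ids):
            raise ValueError("duplicate experiment identifiers in reference")
        if not self.drug_of:
            self.drug_of = {
                e: parse_profile_id(e)[0] for e in self.experiment_ids
            }
        missing = [e for e in self.experiment_ids if e not in self.drug_of]
        if missing:
            raise ValueError(f"experiments without a drug mapping: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    @property
    def drugs(self) -> list[str]:
        """Distinct perturbagen names, in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.experiment_ids:
            seen.setdefault(self.drug_of[e], None)
        return list(seen)

    def experiments_of(self, drug: str) -> list[str]:
        return [e for e in self.experiment_ids if self.drug_of[e] == drug]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)


@dataclass
class AnnotationTable:
    """Drug annotations: MoA labels and target genes per drug.

    A drug with an empty label set simply contributes to no MoA (or target)
    grouping; it still occupies a rank position in the compound ranking.
    """

    drugs: list[str]
    moa_labels: dict[str, set[str]]
    target_genes: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug rows in annotation table")
        for d in self.drugs:
            self.moa_labels.setdefault(d, set())
            self.target_genes.setdefault(d, set())

    def moa_sets(self) -> dict[str, set[str]]:
        """Invert the annotation: MoA label -> set of drugs carrying it."""
        out: dict[str, set[str]] = {}
        for d in self.drugs:
            for m in self.moa_labels[d]:
                out.setdefault(m, set()).add(d)
        return out

    def target_sets(self) -> dict[str, set[str]]:
        """Invert the annotation: target gene -> set of drugs annotated to it."""
        out: dict[str, set[str]] = {}
        for d in self.drugs:
            for t in self.target_genes[d]:
                out.setdefault(t, set()).add(d)
        return out


def parse_profile_id(header: str) -> tuple[str, str]:
    """Split a reference column header into (drug, profile id).

    ``'@'`` takes precedence over ``'_'`` (profile identifiers routinely
    contain underscores, e.g. ``CPC004_PC3_6H``); the split happens at the
    FIRST occurrence of the separator. A header with neither separator is
    used verbatim as both drug and profile id, with a warning, so that toy
    inputs still work.
    """
    if not header:
        raise ValueError("empty profile header")
    if "@" in header:
        drug, profile = header.split("@", 1)
    elif "_" in header:
        drug, profile = header.split("_", 1)
    else:
        warnings.warn(
            f"profile header {header!r} has no '@' or '_' separator; "
            "using the whole header as the drug name",
            stacklevel=2,
        )
        return header, header
    return drug, profile


def _read_matrix_frame(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a TSV or GCT v1.2 matrix into a DataFrame (genes x columns)."""
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    fmt = fmt.lower()
    if fmt == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            nrow, ncol = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        # column 1 is the Description field of GCT v1.2
        df = df.iloc[:, 1:]
        if df.shape != (nrow, ncol):
            raise ValueError(
                f"GCT header promises {nrow}x{ncol}, file holds {df.shape}"
            )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gctx":
        df = _read_gctx_frame(path)
    else:
        raise ValueError(f"unknown matrix format: {fmt!r}")
    if df.shape[1] == 0:
        raise ValueError(f"{path} contains no data columns")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str).str.strip()
    return df


def _read_gctx_frame(path: str | Path) -> pd.DataFrame:
    """Optional GCTX (HDF5) reader behind the same interface; needs h5py."""
    import h5py  # optional extra

    with h5py.File(path, "r") as f:
        mat = f["0/DATA/0/matrix"][...]
        rows = [s.decode() if isinstance(s, bytes) else str(s)
                for s in f["0/META/ROW/id"][...]]
        cols = [s.decode() if isinstance(s, bytes) else str(s)
                for s in f["0/META/COL/id"][...]]
    if mat.shape == (len(cols), len(rows)):
        mat = mat.T
    return pd.DataFrame(mat, index=rows, columns=cols)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene id, the row with the largest |mean| value."""
    if not df.index.duplicated().any():
        return df
    score = df.mean(axis=1, skipna=True).abs().to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(score).groupby(df.index.to_numpy(), sort=False).idxmax()
    keep[order.to_numpy()] = True
    return df.loc[keep]


def read_query(path: str | Path, fmt: str | None = None) -> QueryMatrix:
    """Read a query fold-change matrix from TSV or GCT.

    Non-numeric cells become missing (NaN); duplicate gene rows are
    collapsed to the row with the largest mean absolute value; an
    all-missing contrast column is an error.
    """
    df = _read_matrix_frame(path, fmt)
    df = _collapse_duplicate_genes(df)
    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        raise ValueError(f"all-missing contrast column(s): {empty}")
    return QueryMatrix(list(df.index), df.to_numpy(dtype=float), list(df.columns))


def _raw_headers(path: Path, fmt: str | None) -> list[str]:
    """Column headers exactly as they appear on disk (pandas de-duplicates)."""
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gctx":
        return []  # HDF5 ids cannot silently collide in the same way
    with open(path, encoding="utf-8") as fh:
        if fmt == "gct":
            fh.readline()
            fh.readline()
            header = fh.readline().rstrip("\n").split("\t")[2:]
        else:
            header = fh.readline().rstrip("\n").split("\t")[1:]
    return header


def read_reference(path: str | Path, fmt: str | None = None) -> ReferenceDatabase:
    """Read a reference perturbation matrix; headers are parsed for drugs."""
    path = Path(path)
    headers = _raw_headers(path, fmt)
    if len(set(headers)) != len(headers):
        seen: set[str] = set()
        dupes: list[str] = []
        for h in headers:
            if h in seen:
                dupes.append(h)
            seen.add(h)
        raise ValueError(f"duplicate experiment identifiers: {dupes[:5]}")
    df = _read_matrix_frame(path, fmt)
    df = _collapse_duplicate_genes(df)
    return ReferenceDatabase(
        list(df.index), df.to_numpy(dtype=float), [str(c) for c in df.columns]
    )


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a drug annotation table (CSV or TSV, sniffed).

    Requires columns ``drug``, ``moa`` and ``target`` (case-insensitive).
    Multi-valued MoA / target cells are split on ``'|'`` and whitespace is
    trimmed; empty cells yield empty sets.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("drug", "moa", "target"):
        if required not in cols:
            raise ValueError(f"missing column: {required}")

    def split_cell(cell: object) -> set[str]:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return set()
        parts = [p.strip() for p in str(cell).split("|")]
        return {p for p in parts if p}

    drugs: list[str] = []
    moa: dict[str, set[str]] = {}
    targets: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        d = str(row[cols["drug"]]).strip()
        drugs.append(d)
        moa[d] = split_cell(row[cols["moa"]])
        targets[d] = split_cell(row[cols["target"]])
    return AnnotationTable(drugs, moa, targets)


def write_query(query: QueryMatrix, path: str | Path) -> None:
    query.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def write_reference(ref: ReferenceDatabase, path: str | Path) -> None:
    ref.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV.

    Rows are sorted by level, then contrast, then descending NES with ties
    broken by name ascending; the leading edge is '|'-joined.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty result table")
    df = results.copy()
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table lacks columns: {missing}")
    if df["leading_edge"].map(lambda v: isinstance(v, (list, tuple, set))).any():
        df["leading_edge"] = df["leading_edge"].map(
            lambda v: "|".join(v) if isinstance(v, (list, tuple)) else
            ("|".join(sorted(v)) if isinstance(v, set) else v)
        )
    df = df.sort_values(
        by=["level", "contrast", "nes", "name"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    df[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_result_table`."""
    df = pd.read_csv(path, sep="\t")
    df["leading_edge"] = df["leading_edge"].map(
        lambda v: [] if pd.isna(v) or v == "" else str(v).split("|")
    )
    return df
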