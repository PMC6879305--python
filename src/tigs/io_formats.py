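"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices arrive as TSV/CSV (genes in rows, samples in columns)
or GCT 1.2; gene sets as GMT; somatic mutations as MAF; clinical and score
tables as TSV.  All loaders validate the invariants the downstream scoring
code relies on (unique identifiers, finite values, controlled mutation
vocabulary) and fail loudly with the offending coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


#: MAF Variant_Classification controlled vocabulary (TCGA dialect).
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Splice_Site",
        "Splice_Region",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene symbols (HGNC, matched case-sensitively downstream).
    sample_ids : list of str
        Unique sample identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite, real-valued expression.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])


@dataclass
class GeneSet:
    """A named list of gene symbols (duplicates removed on construction)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        dups = []
        for g in self.genes:
            if g in seen:
                dups.append(g)
            seen[g] = None
        if dups:
            warnings.warn(
                f"gene set {self.name!r}: removed duplicate genes {sorted(set(dups))}"
            )
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MutationRecord:
    sample_id: str
    gene_symbol: str
    variant_classification: str


@dataclass
class MutationTable:
    """Per-sample somatic variant records from a MAF file.

    ``unknown_classes`` lists Variant_Classification strings outside the
    controlled vocabulary; their records are preserved but flagged.
    """

    records: list[MutationRecord]
    unknown_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = sorted(
            {r.variant_classification for r in self.records}
            - set(MAF_VARIANT_CLASSES)
        )
        if unknown:
            self.unknown_classes = unknown
            warnings.warn(
                f"mutation table contains classifications outside the MAF "
                f"vocabulary: {unknown}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Tumor_Sample_Barcode": [r.sample_id for r in self.records],
                "Hugo_Symbol": [r.gene_symbol for r in self.records],
                "Variant_Classification": [
                    r.variant_classification for r in self.records
                ],
            }
        )


@dataclass
class ClinicalTable:
    """Per-sample immunotherapy outcome data.

    response : 1 = responder, 0 = non-responder, NaN = missing.
    os_time  : overall-survival time in study units, >= 0.
    os_event : 1 = death observed, 0 = censored.
    """

    sample_ids: list[str]
    response: np.ndarray
    os_time: np.ndarray
    os_event: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.response) == len(self.os_time) == len(self.os_event) == n):
            raise ValueError("clinical columns must align with sample_ids")
        if np.any(self.os_time < 0):
            raise ValueError("os_time must be >= 0")
        if not np.all(np.isin(self.os_event[~np.isnan(self.os_event)], (0, 1))):
            raise ValueError("os_event must be 0 (censored) or 1 (death)")
        obs = self.response[~np.isnan(self.response)]
        if not np.all(np.isin(obs, (0, 1))):
            raise ValueError("response must be 0, 1, or missing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "response": self.response,
                "os_time": self.os_time,
                "os_event": self.os_event,
            }
        ).set_index("sample_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClinicalTable":
        return cls(
            list(df.index),
            df["response"].to_numpy(dtype=float),
            df["os_time"].to_numpy(dtype=float),
            df["os_event"].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# Expression matrices


def _collapse_duplicate_genes(df: pd.DataFrame, rule: str) -> pd.DataFrame:
    dup_mask = df.index.duplicated(keep=False)
    if not dup_mask.any():
        return df
    dups = sorted(set(df.index[dup_mask]))
    if rule == "max_mean":
        # keep, per symbol, the row with the highest mean expression
        order = df.mean(axis=1).to_numpy()
        keep = (
            pd.DataFrame({"gene": df.index, "mean": order, "pos": range(len(df))})
            .sort_values(["gene", "mean"], kind="stable")
            .groupby("gene", sort=False)
            .tail(1)
            .sort_values("pos")["pos"]
            .to_numpy()
        )
        out = df.iloc[keep]
    elif rule == "mean":
        out = df.groupby(level=0, sort=False).mean()
    elif rule == "first":
        out = df[~df.index.duplicated(keep="first")]
    else:
        raise ValueError(f"unknown duplicate-gene collapse rule {rule!r}")
    logger.info(
        "collapsed %d duplicate gene symbols (%s) by rule %r",
        len(dups),
        dups[:5],
        rule,
    )
    return out


def _finalize_expression(
    df: pd.DataFrame, duplicate_rule: str, drop_incomplete_genes: bool
) -> ExpressionMatrix:
    non_numeric = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = non_numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric expression value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    df = non_numeric
    if df.isna().any().any():
        if drop_incomplete_genes:
            before = len(df)
            df = df.dropna(axis=0)
            logger.info("dropped %d genes with missing values", before - len(df))
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            raise FormatError(
                f"expression matrix has missing values (e.g. gene {gene!r}); "
                "enrichment scoring requires complete columns — pass "
                "drop_incomplete_genes=True to pre-filter"
            )
    df = _collapse_duplicate_genes(df, duplicate_rule)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    logger.info("expression matrix: %d genes x %d samples", *df.shape)
    return ExpressionMatrix.from_frame(df)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise FormatError(f"GCT version line must be '#1.2', got {version!r}")
        dims = fh.readline().rstrip("\n").split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (IndexError, ValueError):
            raise FormatError(f"malformed GCT dimension line: {dims!r}") from None
        body = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in body.columns:
        body = body.drop(columns="Description")
    else:
        # second column is the description regardless of its header
        body = body.drop(columns=body.columns[0])
    if body.shape != (n_genes, n_samples):
        raise FormatError(
            f"GCT declares {n_genes} genes x {n_samples} samples but the body "
            f"has shape {body.shape[0]} x {body.shape[1]}"
        )
    return body


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    *,
    duplicate_rule: str = "max_mean",
    drop_incomplete_genes: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    Parameters
    ----------
    path : str or Path
    format : {"tsv", "csv", "gct"}, optional
        Inferred from the file suffix when omitted.
    duplicate_rule : {"max_mean", "mean", "first"}
        How duplicate gene symbols are collapsed.  The default keeps the
        row with the highest mean expression — the usual convention for
        multi-probe microarray data.
    drop_incomplete_genes : bool
        If True, genes with any missing value are dropped before
        validation instead of raising.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "tsv"
    format = format.lower()
    if format == "gct":
        df = _read_gct(path)
    elif format in ("tsv", "txt"):
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif format == "csv":
        df = pd.read_csv(path, sep=",", index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: no columns parsed; malformed header?")
    return _finalize_expression(df, duplicate_rule, drop_incomplete_genes)


def write_expression_matrix(path: str | Path, expr: ExpressionMatrix) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per tab-separated line
    (name, description, gene, gene, ...); the description is discarded."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}, line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[2:]))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# MAF


_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(path: str | Path) -> MutationTable:
    """Load a (TCGA-dialect) MAF mutation table.

    Requires Hugo_Symbol, Tumor_Sample_Barcode and Variant_Classification
    columns (matched case-insensitively); leading '#' comment lines are
    skipped.  Only those three columns are consumed.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    colmap = {c.lower(): c for c in df.columns}
    missing = [c for c in _MAF_REQUIRED if c.lower() not in colmap]
    if missing:
        raise FormatError(f"{path}: MAF is missing required column(s) {missing}")
    records = [
        MutationRecord(sample_id=s, gene_symbol=g, variant_classification=v)
        for g, s, v in zip(
            df[colmap["hugo_symbol"]],
            df[colmap["tumor_sample_barcode"]],
            df[colmap["variant_classification"]],
        )
    ]
    logger.info("read %d mutation records from %s", len(records), path)
    return MutationTable(records)


def write_maf(path: str | Path, muts: MutationTable) -> None:
    muts.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical and score tables


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("response", "os_time", "os_event"):
        if col not in df.columns:
            raise FormatError(f"{path}: clinical table is missing column {col!r}")
    return ClinicalTable.from_frame(df)


def write_clinical(path: str | Path, clin: ClinicalTable) -> None:
    clin.to_frame().to_csv(path, sep="\t")


def write_scores(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-sample score table as TSV at full float precision.

    Missing entries are emitted as empty cells, never as zero, so the
    write/read round trip is value-exact (repr-precision floats).
    """
    if table.empty:
        raise ValueError("refusing to write an empty score table")
    # default float formatting is shortest-round-trip repr; paired with
    # round_trip parsing below the cycle is value-exact
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col="sample_id", float_precision="round_trip"
    )
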