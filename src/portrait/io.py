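"""Readers, writers and the shared tabular data model.

Four kinds of tables flow through the pipeline:

* :class:`LabeledMatrix` — a features x samples numeric grid (expression,
  protein abundance, per-gene copy number) with optional per-sample
  annotations.  Missing entries are ``NaN`` and are always distinguished
  from zero.
* :class:`SegmentTable` — per-sample copy-number segments on the
  ``log2(CN/2)`` scale, 1-based inclusive coordinates (SEG convention).
* :class:`MutationTable` — per-sample somatic variant records (MAF
  convention, 1-based positions).
* :class:`CoverageTable` — per-sample sequencing-coverage intervals in
  0-based half-open BED convention, so covered bases = end - start.

Chromosome labels are normalized on read: a leading ``chr`` is stripped,
sex chromosomes are upper-cased, and mitochondrial records are dropped by
default (array and sequencing sources disagree on dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

_MITO_LABELS = {"MT", "M"}


def normalize_chromosome(label: str) -> str:
    """Map a chromosome label to the package-wide dialect (no ``chr``, X/Y upper)."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in ("x", "y", "mt", "m") else s


# ---------------------------------------------------------------------------
# LabeledMatrix


@dataclass
class LabeledMatrix:
    """Features x samples numeric grid with optional sample annotations.

    ``data`` rows are features, columns are samples; missing entries are NaN.
    """

    data: pd.DataFrame
    sample_annotations: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


def read_matrix(path: str | Path) -> LabeledMatrix:
    """Read a tab-delimited matrix: first column feature ids, first row sample ids.

    Empty cells become missing (NaN), never zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric cell in matrix {path}: {exc}") from exc
    return LabeledMatrix(values)


def write_matrix(matrix: LabeledMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "feature_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", na_rep="")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited sample annotation table keyed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError("annotation table lacks a sample_id column")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# SegmentTable

SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "segment_mean"]
_SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "seg.mean"]


@dataclass
class SegmentTable:
    """Per-sample copy-number segments, 1-based inclusive, log2(CN/2) means."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)[SEG_COLUMNS].astype(
            {"sample_id": str, "chromosome": str, "start": np.int64,
             "end": np.int64, "segment_mean": float}
        )
        self.validate()

    def validate(self) -> None:
        df = self.df
        bad = df["start"] > df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"segment start > end at record {i}")
        if not np.isfinite(df["segment_mean"]).all():
            raise ValidationError("non-finite segment mean")
        for (sample, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"overlapping segments for sample {sample!r} on chromosome {chrom}"
                )

    def for_sample(self, sample_id: str) -> "SegmentTable":
        return SegmentTable(self.df[self.df["sample_id"] == sample_id])

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    def lengths(self) -> np.ndarray:
        """Segment lengths in bases (1-based inclusive: end - start + 1)."""
        return (self.df["end"] - self.df["start"] + 1).to_numpy()


def read_seg(path: str | Path, *, keep_mito: bool = False) -> SegmentTable:
    """Read a tab-delimited SEG file (ID, chrom, loc.start, loc.end, seg.mean)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5:
            raise SchemaError(f"SEG header has {len(header)} columns, expected >= 5")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError("too few columns", line=lineno)
            sample, chrom, start_s, end_s, mean_s = parts[:5]
            try:
                start, end, mean = int(start_s), int(end_s), float(mean_s)
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if start > end:
                raise ParseError(f"start {start} > end {end}", line=lineno)
            chrom = normalize_chromosome(chrom)
            if not keep_mito and chrom in _MITO_LABELS:
                continue
            rows.append((sample, chrom, start, end, mean))
    return SegmentTable(pd.DataFrame(rows, columns=SEG_COLUMNS))


def write_seg(table: SegmentTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SEG_HEADER) + "\n")
        for row in table.df.itertuples(index=False):
            fh.write(
                f"{row.sample_id}\t{row.chromosome}\t{row.start}\t{row.end}\t"
                f"{row.segment_mean!r}\n"
            )


# ---------------------------------------------------------------------------
# MutationTable

MUTATION_COLUMNS = [
    "sample_id", "gene_id", "chromosome", "position", "ref_allele",
    "alt_allele", "variant_classification", "somatic", "context",
]

_MAF_REQUIRED = [
    "Hugo_Symbol", "Chromosome", "Start_position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "Mutation_Status",
]

_BASES = set("ACGT")


@dataclass
class MutationTable:
    """Per-sample variant records (MAF-style, 1-based positions)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in MUTATION_COLUMNS:
            if col not in df.columns:
                if col == "context":
                    df["context"] = pd.NA
                else:
                    raise SchemaError(f"MutationTable missing column {col!r}")
        self.df = df[MUTATION_COLUMNS].astype(
            {"sample_id": str, "gene_id": str, "chromosome": str,
             "position": np.int64, "ref_allele": str, "alt_allele": str,
             "variant_classification": str, "somatic": bool}
        )
        self.validate()

    def validate(self) -> None:
        df = self.df
        same = df["ref_allele"] == df["alt_allele"]
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise ValidationError(
                f"record {i}: reference allele equals alternate allele"
            )
        ctx = df["context"].dropna()
        for i, c in ctx.items():
            c = str(c)
            if len(c) != 5:
                raise ValidationError(f"record {i}: context {c!r} is not 5 bases")
            if c[2] != df.at[i, "ref_allele"]:
                raise ValidationError(
                    f"record {i}: context middle base {c[2]!r} != ref "
                    f"{df.at[i, 'ref_allele']!r}"
                )

    def is_snv(self) -> pd.Series:
        """True for single-base substitutions (both alleles one of ACGT)."""
        return self.df["ref_allele"].isin(_BASES) & self.df["alt_allele"].isin(_BASES)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))


def read_maf(path: str | Path, *, keep_mito: bool = False) -> MutationTable:
    """Read a minimal TCGA-style MAF (tab-delimited, # comment lines allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"MAF missing mandatory columns: {', '.join(missing)}")
    sample_col = "Tumor_Sample_Barcode" if "Tumor_Sample_Barcode" in df.columns else None
    if sample_col is None:
        raise SchemaError("MAF missing mandatory columns: Tumor_Sample_Barcode")
    out = pd.DataFrame(
        {
            "sample_id": df[sample_col],
            "gene_id": df["Hugo_Symbol"],
            "chromosome": df["Chromosome"].map(normalize_chromosome),
            "position": pd.to_numeric(df["Start_position"]),
            "ref_allele": df["Reference_Allele"].str.upper(),
            "alt_allele": df["Tumor_Seq_Allele2"].str.upper(),
            "variant_classification": df["Variant_Classification"],
            "somatic": df["Mutation_Status"].str.lower() == "somatic",
            "context": df["context"].replace("", pd.NA) if "context" in df.columns else pd.NA,
        }
    )
    if not keep_mito:
        out = out[~out["chromosome"].isin(_MITO_LABELS)]
    return MutationTable(out)


def write_maf(table: MutationTable, path: str | Path) -> None:
    df = table.df
    out = pd.DataFrame(
        {
            "Hugo_Symbol": df["gene_id"],
            "Chromosome": df["chromosome"],
            "Start_position": df["position"],
            "Reference_Allele": df["ref_allele"],
            "Tumor_Seq_Allele2": df["alt_allele"],
            "Variant_Classification": df["variant_classification"],
            "Mutation_Status": np.where(df["somatic"], "Somatic", "Germline"),
            "Tumor_Sample_Barcode": df["sample_id"],
            "context": df["context"].fillna(""),
        }
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CoverageTable

COVERAGE_COLUMNS = ["sample_id", "chromosome", "start", "end"]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent-overlapping 0-based half-open intervals."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s, dtype=np.int64), np.array(merged_e, dtype=np.int64)


@dataclass
class CoverageTable:
    """Per-sample covered intervals, 0-based half-open; normalized on build."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)[COVERAGE_COLUMNS].astype(
            {"sample_id": str, "chromosome": str, "start": np.int64, "end": np.int64}
        )
        if (df["start"] >= df["end"]).any():
            i = int(np.flatnonzero(df["start"] >= df["end"])[0])
            raise ValidationError(f"coverage record {i}: start >= end")
        rows = []
        for (sample, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
            s, e = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
            rows.append(pd.DataFrame(
                {"sample_id": sample, "chromosome": chrom, "start": s, "end": e}
            ))
        self.df = (
            pd.concat(rows, ignore_index=True)
            if rows else pd.DataFrame(columns=COVERAGE_COLUMNS).astype(
                {"sample_id": str, "chromosome": str, "start": np.int64, "end": np.int64})
        )

    def covered_bases(self, sample_id: str) -> int:
        sub = self.df[self.df["sample_id"] == sample_id]
        return int((sub["end"] - sub["start"]).sum())

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))


def read_bed_coverage(
    path: str | Path, *, sample_id: str | None = None, keep_mito: bool = False
) -> CoverageTable:
    """Read coverage intervals from BED3 (one sample, pass ``sample_id``) or a
    4-column (sample, chrom, start, end) table.  Intervals are merged per sample."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if sample_id is not None:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    sample = sample_id
                else:
                    sample, chrom, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", line=lineno)
            chrom = normalize_chromosome(chrom)
            if not keep_mito and chrom in _MITO_LABELS:
                continue
            rows.append((sample, chrom, start, end))
    return CoverageTable(pd.DataFrame(rows, columns=COVERAGE_COLUMNS))


def write_bed_coverage(table: CoverageTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(f"{row.sample_id}\t{row.chromosome}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# GeneModelTable

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end"]


@dataclass
class GeneModelTable:
    """Gene coordinates (1-based inclusive) used for segment-to-gene mapping."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)[GENE_COLUMNS].astype(
            {"gene_id": str, "chromosome": str, "start": np.int64, "end": np.int64}
        )
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if (df["start"] > df["end"]).any():
            raise ValidationError("gene model with start > end")
        self.df = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df["gene_id"])


def read_gene_models(path: str | Path) -> GeneModelTable:
    """Read gene models from BED4 (chrom, start, end, gene_id; 0-based half-open)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except (IndexError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
            # BED half-open -> 1-based inclusive
            rows.append((gene, normalize_chromosome(chrom), start + 1, end))
    return GeneModelTable(pd.DataFrame(rows, columns=GENE_COLUMNS))


def write_gene_models(table: GeneModelTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")
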