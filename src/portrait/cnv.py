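"""Copy-number layer: genome-altered fraction, segment-to-gene mapping,
amplification/deletion calls, and CNV similarity (score component B).

Segment means are on the log2(CN/2) scale (0 = diploid).  The fraction of
genome altered (FGA) for a sample is

    FGA = sum of L(i) over segments with |mean_i| > T  /  sum of all L(i)

with L(i) the segment length in bases and T a cutoff chosen per cohort (cell
lines carry more aberrations than tumors, so their cutoff sits higher).
Per-gene copy number is the overlap-length-weighted mean of the segments a
gene intersects; the similarity layer then correlates cell lines against
tumors over the most variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .correlate import PairwiseCorrelationTable, pairwise_correlation
from .errors import UndefinedResultError
from .io import GeneModelTable, LabeledMatrix, SegmentTable

DEFAULT_FGA_THRESHOLD_TUMOR = 0.2
DEFAULT_FGA_THRESHOLD_CELL = 0.3
AMP_CUTOFF = 0.3   # per-gene segment mean above which a gene is called amplified
DEL_CUTOFF = -0.3  # and below which it is called deleted


@dataclass(frozen=True)
class FgaParams:
    threshold: float = DEFAULT_FGA_THRESHOLD_TUMOR

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("FGA threshold must be > 0")


def compute_fga(segments: SegmentTable, params: FgaParams | float = FgaParams()) -> float:
    """Fraction of total segment length with |segment mean| above the cutoff.

    ``segments`` must hold exactly one sample's records.
    """
    if isinstance(params, (int, float)):
        params = FgaParams(float(params))
    df = segments.df
    if len(df) == 0:
        raise UndefinedResultError("FGA undefined on an empty segment set")
    if df["sample_id"].nunique() > 1:
        raise ValueError("compute_fga expects segments of a single sample")
    lengths = segments.lengths().astype(float)
    altered = np.abs(df["segment_mean"].to_numpy()) > params.threshold
    return float(lengths[altered].sum() / lengths.sum())


def fga_per_sample(segments: SegmentTable, params: FgaParams | float = FgaParams()) -> pd.Series:
    return pd.Series(
        {s: compute_fga(segments.for_sample(s), params) for s in segments.sample_ids},
        name="fga",
    )


def map_segments_to_genes(segments: SegmentTable, genes: GeneModelTable) -> LabeledMatrix:
    """Per-gene, per-sample overlap-length-weighted mean segment value.

    Genes with no overlapping segment in a sample are missing.  Coordinates on
    both sides are 1-based inclusive, so the overlap of segment [s1,e1] and
    gene [s2,e2] covers max(0, min(e1,e2) - max(s1,s2) + 1) bases.
    """
    gene_ids = genes.gene_ids
    samples = segments.sample_ids
    values = np.full((len(gene_ids), len(samples)), np.nan)
    gene_rows = {g: i for i, g in enumerate(gene_ids)}
    genes_by_chrom = dict(tuple(genes.df.groupby("chromosome", sort=False)))
    for j, sample in enumerate(samples):
        sub = segments.df[segments.df["sample_id"] == sample]
        for chrom, seg in sub.groupby("chromosome", sort=False):
            gsub = genes_by_chrom.get(chrom)
            if gsub is None:
                continue
            seg = seg.sort_values("start")
            s_start = seg["start"].to_numpy()
            s_end = seg["end"].to_numpy()
            s_mean = seg["segment_mean"].to_numpy()
            for g_id, g_start, g_end in zip(
                gsub["gene_id"], gsub["start"].to_numpy(), gsub["end"].to_numpy()
            ):
                # segments are sorted and non-overlapping within a sample
                lo = np.searchsorted(s_end, g_start, side="left")
                hi = np.searchsorted(s_start, g_end, side="right")
                if lo >= hi:
                    continue
                ov = (
                    np.minimum(s_end[lo:hi], g_end)
                    - np.maximum(s_start[lo:hi], g_start)
                    + 1
                ).astype(float)
                keep = ov > 0
                if not keep.any():
                    continue
                values[gene_rows[g_id], j] = float(
                    np.average(s_mean[lo:hi][keep], weights=ov[keep])
                )
    return LabeledMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))


def call_cnv(matrix: LabeledMatrix) -> pd.DataFrame:
    """Threshold per-gene values into 'amplified' / 'deleted' / 'neutral' calls.

    Missing values stay missing.
    """
    v = matrix.data
    calls = pd.DataFrame(
        np.select([v > AMP_CUTOFF, v < DEL_CUTOFF], ["amplified", "deleted"], "neutral"),
        index=v.index, columns=v.columns, dtype=object,
    )
    return calls.mask(v.isna())


def alteration_frequency(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fractions of non-missing samples called amplified / deleted."""
    present = calls.notna().sum(axis=1)
    amp = calls.eq("amplified").sum(axis=1) / present.where(present > 0)
    dele = calls.eq("deleted").sum(axis=1) / present.where(present > 0)
    return pd.DataFrame({"amp_fraction": amp, "del_fraction": dele})


def select_top_variable(
    matrix: LabeledMatrix, fraction: float = 0.10, *, n_genes: int | None = None
) -> list[str]:
    """Genes ranked by variance across all samples; the top slice is returned.

    ``fraction`` of the eligible genes (>= 2 observed values), rounded up, or
    an explicit ``n_genes`` override.  Ties break lexicographically.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    data = matrix.data
    eligible = data.notna().sum(axis=1) >= 2
    var = data.loc[eligible].var(axis=1, ddof=1, skipna=True)
    ranked = var.sort_index().sort_values(ascending=False, kind="stable")
    k = n_genes if n_genes is not None else ceil(fraction * len(ranked))
    return list(ranked.index[:k])


def cnv_similarity(
    cells: LabeledMatrix,
    tumors: LabeledMatrix,
    genes: list[str] | None = None,
    *,
    top_fraction: float = 0.10,
) -> PairwiseCorrelationTable:
    """Pearson r per (cell, tumor) pair over the selected high-variance genes.

    Without an explicit gene list, the top ``top_fraction`` genes by variance
    over the pooled cohorts are used, so both cohorts see one gene set.
    """
    if genes is None:
        pooled = LabeledMatrix(pd.concat([cells.data, tumors.data], axis=1))
        genes = select_top_variable(pooled, top_fraction)
    return pairwise_correlation(cells, tumors, genes, layer="cnv")
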