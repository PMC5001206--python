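"""Expression-based similarity (score component A) and mRNA-vs-protein coupling.

The expression layer correlates every cell line's transcript profile against
every tumor's over the shared (optionally restricted) gene set, then averages
per cell line.  It also measures, per gene, how well transcript abundance
tracks (phospho-)protein abundance across samples profiled on both platforms:
each probe/protein-form pair gets a Pearson r across shared samples and the
pairs are averaged to one value per gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .correlate import PairwiseCorrelationTable, pairwise_correlation
from .io import LabeledMatrix

__all__ = ["expression_similarity", "aggregate_by_cell", "mrna_protein_correlation"]


def expression_similarity(
    cells: LabeledMatrix,
    tumors: LabeledMatrix,
    features: list[str] | None = None,
) -> PairwiseCorrelationTable:
    """Pearson r for each (cell line, tumor) pair over shared expressed genes."""
    return pairwise_correlation(cells, tumors, features, layer="expression")


def aggregate_by_cell(
    table: PairwiseCorrelationTable,
    restrict_subtype: dict[str, str] | None = None,
) -> pd.Series:
    """Mean correlation per cell line; optionally over same-subtype tumors only."""
    return table.mean_per_cell(restrict_subtype)


def mrna_protein_correlation(
    expr: LabeledMatrix,
    protein: LabeledMatrix,
    mapping: dict[str, list[tuple[str, str]]],
    *,
    min_samples: int = 3,
) -> pd.Series:
    """Per-gene mean Pearson r between mRNA and protein forms.

    ``mapping`` is gene id -> list of (probe id, protein id) pairs; a gene with
    multiple probes or phospho-forms gets the average over all its pairs.
    Genes with no usable pair are NaN.
    """
    shared_samples = [s for s in expr.sample_ids if s in set(protein.sample_ids)]
    out: dict[str, float] = {}
    n_skipped = 0
    for gene, pairs in mapping.items():
        rs = []
        for probe, prot in pairs:
            if probe not in expr.data.index or prot not in protein.data.index:
                continue
            x = expr.data.loc[probe, shared_samples].to_numpy(dtype=float)
            y = protein.data.loc[prot, shared_samples].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < min_samples:
                n_skipped += 1
                continue
            xs, ys = x[mask], y[mask]
            if xs.std() == 0 or ys.std() == 0:
                continue
            rs.append(float(np.corrcoef(xs, ys)[0, 1]))
        out[gene] = float(np.mean(rs)) if rs else np.nan
    if n_skipped:
        warnings.warn(
            f"{n_skipped} probe/protein pair(s) skipped: fewer than "
            f"{min_samples} complete shared samples",
            stacklevel=2,
        )
    return pd.Series(out, name="mrna_protein_r")
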