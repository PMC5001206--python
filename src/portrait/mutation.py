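"""Mutation layer: somatic filtering, per-gene binarization, burden, the
six-category substitution spectrum with flanking-context profiles, and the
binary-profile mutation similarity (score component C).

Substitutions are complement-collapsed: a G>A change is the same event as
C>T read from the opposite strand, so every record is normalized to a
reference base of A or C, giving the six categories
A>C, A>G, A>T, C>A, C>G, C>T.  Contexts (the two bases either side of the
variant) are reverse-complemented along with their record.

Binary mutation similarity is the Pearson correlation of two genes x 1
indicator columns, which equals the phi coefficient of their 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import PairwiseCorrelationTable, pairwise_correlation
from .errors import UndefinedResultError
from .io import CoverageTable, LabeledMatrix, MutationTable

SPECTRUM_CATEGORIES = ["A>C", "A>G", "A>T", "C>A", "C>G", "C>T"]
FLANK_POSITIONS = [-2, -1, 1, 2]
NUCLEOTIDES = ["A", "C", "G", "T"]

# variant classes counted as functional (protein-affecting); intronic, silent,
# UTR and other non-exonic classes are dropped
FUNCTIONAL_CLASSES = frozenset(
    {
        "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
        "Splice_Site", "Frame_Shift_Ins", "Frame_Shift_Del",
        "In_Frame_Ins", "In_Frame_Del", "Translation_Start_Site",
    }
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_somatic_functional(
    muts: MutationTable,
    germline_sites: set[tuple[str, int]] | None = None,
    *,
    functional_classes: frozenset[str] = FUNCTIONAL_CLASSES,
) -> MutationTable:
    """Keep somatic, functional records not on the germline-site blacklist.

    ``germline_sites`` is a set of (chromosome, position) pairs standing in
    for known-polymorphism databases.
    """
    df = muts.df
    keep = df["somatic"] & df["variant_classification"].isin(functional_classes)
    if germline_sites:
        at_site = [
            (c, int(p)) in germline_sites
            for c, p in zip(df["chromosome"], df["position"])
        ]
        keep &= ~np.array(at_site)
    return MutationTable(df[keep])


def binarize(
    muts: MutationTable, gene_panel: list[str], samples: list[str]
) -> LabeledMatrix:
    """Genes x samples 0/1 indicator: 1 iff the sample has >= 1 record in the gene."""
    mat = pd.DataFrame(0.0, index=list(gene_panel), columns=list(samples))
    hits = muts.df[
        muts.df["gene_id"].isin(mat.index) & muts.df["sample_id"].isin(mat.columns)
    ]
    for gene, sample in zip(hits["gene_id"], hits["sample_id"]):
        mat.at[gene, sample] = 1.0
    return LabeledMatrix(mat)


def mutation_frequency(binary: LabeledMatrix) -> pd.Series:
    """Fraction of samples carrying a mutation, per gene (row mean)."""
    if binary.shape[1] == 0:
        raise UndefinedResultError("mutation frequency needs >= 1 sample")
    return binary.data.mean(axis=1)


def mutation_rate_per_mb(
    muts: MutationTable, coverage: CoverageTable, sample: str
) -> float:
    """Mutations per megabase of covered sequence for one sample.

    Coverage intervals are merged (half-open), so double-listed intervals do
    not inflate the denominator.
    """
    bases = coverage.covered_bases(sample)
    if bases <= 0:
        raise UndefinedResultError(f"sample {sample!r} has zero covered bases")
    count = int((muts.df["sample_id"] == sample).sum())
    return count * 1e6 / bases


@dataclass
class SpectrumVector:
    """Proportions of the six complement-collapsed substitution categories."""

    proportions: pd.Series  # indexed by SPECTRUM_CATEGORIES, sums to 1

    def to_array(self) -> np.ndarray:
        return self.proportions.reindex(SPECTRUM_CATEGORIES).to_numpy()


def _collapse(ref: str, alt: str) -> str | None:
    """Map a single-base substitution to its category, or None for non-SNVs."""
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        return None
    if ref in "GT":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    return f"{ref}>{alt}"


def spectrum(muts: MutationTable) -> SpectrumVector:
    """Six-category substitution proportions over all single-base records."""
    cats = [
        c
        for c in (
            _collapse(r, a) for r, a in zip(muts.df["ref_allele"], muts.df["alt_allele"])
        )
        if c is not None
    ]
    if not cats:
        raise UndefinedResultError("no single-base substitutions in input")
    counts = pd.Series(cats).value_counts().reindex(SPECTRUM_CATEGORIES, fill_value=0)
    return SpectrumVector(counts / counts.sum())


@dataclass
class ContextProfile:
    """Per category, nucleotide proportions at the four flanking positions.

    ``grids[category]`` is a 4 nucleotides x 4 positions DataFrame whose
    columns (positions -2, -1, +1, +2) each sum to 1 when data is present.
    """

    grids: dict[str, pd.DataFrame]
    n_missing_context: int = 0

    def flatten(self, categories: list[str] | None = None) -> np.ndarray:
        cats = categories if categories is not None else sorted(self.grids)
        return np.concatenate([self.grids[c].to_numpy().ravel() for c in cats])


def context_profile(muts: MutationTable) -> ContextProfile:
    """Flanking-base composition (+-2 bp) per substitution category.

    Records whose reference base collapses from G/T have their context
    reverse-complemented so both strands contribute to one profile.  Records
    without a context string are skipped and counted.
    """
    counts = {
        c: pd.DataFrame(0.0, index=NUCLEOTIDES, columns=FLANK_POSITIONS)
        for c in SPECTRUM_CATEGORIES
    }
    n_missing = 0
    any_data = False
    for row in muts.df.itertuples(index=False):
        cat = _collapse(row.ref_allele, row.alt_allele)
        if cat is None:
            continue
        ctx = row.context
        if not isinstance(ctx, str) or len(ctx) != 5:
            n_missing += 1
            continue
        if row.ref_allele in "GT":
            ctx = reverse_complement(ctx)
        for pos, base in zip(FLANK_POSITIONS, (ctx[0], ctx[1], ctx[3], ctx[4])):
            if base in NUCLEOTIDES:
                counts[cat].at[base, pos] += 1.0
                any_data = True
    if not any_data:
        raise UndefinedResultError("no substitution records carry context strings")
    grids = {}
    for cat, grid in counts.items():
        totals = grid.sum(axis=0)
        grids[cat] = grid / totals.where(totals > 0)
    return ContextProfile(grids, n_missing_context=n_missing)


def spectrum_correlation(a: np.ndarray | SpectrumVector, b: np.ndarray | SpectrumVector) -> float:
    """Pearson r between two spectra (or flattened context profiles)."""
    x = a.to_array() if isinstance(a, SpectrumVector) else np.asarray(a, dtype=float)
    y = b.to_array() if isinstance(b, SpectrumVector) else np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("spectra must have the same dimension")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        raise UndefinedResultError("correlation undefined for constant spectra")
    return float(np.corrcoef(x, y)[0, 1])


def mutation_similarity(
    cells_binary: LabeledMatrix, tumors_binary: LabeledMatrix
) -> PairwiseCorrelationTable:
    """Pearson r (= phi coefficient) between binary mutation profiles.

    Pairs where either column is constant over the shared panel are NaN.
    """
    return pairwise_correlation(cells_binary, tumors_binary, layer="mutation")


def subtype_spectra(
    muts: MutationTable, subtype_map: dict[str, str]
) -> dict[str, SpectrumVector]:
    """Pooled spectrum per subtype (records of all the subtype's samples)."""
    out = {}
    labels = muts.df["sample_id"].map(subtype_map)
    for subtype in sorted(set(subtype_map.values())):
        sub = MutationTable(muts.df[labels == subtype])
        if len(sub.df):
            try:
                out[subtype] = spectrum(sub)
            except UndefinedResultError:
                continue
    return out
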