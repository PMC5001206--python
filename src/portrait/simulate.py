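"""Synthetic matched tumor / cell-line cohorts.

The generator emits every table the comparison pipeline consumes —
subtype-structured expression, piecewise-constant copy-number segments with
recurrent chromosome-level events, somatic substitutions with a configurable
six-category spectrum and flanking contexts, per-sample coverage intervals,
and protein values coupled to mRNA at a tunable correlation — together with
a truth table, so every analysis stage can be validated against planted
structure without any external download.

Structure emulated (qualitatively) from the real cohorts it stands in for:

* four intrinsic subtypes with expression centroids separated well beyond
  the within-subtype noise;
* recurrent amplification on chromosomes 1 and 8 and deletion on 13 and 16
  as cohort-defining hallmark events (always present, amplitudes varying
  segment to segment), plus one weaker subtype-specific event each;
* cell lines mirror tumors only partially: extra expression noise, a
  multiplier on copy-number effect sizes, noisier segment amplitudes and
  private culture-acquired chromosome events, a higher mutation rate, and
  extra protein noise — so a cell line that is an exact copy of a tumor is
  the best attainable model of the cohort;
* a C>T / C>G dominated substitution spectrum;
* protein abundance tracking mRNA at Pearson ``protein_coupling_r`` on the
  tumor side.

Determinism: one integer seed fully determines the cohort.  Each sample
draws from its own child random stream keyed by (subtype, kind, index), so
enlarging the cohort never perturbs previously generated samples; setup
(centroids, genome layout) and protein noise use separate keyed streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .correlate import pairwise_correlation
from .errors import UndefinedResultError, ValidationError
from .io import (
    CoverageTable,
    GeneModelTable,
    LabeledMatrix,
    MutationTable,
    SegmentTable,
)
from .mutation import SPECTRUM_CATEGORIES, reverse_complement
from .subtyping import SubtypeCall

# autosome lengths in Mb, proportional to the human karyotype (rounded)
KARYOTYPE_MB: dict[str, int] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 134, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 102, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51,
}

DEFAULT_SUBTYPES = ("LuminalA", "LuminalB", "HER2amp", "BasalLike")

# one recurrent chromosome-level event per subtype, disjoint from the shared
# chromosome 1/8 amplifications and 13/16 deletions
DEFAULT_SUBTYPE_EVENTS: dict[str, tuple[str, int]] = {
    "LuminalA": ("5", +1),
    "LuminalB": ("11", +1),
    "HER2amp": ("17", +1),
    "BasalLike": ("4", -1),
}

# mutations per Mb per subtype (Luminal B highest, Luminal A lowest)
DEFAULT_MUTATION_RATES: dict[str, float] = {
    "LuminalA": 1.2, "LuminalB": 3.0, "HER2amp": 2.5, "BasalLike": 2.0,
}

DEFAULT_SPECTRUM_WEIGHTS = (0.05, 0.15, 0.05, 0.10, 0.20, 0.45)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator parameters; the defaults define the reference study conditions."""

    seed: int = 0
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    n_tumors_per_subtype: int = 40
    n_cells_per_subtype: int = 8

    # expression
    n_genes: int = 500
    n_marker_genes: int = 50          # per-subtype signature block
    centroid_separation: float = 5.0  # log-intensity units added on a subtype's block
    expression_noise_sd: float = 1.0
    cell_noise_multiplier: float = 3.5  # culture/platform noise on top of biology

    # copy number
    chromosome_lengths_mb: Mapping[str, int] = field(
        default_factory=lambda: dict(KARYOTYPE_MB)
    )
    n_segments_per_chromosome: int = 10
    segment_noise_sd: float = 0.05
    shared_amp_chromosomes: tuple[str, ...] = ("1", "8")
    shared_del_chromosomes: tuple[str, ...] = ("13", "16")
    shared_event_prob: float = 1.0
    subtype_events: Mapping[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_EVENTS)
    )
    subtype_event_prob: float = 1.0
    subtype_event_effect: float = 0.3  # weaker than the shared hallmark events
    cnv_effect: float = 0.5
    cnv_amplitude_cv: float = 0.5  # event amplitudes vary sample to sample
    cell_aberration_multiplier: float = 1.3
    cell_private_event_prob: float = 0.3  # per-chromosome culture-acquired events
    cell_cnv_noise_multiplier: float = 2.0  # instability: noisier segment amplitudes

    # mutations
    mutation_rate_per_mb: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    cell_mutation_multiplier: float = 1.5
    spectrum_weights: tuple[float, ...] = DEFAULT_SPECTRUM_WEIGHTS
    panel_size: int = 150             # sequenced genes (coverage + binary matrix)
    panel_gene_length: int = 200_000  # bases of covered sequence per panel gene
    n_driver_genes_per_subtype: int = 5
    driver_enrichment: float = 5.0    # mutation-placement weight on driver genes

    # proteins
    n_protein_genes: int = 38
    n_proteins: int = 50
    protein_coupling_r: float = 0.7   # tumor-side mRNA/protein Pearson target
    protein_noise_floor: float = 0.02
    cell_protein_noise_multiplier: float = 4.0

    clone_cell_from_tumor: bool = False  # append a cell line copied from tumor 1

    def validate(self) -> None:
        w = np.asarray(self.spectrum_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValidationError("spectrum_weights must be 6 non-negative values summing to 1")
        if not 0 <= self.protein_coupling_r <= 1:
            raise ValidationError("protein_coupling_r must lie in [0, 1]")
        if self.protein_coupling_r == 1.0 and self.protein_noise_floor > 0:
            raise ValidationError(
                "protein_coupling_r = 1 is unattainable with a positive noise floor"
            )
        if self.cell_aberration_multiplier < 1 or self.cell_mutation_multiplier < 0:
            raise ValidationError("multipliers must be >= 1 (aberration) / >= 0 (mutation)")
        if self.expression_noise_sd < 0 or self.centroid_separation < 0:
            raise ValidationError("noise sd and separation must be >= 0")
        if self.n_proteins < self.n_protein_genes:
            raise ValidationError("n_proteins must be >= n_protein_genes")
        if self.n_genes < len(self.subtypes) * self.n_marker_genes:
            raise ValidationError("n_genes too small for the marker blocks")
        per_block = -(-self.n_protein_genes // len(self.subtypes))
        if per_block > self.n_marker_genes:
            raise ValidationError("marker blocks too small for the protein panel")

    def rate_for(self, subtype: str) -> float:
        if isinstance(self.mutation_rate_per_mb, Mapping):
            return float(self.mutation_rate_per_mb[subtype])
        return float(self.mutation_rate_per_mb)


@dataclass
class SyntheticCohort:
    """All generated tables plus the planted truth."""

    config: SimConfig
    expression: LabeledMatrix
    segments: SegmentTable
    mutations: MutationTable
    coverage: CoverageTable
    proteins: LabeledMatrix
    truth: pd.DataFrame  # index sample_id; columns kind, subtype, source_tumor
    centroids: LabeledMatrix
    gene_models: GeneModelTable
    protein_mapping: dict[str, list[tuple[str, str]]]

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.truth.index[self.truth["kind"] == "tumor"])

    @property
    def cell_ids(self) -> list[str]:
        return list(self.truth.index[self.truth["kind"] == "cell"])

    def subtype_map(self) -> dict[str, str]:
        return dict(self.truth["subtype"])


def _gene_layout(config: SimConfig) -> GeneModelTable:
    """Place genes evenly along the chromosomes, proportional to length."""
    chroms = list(config.chromosome_lengths_mb)
    lengths = np.array([config.chromosome_lengths_mb[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(config.n_genes * lengths / lengths.sum())).astype(int)
    # adjust the largest chromosome so the total is exact
    counts[0] += config.n_genes - counts.sum()
    rows, g = [], 0
    for chrom, n in zip(chroms, counts):
        span = config.chromosome_lengths_mb[chrom] * 1_000_000
        spacing = span // (n + 1)
        glen = min(config.panel_gene_length, max(1000, spacing // 2))
        for i in range(n):
            start = (i + 1) * spacing
            rows.append((f"g{g:04d}", chrom, start, start + glen - 1))
            g += 1
    return GeneModelTable(pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"]))


def _panel_genes(config: SimConfig, genes: GeneModelTable) -> list[str]:
    """An evenly spread subset of genes is 'sequenced' (covered)."""
    ids = genes.gene_ids
    step = max(1, len(ids) // config.panel_size)
    return ids[::step][: config.panel_size]


def _chromosome_events(
    config: SimConfig, subtype: str, is_cell: bool, rng: np.random.Generator
) -> dict[str, float]:
    """Draw the per-chromosome baseline shifts for one sample."""
    mult = config.cell_aberration_multiplier if is_cell else 1.0
    effect = config.cnv_effect * mult  # segment-level jitter applied downstream
    shifts: dict[str, float] = {}
    for chrom in config.shared_amp_chromosomes:
        if rng.random() < config.shared_event_prob:
            shifts[chrom] = effect
    for chrom in config.shared_del_chromosomes:
        if rng.random() < config.shared_event_prob:
            shifts[chrom] = -effect
    ev = config.subtype_events.get(subtype)
    if ev is not None:
        chrom, sign = ev
        if rng.random() < config.subtype_event_prob:
            shifts[chrom] = shifts.get(chrom, 0.0) + sign * config.subtype_event_effect * mult
    if is_cell:
        # culture-acquired private aberrations, uncorrelated with the tumors
        for chrom in config.chromosome_lengths_mb:
            if rng.random() < config.cell_private_event_prob:
                sign = 1 if rng.random() < 0.5 else -1
                shifts[chrom] = shifts.get(chrom, 0.0) + sign * effect
    return shifts


def _sample_segments(
    config: SimConfig,
    sample_id: str,
    shifts: dict[str, float],
    rng: np.random.Generator,
    *,
    is_cell: bool = False,
) -> list[tuple[str, str, int, int, float]]:
    rows = []
    jitter_sd = config.cnv_amplitude_cv * (
        config.cell_cnv_noise_multiplier if is_cell else 1.0
    )
    for chrom, mb in config.chromosome_lengths_mb.items():
        span = mb * 1_000_000
        k = config.n_segments_per_chromosome
        cuts = np.sort(rng.integers(2, span, size=k - 1)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate(([1], cuts, [span + 1]))
        base = shifts.get(chrom, 0.0)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            # segment-level re-jitter of the event amplitude: segmentation of a
            # real aberrant chromosome yields a staircase, not one flat level
            seg_base = base * max(0.1, rng.normal(1.0, jitter_sd))
            mean = seg_base + rng.normal(0.0, config.segment_noise_sd)
            rows.append((sample_id, chrom, int(lo), int(hi - 1), float(mean)))
    return rows


def _sample_mutations(
    config: SimConfig,
    sample_id: str,
    subtype: str,
    is_cell: bool,
    panel: pd.DataFrame,
    driver_weights: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple]:
    gene_lengths = (panel["end"] - panel["start"] + 1).to_numpy(dtype=float)
    covered_mb = gene_lengths.sum() / 1e6
    rate = config.rate_for(subtype) * (config.cell_mutation_multiplier if is_cell else 1.0)
    n = int(rng.poisson(rate * covered_mb))
    if n == 0:
        return []
    weights = gene_lengths * driver_weights
    weights = weights / weights.sum()
    gene_idx = rng.choice(len(panel), size=n, p=weights)
    cats = rng.choice(6, size=n, p=np.asarray(config.spectrum_weights, dtype=float))
    flip = rng.random(n) < 0.5  # report half the events on the opposite strand
    offsets = rng.random(n)  # fractional position within the chosen gene
    flank_idx = rng.integers(0, 4, size=(n, 4))
    rows = []
    alts = {"A>C": "C", "A>G": "G", "A>T": "T", "C>A": "A", "C>G": "G", "C>T": "T"}
    for i in range(n):
        cat = SPECTRUM_CATEGORIES[cats[i]]
        ref, alt = cat[0], alts[cat]
        gene = panel.iloc[int(gene_idx[i])]
        pos = int(gene["start"]) + int(offsets[i] * gene_lengths[int(gene_idx[i])])
        f = _BASES[flank_idx[i]]
        context = f"{f[0]}{f[1]}{ref}{f[2]}{f[3]}"
        if flip[i]:
            context = reverse_complement(context)
            ref, alt = context[2], alt.translate(str.maketrans("ACGT", "TGCA"))
        rows.append(
            (sample_id, gene["gene_id"], gene["chromosome"], pos, ref, alt,
             "Missense_Mutation", True, context)
        )
    return rows


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full matched cohort deterministically from ``config.seed``."""
    config.validate()
    # independent child streams keyed by role so enlarging the cohort never
    # changes the draws of previously existing samples
    setup_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    protein_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))

    genes = _gene_layout(config)
    gene_ids = genes.gene_ids
    panel_ids = _panel_genes(config, genes)
    panel = genes.df.set_index("gene_id").loc[panel_ids].reset_index()

    # expression centroids: shared baseline + per-subtype marker block shift
    base = setup_rng.normal(8.0, 1.0, size=config.n_genes)
    centroid_values = {}
    for k, subtype in enumerate(config.subtypes):
        c = base.copy()
        block = slice(k * config.n_marker_genes, (k + 1) * config.n_marker_genes)
        c[block] += config.centroid_separation
        centroid_values[subtype] = c
    centroids = LabeledMatrix(pd.DataFrame(centroid_values, index=gene_ids))

    # per-subtype driver weights for mutation placement
    driver_weights = {}
    for k, subtype in enumerate(config.subtypes):
        w = np.ones(len(panel))
        lo = k * config.n_driver_genes_per_subtype
        w[lo: lo + config.n_driver_genes_per_subtype] = config.driver_enrichment
        driver_weights[subtype] = w

    # roster entries carry a stable spawn key (subtype index, kind, index)
    roster: list[tuple[str, str, bool, tuple[int, int, int]]] = []
    t = c = 0
    for si, subtype in enumerate(config.subtypes):
        for j in range(config.n_tumors_per_subtype):
            t += 1
            roster.append((f"T{t:04d}", subtype, False, (si, 0, j)))
        for j in range(config.n_cells_per_subtype):
            c += 1
            roster.append((f"C{c:04d}", subtype, True, (si, 1, j)))

    expr_cols: dict[str, np.ndarray] = {}
    seg_rows: list[tuple] = []
    mut_rows: list[tuple] = []
    cov_rows: list[tuple] = []
    truth_rows: list[dict] = []
    cov_template = [
        (row.chromosome, int(row.start) - 1, int(row.end))
        for row in panel.itertuples(index=False)
    ]

    for sample_id, subtype, is_cell, key in roster:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, *key)))
        noise_sd = config.expression_noise_sd * (
            config.cell_noise_multiplier if is_cell else 1.0
        )
        expr_cols[sample_id] = centroid_values[subtype] + rng.normal(
            0.0, noise_sd, size=config.n_genes
        )
        shifts = _chromosome_events(config, subtype, is_cell, rng)
        seg_rows.extend(_sample_segments(config, sample_id, shifts, rng, is_cell=is_cell))
        mut_rows.extend(
            _sample_mutations(
                config, sample_id, subtype, is_cell, panel, driver_weights[subtype], rng
            )
        )
        cov_rows.extend((sample_id, ch, s, e) for ch, s, e in cov_template)
        truth_rows.append(
            {"sample_id": sample_id, "kind": "cell" if is_cell else "tumor",
             "subtype": subtype, "source_tumor": ""}
        )

    if config.clone_cell_from_tumor:
        src_id, src_subtype = roster[0][0], roster[0][1]
        clone_id = "C_CLONE"
        expr_cols[clone_id] = expr_cols[src_id].copy()
        seg_rows.extend(
            (clone_id, ch, s, e, m)
            for sid, ch, s, e, m in seg_rows[:]
            if sid == src_id
        )
        mut_rows.extend(
            (clone_id, *rest) for sid, *rest in mut_rows[:] if sid == src_id
        )
        cov_rows.extend((clone_id, ch, s, e) for ch, s, e in cov_template)
        truth_rows.append(
            {"sample_id": clone_id, "kind": "cell", "subtype": src_subtype,
             "source_tumor": src_id}
        )

    expression = LabeledMatrix(pd.DataFrame(expr_cols, index=gene_ids))
    segments = SegmentTable(
        pd.DataFrame(seg_rows, columns=["sample_id", "chromosome", "start", "end", "segment_mean"])
    )
    mutations = MutationTable(
        pd.DataFrame(
            mut_rows,
            columns=["sample_id", "gene_id", "chromosome", "position", "ref_allele",
                     "alt_allele", "variant_classification", "somatic", "context"],
        )
        if mut_rows
        else pd.DataFrame(
            columns=["sample_id", "gene_id", "chromosome", "position", "ref_allele",
                     "alt_allele", "variant_classification", "somatic", "context"]
        ).astype({"position": np.int64, "somatic": bool})
    )
    coverage = CoverageTable(
        pd.DataFrame(cov_rows, columns=["sample_id", "chromosome", "start", "end"])
    )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")

    # proteins: protein = mRNA + noise, with the noise sd calibrated per gene
    # from the realized tumor-side mRNA variance so the expected tumor-side
    # Pearson r equals the configured coupling; cell lines get extra noise
    protein_genes = _protein_gene_ids(config)
    mapping: dict[str, list[tuple[str, str]]] = {}
    prot_rows: dict[str, np.ndarray] = {}
    sample_order = list(expression.sample_ids)
    tumor_ids = [entry[0] for entry in roster if not entry[2]]
    tumor_pos = [sample_order.index(s) for s in tumor_ids]
    is_cell_arr = np.array(
        [truth.at[s, "kind"] == "cell" for s in sample_order], dtype=bool
    )
    r = config.protein_coupling_r
    for i, gene in enumerate(protein_genes):
        n_forms = 2 if i < config.n_proteins - config.n_protein_genes else 1
        mrna = expression.data.loc[gene].to_numpy()
        sd = float(mrna[tumor_pos].std())
        if r == 0:
            noise_sd = None  # pure noise, no coupling
        else:
            noise_sd = max(config.protein_noise_floor, sd * np.sqrt(1.0 / r**2 - 1.0))
        mapping[gene] = []
        for form in range(n_forms):
            pid = f"{gene}_p" if form == 0 else f"{gene}_pS{form + 1}"
            if noise_sd is None:
                prot_rows[pid] = protein_rng.normal(0.0, 1.0, size=len(sample_order))
            else:
                eps = protein_rng.normal(0.0, noise_sd, size=len(sample_order))
                eps[is_cell_arr] *= config.cell_protein_noise_multiplier
                prot_rows[pid] = mrna + eps
            mapping[gene].append((gene, pid))
    proteins = LabeledMatrix(
        pd.DataFrame.from_dict(prot_rows, orient="index", columns=sample_order)
    )
    if config.clone_cell_from_tumor:
        # the clone is the same specimen re-assayed: copy its protein column
        proteins.data["C_CLONE"] = proteins.data[roster[0][0]]

    return SyntheticCohort(
        config=config, expression=expression, segments=segments,
        mutations=mutations, coverage=coverage, proteins=proteins,
        truth=truth, centroids=centroids, gene_models=genes,
        protein_mapping=mapping,
    )


def _protein_gene_ids(config: SimConfig) -> list[str]:
    """Protein panel drawn round-robin from the subtype marker blocks so the
    protein layer inherits the subtype structure."""
    k = len(config.subtypes)
    ids = []
    for i in range(config.n_protein_genes):
        block = i % k
        offset = i // k
        ids.append(f"g{block * config.n_marker_genes + offset:04d}")
    return ids


def _p_segment_altered(effect: float, threshold: float, config: SimConfig) -> float:
    """P(|segment mean| > threshold) for a segment whose event base is ``effect``.

    Integrates over the truncated-normal amplitude jitter and the additive
    segment noise; ``effect`` may be 0 (no event on the chromosome).
    """
    from scipy.stats import norm

    sigma = config.segment_noise_sd
    if effect == 0.0:
        return float(2 * norm.sf(threshold / sigma)) if sigma > 0 else 0.0
    # amplitude multiplier m = max(0.1, N(1, cv)); grid integration over m
    cv = config.cnv_amplitude_cv
    grid = np.linspace(-6, 6, 4001)
    m = np.maximum(0.1, 1.0 + cv * grid)
    w = norm.pdf(grid)
    w /= w.sum()
    b = abs(effect) * m
    if sigma > 0:
        p = norm.sf((threshold - b) / sigma) + norm.cdf((-threshold - b) / sigma)
    else:
        p = (b > threshold).astype(float)
    return float(np.sum(w * p))


def expected_fga(config: SimConfig, subtype: str, *, threshold: float = 0.2) -> float:
    """Expected genome-altered fraction of a tumor sample under the priors.

    Segment lengths are independent of alteration status, so the expectation
    is the length-weighted mean of the per-chromosome alteration
    probabilities.  Tumor samples only (cell private events and their
    possible cancellations are not modelled here).
    """
    events: dict[str, tuple[float, float]] = {}  # chrom -> (presence prob, effect)
    for chrom in config.shared_amp_chromosomes + config.shared_del_chromosomes:
        events[chrom] = (config.shared_event_prob, config.cnv_effect)
    ev = config.subtype_events.get(subtype)
    if ev is not None and ev[0] not in events:
        events[ev[0]] = (config.subtype_event_prob, config.subtype_event_effect)
    total = sum(config.chromosome_lengths_mb.values())
    p_bg = _p_segment_altered(0.0, threshold, config)
    acc = 0.0
    for chrom, mb in config.chromosome_lengths_mb.items():
        if chrom in events:
            prob, effect = events[chrom]
            p = prob * _p_segment_altered(effect, threshold, config) + (1 - prob) * p_bg
        else:
            p = p_bg
        acc += mb * p
    return acc / total


def planted_recovery_report(
    cohort: SyntheticCohort,
    score_table: pd.DataFrame | None = None,
    subtype_calls: list[SubtypeCall] | None = None,
) -> dict[str, float]:
    """Compare pipeline output against the planted truth.

    Reports subtype-call accuracy, the fraction of cell lines whose
    top-correlated tumor shares their planted subtype, and (when a clone was
    planted and a score table given) the clone's rank.
    """
    truth = cohort.truth
    report: dict[str, float] = {}
    if subtype_calls is not None:
        hits = total = 0
        for call in subtype_calls:
            if call.sample_id not in truth.index:
                raise ValidationError(f"unknown sample in calls: {call.sample_id!r}")
            total += 1
            hits += call.final_label.value == truth.at[call.sample_id, "subtype"]
        if total == 0:
            raise UndefinedResultError("no subtype calls supplied")
        report["subtype_accuracy"] = hits / total
    # top-correlated tumor shares the cell's subtype (expression layer)
    cells = LabeledMatrix(cohort.expression.data[cohort.cell_ids])
    tumors = LabeledMatrix(cohort.expression.data[cohort.tumor_ids])
    corr = pairwise_correlation(cells, tumors, layer="expression").df
    best_tumor = corr.idxmax(axis=1)
    same = [
        truth.at[cell, "subtype"] == truth.at[best_tumor[cell], "subtype"]
        for cell in corr.index
    ]
    report["top_tumor_same_subtype_fraction"] = float(np.mean(same))
    if score_table is not None:
        missing = set(score_table["cell_id"]) - set(truth.index)
        if missing:
            raise ValidationError(f"score table has unknown cell ids: {sorted(missing)}")
        clones = truth.index[truth["source_tumor"] != ""]
        if len(clones):
            clone = clones[0]
            row = score_table.loc[score_table["cell_id"] == clone]
            if len(row):
                report["clone_rank"] = float(row["rank"].iloc[0])
                report["clone_is_rank1"] = float(report["clone_rank"] == 1.0)
    return report
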