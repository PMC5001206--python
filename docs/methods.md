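# Methods

This note documents the models and procedures implemented in `portrait`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic cohorts do and do not establish about real data.

## Subtype assignment

Samples are labelled in two stages.  The receptor (IHC) rule maps
ER/PR/HER2 status to the four intrinsic subtypes: HER2-negative with ER or
PR positive → Luminal A; HER2-positive with ER or PR positive → Luminal B;
triple ER−/PR−/HER2+ → HER2amp; triple-negative → Basal-like.  Unknown
markers are handled by enumerating both completions of each unknown: the
rule's label is returned only when every completion agrees, otherwise the
sample is Unclassified.  This makes the classifier a total function whose
non-Unclassified output provably never depends on how unknowns are resolved
(checked exhaustively over all 27 status triples in the tests).

Unclassified samples fall back to nearest-centroid prediction: Pearson
correlation between the sample's profile and each column of a
caller-supplied centroid matrix over their shared genes (at least 3
required), highest correlation wins, ties broken by the fixed order
Luminal A < Luminal B < HER2amp < Basal-like.  A centroid labelled
"Normal"/"other" can win the correlation contest but yields Unclassified,
since normal-like profiles are excluded from the subtype comparison.
Centroid estimation and the RT-qPCR calibration behind published 50-gene
signatures are out of scope; the centroid table is data, not code.

The packaged table `table3_cell_lines.tsv` transcribes a published
68-cell-line annotation (receptor status, expression-based call, final
classification) exactly as printed, including its internal
inconsistencies (e.g. a triple-negative line carrying a HER2amp final
label).  It is a fixture for the concordance computation — 34 of the 56
lines with an expression-based call agree with the final classification,
60.71 % — not a re-derivation from the rules.

## Per-layer similarity

All four layers reduce to one operation: Pearson correlation between a
cell-line column and a tumor column over shared features, computed on
pairwise-complete observations with a minimum of 3 (pairs below the
minimum, or with a constant column, are missing rather than zero).
Missingness is first-class throughout; no imputation is performed.
Per-cell-line summaries are arithmetic means over tumors, either all tumors
(default) or only same-subtype tumors (option) — both conventions appear in
practice and the choice is exposed rather than hidden.

**Copy number.**  Segments (1-based inclusive, log2(CN/2) means) are mapped
to genes by overlap-length-weighted averaging; a per-base averaging oracle
in the test suite pins this semantics, since segmentation toolchains do not
agree on a rule.  FGA uses segment lengths `end − start + 1` and cutoffs
0.2 (tumors) / 0.3 (cell lines); gene-level amplification/deletion calls
use ±0.3.  The similarity layer restricts to the top 10 % most variable
genes, ranked by across-sample variance with cohorts pooled so both sides
see one gene set; variance rather than amplitude was chosen because it
maximizes cross-cohort discriminative signal, and an explicit gene-count
override exists because the right selection universe is ambiguous.

**Mutation.**  Records are filtered to somatic calls in an explicit
functional-class keep-set (missense, nonsense, nonstop, splice-site,
frame-shift and in-frame indels, translation-start); germline removal is a
site blacklist file, not a live database query, so the pipeline runs
offline.  Gene × sample indicators (1 = at least one record) feed the
similarity layer; Pearson on 0/1 columns equals the phi coefficient of the
2×2 contingency table, which the tests verify against the closed form.
Mutation burden is filtered records × 10⁶ / covered bases, with coverage
intervals merged (0-based half-open) so double-listed intervals cannot
inflate the denominator.  Substitution spectra collapse complementary
strands (reference normalized to A or C), giving six categories; flanking
±2 bp context profiles reverse-complement the context together with the
record, making the spectrum exactly invariant under strand flips.

**Protein.**  Pearson over shared proteins, optionally restricted to
same-subtype pairs.  Hierarchical clustering of samples uses
1 − Pearson (or Euclidean) distance with average (or complete/single)
linkage via SciPy; results are deterministic given input order.  The
mRNA-vs-protein coupling computes Pearson r for every (probe,
protein-form) pair of a gene across shared samples and averages the pairs
to one value per gene, reflecting that a gene may have several probes and
phospho-forms.

## The suitability score

`score = A + B + C + D` — the four per-layer mean correlations enter
unweighted and unstandardized, despite their very different scales
(expression correlations are large, binary mutation correlations near
zero), because the sum is the established form of this index; an optional
z-scoring across cell lines exists but is off by default.  The default
missing-layer policy `require_all` scores only cell lines observed on all
four platforms; `available_mean` rescales the mean of present components by
4.  Ranking is descending by score with lexicographic ties and unscorable
lines listed last.

## Synthetic cohorts

The generator produces every input table with planted structure:

* **Expression** — a shared baseline profile (N(8, 1) per gene) plus a
  +`centroid_separation` shift on each subtype's disjoint 50-gene marker
  block; samples are centroid + iid N(0, `expression_noise_sd`).  Defaults:
  separation 5, noise sd 1, 500 genes, 4 subtypes, 40 tumors and 8 cell
  lines per subtype.
* **Copy number** — 22 autosomes with human-karyotype lengths, 10 segments
  per chromosome at uniform breakpoints.  Hallmark events (chr1/8
  amplification, chr13/16 deletion, effect 0.5) are present in every
  sample, with amplitudes re-drawn per segment as
  `effect × max(0.1, N(1, 0.5))` — segmentation of a real aberrant
  chromosome yields a staircase, not one flat level.  Each subtype adds a
  weaker private event (effect 0.3: chr5, 11, 17 amplification for the
  luminal/HER2 groups, chr4 deletion for basal-like).
* **Mutations** — per-sample counts Poisson(rate × covered Mb) over a
  150-gene sequenced panel (200 kb per gene ≈ 30 Mb), with per-subtype
  default rates 1.2–3.0 /Mb (Luminal B highest, Luminal A lowest).
  Categories follow the spectrum weights, default
  (0.05, 0.15, 0.05, 0.10, 0.20, 0.45) — C>T and C>G dominated; half the
  records are emitted on the opposite strand with reverse-complemented
  context, exercising the collapse.  Five driver genes per subtype receive
  a 5× placement weight, creating subtype-specific mutation patterns
  without changing the total rate.
* **Proteins** — 50 forms over 38 genes drawn from the marker blocks;
  `protein = mRNA + N(0, σ)` with σ calibrated per gene from the realized
  tumor-side mRNA variance so the expected tumor-side Pearson r equals
  `protein_coupling_r` (default 0.7).  A coupling of exactly 1 with a
  positive noise floor is rejected as infeasible.

**Cell-line degradation.**  Cell lines mirror tumors only partially, and
the generator encodes that as explicit distortions: expression noise ×3.5,
copy-number effect ×1.3 with segment-amplitude jitter ×2 and private
chromosome-scale events (probability 0.3 per autosome), mutation rate ×1.5,
protein noise ×4.  These magnitudes were chosen as an identifiability
condition, analogous to requiring cluster separation well above noise: they
make a cell line cloned from a tumor (the `clone_cell_from_tumor` option
copies one tumor's expression, segments, mutations and protein column
verbatim) the best attainable model by a margin that exceeds the sampling
spread of the per-cell-line means, so the planted optimum is recovered at
rank 1 reliably rather than on average.  Under weaker distortions the score
still orders cell lines sensibly, but the maximal-similarity construction
is no longer guaranteed to win every draw — mean-over-tumors correlation
favours archetypal profiles, and a clone of one random tumor is typical,
not archetypal.  For the same reason the hallmark events are modelled as
always present with varying amplitude: if event *presence* varied, a clone
of a tumor that happened to miss an event would be atypical by
construction.

**Determinism.**  One integer seed fixes the cohort bit-for-bit.  Every
sample draws from a child random stream keyed by (subtype, kind, index), so
enlarging a cohort never perturbs existing samples; setup (centroids, gene
layout) and protein noise use separate keyed streams.

**Problem sizes.**  The reference cohort is 160 tumors + 32 cell lines
(40/8 per subtype) with 500 genes, a 150-gene sequenced panel and 50
proteins; closure statistics use 200 tumors.  The planted-recovery property
is exercised over 20 independent seeds in the test suite and summarized
over 10 seeds in `scripts/acceptance.py`; these sizes give multinomial and
mean-correlation standard errors small enough for three-standard-error
closure checks while keeping a full run in the minutes range on one core.

**What passing tests show.**  The synthetic cohorts have iid Gaussian
expression noise, no batch effects, no subclonal structure, uniform
coverage, and mutation placement independent across sites.  Closure tests
(the pipeline's own estimators recover the configured mutation rate,
spectrum, genome-altered fraction and protein coupling within three
standard errors at n = 200 tumors) validate the estimators and the
generator against each other; they do not establish how the score behaves
under real-data pathologies such as platform batch effects or
hypermutators.  The expected FGA used in closure integrates the amplitude
jitter and segment noise numerically; segment lengths are independent of
alteration status, so the expectation is the length-weighted mean of
per-chromosome alteration probabilities.

## Numerical choices and edge cases

* Pearson denominators of zero (constant vectors) yield missing values, not
  errors, inside similarity tables; statistics defined on a single vector
  (spectrum of an indel-only set, FGA of an empty segment set, correlation
  of a constant spectrum) raise `UndefinedResultError`.
* Centroid ties break by the fixed subtype order; ranking ties break by
  cell id; top-variance ties break lexicographically — all choices made for
  cross-platform determinism.
* Coordinates: SEG and MAF are 1-based inclusive (length = end − start + 1);
  BED coverage is 0-based half-open (bases = end − start).  Chromosome
  labels are normalized (leading `chr` stripped, X/Y upper-cased) and
  mitochondrial records dropped by default, since array and sequencing
  sources disagree on dialect.
* Writers emit UTF-8 with LF endings and full float precision (`repr`
  round-trip), so reader∘writer is an identity on valid tables.

## Known limitations

* The subtype concordance on the packaged table is a fixture computation;
  tumor-side concordance requires per-tumor calls that are not packaged.
* The "top 10 %" gene-selection universe for the copy-number layer is
  ambiguous in the literature this follows; both the fraction and an
  absolute gene count are exposed, and no attempt is made to reproduce any
  particular published gene count.
* Probe-to-gene and protein-name harmonization are explicit mapping inputs;
  the package performs no annotation-based collapsing of its own.
* The score sums correlations of very different magnitudes; interpretation
  should rest on the ranking, not on the absolute score value.
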