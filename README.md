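# portrait

Multi-omics similarity scoring between cancer cell lines and primary tumors.

Cell lines are the workhorse models of cancer pharmacology, but a line that
diverged in culture can misrepresent the tumors it is meant to model.  This
package quantifies, layer by layer, how faithfully each breast-cancer cell
line mirrors a tumor cohort — in mRNA expression, DNA copy number, somatic
mutation profile, and (phospho-)protein abundance — and combines the four
measurements into a single suitability score for ranking candidate models.
It is written for computational biologists who want a tested, reproducible
version of this comparison that runs on standard file formats (tab-delimited
matrices, SEG, MAF, BED).

## The statistics at its core

* **Subtype assignment.**  ER/PR/HER2 receptor status maps to Luminal A,
  Luminal B, HER2amp or Basal-like by the standard immunoprofile rules;
  samples with unknown markers fall back to nearest-centroid prediction on a
  50-gene expression signature (PAM50-style; centroids are an input).  A
  packaged 68-cell-line annotation table reproduces the printed concordance
  between the two classifiers: 34/56 = 60.71 %.
* **Fraction of genome altered (FGA).**  For a sample with copy-number
  segments of length *L(i)* and segment mean *CN(i)* on the log2(CN/2)
  scale,

      FGA = Σ_{|CN(i)| > T} L(i) / Σ L(i)

  with cutoff *T* = 0.2 for tumors and 0.3 for cell lines.
* **Per-layer similarity.**  Every (cell line, tumor) pair gets a Pearson
  correlation: over shared expressed genes; over the top-variance 10 % of
  genes after mapping segments to genes by overlap-weighted means; between
  0/1 gene-mutation indicator vectors (equivalently the phi coefficient);
  and over shared proteins.  Somatic mutations are filtered to functional
  classes, and substitution spectra use the six complement-collapsed
  categories A>C, A>G, A>T, C>A, C>G, C>T.
* **Suitability score.**  `score = A + B + C + D`, the sum of a cell line's
  four layer-wise mean correlations with the tumors; higher is a better
  model.

A seeded synthetic-cohort generator (`portrait.simulate`) emits every input
table with planted subtype structure, hallmark copy-number events, a
configurable mutation spectrum and mRNA-coupled proteins, so the whole
pipeline is testable without any external data.

## Worked example

The numbered scripts under `analysis/` run the full study on the reference
synthetic cohort (seed 17; 160 tumors, 32 cell lines, four subtypes, plus
one cell line cloned from a tumor as a planted best-possible model):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_subtype_concordance.py
python analysis/03_layer_similarities.py
python analysis/04_suitability_scores.py
```

The last script prints:

```
top 5 cell lines by combined suitability score:
cell_id     A     B      C     D  score  rank  n_layers_present
C_CLONE 0.338 0.796  0.003 0.103  1.240   1.0                 4
  C0002 0.194 0.759  0.014 0.034  1.001   2.0                 4
  C0020 0.165 0.727  0.014 0.093  0.999   3.0                 4
  C0030 0.202 0.742 -0.000 0.047  0.990   4.0                 4
  C0003 0.190 0.699  0.010 0.086  0.985   5.0                 4
```

`A`–`D` are the mean correlations per layer (expression, copy number,
mutation, protein) and `score` their sum.  `C_CLONE`, the cell line copied
from tumor `T0001`, outranks every ordinary cell line on the combined score
— ordinary lines lose similarity to extra expression noise, private
copy-number aberrations, a higher mutation burden and noisier protein
values, which is exactly the degradation the score is designed to detect.
Earlier scripts report the packaged-table concordance (34/56 = 60.71 %),
perfect subtype recovery on the separated synthetic cohort, and a tumor-side
mRNA/protein coupling of r = 0.70 matching the generator's target.

The same steps are available as a CLI (`portrait simulate / expr / cnv /
mut / prot / score / run`) for file-based inputs; `portrait run --config
pipeline.yaml` drives all stages and writes a run manifest.

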