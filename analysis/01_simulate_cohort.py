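#!/usr/bin/env python
"""Generate the reference synthetic cohort and summarize what it contains.

The cohort stands in for the matched tumor / cell-line multi-omics inputs:
160 tumors and 32 cell lines across four intrinsic subtypes, with expression,
copy-number segments, somatic mutations with coverage, and RPPA-style
protein tables, plus one cell line cloned from a tumor as a planted
best-possible model.  Writes a per-sample summary to results/ and the full
cohort files (SEG/MAF/BED/TSV) to scratch/cohort/ for ad-hoc inspection.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import pandas as pd

from portrait.cnv import fga_per_sample
from portrait.io import MutationTable, SegmentTable
from portrait.mutation import filter_somatic_functional, mutation_rate_per_mb
from portrait.pipeline import write_cohort
from portrait.simulate import SimConfig, simulate_cohort

SEED = 17
RESULTS = Path("results")
SCRATCH = Path("scratch/cohort")


def main() -> None:
    cfg = SimConfig(seed=SEED, clone_cell_from_tumor=True)
    cohort = simulate_cohort(cfg)
    RESULTS.mkdir(exist_ok=True)
    write_cohort(cohort, SCRATCH)

    muts = filter_somatic_functional(cohort.mutations)
    rows = []
    for sample in cohort.truth.index:
        kind = cohort.truth.at[sample, "kind"]
        threshold = 0.3 if kind == "cell" else 0.2
        seg = cohort.segments.for_sample(sample)
        rows.append({
            "sample_id": sample,
            "kind": kind,
            "subtype": cohort.truth.at[sample, "subtype"],
            "fga": fga_per_sample(seg, threshold).iloc[0],
            "mutations_per_mb": mutation_rate_per_mb(
                MutationTable(muts.df[muts.df["sample_id"] == sample]),
                cohort.coverage, sample,
            ),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)

    by_kind = summary.groupby("kind")[["fga", "mutations_per_mb"]].mean().round(3)
    print(f"cohort: {len(cohort.tumor_ids)} tumors, {len(cohort.cell_ids)} cell "
          f"lines, {len(cohort.mutations.df)} somatic mutations (seed {SEED})")
    print("mean genome-altered fraction and mutation burden by sample kind:")
    print(by_kind.to_string())
    print("cell lines carry more copy-number alteration and a higher mutation "
          "burden than tumors, as intended; full tables in scratch/cohort/.")


if __name__ == "__main__":
    main()
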