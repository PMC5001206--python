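"""The cell-line suitability score.

A cell line's overall resemblance to the tumor cohort is the plain sum of
its four layer-wise mean correlations:

    score = A + B + C + D

where A is the mean expression correlation with tumors, B the copy-number
correlation, C the binary mutation-profile correlation and D the protein
correlation.  The components enter unweighted and unstandardized; the score
ranks candidate cell-line models, it is not calibrated to any absolute
scale.  Two missing-layer policies exist: ``require_all`` (the default)
scores only cell lines observed on all four platforms; ``available_mean``
rescales the mean of the present components back to the four-layer scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np
import pandas as pd

from .errors import UndefinedResultError

COMPONENT_NAMES = ["A", "B", "C", "D"]


@dataclass(frozen=True)
class SimilarityComponents:
    """Per-layer mean correlations for one cell line (NaN = layer missing)."""

    cell_id: str
    A: float = float("nan")  # expression
    B: float = float("nan")  # copy number
    C: float = float("nan")  # mutation
    D: float = float("nan")  # protein

    def values(self) -> list[float]:
        return [self.A, self.B, self.C, self.D]

    def n_present(self) -> int:
        return sum(not isnan(v) for v in self.values())


def total_score(
    c: SimilarityComponents, policy: str = "require_all"
) -> float:
    """Combine the four components into one score (NaN when unscorable)."""
    vals = c.values()
    present = [v for v in vals if not isnan(v)]
    if policy == "require_all":
        return float(sum(vals)) if len(present) == 4 else float("nan")
    if policy == "available_mean":
        return float(np.mean(present) * 4) if present else float("nan")
    raise ValueError(f"unknown policy {policy!r}")


def rank_cell_lines(
    components: list[SimilarityComponents], policy: str = "require_all"
) -> pd.DataFrame:
    """Score table sorted best-first.

    Columns: A..D, score, rank (1 = highest score; ties broken by cell id),
    n_layers_present.  Cell lines without a defined score are listed last,
    unranked.
    """
    rows = []
    for c in components:
        rows.append(
            {
                "cell_id": c.cell_id, "A": c.A, "B": c.B, "C": c.C, "D": c.D,
                "score": total_score(c, policy),
                "n_layers_present": c.n_present(),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["score"].notna().sum() == 0:
        raise UndefinedResultError("no cell line has a defined score")
    scored = df[df["score"].notna()].sort_values(
        ["score", "cell_id"], ascending=[False, True], kind="stable"
    )
    scored = scored.assign(rank=np.arange(1, len(scored) + 1))
    unscored = df[df["score"].isna()].sort_values("cell_id").assign(rank=np.nan)
    out = pd.concat([scored, unscored], ignore_index=True)
    return out[["cell_id", "A", "B", "C", "D", "score", "rank", "n_layers_present"]]


def components_from_means(
    cell_ids: list[str],
    expression: pd.Series | None = None,
    cnv: pd.Series | None = None,
    mutation: pd.Series | None = None,
    protein: pd.Series | None = None,
) -> list[SimilarityComponents]:
    """Assemble components from per-layer mean-correlation series."""

    def get(series: pd.Series | None, cell: str) -> float:
        if series is None or cell not in series.index:
            return float("nan")
        v = series[cell]
        return float(v) if pd.notna(v) else float("nan")

    return [
        SimilarityComponents(
            cell,
            A=get(expression, cell), B=get(cnv, cell),
            C=get(mutation, cell), D=get(protein, cell),
        )
        for cell in cell_ids
    ]
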