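"""Pairwise Pearson correlation between two labeled matrices.

Every similarity layer (expression, copy number, binary mutation, protein)
reduces to the same operation: correlate each cell-line column against each
tumor column over the features the two matrices share, using
pairwise-complete observations, and record the result in a cells x tumors
table.  The helpers here implement that once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientOverlapError
from .io import LabeledMatrix

MIN_COMPLETE_OBS = 3


@dataclass
class PairwiseCorrelationTable:
    """Cells (rows) x tumors (columns) Pearson r values; NaN = undefined pair."""

    df: pd.DataFrame
    layer: str = ""
    features_used: list[str] = field(default_factory=list)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.df.columns)

    def mean_per_cell(self, subtype_map: dict[str, str] | None = None) -> pd.Series:
        """Arithmetic mean of defined correlations per cell line.

        With ``subtype_map`` (sample id -> subtype label), only tumors sharing
        the cell line's label contribute; a cell with zero usable pairs is NaN.
        """
        if subtype_map is None:
            return self.df.mean(axis=1, skipna=True)
        out = {}
        for cell in self.df.index:
            label = subtype_map.get(cell)
            cols = [t for t in self.df.columns if subtype_map.get(t) == label]
            out[cell] = self.df.loc[cell, cols].mean(skipna=True) if cols else np.nan
        return pd.Series(out, name=self.df.index.name)


def _pairwise_complete_corr(a: np.ndarray, b: np.ndarray, min_obs: int) -> np.ndarray:
    """r for every column pair of a (k x n) and b (k x m), pairwise-complete."""
    n, m = a.shape[1], b.shape[1]
    out = np.full((n, m), np.nan)
    a_ok, b_ok = np.isfinite(a), np.isfinite(b)
    for i in range(n):
        for j in range(m):
            mask = a_ok[:, i] & b_ok[:, j]
            if mask.sum() < min_obs:
                continue
            x, y = a[mask, i], b[mask, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            out[i, j] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return out


def _fast_complete_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized r for fully observed matrices (columns standardized)."""
    k = a.shape[0]
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = az.std(axis=0)
    sb = bz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az / np.where(sa == 0, np.nan, sa)).T @ (bz / np.where(sb == 0, np.nan, sb)) / k
    return r


def pairwise_correlation(
    cells: LabeledMatrix,
    tumors: LabeledMatrix,
    features: list[str] | None = None,
    *,
    layer: str = "",
    min_obs: int = MIN_COMPLETE_OBS,
) -> PairwiseCorrelationTable:
    """Pearson r for every (cell, tumor) column pair over shared features.

    Features are the intersection of the two matrices' feature ids, optionally
    restricted to ``features``.  Pairs with fewer than ``min_obs`` complete
    observations, or a constant column, are NaN.
    """
    shared = [f for f in cells.feature_ids if f in set(tumors.feature_ids)]
    if features is not None:
        wanted = set(features)
        shared = [f for f in shared if f in wanted]
    if len(shared) < min_obs:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared features (need >= {min_obs})"
        )
    a = cells.data.loc[shared].to_numpy(dtype=float)
    b = tumors.data.loc[shared].to_numpy(dtype=float)
    if np.isfinite(a).all() and np.isfinite(b).all():
        r = _fast_complete_corr(a, b)
    else:
        r = _pairwise_complete_corr(a, b, min_obs)
    df = pd.DataFrame(r, index=cells.sample_ids, columns=tumors.sample_ids)
    return PairwiseCorrelationTable(df, layer=layer, features_used=shared)


def write_correlation_table(table: PairwiseCorrelationTable, path) -> None:
    df = table.df.copy()
    df.index.name = "cell_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", na_rep="")


def read_correlation_table(path, *, layer: str = "") -> PairwiseCorrelationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairwiseCorrelationTable(df, layer=layer)
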