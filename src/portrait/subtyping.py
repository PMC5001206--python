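"""Breast-cancer subtype assignment and classification concordance.

Two classifiers are combined.  The marker-based (immunohistochemistry, IHC)
rule maps ER/PR/HER2 receptor status to the four intrinsic subtypes:

* HER2- and at least one of ER/PR positive  -> Luminal A
* HER2+ and at least one of ER/PR positive  -> Luminal B
* ER-/PR-/HER2+                              -> HER2amp
* ER-/PR-/HER2-  (triple negative)           -> Basal-like

When a marker is unknown the rule is applied to every completion of the
unknowns; if all completions agree the common label is returned, otherwise
the sample is Unclassified.  Samples the IHC rule cannot label fall back to
nearest-centroid prediction on expression (a PAM50-style classifier with the
centroid table supplied as data): the subtype whose centroid has the highest
Pearson correlation with the sample's signature-gene profile wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

from .errors import InsufficientOverlapError, UndefinedResultError
from .io import LabeledMatrix


class Subtype(Enum):
    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"
    HER2_AMP = "HER2amp"
    BASAL_LIKE = "BasalLike"
    UNCLASSIFIED = "Unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# fixed order used for deterministic tie-breaking in the centroid classifier
LABEL_ORDER = [Subtype.LUMINAL_A, Subtype.LUMINAL_B, Subtype.HER2_AMP, Subtype.BASAL_LIKE]

_LABEL_ALIASES = {
    "luminala": Subtype.LUMINAL_A, "luminal a": Subtype.LUMINAL_A, "la": Subtype.LUMINAL_A,
    "luminalb": Subtype.LUMINAL_B, "luminal b": Subtype.LUMINAL_B, "lb": Subtype.LUMINAL_B,
    "her2amp": Subtype.HER2_AMP, "her2-enrichment": Subtype.HER2_AMP,
    "her2": Subtype.HER2_AMP, "her2-enriched": Subtype.HER2_AMP,
    "basallike": Subtype.BASAL_LIKE, "basal-like": Subtype.BASAL_LIKE,
    "basal": Subtype.BASAL_LIKE, "bal": Subtype.BASAL_LIKE,
    "non": Subtype.UNCLASSIFIED, "unclassified": Subtype.UNCLASSIFIED,
    "normal": Subtype.UNCLASSIFIED, "normal-like": Subtype.UNCLASSIFIED,
    "other": Subtype.UNCLASSIFIED, "": Subtype.UNCLASSIFIED,
}


def parse_label(text: str) -> Subtype:
    """Map a printed subtype string (any common spelling) to the enum."""
    key = str(text).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized subtype label {text!r}")
    return _LABEL_ALIASES[key]


@dataclass(frozen=True)
class MarkerStatus:
    """ER/PR/HER2 receptor status; each marker is True/False/None(unknown)."""

    er: bool | None
    pr: bool | None
    her2: bool | None

    @classmethod
    def from_strings(cls, er: str, pr: str, her2: str) -> "MarkerStatus":
        def one(v: str) -> bool | None:
            v = str(v).strip()
            if v in ("+", "positive", "pos", "1"):
                return True
            if v in ("-", "negative", "neg", "0", "−"):
                return False
            if v in ("", "unknown", "na", "nan", "NA"):
                return None
            raise ValueError(f"unrecognized marker status {v!r}")

        return cls(one(er), one(pr), one(her2))


def _ihc_rule(er: bool, pr: bool, her2: bool) -> Subtype:
    if er or pr:
        return Subtype.LUMINAL_B if her2 else Subtype.LUMINAL_A
    return Subtype.HER2_AMP if her2 else Subtype.BASAL_LIKE


def classify_ihc(status: MarkerStatus) -> Subtype:
    """Marker-rule subtype; Unclassified when unknown markers make it ambiguous.

    Unknown markers are resolved by enumerating both completions; the label is
    returned only if every completion agrees.
    """
    options = [(m,) if m is not None else (False, True)
               for m in (status.er, status.pr, status.her2)]
    labels = {_ihc_rule(er, pr, her2) for er, pr, her2 in product(*options)}
    return labels.pop() if len(labels) == 1 else Subtype.UNCLASSIFIED


def classify_centroid(
    profile: dict[str, float] | pd.Series, centroids: LabeledMatrix
) -> tuple[Subtype, float]:
    """Nearest-centroid call: the centroid with the highest Pearson r wins.

    ``centroids`` columns are subtype labels (any spelling :func:`parse_label`
    accepts); a column parsing to Unclassified (e.g. a normal-like centroid)
    can win but yields the Unclassified label.  Ties are broken by the fixed
    label order Luminal A < Luminal B < HER2amp < Basal-like.
    """
    prof = pd.Series(profile, dtype=float)
    shared = [g for g in centroids.feature_ids if g in prof.index]
    best: tuple[int, Subtype, float] | None = None
    for col in centroids.sample_ids:
        cent = centroids.data[col]
        mask = np.isfinite(cent[shared].to_numpy()) & np.isfinite(prof[shared].to_numpy())
        genes = [g for g, ok in zip(shared, mask) if ok]
        if len(genes) < 3:
            continue
        x, y = prof[genes].to_numpy(), cent[genes].to_numpy()
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        label = parse_label(col)
        order = LABEL_ORDER.index(label) if label in LABEL_ORDER else len(LABEL_ORDER)
        if best is None or r > best[2] + 1e-15 or (abs(r - best[2]) <= 1e-15 and order < best[0]):
            best = (order, label, r)
    if best is None:
        raise InsufficientOverlapError(
            "fewer than 3 usable shared genes between profile and every centroid"
        )
    return best[1], best[2]


def assign_final(ihc: Subtype, centroid: Subtype) -> Subtype:
    """Known receptor status wins; expression prediction fills the gaps."""
    return ihc if ihc is not Subtype.UNCLASSIFIED else centroid


@dataclass
class SubtypeCall:
    sample_id: str
    ihc_label: Subtype
    centroid_label: Subtype
    centroid_correlation: float | None

    @property
    def final_label(self) -> Subtype:
        return assign_final(self.ihc_label, self.centroid_label)


def call_samples(
    annotations: pd.DataFrame,
    expression: LabeledMatrix | None = None,
    centroids: LabeledMatrix | None = None,
) -> list[SubtypeCall]:
    """Run the two-stage classifier over an annotation table (er/pr/her2 columns)."""
    calls = []
    for sample_id, row in annotations.iterrows():
        status = MarkerStatus.from_strings(
            row.get("er", ""), row.get("pr", ""), row.get("her2", "")
        )
        ihc = classify_ihc(status)
        cent_label, cent_r = Subtype.UNCLASSIFIED, None
        if expression is not None and centroids is not None and sample_id in expression.sample_ids:
            cent_label, cent_r = classify_centroid(expression.data[sample_id], centroids)
        calls.append(SubtypeCall(str(sample_id), ihc, cent_label, cent_r))
    return calls


def concordance(
    calls_a: list[Subtype],
    calls_b: list[Subtype],
    *,
    exclude_unclassified_in: str = "a",
) -> tuple[int, int, float]:
    """Agreement between two aligned label lists.

    Pairs where the designated list (``"a"``, ``"b"`` or ``"either"``) holds
    Unclassified are dropped from the denominator.  Returns
    ``(n_match, n_total, fraction)``.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("label lists must be index-aligned and equal length")
    if exclude_unclassified_in not in ("a", "b", "either"):
        raise ValueError("exclude_unclassified_in must be 'a', 'b' or 'either'")
    n_match = n_total = 0
    for a, b in zip(calls_a, calls_b):
        drop = (
            (exclude_unclassified_in in ("a", "either") and a is Subtype.UNCLASSIFIED)
            or (exclude_unclassified_in in ("b", "either") and b is Subtype.UNCLASSIFIED)
        )
        if drop:
            continue
        n_total += 1
        n_match += a is b
    if n_total == 0:
        raise UndefinedResultError("no comparable pairs after exclusions")
    return n_match, n_total, n_match / n_total


def load_cell_line_annotations() -> pd.DataFrame:
    """The packaged 68-cell-line annotation table (markers, expression-based
    subtype call, final classification), transcribed as printed in its source
    including its internal inconsistencies."""
    with resources.files("portrait.data").joinpath("table3_cell_lines.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def cell_line_concordance() -> tuple[int, int, float]:
    """Agreement between the expression-based (PAM50) column and the final
    classification column of the packaged cell-line table, dropping rows whose
    expression call is NON (no prediction)."""
    table = load_cell_line_annotations()
    pam = [parse_label(v) for v in table["pam50"]]
    final = [parse_label(v) for v in table["final_classification"]]
    return concordance(pam, final, exclude_unclassified_in="a")
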