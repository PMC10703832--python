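"""Sex-stratified reference ranges, abnormality flagging, and the
count-statistic screener.

A reference range for one item is built from healthy-control values only:
fit a Yeo-Johnson shape by maximum likelihood, take mean +/- 2 SD of the
transformed values (covering ~95.45% under normality), and map both
endpoints back through the inverse transform.  Each subject is then flagged
per item (strictly outside the range), and the per-subject count of
abnormal items (0-24) is the screening statistic, evaluated by ROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .fot_data import (
    ALL_ITEMS,
    Cohort,
    FotItem,
    FotRecord,
    ITEM_COLUMNS,
    Phase,
    Quantity,
)
from .yeo_johnson import TransformParams, fit_transform_params, yj_inverse

__all__ = [
    "ReferenceRange",
    "AbnormalityMatrix",
    "RocCurve",
    "derive_ranges",
    "flag_record",
    "build_matrix",
    "order_hierarchical",
    "roc_from_counts",
    "published_ranges",
    "ranges_to_json",
    "ranges_from_json",
]


@dataclass
class ReferenceRange:
    """Measured-scale interval for one item in one sex stratum.

    Endpoints sit at ``psi_inv(mu_t -/+ 2 sigma_t)``; when an endpoint falls
    outside the inverse transform's domain the corresponding ``unbounded``
    flag is set and the range is one-sided.
    """

    item: FotItem
    stratum: str
    low: float
    high: float
    transform: TransformParams | None = None
    unbounded_low: bool = False
    unbounded_high: bool = False

    def __post_init__(self) -> None:
        lo = -np.inf if self.unbounded_low else self.low
        hi = np.inf if self.unbounded_high else self.high
        if not lo < hi:
            raise ValueError(f"{self.item.column}: low {lo} must be below high {hi}")

    def contains(self, value: float) -> bool:
        """Strict-inequality convention: a value equal to a bound is in range."""
        if not self.unbounded_low and value < self.low:
            return False
        if not self.unbounded_high and value > self.high:
            return False
        return True


def derive_ranges(healthy_cohort: Cohort, stratum: str, n_sd: float = 2.0) -> list[ReferenceRange]:
    """Fit the 24 per-item ranges from one sex stratum of a control cohort.

    Refuses cohorts containing patient records: reference intervals are
    defined by healthy values only.
    """
    bad = [r.subject_id for r in healthy_cohort if r.group != "control"]
    if bad:
        raise ValueError(
            f"reference ranges must be derived from controls only; found "
            f"{len(bad)} non-control records (e.g. {bad[0]!r})"
        )
    sub = healthy_cohort.subset(sex=stratum)
    if len(sub) < 8:
        raise ValueError(f"need >= 8 {stratum} controls, have {len(sub)}")

    ranges: list[ReferenceRange] = []
    for item in ALL_ITEMS:
        sample = np.array([r.values[item] for r in sub])
        params = fit_transform_params(sample, item=item, stratum=stratum)
        lo_t = params.mu_t - n_sd * params.sigma_t
        hi_t = params.mu_t + n_sd * params.sigma_t
        unb_lo = unb_hi = False
        try:
            low = float(yj_inverse(lo_t, params.lambda_hat))
        except ValueError:
            low, unb_lo = -np.inf, True
        try:
            high = float(yj_inverse(hi_t, params.lambda_hat))
        except ValueError:
            high, unb_hi = np.inf, True
        ranges.append(
            ReferenceRange(
                item=item,
                stratum=stratum,
                low=low,
                high=high,
                transform=params,
                unbounded_low=unb_lo,
                unbounded_high=unb_hi,
            )
        )
    return ranges


def flag_record(record: FotRecord, ranges: Sequence[ReferenceRange]) -> tuple[np.ndarray, int]:
    """Boolean out-of-range vector over the 24 items, plus its count."""
    if any(r.stratum != record.sex for r in ranges):
        raise ValueError(
            f"range stratum does not match record sex {record.sex!r} "
            f"(subject {record.subject_id!r})"
        )
    by_item = {r.item: r for r in ranges}
    flags = np.array(
        [not by_item[item].contains(record.values[item]) for item in ALL_ITEMS],
        dtype=bool,
    )
    return flags, int(flags.sum())


@dataclass
class AbnormalityMatrix:
    """Subjects x 24 out-of-range flags, with per-subject counts."""

    subject_ids: list[str]
    groups: list[str]
    flags: np.ndarray  # bool, shape (n_subjects, 24)
    row_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.row_order is None:
            self.row_order = np.arange(self.flags.shape[0])
        if self.col_order is None:
            self.col_order = np.arange(self.flags.shape[1])

    @property
    def counts(self) -> np.ndarray:
        return self.flags.sum(axis=1)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.flags.astype(int), index=self.subject_ids, columns=ITEM_COLUMNS
        )
        df.insert(0, "group", self.groups)
        df.to_csv(path, sep="\t", index_label="subject_id")


def build_matrix(cohort: Cohort, ranges_by_sex: Mapping[str, Sequence[ReferenceRange]]) -> AbnormalityMatrix:
    """Flag every record against the ranges of its own sex stratum."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    flags = []
    for rec in cohort:
        f, _ = flag_record(rec, ranges_by_sex[rec.sex])
        flags.append(f)
    return AbnormalityMatrix(
        subject_ids=[r.subject_id for r in cohort],
        groups=[r.group for r in cohort],
        flags=np.array(flags, dtype=bool),
    )


def _jaccard_linkage(mat: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration on Jaccard distances of binary rows."""
    d = pdist(mat.astype(bool), metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # two all-zero rows are identical
    return hierarchy.linkage(d, method="average")


def order_hierarchical(matrix: AbnormalityMatrix) -> AbnormalityMatrix:
    """Attach deterministic row and column orderings for heatmap display.

    Rows (subjects) and columns (items, on the transposed matrix) are
    ordered by leaves of an average-linkage dendrogram over Jaccard
    distances.  A matrix whose rows are all identical keeps input order.
    """
    mat = matrix.flags

    def leaf_order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 2 or (m == m[0]).all():
            return np.arange(m.shape[0])
        Z = _jaccard_linkage(m)
        return np.asarray(hierarchy.leaves_list(Z))

    matrix.row_order = leaf_order(mat)
    matrix.col_order = leaf_order(mat.T)
    return matrix


@dataclass
class RocCurve:
    """ROC over integer count cutoffs (classify asthma iff count >= cutoff)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "thresholds": self.thresholds.tolist(),
                    "sensitivity": self.sensitivity.tolist(),
                    "specificity": self.specificity.tolist(),
                    "auc": self.auc,
                    "youden_cutoff": self.youden_cutoff,
                },
                fh,
                indent=2,
            )


def roc_from_counts(counts: Sequence[int], labels: Sequence[str]) -> RocCurve:
    """ROC of the abnormality count for control-vs-asthma discrimination.

    Cutoffs span the full 0..25 grid so the curve reaches both corners.
    AUC is the trapezoidal area, which for this construction equals the
    Mann-Whitney concordance with ties counted 1/2.  Youden's cutoff is the
    argmax of sensitivity + specificity - 1, smallest cutoff on ties
    (favouring sensitivity in a screening context).
    """
    counts = np.asarray(counts)
    y = np.asarray([1 if g == "asthma" else 0 for g in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    thresholds = np.arange(0, 26)
    sens = np.array([(counts[y == 1] >= c).mean() for c in thresholds])
    spec = np.array([(counts[y == 0] < c).mean() for c in thresholds])
    fpr = 1.0 - spec
    # integrate along the curve from (1,1) at c=0 to (0,0) at c=25
    auc = float(-np.trapezoid(sens, fpr))
    j = sens + spec - 1.0
    youden = int(thresholds[np.argmax(j)])  # argmax takes first (smallest) on ties
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=youden,
    )


# --------------------------------------------------------------------------
# Published ranges (healthy Japanese adults, 101 male / 114 female controls).
# These are the printed study values, shipped for flagging real MostGraph
# reports; they cannot be recomputed here because the underlying individual
# measurements are not public.
# --------------------------------------------------------------------------

_PUBLISHED = {
    "male": {
        "R5_avg": (0.89, 5.04), "R5_ex": (0.95, 5.85), "R5_in": (0.77, 4.57),
        "R5_delta": (-0.52, 2.14),
        "R20_avg": (1.03, 4.34), "R20_ex": (1.07, 4.74), "R20_in": (0.94, 4.12),
        "R20_delta": (-0.62, 1.33),
        "R5mR20_avg": (-0.61, 0.99), "R5mR20_ex": (-0.59, 1.37),
        "R5mR20_in": (-0.67, 0.80), "R5mR20_delta": (-0.27, 0.99),
        "X5_avg": (-0.85, 0.29), "X5_ex": (-0.98, 0.38), "X5_in": (-0.91, 0.30),
        "X5_delta": (-0.69, 0.78),
        "Fres_avg": (3.99, 10.59), "Fres_ex": (3.72, 11.58), "Fres_in": (3.84, 10.85),
        "Fres_delta": (-4.07, 3.72),
        "ALX_avg": (-0.06, 4.05), "ALX_ex": (-0.09, 3.71), "ALX_in": (-0.11, 4.62),
        "ALX_delta": (-2.40, 4.02),
    },
    "female": {
        "R5_avg": (1.27, 4.44), "R5_ex": (1.32, 5.35), "R5_in": (1.17, 3.94),
        "R5_delta": (-0.29, 2.40),
        "R20_avg": (1.37, 4.25), "R20_ex": (1.38, 4.71), "R20_in": (1.33, 4.00),
        "R20_delta": (-0.23, 1.51),
        "R5mR20_avg": (-0.73, 1.14), "R5mR20_ex": (-0.64, 1.43),
        "R5mR20_in": (-0.90, 0.97), "R5mR20_delta": (-0.20, 1.10),
        "X5_avg": (-1.16, 0.19), "X5_ex": (-1.29, 0.33), "X5_in": (-1.20, 0.17),
        "X5_delta": (-0.62, 0.86),
        "Fres_avg": (4.30, 11.30), "Fres_ex": (3.71, 12.48), "Fres_in": (4.33, 11.19),
        "Fres_delta": (-3.99, 2.74),
        "ALX_avg": (0.01, 5.73), "ALX_ex": (-0.12, 7.32), "ALX_in": (-0.01, 5.70),
        "ALX_delta": (-2.93, 3.67),
    },
}

_COLUMN_TO_ITEM = {it.column: it for it in ALL_ITEMS}


def published_ranges(stratum: str) -> list[ReferenceRange]:
    """The published adult reference ranges for one sex, as range objects."""
    if stratum not in _PUBLISHED:
        raise ValueError(f"stratum must be 'male' or 'female', got {stratum!r}")
    return [
        ReferenceRange(item=_COLUMN_TO_ITEM[col], stratum=stratum, low=lo, high=hi)
        for col, (lo, hi) in _PUBLISHED[stratum].items()
    ]


def ranges_to_json(ranges: Sequence[ReferenceRange], path) -> None:
    payload = []
    for r in ranges:
        entry = {
            "item": r.item.column,
            "stratum": r.stratum,
            "low": None if r.unbounded_low else r.low,
            "high": None if r.unbounded_high else r.high,
        }
        if r.transform is not None:
            entry["transform"] = r.transform.to_dict()
        payload.append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def ranges_from_json(path) -> list[ReferenceRange]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for entry in payload:
        t = entry.get("transform")
        params = None
        if t is not None:
            params = TransformParams(
                lambda_hat=t["lambda"], mu_t=t["mu_t"], sigma_t=t["sigma_t"], n=t["n"],
                at_bound=t.get("at_bound", False),
            )
        out.append(
            ReferenceRange(
                item=_COLUMN_TO_ITEM[entry["item"]],
                stratum=entry["stratum"],
                low=-np.inf if entry["low"] is None else entry["low"],
                high=np.inf if entry["high"] is None else entry["high"],
                transform=params,
                unbounded_low=entry["low"] is None,
                unbounded_high=entry["high"] is None,
            )
        )
    return out
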