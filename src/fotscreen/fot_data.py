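"""Domain types and CSV I/O for forced-oscillation-technique (FOT) cohorts.

A MostGraph report carries, for each of five impedance quantities (R5, R20,
X5, Fres, ALX), an inhaled and an exhaled value.  From those 10 phase
measurements the device report derives 14 more: the within-breath average
and delta (exhale - inhale) of each quantity, and the frequency-dependence
index R5-R20 in every phase, giving 24 items in total.  The 10 phase
measurements are the canonical storage here; derived items are always
recomputed so a cohort can never be internally inconsistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Quantity",
    "Phase",
    "FotItem",
    "FotRecord",
    "Cohort",
    "ALL_ITEMS",
    "PHASE_COLUMNS",
    "ITEM_COLUMNS",
    "complete_derived",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "CohortValidationError",
    "TAU_DER_EXACT",
    "TAU_DER_ROUNDED",
]


class Quantity(str, Enum):
    """The six reported impedance quantities."""

    R5 = "R5"        # resistance at 5 Hz, cmH2O/L/s
    R20 = "R20"      # resistance at 20 Hz, cmH2O/L/s
    R5_R20 = "R5mR20"  # R5 - R20 (frequency dependence), cmH2O/L/s; derived
    X5 = "X5"        # reactance at 5 Hz, cmH2O/L/s
    FRES = "Fres"    # resonant frequency, Hz
    ALX = "ALX"      # low-frequency reactance area, cmH2O/L/s*Hz


class Phase(str, Enum):
    AVERAGE = "avg"
    INHALE = "in"
    EXHALE = "ex"
    DELTA = "delta"


#: quantities measured directly (R5_R20 is derived from R5 and R20)
MEASURED_QUANTITIES = (
    Quantity.R5,
    Quantity.R20,
    Quantity.X5,
    Quantity.FRES,
    Quantity.ALX,
)

#: quantities whose inhale/exhale values must be strictly positive
POSITIVE_QUANTITIES = (Quantity.R5, Quantity.R20, Quantity.FRES)

UNITS = {
    Quantity.R5: "cmH2O/L/s",
    Quantity.R20: "cmH2O/L/s",
    Quantity.R5_R20: "cmH2O/L/s",
    Quantity.X5: "cmH2O/L/s",
    Quantity.FRES: "Hz",
    Quantity.ALX: "cmH2O/L/s.Hz",
}


@dataclass(frozen=True, order=True)
class FotItem:
    """One of the 24 reported measurement items (quantity x phase)."""

    quantity: Quantity
    phase: Phase

    @property
    def column(self) -> str:
        return f"{self.quantity.value}_{self.phase.value}"

    @property
    def units(self) -> str:
        return UNITS[self.quantity]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.column


_QUANTITY_ORDER = (
    Quantity.R5,
    Quantity.R20,
    Quantity.R5_R20,
    Quantity.X5,
    Quantity.FRES,
    Quantity.ALX,
)
_PHASE_ORDER = (Phase.AVERAGE, Phase.INHALE, Phase.EXHALE, Phase.DELTA)

#: all 24 item identities in canonical (report) order
ALL_ITEMS: tuple[FotItem, ...] = tuple(
    FotItem(q, p) for q in _QUANTITY_ORDER for p in _PHASE_ORDER
)

#: the 10 independent phase measurements, in canonical column order
PHASE_ITEMS: tuple[FotItem, ...] = tuple(
    FotItem(q, p)
    for q in MEASURED_QUANTITIES
    for p in (Phase.INHALE, Phase.EXHALE)
)
PHASE_COLUMNS: tuple[str, ...] = tuple(it.column for it in PHASE_ITEMS)
ITEM_COLUMNS: tuple[str, ...] = tuple(it.column for it in ALL_ITEMS)

_COLUMN_TO_ITEM = {it.column: it for it in ALL_ITEMS}

#: derivation identities hold exactly for synthetic data
TAU_DER_EXACT = 1e-6
#: device reports print 2 decimals; use this when validating real exports
TAU_DER_ROUNDED = 0.015


class CohortValidationError(ValueError):
    """Malformed cohort input (bad token, duplicate id, missing value)."""


@dataclass
class FotRecord:
    """One subject: metadata plus a mapping of FotItem -> value."""

    subject_id: str
    sex: str  # "male" | "female"
    group: str  # "control" | "asthma"
    values: dict[FotItem, float] = field(default_factory=dict)
    age: float | None = None

    def __post_init__(self) -> None:
        self.sex = _canon_token(self.sex, {"male", "female"}, "sex")
        self.group = _canon_token(self.group, {"control", "asthma"}, "group")

    def value(self, quantity: Quantity, phase: Phase) -> float:
        return self.values[FotItem(quantity, phase)]


def _canon_token(token: str, allowed: set[str], what: str) -> str:
    t = str(token).strip().lower()
    if t not in allowed:
        raise CohortValidationError(f"unknown {what} token {token!r}; expected one of {sorted(allowed)}")
    return t


@dataclass
class Cohort:
    """Ordered collection of records with a free-text provenance tag."""

    records: list[FotRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise CohortValidationError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FotRecord]:
        return iter(self.records)

    def subset(self, *, sex: str | None = None, group: str | None = None) -> "Cohort":
        recs = [
            r
            for r in self.records
            if (sex is None or r.sex == sex) and (group is None or r.group == group)
        ]
        return Cohort(records=recs, provenance=self.provenance)

    def to_frame(self, derived: bool = True) -> pd.DataFrame:
        """Tabular view; columns per the CSV schema."""
        cols = ITEM_COLUMNS if derived else PHASE_COLUMNS
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "age": rec.age,
                "group": rec.group,
            }
            for c in cols:
                row[c] = rec.values.get(_COLUMN_TO_ITEM[c], math.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=["subject_id", "sex", "age", "group", *cols])


def complete_derived(record: FotRecord) -> FotRecord:
    """Fill the 14 derived items from the 10 phase measurements.

    average = (inhale + exhale) / 2, delta = exhale - inhale, and
    R5-R20 = R5 - R20 phase-wise.  Raises when any phase measurement is
    missing or non-finite, naming the offending item.
    """
    vals: dict[FotItem, float] = {}
    for q in MEASURED_QUANTITIES:
        for p in (Phase.INHALE, Phase.EXHALE):
            item = FotItem(q, p)
            v = record.values.get(item)
            if v is None or not math.isfinite(v):
                raise CohortValidationError(
                    f"subject {record.subject_id!r}: missing or non-finite value for {item.column}"
                )
            vals[item] = float(v)
    for q in MEASURED_QUANTITIES:
        vin = vals[FotItem(q, Phase.INHALE)]
        vex = vals[FotItem(q, Phase.EXHALE)]
        vals[FotItem(q, Phase.AVERAGE)] = (vin + vex) / 2.0
        vals[FotItem(q, Phase.DELTA)] = vex - vin
    for p in _PHASE_ORDER:
        vals[FotItem(Quantity.R5_R20, p)] = (
            vals[FotItem(Quantity.R5, p)] - vals[FotItem(Quantity.R20, p)]
        )
    return replace(record, values=vals)


@dataclass(frozen=True)
class Violation:
    item: FotItem
    observed: float
    expected: float | None
    kind: str  # "derivation" | "positivity"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "positivity":
            return f"{self.item.column}: {self.observed} must be > 0"
        return f"{self.item.column}: observed {self.observed}, expected {self.expected}"


def validate_record(record: FotRecord, tau_der: float = TAU_DER_EXACT) -> list[Violation]:
    """Check the derivation identities and positivity constraints.

    Returns a (possibly empty) list of violations; inconsistent data is a
    result, not an exception.
    """
    out: list[Violation] = []
    v = record.values

    def check(item: FotItem, expected: float) -> None:
        obs = v[item]
        if abs(obs - expected) > tau_der:
            out.append(Violation(item, obs, expected, "derivation"))

    for q in MEASURED_QUANTITIES:
        vin = v[FotItem(q, Phase.INHALE)]
        vex = v[FotItem(q, Phase.EXHALE)]
        check(FotItem(q, Phase.AVERAGE), (vin + vex) / 2.0)
        check(FotItem(q, Phase.DELTA), vex - vin)
    for p in _PHASE_ORDER:
        check(
            FotItem(Quantity.R5_R20, p),
            v[FotItem(Quantity.R5, p)] - v[FotItem(Quantity.R20, p)],
        )
    for q in POSITIVE_QUANTITIES:
        for p in (Phase.INHALE, Phase.EXHALE):
            item = FotItem(q, p)
            if v[item] <= 0:
                out.append(Violation(item, v[item], None, "positivity"))
    return out


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV with all 24 item columns.

    Values are printed with 17 significant digits (shortest exact decimal
    for float64) so a write/read round trip is value-exact.
    """
    df = cohort.to_frame(derived=True)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_cohort(path, tau_der: float = TAU_DER_EXACT, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV.

    The file must contain ``subject_id``, ``sex``, ``group`` (``age``
    optional) plus at least the 10 phase columns; derived columns are
    recomputed from the phase measurements on load.  Errors carry the
    1-based data row number.
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing_meta = {"subject_id", "sex", "group"} - set(df.columns)
    if missing_meta:
        raise CohortValidationError(f"missing metadata columns: {sorted(missing_meta)}")
    missing_phase = set(PHASE_COLUMNS) - set(df.columns)
    if missing_phase:
        raise CohortValidationError(f"missing phase columns: {sorted(missing_phase)}")

    records: list[FotRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        sid = str(rowd["subject_id"])
        if sid in seen:
            raise CohortValidationError(f"row {i}: duplicate subject_id {sid!r}")
        seen.add(sid)
        age = rowd.get("age")
        if age is not None and (isinstance(age, float) and math.isnan(age)):
            age = None
        vals: dict[FotItem, float] = {}
        for c in PHASE_COLUMNS:
            raw = rowd[c]
            try:
                vals[_COLUMN_TO_ITEM[c]] = float(raw)
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(f"row {i}: malformed numeric cell {c}={raw!r}") from exc
        try:
            rec = FotRecord(
                subject_id=sid,
                sex=rowd["sex"],
                group=rowd["group"],
                age=None if age is None else float(age),
                values=vals,
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from None
        records.append(complete_derived(rec))
    return Cohort(records=records, provenance=provenance or str(path))
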