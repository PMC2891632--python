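"""Patient and cohort data model for melanoma prognostic analyses.

A cohort is a collection of patients excised for primary cutaneous
melanoma, each labelled by five-year metastatic outcome and carrying the
three measurements the Shields index needs — epi-tumoural lymphatic
vessel density (LVD, vessels/mm^2), lymphatic vessel invasion (LVI,
present/absent), and Breslow thickness (mm) — plus optional clinical
covariates (age, Clark level, AJCC stage, hot-spot LVD, sentinel-node
biopsy status, follow-up time, ulceration, in-situ flags).

The module provides CSV round-trip I/O, the inclusion/exclusion filter
used to assemble an analysable cohort, and per-group summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

GROUP_METASTATIC = "metastatic"
GROUP_NON_METASTATIC = "non_metastatic"
GROUPS = (GROUP_METASTATIC, GROUP_NON_METASTATIC)

SLNB_STATUSES = ("positive", "negative", "not_done")

#: CSV column order.  Booleans are written as 0/1, missing optionals as
#: empty cells.  ``metastatic_at_excision`` is accepted on input but only
#: written when any record sets it.
CSV_COLUMNS = [
    "patient_id",
    "group",
    "age_years",
    "breslow_mm",
    "clark_level",
    "ajcc_stage",
    "lvd_total_mm2",
    "lvi",
    "lvd_hotspot_mm2",
    "slnb_status",
    "followup_months",
    "ulceration",
    "in_situ",
]

REQUIRED_COLUMNS = [
    "patient_id",
    "group",
    "breslow_mm",
    "lvd_total_mm2",
    "lvi",
    "followup_months",
    "ulceration",
    "in_situ",
]


class CohortSchemaError(ValueError):
    """A required CSV column is absent or mis-typed."""


class CohortValidationError(ValueError):
    """A record violates a field invariant (the row is identified)."""


@dataclass
class PatientRecord:
    """One patient: outcome label, index components and optional covariates.

    ``lvd_total`` may be ``None`` (density not assessable); such records
    are removed by :func:`apply_inclusion_criteria`.  ``breslow_mm`` must
    be positive except for in-situ lesions, which carry no invasive
    thickness.
    """

    patient_id: str
    group: str
    lvd_total: float | None
    lvi: bool
    breslow_mm: float | None
    followup_months: float
    ulceration: bool = False
    in_situ: bool = False
    age_years: float | None = None
    clark_level: int | None = None
    ajcc_stage: int | None = None
    lvd_hotspot: float | None = None
    slnb_status: str | None = None
    metastatic_at_excision: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.lvd_total is not None and self.lvd_total < 0:
            raise CohortValidationError(
                f"lvd_total must be >= 0, got {self.lvd_total}"
            )
        if not self.in_situ:
            if self.breslow_mm is None or self.breslow_mm <= 0:
                raise CohortValidationError(
                    f"breslow_mm must be > 0 for invasive lesions, got {self.breslow_mm}"
                )
        if self.followup_months < 0:
            raise CohortValidationError(
                f"followup_months must be >= 0, got {self.followup_months}"
            )
        if self.lvd_hotspot is not None and self.lvd_hotspot < 0:
            raise CohortValidationError(
                f"lvd_hotspot must be >= 0, got {self.lvd_hotspot}"
            )
        if self.slnb_status is not None and self.slnb_status not in SLNB_STATUSES:
            raise CohortValidationError(
                f"slnb_status must be one of {SLNB_STATUSES}, got {self.slnb_status!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.group == GROUP_METASTATIC


@dataclass
class Cohort:
    """Ordered, validated collection of :class:`PatientRecord`."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def n_cases(self) -> int:
        return sum(r.is_case for r in self.records)

    @property
    def n_controls(self) -> int:
        return len(self.records) - self.n_cases

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view following the CSV schema (None for missing)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "group": r.group,
                    "age_years": r.age_years,
                    "breslow_mm": r.breslow_mm,
                    "clark_level": r.clark_level,
                    "ajcc_stage": r.ajcc_stage,
                    "lvd_total_mm2": r.lvd_total,
                    "lvi": int(r.lvi),
                    "lvd_hotspot_mm2": r.lvd_hotspot,
                    "slnb_status": r.slnb_status,
                    "followup_months": r.followup_months,
                    "ulceration": int(r.ulceration),
                    "in_situ": int(r.in_situ),
                    "metastatic_at_excision": int(r.metastatic_at_excision),
                }
            )
        df = pd.DataFrame(rows, columns=CSV_COLUMNS + ["metastatic_at_excision"])
        return df


@dataclass
class ExclusionTally:
    """Counts of excluded records by first-matching reason.

    Precedence (fixed so tallies are deterministic):
    metastatic_at_excision > in_situ > thickness_ge_8mm > ulceration >
    insufficient_followup > missing_lvd.
    """

    thickness_ge_8mm: int = 0
    in_situ: int = 0
    ulceration: int = 0
    insufficient_followup: int = 0
    missing_lvd: int = 0
    metastatic_at_excision: int = 0

    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"0", "false", "no"}:
        return False
    if s in {"1", "true", "yes"}:
        return True
    raise CohortValidationError(f"row {row}: cannot parse {column}={value!r} as 0/1")


def _parse_float(value, column: str, row: int, optional: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    ):
        if optional:
            return None
        raise CohortValidationError(f"row {row}: required field {column} is empty")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(
            f"row {row}: cannot parse {column}={value!r} as a number"
        ) from exc


def _parse_int(value, column: str, row: int) -> int | None:
    x = _parse_float(value, column, row, optional=True)
    return None if x is None else int(round(x))


def read_cohort_csv(path: str | Path, provenance: str | None = None) -> Cohort:
    """Read a patient cohort from CSV.

    The header must contain the required columns
    (``patient_id, group, breslow_mm, lvd_total_mm2, lvi,
    followup_months, ulceration, in_situ``); optional columns may be
    absent.  Empty cells encode missing optional values.  Validation
    failures raise with the offending (1-based) data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "slnb_status": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")

    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()

        def get(col):
            return row.get(col)

        try:
            in_situ = _parse_bool(get("in_situ"), "in_situ", i)
            # lvd_total may be missing (excluded later); breslow may be
            # missing only for in-situ lesions.
            rec = PatientRecord(
                patient_id=str(get("patient_id")),
                group=str(get("group")).strip(),
                lvd_total=_parse_float(get("lvd_total_mm2"), "lvd_total_mm2", i, optional=True),
                lvi=_parse_bool(get("lvi"), "lvi", i),
                breslow_mm=_parse_float(get("breslow_mm"), "breslow_mm", i, optional=in_situ),
                followup_months=_parse_float(get("followup_months"), "followup_months", i, optional=False),
                ulceration=_parse_bool(get("ulceration"), "ulceration", i),
                in_situ=in_situ,
                age_years=_parse_float(get("age_years"), "age_years", i, optional=True) if "age_years" in row else None,
                clark_level=_parse_int(get("clark_level"), "clark_level", i) if "clark_level" in row else None,
                ajcc_stage=_parse_int(get("ajcc_stage"), "ajcc_stage", i) if "ajcc_stage" in row else None,
                lvd_hotspot=_parse_float(get("lvd_hotspot_mm2"), "lvd_hotspot_mm2", i, optional=True) if "lvd_hotspot_mm2" in row else None,
                slnb_status=(None if get("slnb_status") is None or (isinstance(get("slnb_status"), float) and math.isnan(get("slnb_status"))) or str(get("slnb_status")).strip() == "" else str(get("slnb_status")).strip()) if "slnb_status" in row else None,
                metastatic_at_excision=_parse_bool(get("metastatic_at_excision"), "metastatic_at_excision", i) if "metastatic_at_excision" in row else False,
            )
        except CohortValidationError as exc:
            if str(exc).startswith("row "):
                raise
            raise CohortValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return Cohort(records, provenance=provenance if provenance is not None else str(path))


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; ``read_cohort_csv`` round-trips it exactly
    (floats to full repr precision)."""
    df = cohort.to_dataframe()
    if not any(r.metastatic_at_excision for r in cohort.records):
        df = df[CSV_COLUMNS]
    # pandas writes None/NaN as empty cells; ints stay unquoted
    df.to_csv(path, index=False)


def apply_inclusion_criteria(
    cohort: Cohort,
    max_thickness_mm: float = 8.0,
    min_control_followup_months: float = 60.0,
) -> tuple[Cohort, ExclusionTally]:
    """Filter a cohort to the analysable set and tally exclusions.

    Retained records are invasive (not in situ), non-ulcerated, with
    Breslow thickness strictly below ``max_thickness_mm``, an assessable
    LVD, and — for non-metastatic patients only — follow-up exceeding
    ``min_control_followup_months`` (cases qualify by their event).
    Each excluded record is counted once, under the first matching
    reason in the :class:`ExclusionTally` precedence order.
    """
    tally = ExclusionTally()
    kept: list[PatientRecord] = []
    for r in cohort.records:
        if r.metastatic_at_excision:
            tally.metastatic_at_excision += 1
        elif r.in_situ:
            tally.in_situ += 1
        elif r.breslow_mm is not None and r.breslow_mm >= max_thickness_mm:
            tally.thickness_ge_8mm += 1
        elif r.ulceration:
            tally.ulceration += 1
        elif (not r.is_case) and r.followup_months <= min_control_followup_months:
            tally.insufficient_followup += 1
        elif r.lvd_total is None:
            tally.missing_lvd += 1
        else:
            kept.append(replace(r))
    out = Cohort(kept, provenance=cohort.provenance)
    assert len(cohort) == len(out) + tally.total()
    return out, tally


_SUMMARY_FIELDS = {
    "age_years": "age_years",
    "breslow_mm": "breslow_mm",
    "followup_months": "followup_months",
    "clark_level": "clark_level",
    "lvd_total_mm2": "lvd_total",
    "lvd_hotspot_mm2": "lvd_hotspot",
}


def summarize_groups(cohort: Cohort) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1) of every numeric field present.

    Returns a frame indexed by group with a two-level column index
    ``(field, {mean, sd, n})``.  Raises if either outcome group is
    empty.
    """
    for g in GROUPS:
        if not any(r.group == g for r in cohort.records):
            raise ValueError(f"group {g!r} is empty")
    df = cohort.to_dataframe()
    pieces = {}
    for col, _attr in _SUMMARY_FIELDS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().sum() == 0:
            continue
        grouped = vals.groupby(df["group"])
        pieces[col] = pd.DataFrame(
            {
                "mean": grouped.mean(),
                "sd": grouped.std(ddof=1),
                "n": grouped.count().astype(float),
            }
        )
    out = pd.concat(pieces, axis=1)
    out.index.name = "group"
    return out


def case_control_values(
    records: Iterable[PatientRecord], attr: str
) -> tuple[np.ndarray, np.ndarray]:
    """Split one numeric attribute into (case, control) arrays, dropping
    missing values."""
    cases, controls = [], []
    for r in records:
        v = getattr(r, attr)
        if v is None:
            continue
        (cases if r.is_case else controls).append(float(v))
    return np.asarray(cases), np.asarray(controls)
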