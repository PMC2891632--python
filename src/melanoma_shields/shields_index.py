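"""The Shields prognostic index.

    index = LVD^2 * invasion * Breslow thickness

where LVD is the epi-tumoural lymphatic vessel density (vessels/mm^2),
invasion is 2 if lymphatic vessel invasion is present and 1 otherwise,
and thickness is in mm.  The squared LVD term weights the component
most strongly associated with metastasis.  The index is analysed and
thresholded on the log10 scale (default clinical cutoff 2.1); the raw
index is treated as a unitless score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort_model import Cohort, PatientRecord

VARIANTS = ("total", "hotspot")
DEFAULT_CUTOFF_LOG10 = 2.1


@dataclass(frozen=True)
class ShieldsScore:
    """One patient's index with the components that produced it.

    ``log10_index`` is ``None`` when the raw index is 0 (possible only
    at LVD = 0); such scores rank lowest and classify negative.
    """

    lvd_used: float
    invasion_factor: int
    thickness_mm: float
    index: float
    log10_index: float | None
    variant: str = "total"


@dataclass
class ScoredCohort:
    """Cohort records paired one-to-one with their scores (order
    preserved); ``n_skipped`` counts records lacking the LVD variant."""

    records: list[PatientRecord]
    scores: list[ShieldsScore]
    variant: str
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def log10_values(self, fill: float = -math.inf) -> np.ndarray:
        """log10 index per record; zero-index records get ``fill`` so the
        array stays rank-equivalent to the raw index."""
        return np.array(
            [s.log10_index if s.log10_index is not None else fill for s in self.scores]
        )

    def labels(self) -> np.ndarray:
        """1 for metastatic cases, 0 for controls, aligned to scores."""
        return np.array([int(r.is_case) for r in self.records])


def compute_index(
    lvd: float, lvi: bool, thickness_mm: float, variant: str = "total"
) -> ShieldsScore:
    """Score one patient.

    Raises ``ValueError`` for negative LVD or non-positive thickness.

    >>> compute_index(10.0, True, 2.0).index
    400.0
    """
    if not math.isfinite(lvd) or lvd < 0:
        raise ValueError(f"lvd must be finite and >= 0, got {lvd}")
    if not math.isfinite(thickness_mm) or thickness_mm <= 0:
        raise ValueError(f"thickness_mm must be finite and > 0, got {thickness_mm}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    invasion = 2 if lvi else 1
    index = lvd * lvd * invasion * thickness_mm
    log10_index = math.log10(index) if index > 0 else None
    return ShieldsScore(
        lvd_used=lvd,
        invasion_factor=invasion,
        thickness_mm=thickness_mm,
        index=index,
        log10_index=log10_index,
        variant=variant,
    )


def score_cohort(cohort: Cohort, variant: str = "total") -> ScoredCohort:
    """Score every eligible record of a cohort.

    ``variant="hotspot"`` uses hot-spot LVD; records without a hot-spot
    reading (or, for ``total``, without total LVD) are skipped and
    counted.  A hotspot request against a cohort with no hot-spot data
    at all raises.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    records, scores, skipped = [], [], 0
    for r in cohort:
        lvd = r.lvd_total if variant == "total" else r.lvd_hotspot
        if lvd is None or r.breslow_mm is None:
            skipped += 1
            continue
        records.append(r)
        scores.append(compute_index(lvd, r.lvi, r.breslow_mm, variant=variant))
    if variant == "hotspot" and not scores:
        raise ValueError("cohort has no hot-spot LVD measurements")
    return ScoredCohort(records=records, scores=scores, variant=variant, n_skipped=skipped)


def classify(
    scores: Iterable[ShieldsScore] | Sequence[float] | np.ndarray,
    cutoff_log10: float = DEFAULT_CUTOFF_LOG10,
) -> np.ndarray:
    """Predict metastasis by strict exceedance of the log10 cutoff.

    Accepts ShieldsScore objects or raw log10 values; an undefined
    log10 (zero index) predicts negative.  A score exactly at the
    cutoff is negative.
    """
    if not math.isfinite(cutoff_log10):
        raise ValueError("cutoff must be finite")
    vals = []
    for s in scores:
        if isinstance(s, ShieldsScore):
            vals.append(-math.inf if s.log10_index is None else s.log10_index)
        else:
            vals.append(float(s))
    return np.array(vals) > cutoff_log10
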