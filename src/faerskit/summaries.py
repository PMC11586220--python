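"""Demographic and outcome summaries per drug cohort.

Reproduces the layout of conventional pharmacovigilance descriptive tables:
age median (Q1, Q3) and strata, sex counts with a female/male ratio,
reporter occupations, top reporting countries, yearly counts, dose medians,
and the seven-category FAERS outcome distribution (Death, Life-Threatening,
Hospitalization, Disability, Congenital Anomaly, Required Intervention,
Other Serious).

Rounding follows table conventions: proportions to 2 decimals, ratios to 1
decimal, both half-up.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .ingest import OUTCOME_CODES, ReportCase

__all__ = [
    "OUTCOME_LABELS",
    "CohortSummary",
    "OutcomeSummary",
    "round_half_up",
    "summarize_cohort",
    "summarize_outcomes",
]

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other Serious (Important Medical Event)",
}

AGE_STRATA = ("[0-18)", "[18-60)", "[60-100)", "unknown")


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ndigits decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class CohortSummary:
    n_cases: int
    age_median: Optional[float]
    age_q1: Optional[float]
    age_q3: Optional[float]
    age_strata: dict[str, int]
    sex_counts: dict[str, int]
    sex_props: dict[str, float]  # percent, 2 decimals
    female_male_ratio: Optional[float]  # 1 decimal
    reporter_counts: dict[str, int]
    reporter_props: dict[str, float]
    top_countries: list[tuple[str, float]]  # (country, percent), top 5
    yearly_counts: dict[int, int]
    yearly_props: dict[int, float]
    single_dose: Optional[dict] = None  # median/q1/q3/unit/n_used/n_excluded
    cumulative_dose: Optional[dict] = None


def _dose_summary(doses: list[tuple[float, str]]) -> Optional[dict]:
    """Median (Q1, Q3) in the cohort's canonical (modal) unit; values in
    other units are excluded and counted."""
    if not doses:
        return None
    unit_counts = Counter(u for _, u in doses)
    unit = unit_counts.most_common(1)[0][0]
    used = [v for v, u in doses if u == unit]
    med, q1, q3 = _quartiles(used)
    return {
        "median": med, "q1": q1, "q3": q3, "unit": unit,
        "n_used": len(used), "n_excluded": len(doses) - len(used),
    }


def summarize_cohort(cases: Sequence[ReportCase]) -> CohortSummary:
    """Demographic summary of one drug cohort; raises on an empty cohort."""
    if not cases:
        raise ValueError("empty cohort")
    n = len(cases)

    ages = [c.age_years for c in cases if c.age_years is not None]
    strata = dict.fromkeys(AGE_STRATA, 0)
    for c in cases:
        a = c.age_years
        if a is None or a >= 100:
            strata["unknown"] += 1
        elif a < 18:
            strata["[0-18)"] += 1
        elif a < 60:
            strata["[18-60)"] += 1
        else:
            strata["[60-100)"] += 1

    sex_counts = Counter(c.sex for c in cases)
    sex_counts = {k: sex_counts.get(k, 0) for k in ("F", "M", "unknown")}
    sex_props = {k: round_half_up(100.0 * v / n, 2) for k, v in sex_counts.items()}
    ratio = (
        round_half_up(sex_counts["F"] / sex_counts["M"], 1) if sex_counts["M"] else None
    )

    rep_counts = dict(Counter(c.reporter for c in cases).most_common())
    rep_props = {k: round_half_up(100.0 * v / n, 2) for k, v in rep_counts.items()}

    country_counts = Counter(c.country for c in cases)
    top = [
        (ctry, round_half_up(100.0 * cnt / n, 2))
        for ctry, cnt in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    ]

    yearly = dict(sorted(Counter(c.report_year for c in cases).items()))
    yearly_props = {y: round_half_up(100.0 * v / n, 2) for y, v in yearly.items()}

    med = q1 = q3 = None
    if ages:
        med, q1, q3 = _quartiles(ages)

    return CohortSummary(
        n_cases=n,
        age_median=med,
        age_q1=q1,
        age_q3=q3,
        age_strata=strata,
        sex_counts=sex_counts,
        sex_props=sex_props,
        female_male_ratio=ratio,
        reporter_counts=rep_counts,
        reporter_props=rep_props,
        top_countries=top,
        yearly_counts=yearly,
        yearly_props=yearly_props,
        single_dose=_dose_summary([c.single_dose for c in cases if c.single_dose]),
        cumulative_dose=_dose_summary(
            [c.cumulative_dose for c in cases if c.cumulative_dose]
        ),
    )


@dataclass
class OutcomeSummary:
    counts: dict[str, int]  # outcome code -> record count
    proportions: dict[str, float]  # percent of all outcome records, 2 decimals

    @property
    def labels(self) -> dict[str, str]:
        return OUTCOME_LABELS

    @property
    def total_records(self) -> int:
        return sum(self.counts.values())


def summarize_outcomes(cases: Sequence[ReportCase]) -> OutcomeSummary:
    """Seven-category outcome distribution for one cohort.

    Each case contributes one record per reported outcome code, so the
    proportion denominator is the sum of the seven counts, not the cohort
    size. Raises when no case carries any outcome.
    """
    counts = dict.fromkeys(OUTCOME_CODES, 0)
    for c in cases:
        for code in c.outcomes:
            counts[code] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no outcome data")
    props = {k: round_half_up(100.0 * v / total, 2) for k, v in counts.items()}
    return OutcomeSummary(counts=counts, proportions=props)
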