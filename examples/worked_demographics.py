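"""Demographic and outcome table cells from known cohort counts.

Builds a 580-case cohort with the sex split 362 F / 149 M / 69 unknown and
a 75-record outcome column (1 death, 6 life-threatening, 22
hospitalizations, 3 disability, 43 other-serious) and prints the summary
cells: the female/male ratio, the percent columns, and the outcome
distribution whose denominator is the number of outcome *records* (a case
reporting two outcome codes contributes twice).
"""

from faerskit.ingest import ReportCase
from faerskit.summaries import OUTCOME_LABELS, summarize_cohort, summarize_outcomes


def case(pid, sex="F", outcomes=()):
    return ReportCase(
        primaryid=pid, caseid=pid, version=1, age_years=None, sex=sex,
        reporter="consumer", country="US", report_year=2021,
        events=["Any event"], outcomes=frozenset(outcomes),
    )


cohort = (
    [case(f"f{i}", "F") for i in range(362)]
    + [case(f"m{i}", "M") for i in range(149)]
    + [case(f"u{i}", "unknown") for i in range(69)]
)
demo = summarize_cohort(cohort)
print(f"cohort n = {demo.n_cases}")
print(f"female/male ratio = {demo.female_male_ratio}")
for sex in ("F", "M", "unknown"):
    print(f"  {sex:8s} {demo.sex_counts[sex]:4d}  {demo.sex_props[sex]:6.2f}%")

outcome_counts = {"DE": 1, "LT": 6, "HO": 22, "DS": 3, "CA": 0, "RI": 0, "OT": 43}
ocases, i = [], 0
for code, n in outcome_counts.items():
    for _ in range(n):
        ocases.append(case(str(i), outcomes=[code]))
        i += 1
oc = summarize_outcomes(ocases)
print(f"\noutcome records = {oc.total_records}")
for code in outcome_counts:
    print(f"  {OUTCOME_LABELS[code][:40]:40s} {oc.counts[code]:3d}  {oc.proportions[code]:6.2f}%")
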