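"""Empirical-Bayes shrinkage of the MGPS relative reporting rate.

For a fixed observed/expected ratio a/E = 5, EBGM is pulled toward 1 when
the count is small (little evidence) and approaches the raw ratio as the
count grows. EB05, the 5th posterior percentile, is the screening
statistic: EB05 > 2 declares an MGPS signal.
"""

import math

from faerskit.disprop import DUMOUCHEL_START, ContingencyTable, compute_ebgm


def table(a: int, e: float, n: int = 10_000_000) -> ContingencyTable:
    margin = int(round(math.sqrt(e * n)))
    return ContingencyTable(a, margin - a, margin - a, n - 2 * margin + a)


print(f"{'a':>6} {'E':>8} {'a/E':>6} {'EBGM':>7} {'EB05':>7}  signal(EB05>2)")
for a in (1, 2, 5, 20, 100, 1000):
    e = a / 5.0
    t = table(a, e)
    r = compute_ebgm(t, DUMOUCHEL_START)
    print(f"{a:>6} {t.expected:8.2f} {a / t.expected:6.2f} "
          f"{r.ebgm:7.2f} {r.eb05:7.2f}  {r.eb05 > 2}")
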