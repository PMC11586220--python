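"""Roll PT-level signals up the MedDRA hierarchy to SOC proportions.

Runs the full pipeline on a synthetic database with two planted psychiatric
signals and one respiratory signal for the same drug, then aggregates the
positive signals to System Organ Class level. Proportions are weighted by
signal case count (each group's share of the drug's total signal cases);
a signal-count weighting is emitted alongside.
"""

import faerskit as fk
from faerskit.meddra import aggregate_signals, map_from_catalog
from faerskit.pipeline import cases_from_dataset, synonyms_from_catalog

cfg = fk.SyntheticConfig(
    n_cases=30_000,
    planted_signals=[
        ("solriamfetol", "Suicidal ideation", 8.0),
        ("solriamfetol", "Abnormal dreams", 6.0),
        ("solriamfetol", "Sleep apnoea syndrome", 8.0),
    ],
    seed=7,
)
cases, _ = cases_from_dataset(
    fk.generate_dataset(cfg), synonyms_from_catalog(cfg.drug_catalog)
)
result = fk.evaluate_database(cases, sorted(g.name for g in cfg.drug_catalog))
signals = result.signals("solriamfetol")
print(f"solriamfetol: {len(signals)} positive signals")

mm = map_from_catalog(cfg.event_catalog)
for level in ("SOC", "HLGT"):
    agg = aggregate_signals(signals, mm, level=level)
    print(f"\n{level} aggregation:")
    for row in agg.itertuples(index=False):
        print(f"  {row.group[:52]:52s} n_sig={row.n_signals} "
              f"cases={row.case_count:5d}  {100 * row.proportion:5.1f}%")
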