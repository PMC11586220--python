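"""End-to-end orchestration: simulate -> ingest -> signals -> aggregate -> summarize.

A run is fully described by a :class:`RunConfig` (data source, synonym and
MedDRA configuration, study window, signal policy, seed) and produces
per-drug signal tables, HLGT/SOC aggregation tables, top-k rankings,
cohort/outcome summaries, and a machine-readable manifest reconciling the
case counts at every stage. Identical config + seed gives byte-identical
outputs; any stage failure aborts with the stage name and removes partial
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import disprop, meddra, summaries
from .ingest import IngestTables, SynonymConfig, assemble_cases, deduplicate, read_tables
from .synthetic import (
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    write_faers_ascii,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "synonyms_from_catalog",
    "cases_from_tables",
    "cases_from_dataset",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def synonyms_from_catalog(drug_catalog: Sequence) -> SynonymConfig:
    """Synonym table (group -> generic+brand names) from a DrugGroup catalog."""
    return SynonymConfig({g.name: list(g.all_names) for g in drug_catalog})


def cases_from_tables(
    tables: IngestTables, synonyms: SynonymConfig
) -> tuple[list, dict]:
    """Deduplicate DEMO, assemble ReportCase records, return cases + stage log."""
    demo, n_removed = deduplicate(tables["DEMO"])
    t = dict(tables.tables)
    t["DEMO"] = demo
    cases, log = assemble_cases(t, synonyms)
    log["duplicates_removed"] = n_removed
    log["outside_window"] = tables.n_outside_window
    log["skipped_lines"] = dict(tables.skipped)
    return cases, log


def cases_from_dataset(
    dataset: SyntheticDataset, synonyms: Optional[SynonymConfig] = None
) -> tuple[list, dict]:
    """In-memory ingest of a generated dataset (no file round trip)."""
    tables = IngestTables(tables=dict(dataset.tables), skipped={})
    if synonyms is None:
        raise ValueError("synonyms required")
    return cases_from_tables(tables, synonyms)


@dataclass
class RunConfig:
    out_dir: Path
    synonyms: SynonymConfig
    meddra_map: meddra.MeddraMap
    data_dir: Optional[Path] = None  # read an existing FAERS-style directory ...
    synthetic: Optional[SyntheticConfig] = None  # ... or generate one
    window: Optional[tuple[int, int]] = None
    policy: str = "all"
    thresholds: disprop.SignalThresholds = disprop.DEFAULT_THRESHOLDS
    top_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of data_dir / synthetic must be given")
        if self.policy not in ("all", "any"):
            raise ValueError(f"policy must be 'all' or 'any', got {self.policy!r}")
        if self.window is not None and self.window[0] > self.window[1]:
            raise ValueError("window is empty")


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir).

    Output layout::

        out_dir/
          data/                      # synthetic source tables (if generated)
          signals_<drug>.tsv         # all evaluated pairs with stats + flags
          top15_<drug>.tsv           # top-k positive signals
          agg_<level>_<drug>.tsv     # HLGT/SOC aggregation of positive signals
          summary_<drug>.json        # demographic + outcome summaries
          manifest.json
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        manifest: dict = {"seed": config.seed, "policy": config.policy, "stages": {}}

        if config.synthetic is not None:
            stage = "simulate"
            sim = dataclasses.replace(config.synthetic, seed=config.seed)
            dataset = generate_dataset(sim)
            data_dir = out_dir / "data"
            written.extend(write_faers_ascii(dataset, data_dir))
            manifest["stages"]["simulate"] = {
                "n_cases": sim.n_cases,
                "planted_signals": [list(p) for p in sim.planted_signals],
            }
        else:
            data_dir = Path(config.data_dir)

        stage = "ingest"
        tables = read_tables(data_dir, window=config.window)
        cases, log = cases_from_tables(tables, config.synonyms)
        manifest["stages"]["ingest"] = log

        stage = "signals"
        drug_groups = sorted(config.synonyms.groups)
        result = disprop.evaluate_database(
            cases, drug_groups, policy=config.policy, thresholds=config.thresholds
        )
        manifest["stages"]["signals"] = {
            "n_cases": result.n_cases,
            "cohort_sizes": result.cohort_sizes,
            "tables_evaluated": {g: len(rs) for g, rs in result.rows.items()},
            "signals_found": {g: len(result.signals(g)) for g in drug_groups},
            "mgps_prior": {
                "alpha1": result.prior.alpha1, "beta1": result.prior.beta1,
                "alpha2": result.prior.alpha2, "beta2": result.prior.beta2,
                "p_mix": result.prior.p_mix, "converged": result.prior.converged,
            },
        }
        mm = config.meddra_map
        for g in drug_groups:
            rows = result.rows.get(g, [])
            df = pd.DataFrame([r.to_dict() for r in rows])
            if len(df):
                df.insert(2, "hlgt", [mm.hlgt(r.pt) or meddra.UNMAPPED for r in rows])
                df.insert(3, "soc", [mm.soc(r.pt) or meddra.UNMAPPED for r in rows])
            _write_tsv(df, out_dir / f"signals_{g}.tsv", written)
            top = disprop.rank_top_k(result.signals(g), config.top_k)
            _write_tsv(
                pd.DataFrame([r.to_dict() for r in top]),
                out_dir / f"top{config.top_k}_{g}.tsv",
                written,
            )

        stage = "aggregate"
        for g in drug_groups:
            for level in ("HLGT", "SOC"):
                agg = meddra.aggregate_signals(result.signals(g), mm, level=level)
                _write_tsv(agg, out_dir / f"agg_{level.lower()}_{g}.tsv", written)

        stage = "summarize"
        for g in drug_groups:
            cohort = [c for c in cases if c.in_cohort(g)]
            summary: dict = {"drug": g, "n_cases": len(cohort)}
            if cohort:
                cs = summaries.summarize_cohort(cohort)
                summary["demographics"] = dataclasses.asdict(cs)
                try:
                    os_ = summaries.summarize_outcomes(cohort)
                    summary["outcomes"] = {
                        "counts": os_.counts, "proportions": os_.proportions,
                    }
                except ValueError:
                    summary["outcomes"] = None
            path = out_dir / f"summary_{g}.json"
            with open(path, "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            written.append(path)

        stage = "manifest"
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        written.append(manifest_path)
        return manifest
    except Exception as err:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(stage, err) from err
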