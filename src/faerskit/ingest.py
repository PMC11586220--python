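"""Ingestion of FAERS-style quarterly ASCII tables into case records.

FAERS publishes seven $-delimited tables per quarter (DEMO, DRUG, REAC,
OUTC, RPSR, THER, INDI). This module reads that dialect, restricts to a
study window by FDA receipt year, deduplicates cases (one report per FAERS
caseid, keeping the latest version), normalizes verbatim drug names to
configured drug groups via generic/brand synonym lists, and assembles one
:class:`ReportCase` per retained report.

The counting unit everywhere downstream is the deduplicated case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "TABLE_NAMES",
    "TABLE_COLUMNS",
    "OUTCOME_CODES",
    "DrugMention",
    "ReportCase",
    "SynonymConfig",
    "IngestTables",
    "read_tables",
    "deduplicate",
    "normalize_drug",
    "assemble_cases",
]

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")

TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
        "sex", "occp_cod", "occr_country",
    ],
    "DRUG": [
        "primaryid", "caseid", "drug_seq", "role_cod", "drugname",
        "dose_amt", "dose_unit", "cum_dose_chr", "cum_dose_unit",
    ],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
ROLE_CODES = ("PS", "SS", "C", "I")

# FAERS occp_cod -> reporter category used in demographic summaries
_REPORTER_MAP = {
    "CN": "consumer",
    "HP": "health-professional",
    "LW": "lawyer",
    "MD": "physician",
    "OT": "other health-professional",
    "PH": "pharmacist",
}

# FAERS age_cod -> factor converting the stated value to years
_AGE_FACTORS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.0,
    "DY": 1 / 365.25, "HR": 1 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0


@dataclass
class DrugMention:
    raw_name: str
    drug_group: Optional[str]
    role_code: str
    dose_amt: Optional[float] = None
    dose_unit: Optional[str] = None
    cum_dose_amt: Optional[float] = None
    cum_dose_unit: Optional[str] = None
    therapy_start: Optional[date] = None
    therapy_end: Optional[date] = None


@dataclass
class ReportCase:
    """One deduplicated safety report."""

    primaryid: str
    caseid: str
    version: int
    age_years: Optional[float]
    sex: str  # F | M | unknown
    reporter: str
    country: str
    report_year: int
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    outcomes: frozenset[str] = frozenset()
    single_dose: Optional[tuple[float, str]] = None
    cumulative_dose: Optional[tuple[float, str]] = None
    cohort_groups: frozenset[str] = frozenset()

    def in_cohort(self, drug_group: str) -> bool:
        """True iff the case has a qualifying (primary-suspect) mention of the group."""
        return drug_group in self.cohort_groups


# ---------------------------------------------------------------------------
# Drug-name normalization


_STRENGTH_RE = re.compile(r"\s*\([^)]*\)\s*$")


def _canon(name: str) -> str:
    """Case-fold, trim, and strip one trailing parenthetical (strength) suffix."""
    return _STRENGTH_RE.sub("", name.strip()).strip().upper()


class SynonymConfig:
    """Drug-group synonym table: group id -> generic and brand name strings."""

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        self.groups = {g: sorted({_canon(n) for n in names}) for g, names in groups.items()}
        self._reverse: dict[str, str] = {}
        for g, names in self.groups.items():
            for n in names:
                other = self._reverse.get(n)
                if other is not None and other != g:
                    raise ValueError(
                        f"synonym {n!r} claimed by both groups {other!r} and {g!r}"
                    )
                self._reverse[n] = g

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynonymConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"synonym file {path} must map group -> name list")
        return cls(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({g: list(ns) for g, ns in self.groups.items()}, fh, sort_keys=True)

    def lookup(self, raw_name: str) -> Optional[str]:
        return self._reverse.get(_canon(raw_name))


def normalize_drug(raw_name: str, synonyms: SynonymConfig) -> Optional[str]:
    """Resolve a verbatim drug name to its configured group, else None.

    Matching is exact after case folding, whitespace trimming and removal of
    a trailing parenthetical strength, e.g. ``"Wakix (17.8 mg)"`` matches a
    ``WAKIX`` synonym.
    """
    return synonyms.lookup(raw_name)


# ---------------------------------------------------------------------------
# Reading the $-delimited quarterly dialect


@dataclass
class IngestTables:
    """Parsed raw tables plus per-table parse/window accounting."""

    tables: dict[str, pd.DataFrame]
    skipped: dict[str, int]
    n_outside_window: int = 0

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Parse one $-delimited file; malformed lines (wrong field count) are
    skipped and counted rather than padded — FAERS rows are fixed-arity."""
    with open(path, newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise ValueError(f"{path.name}: empty file (no header)")
    header = lines[0].split("$")
    ncol = len(header)
    rows, skipped = [], 0
    for line in lines[1:]:
        fields = line.split("$")
        if len(fields) != ncol:
            skipped += 1
            continue
        rows.append(fields)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    return df, skipped


def read_tables(
    directory: str | Path,
    window: Optional[tuple[int, int]] = None,
) -> IngestTables:
    """Read the seven FAERS-style tables from ``directory``.

    DEMO, DRUG and REAC must exist; the others default to empty. ``window``
    is an inclusive (from_year, to_year) pair applied to the FDA receipt
    date year on DEMO; child-table rows whose primaryid falls outside the
    window are dropped with it.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.txt"
        if not path.exists():
            if name in MANDATORY_TABLES:
                raise FileNotFoundError(f"mandatory table {name} not found at {path}")
            tables[name] = pd.DataFrame(columns=TABLE_COLUMNS[name], dtype=str)
            skipped[name] = 0
            continue
        tables[name], skipped[name] = _read_dollar_file(path)

    n_outside = 0
    if window is not None:
        lo, hi = window
        demo = tables["DEMO"]
        years = pd.to_numeric(demo["fda_dt"].str[:4], errors="coerce")
        keep = (years >= lo) & (years <= hi)
        n_outside = int((~keep).sum())
        tables["DEMO"] = demo[keep].reset_index(drop=True)
        kept_ids = set(tables["DEMO"]["primaryid"])
        for name in TABLE_NAMES[1:]:
            t = tables[name]
            if len(t):
                tables[name] = t[t["primaryid"].isin(kept_ids)].reset_index(drop=True)
    return IngestTables(tables=tables, skipped=skipped, n_outside_window=n_outside)


# ---------------------------------------------------------------------------
# Deduplication


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """One row per caseid: highest version, ties broken by highest primaryid.

    The primaryid tie-break compares numerically via zero padding so that
    e.g. ``"1002"`` beats ``"999"``. Returns the kept rows and the number
    removed. Idempotent.
    """
    if len(demo) == 0:
        return demo.copy(), 0
    width = demo["primaryid"].str.len().max()
    order = demo.assign(
        _ver=pd.to_numeric(demo["caseversion"], errors="coerce").fillna(-1),
        _pid=demo["primaryid"].str.zfill(width),
    ).sort_values(["caseid", "_ver", "_pid"], kind="mergesort")
    kept = order.drop_duplicates("caseid", keep="last").drop(columns=["_ver", "_pid"])
    kept = kept.sort_index().reset_index(drop=True)
    return kept, len(demo) - len(kept)


# ---------------------------------------------------------------------------
# Case assembly


def _parse_float(s: str) -> Optional[float]:
    try:
        v = float(s)
    except (TypeError, ValueError):
        return None
    return v if v == v else None  # NaN guard


def _parse_age(value: str, unit: str) -> Optional[float]:
    v = _parse_float(value)
    if v is None or v < 0:
        return None
    factor = _AGE_FACTORS.get(unit.strip().upper() or "YR")
    if factor is None:
        return None
    years = v * factor
    return years if years <= MAX_PLAUSIBLE_AGE else None


def _parse_date(s: str) -> Optional[date]:
    s = (s or "").strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return datetime.strptime(s, "%Y%m%d").date()
    except ValueError:
        return None


def _cumulative_dose(m: DrugMention) -> Optional[tuple[float, str]]:
    """Dose_amt x administration days when therapy dates + a daily dose are
    present; otherwise the reported cumulative field; otherwise missing."""
    if (
        m.dose_amt is not None
        and m.dose_unit
        and m.therapy_start is not None
        and m.therapy_end is not None
        and m.therapy_end >= m.therapy_start
    ):
        days = (m.therapy_end - m.therapy_start).days + 1
        return (m.dose_amt * days, m.dose_unit)
    if m.cum_dose_amt is not None and m.cum_dose_unit:
        return (m.cum_dose_amt, m.cum_dose_unit)
    return None


def assemble_cases(
    tables: IngestTables | Mapping[str, pd.DataFrame],
    synonyms: SynonymConfig,
    role_filter: Sequence[str] = ("PS",),
) -> tuple[list[ReportCase], dict[str, int]]:
    """Join DRUG/REAC/OUTC/THER onto a deduplicated DEMO into ReportCase records.

    ``tables["DEMO"]`` must already be deduplicated. Cohort membership is
    precomputed: a case carries a drug group iff at least one mention of
    that group has a role code in ``role_filter`` (primary suspect by
    default). Cases with no reaction rows are dropped and counted.
    """
    t = tables.tables if isinstance(tables, IngestTables) else dict(tables)
    demo = t["DEMO"]

    def by_pid(name: str) -> dict[str, list]:
        df = t.get(name)
        out: dict[str, list] = {}
        if df is None or len(df) == 0:
            return out
        for row in df.itertuples(index=False):
            out.setdefault(row.primaryid, []).append(row)
        return out

    drug_g, reac_g, outc_g, ther_g = (by_pid(n) for n in ("DRUG", "REAC", "OUTC", "THER"))

    log = {"demo_rows": len(demo), "no_event_dropped": 0, "unknown_outcome_codes": 0}
    cases: list[ReportCase] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        reac = reac_g.get(pid)
        if not reac:
            log["no_event_dropped"] += 1
            continue
        events = list(dict.fromkeys(r.pt for r in reac))

        mentions: list[DrugMention] = []
        ther_by_seq = {r.dsg_drug_seq: r for r in ther_g.get(pid, [])}
        for d in drug_g.get(pid, []):
            th = ther_by_seq.get(d.drug_seq)
            mentions.append(
                DrugMention(
                    raw_name=d.drugname,
                    drug_group=normalize_drug(d.drugname, synonyms),
                    role_code=d.role_cod if d.role_cod in ROLE_CODES else "C",
                    dose_amt=_parse_float(d.dose_amt),
                    dose_unit=d.dose_unit or None,
                    cum_dose_amt=_parse_float(d.cum_dose_chr),
                    cum_dose_unit=d.cum_dose_unit or None,
                    therapy_start=_parse_date(th.start_dt) if th is not None else None,
                    therapy_end=_parse_date(th.end_dt) if th is not None else None,
                )
            )

        outcomes = set()
        for o in outc_g.get(pid, []):
            if o.outc_cod in OUTCOME_CODES:
                outcomes.add(o.outc_cod)
            else:
                log["unknown_outcome_codes"] += 1

        cohorts = frozenset(
            m.drug_group
            for m in mentions
            if m.drug_group is not None and m.role_code in role_filter
        )
        primary = next((m for m in mentions if m.role_code == "PS"), None)
        single = (
            (primary.dose_amt, primary.dose_unit)
            if primary is not None and primary.dose_amt is not None and primary.dose_unit
            else None
        )
        cumulative = _cumulative_dose(primary) if primary is not None else None

        cases.append(
            ReportCase(
                primaryid=pid,
                caseid=row.caseid,
                version=int(row.caseversion) if row.caseversion.isdigit() else 1,
                age_years=_parse_age(row.age, row.age_cod),
                sex=row.sex if row.sex in ("F", "M") else "unknown",
                reporter=_REPORTER_MAP.get(row.occp_cod, "unknown"),
                country=row.occr_country.strip() or "unknown"
                if isinstance(row.occr_country, str)
                else "unknown",
                report_year=int(row.fda_dt[:4]),
                drugs=mentions,
                events=events,
                outcomes=frozenset(outcomes),
                single_dose=single,
                cumulative_dose=cumulative,
                cohort_groups=cohorts,
            )
        )
    log["cases_assembled"] = len(cases)
    return cases, log
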