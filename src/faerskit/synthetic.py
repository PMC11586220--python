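"""Synthetic FAERS-shaped spontaneous-report databases with known ground truth.

Emulates the structure of the FAERS quarterly extract — seven $-delimited
tables (DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI) keyed by primaryid/caseid
— for a configurable catalog of drug groups and MedDRA-style event terms.
Each case receives one primary-suspect drug; every event PT is then drawn
independently with its background co-reporting probability, multiplied by a
planted relative risk rho for configured (drug, event) signal pairs. A
configurable fraction of cases is re-emitted as a second case version
(same caseid, new primaryid) to exercise deduplication.

Because event draws are independent Bernoullis, the reporting odds ratio
implied by the sampling scheme has a closed form (:func:`scheme_true_ror`),
which downstream recovery tests use as ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import OUTCOME_CODES, TABLE_COLUMNS, TABLE_NAMES

__all__ = [
    "ConfigError",
    "DrugGroup",
    "EventTerm",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_config",
    "generate_dataset",
    "write_faers_ascii",
    "read_ground_truth",
    "scheme_true_ror",
]

GROUND_TRUTH_FILE = "ground_truth.json"


class ConfigError(ValueError):
    """Invalid generator configuration; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class DrugGroup:
    name: str
    generics: tuple[str, ...]
    brands: tuple[str, ...] = ()
    dose_amt: float = 100.0
    dose_unit: str = "MG"

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.generics + self.brands


@dataclass(frozen=True)
class EventTerm:
    pt: str
    hlgt: str
    soc: str
    base_rate: float = 0.05  # baseline per-case co-reporting probability


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate a mid-sized narcolepsy-drug
    reporting population (mostly adult, majority female, US-dominated)."""

    n_cases: int = 1000
    duplicate_fraction: float = 0.10
    drug_catalog: Sequence[DrugGroup] = ()
    event_catalog: Sequence[EventTerm] = ()
    background_rates: dict = field(default_factory=dict)  # (drug, pt) -> prob override
    planted_signals: Sequence[tuple[str, str, float]] = ()
    drug_probs: Optional[Sequence[float]] = None  # uniform when None
    sex_probs: dict = field(default_factory=lambda: {"F": 0.665, "M": 0.285, "UNK": 0.05})
    age_strata_probs: Sequence[float] = (0.04, 0.78, 0.18)  # child / adult / elderly
    age_strata_ranges: Sequence[tuple[int, int]] = ((1, 18), (18, 60), (60, 95))
    missing_age_fraction: float = 0.30
    reporter_probs: dict = field(
        default_factory=lambda: {
            "CN": 0.55, "MD": 0.17, "HP": 0.13, "PH": 0.03, "OT": 0.02,
            "LW": 0.002, "UNK": 0.098,
        }
    )
    country_probs: dict = field(
        default_factory=lambda: {"US": 0.90, "FR": 0.035, "GB": 0.03, "CA": 0.02, "DE": 0.015}
    )
    year_range: tuple[int, int] = (2019, 2023)
    outcome_probs: dict = field(
        default_factory=lambda: {
            "OT": 0.35, "HO": 0.12, "DE": 0.012, "LT": 0.012, "DS": 0.012,
            "CA": 0.003, "RI": 0.003,
        }
    )
    p_secondary_drug: float = 0.20  # cases listing one extra (non-PS) drug
    secondary_role_probs: dict = field(
        default_factory=lambda: {"SS": 0.4, "C": 0.5, "I": 0.1}
    )
    p_therapy: float = 0.70
    therapy_median_days: float = 30.0
    therapy_log_sigma: float = 0.75
    p_rpsr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.drug_catalog:
            self.drug_catalog = DEFAULT_DRUG_CATALOG
        if not self.event_catalog:
            self.event_catalog = DEFAULT_EVENT_CATALOG
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.n_cases, int) or self.n_cases < 1:
            raise ConfigError("n_cases", f"must be a positive integer, got {self.n_cases}")
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigError("duplicate_fraction", "must lie in [0, 1)")
        drugs = {g.name for g in self.drug_catalog}
        pts = {e.pt for e in self.event_catalog}
        if len(drugs) != len(self.drug_catalog):
            raise ConfigError("drug_catalog", "duplicate group names")
        if len(pts) != len(self.event_catalog):
            raise ConfigError("event_catalog", "duplicate PT names")
        for d, e, rho in self.planted_signals:
            if d not in drugs:
                raise ConfigError("planted_signals", f"unknown drug {d!r}")
            if e not in pts:
                raise ConfigError("planted_signals", f"unknown event {e!r}")
            if not rho > 0:
                raise ConfigError("planted_signals", f"relative risk must be > 0, got {rho}")
        for name, probs in (
            ("sex_probs", list(self.sex_probs.values())),
            ("reporter_probs", list(self.reporter_probs.values())),
            ("country_probs", list(self.country_probs.values())),
            ("age_strata_probs", list(self.age_strata_probs)),
            ("secondary_role_probs", list(self.secondary_role_probs.values())),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(name, f"probabilities sum to {sum(probs)}, not 1")
        if self.drug_probs is not None:
            if len(self.drug_probs) != len(self.drug_catalog):
                raise ConfigError("drug_probs", "length must match drug_catalog")
            if abs(sum(self.drug_probs) - 1.0) > 1e-9:
                raise ConfigError("drug_probs", "probabilities must sum to 1")
        rates = self.rate_matrix()
        if np.any(rates < 0) or np.any(rates > 1):
            raise ConfigError("background_rates", "implied event probabilities outside [0, 1]")

    # -- derived quantities ----------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Per (drug, PT) event probability including planted relative risks."""
        rates = np.empty((len(self.drug_catalog), len(self.event_catalog)))
        for i, g in enumerate(self.drug_catalog):
            for j, ev in enumerate(self.event_catalog):
                rates[i, j] = self.background_rates.get((g.name, ev.pt), ev.base_rate)
        for d, e, rho in self.planted_signals:
            i = next(i for i, g in enumerate(self.drug_catalog) if g.name == d)
            j = next(j for j, ev in enumerate(self.event_catalog) if ev.pt == e)
            rates[i, j] *= rho
        return rates

    def effective_drug_probs(self) -> np.ndarray:
        if self.drug_probs is not None:
            return np.asarray(self.drug_probs, dtype=float)
        k = len(self.drug_catalog)
        return np.full(k, 1.0 / k)


DEFAULT_DRUG_CATALOG: tuple[DrugGroup, ...] = (
    DrugGroup("pitolisant", ("PITOLISANT", "PITOLISANT HYDROCHLORIDE"), ("WAKIX",), 17.8, "MG"),
    DrugGroup("sodium_oxybate", ("SODIUM OXYBATE",), ("XYREM", "XYWAV", "LUMRYZ"), 2250.0, "MG"),
    DrugGroup(
        "solriamfetol", ("SOLRIAMFETOL", "SOLRIAMFETOL HYDROCHLORIDE"), ("SUNOSI",), 75.0, "MG"
    ),
    DrugGroup("modafinil", ("MODAFINIL",), ("PROVIGIL",), 200.0, "MG"),
)

_PSY = "Psychiatric disorders"
_NRV = "Nervous system disorders"
_RSP = "Respiratory, thoracic and mediastinal disorders"
_GIT = "Gastrointestinal disorders"
_GEN = "General disorders and administration site conditions"
_CRD = "Cardiac disorders"

DEFAULT_EVENT_CATALOG: tuple[EventTerm, ...] = (
    EventTerm("Insomnia", "Sleep disorders and disturbances", _PSY, 0.10),
    EventTerm("Abnormal dreams", "Sleep disorders and disturbances", _PSY, 0.04),
    EventTerm("Anxiety", "Anxiety disorders and symptoms", _PSY, 0.12),
    EventTerm("Depression", "Depressive mood disorders and disturbances", _PSY, 0.10),
    EventTerm("Suicidal ideation", "Suicidal and self-injurious behaviour", _PSY, 0.03),
    EventTerm("Headache", "Headaches", _NRV, 0.15),
    EventTerm("Migraine", "Headaches", _NRV, 0.03),
    EventTerm("Somnolence", "Neurological disorders NEC", _NRV, 0.08),
    EventTerm("Dizziness", "Neurological disorders NEC", _NRV, 0.08),
    EventTerm("Memory impairment", "Mental impairment disorders", _NRV, 0.03),
    EventTerm("Sleep apnoea syndrome", "Breathing abnormalities", _RSP, 0.04),
    EventTerm("Dyspnoea", "Breathing abnormalities", _RSP, 0.06),
    EventTerm("Cough", "Upper respiratory tract disorders", _RSP, 0.05),
    EventTerm("Nausea", "Gastrointestinal motility and defaecation conditions", _GIT, 0.12),
    EventTerm("Vomiting", "Gastrointestinal motility and defaecation conditions", _GIT, 0.06),
    EventTerm("Diarrhoea", "Gastrointestinal motility and defaecation conditions", _GIT, 0.06),
    EventTerm("Drug ineffective", "Therapeutic and nontherapeutic responses", _GEN, 0.12),
    EventTerm("Fatigue", "General system disorders NEC", _GEN, 0.10),
    EventTerm("Pyrexia", "General system disorders NEC", _GEN, 0.04),
    EventTerm("Palpitations", "Cardiac arrhythmias", _CRD, 0.05),
    EventTerm("Tachycardia", "Cardiac arrhythmias", _CRD, 0.03),
)


@dataclass
class SyntheticDataset:
    """The seven FAERS-style tables (string-typed DataFrames) + ground truth."""

    tables: dict[str, pd.DataFrame]
    ground_truth: dict

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def scheme_true_ror(config: SyntheticConfig, drug: str, pt: str) -> float:
    """Closed-form reporting odds ratio implied by the sampling scheme.

    Counts condition on case retention at ingest (>= 1 reported event), so
    the no-event probability over the *other* PTs enters the b/d cells:
    odds(E | drug g, retained) = p_gE / [(1 - p_gE)(1 - Q_g)] with
    Q_g = prod_{j != E} (1 - p_gj).
    """
    rates = config.rate_matrix()
    w = config.effective_drug_probs()
    di = next(i for i, g in enumerate(config.drug_catalog) if g.name == drug)
    ej = next(j for j, ev in enumerate(config.event_catalog) if ev.pt == pt)
    others = np.delete(np.arange(len(config.event_catalog)), ej)
    retain = 1.0 - np.prod(1.0 - rates[:, others], axis=1)  # P(>=1 other event | drug)
    p_e = rates[:, ej]
    p_a = w[di] * p_e[di]
    p_b = w[di] * (1 - p_e[di]) * retain[di]
    mask = np.arange(len(w)) != di
    p_c = float(np.sum(w[mask] * p_e[mask]))
    p_d = float(np.sum(w[mask] * (1 - p_e[mask]) * retain[mask]))
    return (p_a * p_d) / (p_b * p_c)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("assign", "demo", "drug", "outc", "ther", "rpsr", "dup")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic report database; deterministic for a fixed seed."""
    config.validate()
    rng = _streams(config.seed)
    n = config.n_cases
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    rates = config.rate_matrix()

    caseids = np.array([str(100000001 + i) for i in range(n)])
    pids = np.char.add(caseids, "1")

    # -- drug assignment and event draws (case-level stream) --------------
    ps_idx = rng["assign"].choice(len(drugs), size=n, p=config.effective_drug_probs())
    event_mat = rng["assign"].random((n, len(events))) < rates[ps_idx]

    # -- DEMO --------------------------------------------------------------
    g = rng["demo"]
    sexes = g.choice(list(config.sex_probs), size=n, p=list(config.sex_probs.values()))
    strata = g.choice(len(config.age_strata_probs), size=n, p=list(config.age_strata_probs))
    ages = np.empty(n, dtype=int)
    for k, (lo, hi) in enumerate(config.age_strata_ranges):
        m = strata == k
        ages[m] = g.integers(lo, hi, size=int(m.sum()))
    age_missing = g.random(n) < config.missing_age_fraction
    reporters = g.choice(
        list(config.reporter_probs), size=n, p=list(config.reporter_probs.values())
    )
    countries = g.choice(list(config.country_probs), size=n, p=list(config.country_probs.values()))
    y0, y1 = config.year_range
    years = g.integers(y0, y1 + 1, size=n)
    months = g.integers(1, 13, size=n)
    days = g.integers(1, 29, size=n)
    fda_dt = np.array([f"{y}{m:02d}{d:02d}" for y, m, d in zip(years, months, days)])
    demo = pd.DataFrame(
        {
            "primaryid": pids,
            "caseid": caseids,
            "caseversion": "1",
            "fda_dt": fda_dt,
            "age": np.where(age_missing, "", ages.astype(str)),
            "age_cod": np.where(age_missing, "", "YR"),
            "sex": np.where(sexes == "UNK", "", sexes),
            "occp_cod": np.where(reporters == "UNK", "", reporters),
            "occr_country": countries,
        },
        dtype=str,
    )

    # -- DRUG --------------------------------------------------------------
    g = rng["drug"]
    name_lists = [d.all_names for d in drugs]
    lens = np.array([len(nl) for nl in name_lists])[ps_idx]
    name_idx = np.minimum((g.random(n) * lens).astype(int), lens - 1)
    ps_names = [name_lists[gi][ni] for gi, ni in zip(ps_idx, name_idx)]
    drug_rows = {
        "primaryid": list(pids),
        "caseid": list(caseids),
        "drug_seq": ["1"] * n,
        "role_cod": ["PS"] * n,
        "drugname": ps_names,
        "dose_amt": [_fmt(drugs[i].dose_amt) for i in ps_idx],
        "dose_unit": [drugs[i].dose_unit for i in ps_idx],
        "cum_dose_chr": [""] * n,
        "cum_dose_unit": [""] * n,
    }
    has_sec = g.random(n) < config.p_secondary_drug
    sec_shift = 1 + g.integers(0, max(len(drugs) - 1, 1), size=n)
    sec_idx = (ps_idx + sec_shift) % len(drugs)
    sec_roles = g.choice(
        list(config.secondary_role_probs), size=n, p=list(config.secondary_role_probs.values())
    )
    for i in np.nonzero(has_sec)[0]:
        drug_rows["primaryid"].append(pids[i])
        drug_rows["caseid"].append(caseids[i])
        drug_rows["drug_seq"].append("2")
        drug_rows["role_cod"].append(sec_roles[i])
        drug_rows["drugname"].append(drugs[sec_idx[i]].generics[0])
        drug_rows["dose_amt"].append("")
        drug_rows["dose_unit"].append("")
        drug_rows["cum_dose_chr"].append("")
        drug_rows["cum_dose_unit"].append("")
    drug = pd.DataFrame(drug_rows, dtype=str)

    # -- REAC --------------------------------------------------------------
    case_i, ev_j = np.nonzero(event_mat)
    reac = pd.DataFrame(
        {
            "primaryid": pids[case_i],
            "caseid": caseids[case_i],
            "pt": [events[j].pt for j in ev_j],
        },
        dtype=str,
    )

    # -- OUTC --------------------------------------------------------------
    g = rng["outc"]
    outc_parts = []
    for code in OUTCOME_CODES:
        p = config.outcome_probs.get(code, 0.0)
        m = g.random(n) < p
        if m.any():
            outc_parts.append(
                pd.DataFrame(
                    {"primaryid": pids[m], "caseid": caseids[m], "outc_cod": code}, dtype=str
                )
            )
    outc = (
        pd.concat(outc_parts, ignore_index=True)
        if outc_parts
        else pd.DataFrame(columns=TABLE_COLUMNS["OUTC"], dtype=str)
    )

    # -- THER --------------------------------------------------------------
    g = rng["ther"]
    has_ther = g.random(n) < config.p_therapy
    dur = np.clip(
        np.round(
            np.exp(g.normal(math.log(config.therapy_median_days), config.therapy_log_sigma, n))
        ).astype(int),
        1,
        365,
    )
    t_month = g.integers(1, 12, size=n)
    t_day = g.integers(1, 29, size=n)
    ther_rows = {"primaryid": [], "caseid": [], "dsg_drug_seq": [], "start_dt": [], "end_dt": []}
    for i in np.nonzero(has_ther)[0]:
        start = date(int(years[i]), int(t_month[i]), int(t_day[i]))
        end = start + timedelta(days=int(dur[i]) - 1)
        ther_rows["primaryid"].append(pids[i])
        ther_rows["caseid"].append(caseids[i])
        ther_rows["dsg_drug_seq"].append("1")
        ther_rows["start_dt"].append(start.strftime("%Y%m%d"))
        ther_rows["end_dt"].append(end.strftime("%Y%m%d"))
    ther = pd.DataFrame(ther_rows, dtype=str)

    # -- RPSR / INDI -------------------------------------------------------
    g = rng["rpsr"]
    has_rpsr = g.random(n) < config.p_rpsr
    rpsr_codes = g.choice(["FGN", "SDY", "HP", "CSM", "OTH"], size=n)
    rpsr = pd.DataFrame(
        {
            "primaryid": pids[has_rpsr],
            "caseid": caseids[has_rpsr],
            "rpsr_cod": rpsr_codes[has_rpsr],
        },
        dtype=str,
    )
    indi = pd.DataFrame(
        {
            "primaryid": pids,
            "caseid": caseids,
            "indi_drug_seq": "1",
            "indi_pt": "Narcolepsy",
        },
        dtype=str,
    )

    tables = {
        "DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
        "RPSR": rpsr, "THER": ther, "INDI": indi,
    }
    for name in TABLE_NAMES:  # normalize column sets/order
        tables[name] = tables[name].reindex(columns=TABLE_COLUMNS[name], fill_value="")

    # -- duplicate case versions ------------------------------------------
    n_dup = int(round(config.duplicate_fraction * n))
    dup_pos = np.sort(rng["dup"].choice(n, size=n_dup, replace=False)) if n_dup else np.array([], int)
    dup_caseids = set(caseids[dup_pos])
    if n_dup:
        new_day = rng["dup"].integers(1, 29, size=n_dup)
        demo_dup = demo.iloc[dup_pos].copy()
        demo_dup["caseversion"] = "2"
        demo_dup["primaryid"] = demo_dup["caseid"] + "2"
        demo_dup["fda_dt"] = [
            f"{dt[:6]}{d:02d}" for dt, d in zip(demo_dup["fda_dt"], new_day)
        ]
        tables["DEMO"] = pd.concat([demo, demo_dup], ignore_index=True)
        for name in TABLE_NAMES[1:]:
            tab = tables[name]
            if len(tab) == 0:
                continue
            extra = tab[tab["caseid"].isin(dup_caseids)].copy()
            extra["primaryid"] = extra["caseid"] + "2"
            tables[name] = pd.concat([tab, extra], ignore_index=True)

    # -- ground truth ------------------------------------------------------
    retained = event_mat.any(axis=1)
    a_counts: dict[str, dict[str, int]] = {}
    cohort_sizes: dict[str, int] = {}
    for i, d in enumerate(drugs):
        m = ps_idx == i
        cohort_sizes[d.name] = int((m & retained).sum())
        a_counts[d.name] = {
            events[j].pt: int(event_mat[m, j].sum()) for j in range(len(events))
        }
    ground_truth = {
        "planted_signals": [[d, e, rho] for d, e, rho in config.planted_signals],
        "true_ror": {
            f"{d}|{e}": scheme_true_ror(config, d, e) for d, e, _ in config.planted_signals
        },
        "duplicate_caseids": sorted(dup_caseids),
        "n_cases": n,
        "n_with_events": int(retained.sum()),
        "cohort_sizes": cohort_sizes,
        "a_counts": a_counts,
        "seed": config.seed,
    }
    return SyntheticDataset(tables=tables, ground_truth=ground_truth)


def _fmt(x: float) -> str:
    return f"{x:g}"


def write_faers_ascii(dataset: SyntheticDataset, directory: str | Path) -> list[Path]:
    """Write one $-delimited file per table plus the ground-truth sidecar.

    FAERS quarterly dialect: header line, fields joined by ``$``, one record
    per line, no quoting.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in TABLE_NAMES:
        path = directory / f"{name}.txt"
        df = dataset.tables[name]
        try:
            with open(path, "w", newline="") as fh:
                fh.write("$".join(df.columns) + "\n")
                for row in df.itertuples(index=False):
                    fh.write("$".join(row) + "\n")
        except OSError as err:
            raise OSError(f"failed writing table file {path}: {err}") from err
        written.append(path)
    gt_path = directory / GROUND_TRUTH_FILE
    with open(gt_path, "w") as fh:
        json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True)
    written.append(gt_path)
    return written


def read_ground_truth(directory: str | Path) -> dict:
    with open(Path(directory) / GROUND_TRUTH_FILE) as fh:
        return json.load(fh)


def default_config(**overrides) -> SyntheticConfig:
    """Convenience constructor over the default catalogs."""
    return SyntheticConfig(**overrides)
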