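from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import faerskit as fk
from faerskit.ingest import ReportCase
from faerskit.pipeline import cases_from_dataset, synonyms_from_catalog

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def mk_case(
    pid: str,
    drug: str | None = None,
    events=(),
    sex: str = "F",
    age: float | None = None,
    year: int = 2021,
    outcomes=(),
    reporter: str = "consumer",
    country: str = "US",
    single_dose=None,
    cumulative_dose=None,
) -> ReportCase:
    """Minimal ReportCase for statistic/summary tests."""
    return ReportCase(
        primaryid=pid,
        caseid=pid,
        version=1,
        age_years=age,
        sex=sex,
        reporter=reporter,
        country=country,
        report_year=year,
        drugs=[],
        events=list(events),
        outcomes=frozenset(outcomes),
        single_dose=single_dose,
        cumulative_dose=cumulative_dose,
        cohort_groups=frozenset([drug] if drug else []),
    )


@pytest.fixture(scope="session")
def small_config() -> fk.SyntheticConfig:
    return fk.SyntheticConfig(n_cases=400, duplicate_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> fk.SyntheticDataset:
    return fk.generate_dataset(small_config)


@pytest.fixture(scope="session")
def synonyms(small_config):
    return synonyms_from_catalog(small_config.drug_catalog)


@pytest.fixture(scope="session")
def meddra_map(small_config):
    from faerskit.meddra import map_from_catalog

    return map_from_catalog(small_config.event_catalog)


@pytest.fixture(scope="session")
def small_cases(small_dataset, synonyms):
    cases, _ = cases_from_dataset(small_dataset, synonyms)
    return cases


@pytest.fixture()
def ascii_dir(tmp_path, small_dataset):
    fk.write_faers_ascii(small_dataset, tmp_path / "data")
    return tmp_path / "data"
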