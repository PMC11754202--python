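"""Shared fixtures: the frozen 200-case corpus and small hand-built cases."""

from pathlib import Path

import pytest

from faersignal.cleaning import CaseDrug, CaseReport, assemble_reports, deduplicate
from faersignal.dates import PartialDate
from faersignal.io import DemoRecord, read_quarter
from faersignal.synthetic import default_drug_dictionary, tolvaptan_study_config

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"


@pytest.fixture(scope="session")
def fixture_config():
    return tolvaptan_study_config(n_cases=200, seed=42)


@pytest.fixture(scope="session")
def fixture_data():
    """The frozen corpus, read back through the parser."""
    return read_quarter({t: FIXTURE_DIR / f"{t}.txt"
                         for t in ("demo", "drug", "reac", "outc", "ther")})


@pytest.fixture(scope="session")
def fixture_reports(fixture_data, fixture_config):
    demos = deduplicate(fixture_data.demo)
    reports, _ = assemble_reports(fixture_data, fixture_config.pt_soc_map(),
                                  default_drug_dictionary(), demos=demos)
    return reports


def make_demo(primaryid="1", caseid=None, fda="20200101", **kw) -> DemoRecord:
    return DemoRecord(primaryid=primaryid, caseid=caseid or primaryid,
                      fda_dt=PartialDate.parse(fda), **kw)


def make_case(caseid: str, drugs: list[tuple[str, str]],
              pts: list[tuple[str, str]], outcomes: set[str] | None = None,
              demo_kw: dict | None = None, therapy_starts=None) -> CaseReport:
    """Hand-built CaseReport: drugs as (name, role), pts as (pt, soc)."""
    demo = make_demo(primaryid=caseid, caseid=caseid, **(demo_kw or {}))
    return CaseReport(
        primaryid=caseid, caseid=caseid, demo=demo,
        drugs=[CaseDrug(drug_seq=i + 1, name=n, raw_name=n, role=r)
               for i, (n, r) in enumerate(drugs)],
        pts=list(pts), outcomes=outcomes or set(),
        therapy_starts=therapy_starts or {})
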