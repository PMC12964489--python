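"""Shared fixtures: drug dictionary, synthetic cohorts, micro-patients."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from mcrpcseq import RunConfig, SimScenario, generate_cohort, phenotype_cohort
from mcrpcseq.regimen import DrugDictionary


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary()


@pytest.fixture(scope="session")
def clean_scenario() -> SimScenario:
    """The fixed clean cohort used for exact-recovery checks."""
    return SimScenario(n_patients=2000, seed=2024)


@pytest.fixture(scope="session")
def clean_cohort(clean_scenario):
    return generate_cohort(clean_scenario)


@pytest.fixture(scope="session")
def clean_results(clean_cohort):
    """(tables, phenotypes, attrition, labeled lines) for the clean cohort."""
    phenotypes, attrition, lines = phenotype_cohort(
        clean_cohort.diagnoses,
        clean_cohort.prescriptions,
        clean_cohort.labs,
        clean_cohort.patients,
        RunConfig(),
    )
    return clean_cohort, phenotypes, attrition, lines


@pytest.fixture(scope="session")
def small_cohort():
    """A small clean cohort for cheap invariance tests."""
    return generate_cohort(SimScenario(n_patients=60, seed=7))


def dx_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "icd10", "date"])


def rx_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "drug_id", "date", "days_supplied"])


def lab_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "test", "date", "value"])


def minimal_patient(
    *,
    index1: str = "2016-01-10",
    met: str | None = "2016-06-01",
    crpc_claim: str | None = "2017-03-10",
    index2: str = "2017-04-15",
    last_record_offset: int = 400,
    extra_dx: list[tuple[str, str]] | None = None,
):
    """Smallest includable patient: diagnosis claims plus a single 1L fill.

    With the defaults: crpc = 2017-03-31 (month end), mcrpc = 2017-03-31,
    index2 = 2017-04-15 (delay 15 days), follow-up 400 days.  Returns
    (dx, rx, labs) frames for patient "X".
    """
    pid = "X"
    dx_rows = [(pid, "C61", index1)]
    if met is not None:
        dx_rows.append((pid, "C79.5", met))
    if crpc_claim is not None:
        dx_rows.append((pid, "8848040", crpc_claim))
    last = (pd.Timestamp(index2) + pd.Timedelta(days=last_record_offset)).date()
    dx_rows.append((pid, "C61", last.isoformat()))
    for code, when in extra_dx or []:
        dx_rows.append((pid, code, when))
    rx_rows = [(pid, "enzalutamide", index2, 30)]
    return dx_frame(dx_rows), rx_frame(rx_rows), lab_frame([])
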