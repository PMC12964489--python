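"""Cohort phenotyping: index dates, CRPC/metastasis detection, criteria.

Derives, per patient, the first prostate-cancer diagnosis date (index
date 1), the CRPC qualification date (by diagnosis code or by PSA
progression during ADT), the metastasis date, the mCRPC date (latest of
the two qualifications), and the start of first-line mCRPC treatment
(index date 2), then applies the inclusion/exclusion criteria in their
published order and assigns the disease-course subgroup:

* Subgroup 1 — metastasis documented strictly before CRPC (mCSPC→mCRPC);
* Subgroup 2 — CRPC on or before metastasis (nmCRPC→mCRPC; ties go to 2).

Two data conventions matter throughout.  Diagnosis claims are reliable
to the month only, so a code-based CRPC date is normalized to the *last
day of its claim month*; consequently a 1L start in that same month may
precede the normalized date and its mCRPC-to-index2 duration is reported
as 0.  All day-count rules are inclusive: "within 90 days" admits day
90, "minimum 180-day" admits exactly 180.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .config import (
    COMORBIDITY_GROUPS,
    COMORBIDITY_PREFIXES,
    COMORBIDITY_RANGES,
    METASTASIS_SITES,
    RunConfig,
    normalize_code,
)
from .lines import (
    TreatmentLine,
    adt_exposure_intervals,
    build_lines,
    find_index2,
    label_lines,
)

# exclusion reasons, in the published criterion order
REASONS = (
    "no_pc_diagnosis",
    "under_age",
    "no_crpc",
    "no_metastasis",
    "no_1l_treatment",
    "insufficient_baseline",
    "insufficient_followup",
    "other_malignancy",
    "late_initiation",
)
INCLUDED = "included"

PSA_TEST = "psa"


def month_end(d: date) -> date:
    return date(d.year, d.month, calendar.monthrange(d.year, d.month)[1])


@dataclass
class PatientPhenotype:
    patient_id: str
    birth_year: int | None = None
    sex: str = ""
    index1: date | None = None
    crpc_date: date | None = None
    crpc_mechanism: str = "none"  # code | psa | none
    met_date: date | None = None
    met_sites: frozenset[str] = frozenset()
    mcrpc_date: date | None = None
    index2: date | None = None
    age_at_index1: int | None = None
    age_at_index2: int | None = None
    included: bool = False
    exclusion_reason: str = ""
    subgroup: int = 0  # 1 | 2 | 0 (none)
    comorbidities: frozenset[str] = frozenset()
    followup_days: int | None = None
    mcrpc_to_index2_days: int | None = None
    lines: list[TreatmentLine] = field(default_factory=list)


def first_pc_diagnosis(dx: pd.DataFrame, config: RunConfig) -> date | None:
    """Earliest prostate-cancer code date inside the study window."""
    if dx.empty:
        return None
    prefixes = tuple(normalize_code(c) for c in config.pc_codes)
    best: date | None = None
    for code, when in zip(dx["icd10"], dx["date"]):
        d = _as_date(when)
        if not (config.study_start <= d <= config.study_end):
            continue
        if normalize_code(code).startswith(prefixes):
            if best is None or d < best:
                best = d
    return best


def detect_metastasis(
    dx: pd.DataFrame, index1: date, config: RunConfig
) -> tuple[date | None, frozenset[str]]:
    """Earliest metastasis-code date on or after index1, with site flags."""
    best: date | None = None
    sites: set[str] = set()
    for code, when in zip(dx["icd10"], dx["date"]):
        d = _as_date(when)
        if d < index1:
            continue
        norm = normalize_code(code)
        for site, prefixes in config.met_codes.items():
            if norm.startswith(tuple(normalize_code(p) for p in prefixes)):
                sites.add(site)
                if best is None or d < best:
                    best = d
    return best, frozenset(sites)


def detect_crpc(
    dx: pd.DataFrame,
    labs: pd.DataFrame,
    adt_intervals: list[tuple[date, date]],
    index1: date,
    config: RunConfig,
) -> tuple[date, str] | None:
    """Earliest CRPC qualification across the two mechanisms.

    Code mechanism: a CRPC claim code in the month of index1 or later;
    the date is the last day of the claim month.  PSA mechanism: the
    first PSA measurement during ADT exposure exceeding the running
    nadir (minimum of strictly earlier on-ADT values) by more than
    1 ng/mL *and* more than 25%.  On a date tie the code mechanism wins.
    """
    code_date = _crpc_by_code(dx, index1, config)
    psa_date = _crpc_by_psa(labs, adt_intervals)
    if code_date is not None and (psa_date is None or code_date <= psa_date):
        return code_date, "code"
    if psa_date is not None:
        return psa_date, "psa"
    return None


def _crpc_by_code(dx: pd.DataFrame, index1: date, config: RunConfig) -> date | None:
    codes = {normalize_code(c) for c in config.crpc_codes}
    index1_month = (index1.year, index1.month)
    best: date | None = None
    for code, when in zip(dx["icd10"], dx["date"]):
        if normalize_code(code) not in codes:
            continue
        d = _as_date(when)
        if (d.year, d.month) < index1_month:
            continue
        candidate = month_end(d)
        if best is None or candidate < best:
            best = candidate
    return best


def _crpc_by_psa(
    labs: pd.DataFrame, adt_intervals: list[tuple[date, date]]
) -> date | None:
    if labs.empty or not adt_intervals:
        return None
    psa = [
        (_as_date(when), float(value))
        for test, when, value in zip(labs["test"], labs["date"], labs["value"])
        if str(test).strip().lower() == PSA_TEST
    ]
    psa.sort()
    nadir: float | None = None
    for when, value in psa:
        if not any(lo <= when <= hi for lo, hi in adt_intervals):
            continue
        if nadir is not None and value - nadir > 1.0 and value > 1.25 * nadir:
            return when
        nadir = value if nadir is None else min(nadir, value)
    return None


def summarize_comorbidities(
    dx: pd.DataFrame, index2: date, baseline_days: int = 180
) -> frozenset[str]:
    """Comorbidity groups with at least one code in [index2-180d, index2)."""
    lo = index2 - timedelta(days=baseline_days)
    present: set[str] = set()
    for code, when in zip(dx["icd10"], dx["date"]):
        d = _as_date(when)
        if not (lo <= d < index2):
            continue
        group = comorbidity_group(code)
        if group:
            present.add(group)
    return frozenset(present)


def comorbidity_group(code: str) -> str | None:
    """Comorbidity group of one ICD-10 code, or None."""
    norm = normalize_code(code)
    if len(norm) < 3 or not norm[1:3].isdigit():
        return None
    letter, num = norm[0], int(norm[1:3])
    for group in COMORBIDITY_GROUPS:
        for rl, lo, hi in COMORBIDITY_RANGES[group]:
            if letter == rl and lo <= num <= hi:
                return group
        if norm.startswith(COMORBIDITY_PREFIXES.get(group, ())):
            return group
    return None


def other_malignancy_present(dx: pd.DataFrame, config: RunConfig) -> bool:
    """Any non-prostate primary-malignancy code inside the study window.

    The prostate-cancer codes, the CRPC claim codes and the configured
    metastasis codes are exempt — the latter are how PC metastases are
    recorded, not independent primaries.
    """
    exempt_prefixes = tuple(normalize_code(c) for c in config.pc_codes) + tuple(
        normalize_code(p) for ps in config.met_codes.values() for p in ps
    )
    exempt_exact = {normalize_code(c) for c in config.crpc_codes}
    for code, when in zip(dx["icd10"], dx["date"]):
        d = _as_date(when)
        if not (config.study_start <= d <= config.study_end):
            continue
        norm = normalize_code(code)
        if not norm.startswith("C"):
            continue
        if norm in exempt_exact or norm.startswith(exempt_prefixes):
            continue
        return True
    return False


def assign_subgroup(phenotype: PatientPhenotype) -> int:
    """1 if metastasis preceded CRPC, 2 otherwise (ties to 2)."""
    if not phenotype.included:
        raise ValueError("subgroup assignment requires an included patient")
    assert phenotype.met_date is not None and phenotype.crpc_date is not None
    return 1 if phenotype.met_date < phenotype.crpc_date else 2


def phenotype_patient(
    patient_id: str,
    dx: pd.DataFrame,
    rx_pc: pd.DataFrame,
    labs: pd.DataFrame,
    *,
    birth_year: int | None,
    sex: str,
    config: RunConfig,
) -> PatientPhenotype:
    """Run the full per-patient derivation and criteria cascade.

    ``rx_pc`` must already be restricted to PC medications dispensed
    inside the study window; criteria are evaluated in the published
    order and the first failure is recorded.
    """
    p = PatientPhenotype(patient_id=patient_id, birth_year=birth_year, sex=sex)
    params = config.params
    dictionary = config.dictionary()

    p.index1 = first_pc_diagnosis(dx, config)
    if p.index1 is None:
        p.exclusion_reason = "no_pc_diagnosis"
        return p
    if birth_year is not None:
        p.age_at_index1 = p.index1.year - birth_year
        if p.age_at_index1 < 20:
            p.exclusion_reason = "under_age"
            return p

    intervals = adt_exposure_intervals(
        rx_pc,
        dictionary,
        gap_days=params.continuation_gap_days,
        default_supply=params.default_supply_days,
    )
    crpc = detect_crpc(dx, labs, intervals, p.index1, config)
    if crpc is None:
        p.exclusion_reason = "no_crpc"
        return p
    p.crpc_date, p.crpc_mechanism = crpc

    p.met_date, p.met_sites = detect_metastasis(dx, p.index1, config)
    if p.met_date is None:
        p.exclusion_reason = "no_metastasis"
        return p

    p.mcrpc_date = max(p.crpc_date, p.met_date)

    p.lines = build_lines(
        rx_pc,
        dictionary,
        patient_id=patient_id,
        window_days=params.combination_window_days,
        gap_days=params.continuation_gap_days,
        default_supply=params.default_supply_days,
        data_cutoff=config.study_end,
        end_anchor=config.line_end_anchor,
    )
    p.index2 = find_index2(
        p.lines,
        met_date=p.met_date,
        crpc_date=p.crpc_date,
        crpc_mechanism=p.crpc_mechanism,
    )
    if p.index2 is None:
        p.exclusion_reason = "no_1l_treatment"
        return p
    if birth_year is not None:
        p.age_at_index2 = p.index2.year - birth_year

    first_rec, last_rec = _record_span(dx, rx_pc, labs)
    assert first_rec is not None and last_rec is not None
    if (p.index2 - first_rec).days < params.baseline_days:
        p.exclusion_reason = "insufficient_baseline"
        return p
    p.followup_days = (min(last_rec, config.study_end) - p.index2).days
    if p.followup_days < params.followup_days:
        p.exclusion_reason = "insufficient_followup"
        return p

    if other_malignancy_present(dx, config):
        p.exclusion_reason = "other_malignancy"
        return p

    delta = (p.index2 - p.mcrpc_date).days
    if delta > params.initiation_window_days:
        p.exclusion_reason = "late_initiation"
        return p

    p.included = True
    p.exclusion_reason = ""
    p.mcrpc_to_index2_days = max(0, delta)
    p.subgroup = assign_subgroup(p)
    p.comorbidities = summarize_comorbidities(dx, p.index2, params.baseline_days)
    p.lines = label_lines(p.lines, p.index2)
    return p


def _record_span(*frames: pd.DataFrame) -> tuple[date | None, date | None]:
    lo: date | None = None
    hi: date | None = None
    for frame in frames:
        if frame.empty or "date" not in frame:
            continue
        for when in frame["date"]:
            d = _as_date(when)
            if lo is None or d < lo:
                lo = d
            if hi is None or d > hi:
                hi = d
    return lo, hi


def phenotype_cohort(
    dx: pd.DataFrame,
    rx: pd.DataFrame,
    labs: pd.DataFrame,
    patients: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phenotype every patient; return (phenotypes, attrition, labeled lines).

    Patient identity comes from the union of all tables (the patients
    table contributes birth year and sex when present).
    """
    dictionary = config.dictionary()
    rx = rx.copy()
    rx["date"] = pd.to_datetime(rx["date"])
    in_window = (rx["date"].dt.date >= config.study_start) & (
        rx["date"].dt.date <= config.study_end
    )
    is_pc = rx["drug_id"].map(dictionary.is_pc_drug)
    rx_pc = rx[in_window & is_pc]

    demo = {}
    if not patients.empty:
        for row in patients.itertuples(index=False):
            birth = getattr(row, "birth_year", None)
            demo[str(row.patient_id)] = (
                int(birth) if birth is not None and not pd.isna(birth) else None,
                str(getattr(row, "sex", "")),
            )

    ids = sorted(
        set(map(str, dx.get("patient_id", pd.Series(dtype=str))))
        | set(map(str, rx.get("patient_id", pd.Series(dtype=str))))
        | set(map(str, labs.get("patient_id", pd.Series(dtype=str))))
        | set(demo)
    )
    dx_g = _groups(dx)
    rx_g = _groups(rx_pc)
    lab_g = _groups(labs)
    empty_dx = dx.iloc[0:0]
    empty_rx = rx_pc.iloc[0:0]
    empty_lab = labs.iloc[0:0]

    phenotypes: list[PatientPhenotype] = []
    for pid in ids:
        birth_year, sex = demo.get(pid, (None, ""))
        phenotypes.append(
            phenotype_patient(
                pid,
                dx_g.get(pid, empty_dx),
                rx_g.get(pid, empty_rx),
                lab_g.get(pid, empty_lab),
                birth_year=birth_year,
                sex=sex,
                config=config,
            )
        )

    return (
        phenotypes_to_frame(phenotypes),
        attrition_table(phenotypes),
        _labeled_lines_frame(phenotypes),
    )


def _groups(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if frame.empty:
        return {}
    return {str(k): g for k, g in frame.groupby(frame["patient_id"].astype(str))}


def phenotypes_to_frame(phenotypes: list[PatientPhenotype]) -> pd.DataFrame:
    rows = []
    for p in phenotypes:
        row = {
            "patient_id": p.patient_id,
            "sex": p.sex,
            "index1": _iso(p.index1),
            "crpc_date": _iso(p.crpc_date),
            "crpc_mechanism": p.crpc_mechanism,
            "met_date": _iso(p.met_date),
            "mcrpc_date": _iso(p.mcrpc_date),
            "index2": _iso(p.index2),
            "age_at_index1": p.age_at_index1,
            "age_at_index2": p.age_at_index2,
            "included": p.included,
            "exclusion_reason": p.exclusion_reason,
            "subgroup": p.subgroup,
            "followup_days": p.followup_days,
            "mcrpc_to_index2_days": p.mcrpc_to_index2_days,
        }
        for group in COMORBIDITY_GROUPS:
            row[f"comorb_{group}"] = group in p.comorbidities
        for site in METASTASIS_SITES:
            row[f"site_{site}"] = site in p.met_sites
        rows.append(row)
    return pd.DataFrame(rows)


def attrition_table(phenotypes: list[PatientPhenotype]) -> pd.DataFrame:
    """Patients surviving each criterion, in the published order."""
    remaining = len(phenotypes)
    rows = [{"criterion": "all_patients", "n_remaining": remaining}]
    fail_counts = {r: 0 for r in REASONS}
    for p in phenotypes:
        if not p.included:
            fail_counts[p.exclusion_reason] += 1
    for reason in REASONS:
        remaining -= fail_counts[reason]
        rows.append({"criterion": f"pass_{reason}", "n_remaining": remaining})
    rows.append(
        {"criterion": INCLUDED, "n_remaining": sum(p.included for p in phenotypes)}
    )
    return pd.DataFrame(rows)


def _labeled_lines_frame(phenotypes: list[PatientPhenotype]) -> pd.DataFrame:
    from .lines import lines_to_frame

    all_lines = [l for p in phenotypes for l in p.lines]
    return lines_to_frame(all_lines)


def _iso(d: date | None) -> str:
    return d.isoformat() if d is not None else ""


def _as_date(value) -> date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()
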