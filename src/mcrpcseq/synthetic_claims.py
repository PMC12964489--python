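"""Synthetic hospital-claims generator with embedded ground truth.

Emulates the structure of Japanese DPC-style hospital claims that the
analysis assumes: month-reliable diagnosis claims, prescriptions with a
days-supplied quantity, PSA laboratory series available for only a small
configurable minority of patients, and a pre-mCRPC treatment mix that
drifts across calendar years (vintage hormone therapy declining in favour
of ARSIs).  One hospital per patient: no cross-facility fragmentation is
modelled, mirroring the source database's own limitation.

Every patient is generated from an explicit plan (index dates, CRPC
mechanism, subgroup, ordered treatment lines), and that plan is returned
as :class:`GroundTruth` so each downstream stage can be tested against
known answers.  In the default *clean* mode the plan is constructed so
the line rules are unambiguous — between-line gaps strictly exceed the
continuation grace period G, refill gaps stay strictly below it, and
combination partners co-start on one day — which makes exact recovery of
the embedded structure a correctness requirement, not a statistical hope.

Calendar years are assigned round-robin and regimen categories by seeded
largest-remainder quotas (within year for the pre-mCRPC stage; within
pre-category for first line), so realized category mixes equal the
configured probabilities to within one patient.  Noise is opt-in via
:func:`inject_noise` and always manifest-logged, never silent.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .regimen import (
    ABIRATERONE,
    APALUTAMIDE,
    CABAZITAXEL,
    COMBINATION,
    DAROLUTAMIDE,
    DOCETAXEL,
    ENZALUTAMIDE,
    OLAPARIB,
    OTHERS,
    RADIUM223,
    VINTAGE,
)

DX_COLUMNS = ["patient_id", "icd10", "date"]
RX_COLUMNS = ["patient_id", "drug_id", "date", "days_supplied"]
LAB_COLUMNS = ["patient_id", "test", "date", "value"]
PATIENT_COLUMNS = ["patient_id", "birth_year", "sex"]

SINGLE_AGENT_CATEGORIES = {
    ENZALUTAMIDE,
    ABIRATERONE,
    APALUTAMIDE,
    DAROLUTAMIDE,
    DOCETAXEL,
    CABAZITAXEL,
    RADIUM223,
    OLAPARIB,
}

_ADT_AGENTS = ("leuprorelin", "goserelin", "degarelix")
_FGA_AGENTS = ("bicalutamide", "flutamide")
_ESTROGEN_AGENTS = ("estramustine", "ethinylestradiol")
_OTHER_PC_AGENTS = ("mitoxantrone", "ifosfamide")
_COMBO_PARTNERS = (ENZALUTAMIDE, ABIRATERONE)

_COMORBIDITY_CODES = {
    "liver": ("K72", "K74", "K76.0"),
    "kidney": ("N18", "N39.0", "N03"),
    "cardiovascular": ("I10", "I25.1", "I50"),
    "metabolic": ("E11", "E78.5"),
    "prostatic": ("N40", "N42.0", "N51.0"),
}
_SITE_CODES = {"bone": "C79.5", "lymph_node": "C77", "lung": "C78.0", "liver": "C78.7"}
_SITE_RATES = {"bone": 0.85, "lymph_node": 0.20, "lung": 0.04, "liver": 0.01}
_OTHER_MALIGNANCY_CODE = "C34.1"
_CRPC_CLAIM_CODE = "8848040"
_PC_CLAIM_CODE = "C61"

# mean target durations (days) used to size fill schedules
_PRE_DURATION = {
    VINTAGE: 600, ENZALUTAMIDE: 300, ABIRATERONE: 240, APALUTAMIDE: 300,
    DAROLUTAMIDE: 300, DOCETAXEL: 180, OTHERS: 240, COMBINATION: 300,
    CABAZITAXEL: 150, RADIUM223: 180, OLAPARIB: 240,
}
_POST_DURATION = {
    ENZALUTAMIDE: 500, ABIRATERONE: 430, APALUTAMIDE: 400, DAROLUTAMIDE: 320,
    DOCETAXEL: 180, CABAZITAXEL: 150, RADIUM223: 180, OLAPARIB: 240,
    COMBINATION: 300, OTHERS: 200, VINTAGE: 400,
}

#: number of post-mCRPC lines -> probability
_N_POST_PROBS = {1: 0.30, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10}

# headroom (days) reserved between the pre-line supply end and the latest
# admissible index2, so the CRPC/metastasis/initiation offsets always fit
_PRE_SLACK = 75
_MIN_PRE_FILLS = 8


def default_pre_mix_by_year(
    start_year: int = 2015,
    end_year: int = 2022,
    vintage_start: float = 0.90,
    vintage_end: float = 0.40,
) -> dict[int, dict[str, float]]:
    """Year-indexed pre-mCRPC mix with a linearly declining vintage share."""
    mixes: dict[int, dict[str, float]] = {}
    span = max(1, end_year - start_year)
    for year in range(start_year, end_year + 1):
        v = vintage_start + (vintage_end - vintage_start) * (year - start_year) / span
        r = 1.0 - v
        mix = {
            VINTAGE: v,
            ENZALUTAMIDE: 0.40 * r,
            ABIRATERONE: 0.30 * r,
            APALUTAMIDE: 0.10 * r,
            DAROLUTAMIDE: 0.05 * r,
            DOCETAXEL: 0.10 * r,
        }
        mix[OTHERS] = 1.0 - sum(mix.values())
        mixes[year] = mix
    return mixes


def default_first_line_mix() -> dict[str, float]:
    return {
        ENZALUTAMIDE: 0.43,
        ABIRATERONE: 0.28,
        DOCETAXEL: 0.11,
        RADIUM223: 0.04,
        APALUTAMIDE: 0.05,
        DAROLUTAMIDE: 0.03,
        CABAZITAXEL: 0.02,
        OLAPARIB: 0.01,
        COMBINATION: 0.02,
        OTHERS: 0.01,
    }


def default_comorbidity_rates() -> dict[str, float]:
    # rates matching the published baseline-comorbidity prevalences
    return {
        "liver": 0.145,
        "kidney": 0.423,
        "cardiovascular": 0.376,
        "metabolic": 0.518,
        "prostatic": 0.544,
    }


def default_inclusion_mix() -> dict[str, float]:
    return {
        "included": 0.80,
        "no_metastasis": 0.05,
        "late_initiation": 0.05,
        "insufficient_followup": 0.04,
        "other_malignancy": 0.04,
        "under_age": 0.02,
    }


class SimScenario(BaseModel):
    """Configuration of one simulated cohort (defaults = study conditions)."""

    n_patients: int = Field(ge=0)
    study_start: date = date(2015, 1, 1)
    study_end: date = date(2023, 6, 30)
    psa_available_frac: float = Field(default=0.10, ge=0.0, le=1.0)
    pre_mcrpc_mix_by_year: dict[int, dict[str, float]] = Field(
        default_factory=default_pre_mix_by_year
    )
    first_line_mix: dict[str, float] = Field(default_factory=default_first_line_mix)
    inclusion_mix: dict[str, float] = Field(default_factory=default_inclusion_mix)
    comorbidity_rates: dict[str, float] = Field(default_factory=default_comorbidity_rates)
    subgroup1_frac: float = Field(default=0.75, ge=0.0, le=1.0)
    backbone_frac: float = Field(default=0.70, ge=0.0, le=1.0)
    line_gap_days: tuple[int, int] = (101, 200)  # between-line gap after supply end
    refill_gap_days: tuple[int, int] = (0, 0)  # gap between supply end and refill
    days_supplied_default: int = Field(default=30, gt=0)
    combination_window_days: int = 30  # W honoured by the generator
    continuation_gap_days: int = 90  # G honoured by the generator
    clean: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimScenario":
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for year, mix in self.pre_mcrpc_mix_by_year.items():
            _check_probs(mix, f"pre_mcrpc_mix_by_year[{year}]")
        _check_probs(self.first_line_mix, "first_line_mix")
        _check_probs(self.inclusion_mix, "inclusion_mix")
        if self.clean:
            g = self.continuation_gap_days
            if self.line_gap_days[0] <= g:
                raise ValueError("clean mode requires between-line gaps strictly > G")
            if self.refill_gap_days[1] >= g:
                raise ValueError("clean mode requires refill gaps strictly < G")
        if self.line_gap_days[0] > self.line_gap_days[1]:
            raise ValueError("line_gap_days must be (lo, hi) with lo <= hi")
        if self.refill_gap_days[0] > self.refill_gap_days[1]:
            raise ValueError("refill_gap_days must be (lo, hi) with lo <= hi")
        return self

    def conditional_first_line_mix(self, pre_category: str) -> dict[str, float]:
        """First-line mix given the pre-mCRPC category.

        A same-agent pre->1L transition is impossible under the line
        rules (the refill would continue the old line), so the pre
        category's own single-agent label is zeroed and the mix
        renormalized.
        """
        mix = dict(self.first_line_mix)
        if pre_category in SINGLE_AGENT_CATEGORIES and pre_category in mix:
            mix.pop(pre_category)
            total = sum(mix.values())
            mix = {k: v / total for k, v in mix.items()}
        return mix

    def effective_transition_matrix(self) -> dict[tuple[str, str], float]:
        """Declared pre->1L joint transition probabilities.

        Years contribute equally (round-robin assignment), so the pre
        margin is the across-year mean of the configured yearly mixes.
        """
        years = sorted(self.pre_mcrpc_mix_by_year)
        pre_margin: dict[str, float] = {}
        for year in years:
            for cat, p in self.pre_mcrpc_mix_by_year[year].items():
                pre_margin[cat] = pre_margin.get(cat, 0.0) + p / len(years)
        joint: dict[tuple[str, str], float] = {}
        for pre_cat, p_pre in pre_margin.items():
            for l1_cat, p_l1 in self.conditional_first_line_mix(pre_cat).items():
                joint[(pre_cat, l1_cat)] = p_pre * p_l1
        return joint


def _check_probs(mix: dict, name: str) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name} contains negative probabilities")


@dataclass
class GroundTruth:
    """The structure the generator embedded, one row per patient / line."""

    patients: pd.DataFrame
    lines: pd.DataFrame


class SimTables(NamedTuple):
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    patients: pd.DataFrame
    truth: GroundTruth


def _quota_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n slots to the mix categories."""
    cats = sorted(mix)
    floors = {c: int(np.floor(mix[c] * n)) for c in cats}
    remainder = n - sum(floors.values())
    by_frac = sorted(cats, key=lambda c: (-(mix[c] * n - floors[c]), c))
    for c in by_frac[:remainder]:
        floors[c] += 1
    return floors


def _quota_list(mix: dict[str, float], n: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    for cat, k in sorted(_quota_counts(mix, n).items()):
        out.extend([cat] * k)
    rng.shuffle(out)
    return out


def _month_end(d: date) -> date:
    return date(d.year, d.month, calendar.monthrange(d.year, d.month)[1])


class _Recorder:
    """Accumulates output rows and per-patient record spans."""

    def __init__(self) -> None:
        self.dx: list[tuple] = []
        self.rx: list[tuple] = []
        self.labs: list[tuple] = []
        self.last_record: dict[str, date] = {}

    def _touch(self, pid: str, d: date) -> None:
        cur = self.last_record.get(pid)
        if cur is None or d > cur:
            self.last_record[pid] = d

    def add_dx(self, pid: str, code: str, d: date) -> None:
        self.dx.append((pid, code, d.isoformat()))
        self._touch(pid, d)

    def add_rx(self, pid: str, drug: str, d: date, supply: int) -> None:
        self.rx.append((pid, drug, d.isoformat(), supply))
        self._touch(pid, d)

    def add_lab(self, pid: str, test: str, d: date, value: float) -> None:
        self.labs.append((pid, test, d.isoformat(), round(float(value), 3)))
        self._touch(pid, d)


def generate_cohort(scenario: SimScenario) -> SimTables:
    """Generate the four claims tables and the embedded ground truth.

    Deterministic for a fixed scenario (identical seed => identical
    tables); see the module docstring for the generative model.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_patients
    if n == 0:
        return _empty_tables()

    years = sorted(scenario.pre_mcrpc_mix_by_year)
    year_of = [years[i % len(years)] for i in range(n)]
    per_year: dict[int, int] = {}
    for y in year_of:
        per_year[y] = per_year.get(y, 0) + 1
    pre_lists = {
        y: _quota_list(scenario.pre_mcrpc_mix_by_year[y], k, rng)
        for y, k in sorted(per_year.items())
    }
    pre_cat = [pre_lists[y].pop() for y in year_of]

    # first-line categories: quota within each pre-category group
    groups: dict[str, list[int]] = {}
    for i, cat in enumerate(pre_cat):
        groups.setdefault(cat, []).append(i)
    l1_cat: list[str | None] = [None] * n
    for cat in sorted(groups):
        idx = groups[cat]
        for i, l1 in zip(idx, _quota_list(scenario.conditional_first_line_mix(cat), len(idx), rng)):
            l1_cat[i] = l1

    reasons = list(scenario.inclusion_mix)
    reason_p = np.array([scenario.inclusion_mix[r] for r in reasons])
    intents = rng.choice(reasons, size=n, p=reason_p / reason_p.sum())

    rec = _Recorder()
    patient_rows: list[dict] = []
    line_rows: list[dict] = []
    for i in range(n):
        pid = f"P{i + 1:05d}"
        _generate_patient(
            pid,
            scenario,
            rng,
            rec,
            year=year_of[i],
            pre_category=pre_cat[i],
            l1_category=l1_cat[i],
            intent=str(intents[i]),
            patient_rows=patient_rows,
            line_rows=line_rows,
        )

    dx = pd.DataFrame(rec.dx, columns=DX_COLUMNS).sort_values(DX_COLUMNS, kind="stable")
    rx = pd.DataFrame(rec.rx, columns=RX_COLUMNS).sort_values(RX_COLUMNS, kind="stable")
    labs = pd.DataFrame(rec.labs, columns=LAB_COLUMNS).sort_values(
        LAB_COLUMNS, kind="stable"
    )
    patients = pd.DataFrame(
        [(r["patient_id"], r["birth_year"], "male") for r in patient_rows],
        columns=PATIENT_COLUMNS,
    )
    truth = GroundTruth(
        patients=pd.DataFrame(patient_rows),
        lines=pd.DataFrame(line_rows),
    )
    return SimTables(
        dx.reset_index(drop=True),
        rx.reset_index(drop=True),
        labs.reset_index(drop=True),
        patients,
        truth,
    )


def _empty_tables() -> SimTables:
    return SimTables(
        pd.DataFrame(columns=DX_COLUMNS),
        pd.DataFrame(columns=RX_COLUMNS),
        pd.DataFrame(columns=LAB_COLUMNS),
        pd.DataFrame(columns=PATIENT_COLUMNS),
        GroundTruth(pd.DataFrame(), pd.DataFrame()),
    )


def _drugs_for(
    category: str,
    rng: np.random.Generator,
    *,
    exclude: frozenset[str] = frozenset(),
    vintage_variant: str | None = None,
) -> tuple[str, ...]:
    """Concrete drug identifiers realizing a regimen category."""
    if category == VINTAGE:
        variant = vintage_variant or rng.choice(["adt", "cab", "estrogen"], p=[0.55, 0.35, 0.10])
        adt = str(rng.choice(_ADT_AGENTS))
        if variant == "adt":
            return (adt,)
        if variant == "cab":
            return (adt, str(rng.choice(_FGA_AGENTS)))
        return (str(rng.choice(_ESTROGEN_AGENTS)),)
    if category == COMBINATION:
        pool = [d for d in (DOCETAXEL,) + _COMBO_PARTNERS if d not in exclude]
        if DOCETAXEL in pool and len(pool) > 1:
            rest = [d for d in pool if d != DOCETAXEL]
            return (DOCETAXEL, str(rng.choice(rest)))
        return (pool[0], pool[1])
    if category == OTHERS:
        options = [d for d in _OTHER_PC_AGENTS if d not in exclude]
        return (str(rng.choice(options)),)
    return (category,)  # single-agent categories use the agent name as drug id


def _generate_patient(
    pid: str,
    sc: SimScenario,
    rng: np.random.Generator,
    rec: _Recorder,
    *,
    year: int,
    pre_category: str,
    l1_category: str,
    intent: str,
    patient_rows: list[dict],
    line_rows: list[dict],
) -> None:
    supply = sc.days_supplied_default
    g = sc.continuation_gap_days
    latest_index2 = sc.study_end - timedelta(days=181)

    psa_patient = bool(rng.random() < sc.psa_available_frac)
    subgroup1 = bool(rng.random() < sc.subgroup1_frac)
    backbone = bool(rng.random() < sc.backbone_frac) or (
        psa_patient and pre_category != VINTAGE
    )

    # --- pre-mCRPC line schedule -------------------------------------
    year_lo = date(year, 1, 1)
    year_hi = min(
        date(year, 12, 31),
        latest_index2 - timedelta(days=30 * _MIN_PRE_FILLS + _PRE_SLACK),
    )
    if year_hi < year_lo:
        year_hi = year_lo
    pre_start = year_lo + timedelta(days=int(rng.integers(0, (year_hi - year_lo).days + 1)))
    index1 = max(sc.study_start, pre_start - timedelta(days=int(rng.integers(10, 91))))

    m_cap = (latest_index2 - timedelta(days=_PRE_SLACK) - pre_start).days // 30
    target = _PRE_DURATION.get(pre_category, 300) / 30
    m = int(np.clip(round(rng.normal(target, target / 4)), _MIN_PRE_FILLS, max(_MIN_PRE_FILLS, m_cap)))

    vintage_variant = None
    if pre_category == VINTAGE:
        vintage_variant = str(rng.choice(["adt", "cab", "estrogen"], p=[0.55, 0.35, 0.10]))
        if psa_patient and vintage_variant == "estrogen":
            vintage_variant = "adt"  # the PSA rule needs ADT exposure
    pre_drugs = _drugs_for(pre_category, rng, vintage_variant=vintage_variant)
    adt_agent = str(rng.choice(_ADT_AGENTS))
    pre_backbone = backbone and pre_category != VINTAGE

    fill_dates: list[date] = []
    d = pre_start
    for _ in range(m):
        fill_dates.append(d)
        d = d + timedelta(days=supply + int(rng.integers(sc.refill_gap_days[0], sc.refill_gap_days[1] + 1)))
    supply_end_pre = fill_dates[-1] + timedelta(days=supply)
    last_fill_pre = fill_dates[-1]

    # --- CRPC qualification ------------------------------------------
    mechanism = "psa" if psa_patient else "code"
    psa_visits: list[tuple[date, float]] = []
    if mechanism == "psa":
        visit_dates = []
        t = pre_start
        while t <= supply_end_pre:
            visit_dates.append(t)
            t = t + timedelta(days=90)
        if len(visit_dates) < 3:
            mechanism = "code"
        else:
            v0 = float(rng.uniform(10.0, 50.0))
            nadir = float(rng.uniform(0.5, 4.0))
            k = len(visit_dates) - 1
            for j, vd in enumerate(visit_dates[:-1]):
                frac = j / max(1, k - 1)
                psa_visits.append((vd, nadir + (v0 - nadir) * (1.0 - frac)))
            rise = max(1.0, 0.25 * nadir) * float(rng.uniform(1.3, 1.8)) + 0.05
            psa_visits.append((visit_dates[-1], nadir + rise))
            crpc_date = visit_dates[-1]
    if mechanism == "code":
        crpc_claim = supply_end_pre - timedelta(days=int(rng.integers(0, 46)))
        crpc_date = _month_end(crpc_claim)

    # --- metastasis ---------------------------------------------------
    has_met = intent != "no_metastasis"
    reserve = 61 if mechanism == "psa" else 17
    if subgroup1:
        back = int(rng.integers(30, min(301, max(31, (crpc_date - index1).days))))
        met_date = max(index1, crpc_date - timedelta(days=back))
    else:
        cap = min(60, (latest_index2 - crpc_date).days - reserve)
        met_date = crpc_date + timedelta(days=int(rng.integers(0, max(0, cap) + 1)))
    mcrpc_date = max(crpc_date, met_date)

    # --- index date 2 -------------------------------------------------
    lo = max(0, (last_fill_pre - mcrpc_date).days + 1)
    if intent == "late_initiation":
        delay = int(rng.integers(91, 141))
    else:
        hi = min(90, (latest_index2 - mcrpc_date).days)
        delay = int(rng.integers(lo, max(lo, hi) + 1))
    index2 = mcrpc_date + timedelta(days=delay)

    # --- emit the pre line and its records ----------------------------
    age1 = 19 if intent == "under_age" else int(np.clip(round(rng.normal(74, 8)), 45, 94))
    birth_year = index1.year - age1

    pre_end = min(supply_end_pre + timedelta(days=g), index2)
    truth_lines: list[dict] = [
        {
            "patient_id": pid,
            "ordinal": "pre",
            "start": pre_start.isoformat(),
            "end": pre_end.isoformat(),
            "duration_days": (pre_end - pre_start).days,
            "censored": False,
            "regimen": pre_category,
            "drugs": "|".join(sorted(set(pre_drugs) | ({adt_agent} if pre_backbone else set()))),
        }
    ]
    for fd in fill_dates:
        for drug in pre_drugs:
            rec.add_rx(pid, drug, fd, supply)
        if pre_backbone:
            rec.add_rx(pid, adt_agent, fd, supply)
    for vd, value in psa_visits:
        rec.add_lab(pid, "PSA", vd, value)
    if mechanism == "code":
        rec.add_dx(pid, _CRPC_CLAIM_CODE, crpc_claim)

    # --- post-mCRPC lines ---------------------------------------------
    n_post = int(rng.choice(list(_N_POST_PROBS), p=list(_N_POST_PROBS.values())))
    if intent == "insufficient_followup":
        n_post = 1
    pre_nonbackbone = frozenset(pre_drugs)
    start = index2
    for j in range(1, n_post + 1):
        if start > sc.study_end:
            break
        if j == 1:
            cat = l1_category
            drugs = _drugs_for(cat, rng, exclude=pre_nonbackbone)
        else:
            cat = str(rng.choice(sorted(sc.first_line_mix), p=[sc.first_line_mix[c] for c in sorted(sc.first_line_mix)]))
            drugs = _drugs_for(cat, rng)
        target_j = _POST_DURATION.get(cat, 300) / 30
        m_j = max(1, int(round(rng.normal(target_j, target_j / 4))))
        if intent == "insufficient_followup":
            m_j = 1
        dates_j: list[date] = []
        dj = start
        for _ in range(m_j):
            if dj > sc.study_end:
                break
            dates_j.append(dj)
            dj = dj + timedelta(days=supply + int(rng.integers(sc.refill_gap_days[0], sc.refill_gap_days[1] + 1)))
        if not dates_j:
            break
        supply_end_j = dates_j[-1] + timedelta(days=supply)
        raw_end = supply_end_j + timedelta(days=g)
        censored = raw_end > sc.study_end
        end_j = min(raw_end, sc.study_end)
        for fd in dates_j:
            for drug in drugs:
                rec.add_rx(pid, drug, fd, supply)
            if backbone:
                rec.add_rx(pid, adt_agent, fd, supply)
        truth_lines.append(
            {
                "patient_id": pid,
                "ordinal": f"{j}L",
                "start": start.isoformat(),
                "end": end_j.isoformat(),
                "duration_days": (end_j - start).days,
                "censored": censored,
                "regimen": cat,
                "drugs": "|".join(sorted(set(drugs) | ({adt_agent} if backbone else set()))),
            }
        )
        gap = int(rng.integers(sc.line_gap_days[0], sc.line_gap_days[1] + 1))
        start = supply_end_j + timedelta(days=gap)
        if start > sc.study_end - timedelta(days=30):
            break

    # --- diagnosis claims ----------------------------------------------
    if intent == "insufficient_followup":
        last_activity = index2
    else:
        pad = int(rng.integers(181, 651))
        last_activity = min(index2 + timedelta(days=pad), sc.study_end)
    t = index1
    while t <= last_activity:
        rec.add_dx(pid, _PC_CLAIM_CODE, t)
        t = t + timedelta(days=90)
    if intent != "insufficient_followup":
        rec.add_dx(pid, _PC_CLAIM_CODE, last_activity)

    sites: list[str] = []
    if has_met:
        sites = [s for s in _SITE_CODES if rng.random() < _SITE_RATES[s]]
        if not sites:
            sites = ["bone"]
        first_site = sites[int(rng.integers(0, len(sites)))]
        rec.add_dx(pid, _SITE_CODES[first_site], met_date)
        for s in sites:
            if s != first_site:
                extra = min(met_date + timedelta(days=int(rng.integers(0, 201))), sc.study_end)
                rec.add_dx(pid, _SITE_CODES[s], extra)

    comorbidities = sorted(
        grp for grp, rate in sc.comorbidity_rates.items() if rng.random() < rate
    )
    for grp in comorbidities:
        code = str(rng.choice(_COMORBIDITY_CODES[grp]))
        rec.add_dx(pid, code, index2 - timedelta(days=int(rng.integers(1, 180))))

    if intent == "other_malignancy":
        when = min(index1 + timedelta(days=int(rng.integers(0, 301))), sc.study_end)
        rec.add_dx(pid, _OTHER_MALIGNANCY_CODE, when)

    # --- derive the true inclusion decision ----------------------------
    followup = (min(rec.last_record[pid], sc.study_end) - index2).days
    reason = ""
    if age1 < 20:
        reason = "under_age"
    elif not has_met:
        reason = "no_metastasis"
    elif (index2 - index1).days < 180:
        reason = "insufficient_baseline"
    elif followup < 180:
        reason = "insufficient_followup"
    elif intent == "other_malignancy":
        reason = "other_malignancy"
    elif (index2 - mcrpc_date).days > 90:
        reason = "late_initiation"
    included = reason == ""
    subgroup = (1 if met_date < crpc_date else 2) if included else 0

    patient_rows.append(
        {
            "patient_id": pid,
            "birth_year": birth_year,
            "sex": "male",
            "index1": index1.isoformat(),
            "crpc_date": crpc_date.isoformat(),
            "crpc_mechanism": mechanism,
            "met_date": met_date.isoformat() if has_met else "",
            "mcrpc_date": mcrpc_date.isoformat() if has_met else "",
            "index2": index2.isoformat(),
            "included": included,
            "exclusion_reason": reason,
            "subgroup": subgroup,
            "pre_category": pre_category,
            "first_line_category": l1_category,
            "comorbidities": "|".join(comorbidities),
            "met_sites": "|".join(sorted(sites)),
            "followup_days": followup,
        }
    )
    line_rows.extend(truth_lines)


# --- noise injection ----------------------------------------------------

NOISE_KINDS = ("missing_days_supply", "duplicate_rx", "stray_rx", "psa_jitter")


def inject_noise(
    tables: SimTables,
    noise_spec: dict[str, float | int],
    *,
    seed: int = 0,
    study_start: date = date(2015, 1, 1),
) -> tuple[SimTables, pd.DataFrame]:
    """Apply named perturbations to copies of the tables.

    ``noise_spec`` maps a noise kind to its intensity: fraction of rows
    for ``missing_days_supply`` and ``duplicate_rx``, row count for
    ``stray_rx`` (prescriptions dated before ``study_start``, hence
    outside the analysis window), standard deviation of a multiplicative
    factor for ``psa_jitter``.  Returns the perturbed tables and a
    manifest with one row per injected change; the ground truth is never
    modified.
    """
    unknown = set(noise_spec) - set(NOISE_KINDS)
    if unknown:
        raise ValueError(f"unknown noise kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rx = tables.prescriptions.copy()
    labs = tables.labs.copy()
    manifest: list[dict] = []

    frac = float(noise_spec.get("missing_days_supply", 0))
    if frac > 0 and len(rx):
        rx["days_supplied"] = rx["days_supplied"].astype("Int64")
        idx = rng.choice(len(rx), size=max(1, int(frac * len(rx))), replace=False)
        rx.iloc[idx, rx.columns.get_loc("days_supplied")] = pd.NA
        for i in idx:
            manifest.append(
                {"kind": "missing_days_supply", "patient_id": rx.iloc[i]["patient_id"],
                 "detail": f"{rx.iloc[i]['drug_id']}@{rx.iloc[i]['date']}"}
            )

    frac = float(noise_spec.get("duplicate_rx", 0))
    if frac > 0 and len(rx):
        idx = rng.choice(len(rx), size=max(1, int(frac * len(rx))), replace=False)
        dupes = rx.iloc[sorted(idx)]
        rx = pd.concat([rx, dupes], ignore_index=True)
        for _, row in dupes.iterrows():
            manifest.append(
                {"kind": "duplicate_rx", "patient_id": row["patient_id"],
                 "detail": f"{row['drug_id']}@{row['date']}"}
            )

    count = int(noise_spec.get("stray_rx", 0))
    if count > 0 and len(rx):
        pids = tables.patients["patient_id"].tolist() or rx["patient_id"].unique().tolist()
        earliest = min(
            pd.to_datetime(tables.prescriptions["date"]).min().date(), study_start
        )
        new_rows = []
        for _ in range(count):
            pid = str(rng.choice(pids))
            when = earliest - timedelta(days=int(rng.integers(30, 401)))
            drug = str(rng.choice(["enzalutamide", "docetaxel", "bicalutamide"]))
            new_rows.append((pid, drug, when.isoformat(), 30))
            manifest.append(
                {"kind": "stray_rx", "patient_id": pid, "detail": f"{drug}@{when}"}
            )
        rx = pd.concat(
            [rx, pd.DataFrame(new_rows, columns=RX_COLUMNS)], ignore_index=True
        )

    sd = float(noise_spec.get("psa_jitter", 0))
    if sd > 0 and len(labs):
        factors = rng.normal(1.0, sd, size=len(labs))
        labs["value"] = (labs["value"].astype(float) * factors).round(3)
        for pid in labs["patient_id"].unique():
            manifest.append({"kind": "psa_jitter", "patient_id": pid, "detail": f"sd={sd}"})

    return (
        SimTables(tables.diagnoses.copy(), rx, labs, tables.patients.copy(), tables.truth),
        pd.DataFrame(manifest, columns=["kind", "patient_id", "detail"]),
    )
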