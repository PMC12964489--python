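"""Aggregate outputs: transitions, annual trends, durations, demographics.

All percentages are computed with round-half-up to one decimal, the
convention used by the published tables (e.g. 159/246 -> 64.6).  Patients
with no line at a requested stage contribute ``no_therapy`` at the
pre-mCRPC stage and ``no_therapy_observed`` at 2L-5L; first-line therapy
exists for every included patient by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .regimen import NO_THERAPY, NO_THERAPY_OBSERVED
from .lines import PRE, POST_ORDINALS

STAGES = (PRE,) + POST_ORDINALS


def percent(count: float, denominator: float) -> float:
    """100*count/denominator, rounded half-up to one decimal place."""
    if denominator == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _absent_label(stage: str) -> str:
    return NO_THERAPY if stage == PRE else NO_THERAPY_OBSERVED


def stage_categories(lines: pd.DataFrame, phenotypes: pd.DataFrame, stage: str) -> pd.Series:
    """Per included patient, the regimen category at ``stage``.

    Index: patient_id; absent lines map to the stage's no-therapy label.
    """
    cohort = phenotypes.loc[phenotypes["included"], "patient_id"].astype(str)
    at_stage = lines[lines["ordinal"] == stage]
    mapping = dict(zip(at_stage["patient_id"].astype(str), at_stage["regimen"]))
    absent = _absent_label(stage)
    return pd.Series(
        [mapping.get(pid, absent) for pid in cohort], index=list(cohort), name=stage
    )


def _scope_ids(phenotypes: pd.DataFrame, scope: str) -> set[str]:
    inc = phenotypes[phenotypes["included"]]
    if scope == "full":
        pass
    elif scope == "subgroup1":
        inc = inc[inc["subgroup"] == 1]
    elif scope == "subgroup2":
        inc = inc[inc["subgroup"] == 2]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return set(inc["patient_id"].astype(str))


@dataclass
class TransitionTable:
    stage_from: str
    stage_to: str
    counts: dict[tuple[str, str], int]
    total: int
    mode: str  # "total" | "row"

    @property
    def row_margins(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (a, _), n in self.counts.items():
            out[a] = out.get(a, 0) + n
        return out

    @property
    def col_margins(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, b), n in self.counts.items():
            out[b] = out.get(b, 0) + n
        return out

    def percentage(self, cat_from: str, cat_to: str) -> float:
        n = self.counts.get((cat_from, cat_to), 0)
        denom = self.total if self.mode == "total" else self.row_margins.get(cat_from, 0)
        return percent(n, denom)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage_from": self.stage_from,
                "category_from": a,
                "stage_to": self.stage_to,
                "category_to": b,
                "count": n,
                "percent": self.percentage(a, b),
            }
            for (a, b), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "stage_from",
                "category_from",
                "stage_to",
                "category_to",
                "count",
                "percent",
            ],
        )


def transition_table(
    lines: pd.DataFrame,
    phenotypes: pd.DataFrame,
    stage_from: str,
    stage_to: str,
    *,
    scope: str = "full",
    condition: str | None = None,
    mode: str = "total",
) -> TransitionTable:
    """Counts of patients moving between categories at two stages.

    ``condition`` restricts to patients whose ``stage_from`` category is
    the given label (the conditional flow panels); the percentage
    denominator is then the conditioning cohort (``mode="row"``).
    """
    ids = _scope_ids(phenotypes, scope)
    src = stage_categories(lines, phenotypes, stage_from)
    dst = stage_categories(lines, phenotypes, stage_to)
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for pid in src.index:
        if pid not in ids:
            continue
        a, b = src[pid], dst[pid]
        if condition is not None and a != condition:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
        total += 1
    if condition is not None:
        mode = "row"
    return TransitionTable(stage_from, stage_to, counts, total, mode)


def annual_trend(
    lines: pd.DataFrame,
    phenotypes: pd.DataFrame,
    stage: str,
    *,
    years: range = range(2015, 2023),
    scope: str = "full",
    year_basis: str = "line_start",
) -> pd.DataFrame:
    """Counts and percentages per category per calendar year at a stage.

    The year of a line is the year of its own start date; for the
    pre-mCRPC stage ``year_basis="index2"`` instead buckets by the year
    1L began.  Patients with no line at the stage carry no date and are
    omitted; the denominator is the number of stage lines that year.
    """
    ids = _scope_ids(phenotypes, scope)
    at_stage = lines[lines["ordinal"] == stage]
    at_stage = at_stage[at_stage["patient_id"].astype(str).isin(ids)]
    if year_basis == "line_start":
        year_of = pd.to_datetime(at_stage["start"]).dt.year
    elif year_basis == "index2":
        idx2 = phenotypes.set_index(phenotypes["patient_id"].astype(str))["index2"]
        year_of = (
            at_stage["patient_id"].astype(str).map(idx2).pipe(pd.to_datetime).dt.year
        )
    else:
        raise ValueError(f"unknown year_basis {year_basis!r}")

    rows = []
    for year in years:
        sub = at_stage[year_of == year]
        denom = len(sub)
        if denom == 0:
            continue
        for category, n in sub["regimen"].value_counts().items():
            rows.append(
                {
                    "stage": stage,
                    "year": year,
                    "category": category,
                    "n": int(n),
                    "percent": percent(int(n), denom),
                    "denominator": denom,
                }
            )
    return pd.DataFrame(
        rows, columns=["stage", "year", "category", "n", "percent", "denominator"]
    )


def duration_summary(
    lines: pd.DataFrame,
    stage: str,
    *,
    scope_ids: set[str] | None = None,
    sd_singleton: float | None = 0.0,
) -> pd.DataFrame:
    """Descriptive statistics of line durations per category at a stage.

    Censored lines enter with their observed duration and are counted in
    ``n_censored``.  With a single observation the standard deviation is
    reported as ``sd_singleton`` (0 by default, ``None`` for blank).
    """
    at_stage = lines[lines["ordinal"] == stage]
    if scope_ids is not None:
        at_stage = at_stage[at_stage["patient_id"].astype(str).isin(scope_ids)]
    rows = []
    for category, sub in at_stage.groupby("regimen"):
        d = sub["duration_days"].astype(float)
        sd = d.std(ddof=1)
        if pd.isna(sd):
            sd = sd_singleton
        rows.append(
            {
                "stage": stage,
                "category": category,
                "n": len(d),
                "mean": round(d.mean(), 1),
                "sd": round(sd, 1) if sd is not None else None,
                "median": d.median(),
                "min": d.min(),
                "max": d.max(),
                "q1": d.quantile(0.25),
                "q3": d.quantile(0.75),
                "n_censored": int(sub["censored"].sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stage",
            "category",
            "n",
            "mean",
            "sd",
            "median",
            "min",
            "max",
            "q1",
            "q3",
            "n_censored",
        ],
    )


AGE_BANDS = ((0, 49, "<=49"), (50, 59, "50-59"), (60, 69, "60-69"),
             (70, 79, "70-79"), (80, 89, "80-89"), (90, 200, ">=90"))


def demographic_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Table-style demographics of the included cohort (tidy item/stat rows).

    Metastatic-site rows are not mutually exclusive and may sum past
    100%.  The mCRPC-to-index2 duration uses the month-end convention:
    a 1L start in the CRPC code month counts as 0 days.
    """
    inc = phenotypes[phenotypes["included"]]
    n = len(inc)
    rows: list[dict] = [{"item": "cohort", "stat": "n", "value": n}]

    def describe(item: str, series: pd.Series) -> None:
        s = series.dropna().astype(float)
        if s.empty:
            return
        sd = s.std(ddof=1)
        rows.extend(
            [
                {"item": item, "stat": "mean", "value": round(s.mean(), 1)},
                {"item": item, "stat": "sd", "value": round(0.0 if pd.isna(sd) else sd, 1)},
                {"item": item, "stat": "median", "value": s.median()},
                {"item": item, "stat": "q1", "value": s.quantile(0.25)},
                {"item": item, "stat": "q3", "value": s.quantile(0.75)},
            ]
        )

    describe("age_at_index1", inc["age_at_index1"])
    describe("age_at_index2", inc["age_at_index2"])
    describe("mcrpc_to_index2_days", inc["mcrpc_to_index2_days"])

    ages2 = inc["age_at_index2"].dropna().astype(int)
    for lo, hi, label in AGE_BANDS:
        k = int(((ages2 >= lo) & (ages2 <= hi)).sum())
        rows.append({"item": f"age_band_{label}", "stat": "n", "value": k})
        rows.append({"item": f"age_band_{label}", "stat": "percent", "value": percent(k, n)})

    for sex in ("male", "female"):
        k = int((inc["sex"].str.lower() == sex).sum())
        rows.append({"item": f"sex_{sex}", "stat": "n", "value": k})
        rows.append({"item": f"sex_{sex}", "stat": "percent", "value": percent(k, n)})

    for col in inc.columns:
        if col.startswith("comorb_") or col.startswith("site_"):
            k = int(inc[col].sum())
            rows.append({"item": col, "stat": "n", "value": k})
            rows.append({"item": col, "stat": "percent", "value": percent(k, n)})

    return pd.DataFrame(rows, columns=["item", "stat", "value"])


def export_sankey(tables: list[TransitionTable]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and link records for Sankey-style rendering by any front end.

    Nodes carry (stage, category, total); links carry the transition
    counts and percentages.  Per stage, inbound totals equal outbound
    totals (absent-therapy labels are ordinary nodes, so flow is
    conserved along a chained pre->1L->...->5L export).
    """
    links = (
        pd.concat([t.to_frame() for t in tables], ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "stage_from",
                "category_from",
                "stage_to",
                "category_to",
                "count",
                "percent",
            ]
        )
    )
    node_rows: dict[tuple[str, str], int] = {}
    for t in tables:
        for cat, total in t.row_margins.items():
            node_rows[(t.stage_from, cat)] = total
        for cat, total in t.col_margins.items():
            node_rows[(t.stage_to, cat)] = total
    nodes = pd.DataFrame(
        [
            {"stage": stage, "category": cat, "total": total}
            for (stage, cat), total in sorted(node_rows.items())
        ],
        columns=["stage", "category", "total"],
    )
    return nodes, links
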