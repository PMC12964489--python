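"""Line-of-therapy construction from dispensing records.

A treatment line is a dated episode of one regimen.  The rules, with
combination window ``W`` (default 30 days) and continuation grace period
``G`` (default 90 days):

1. A line starts on the earliest unassigned prescription date.
2. Drugs first dispensed within ``W`` days (inclusive) of the start join
   the regimen; backbone (ADT) drugs join silently at any time without
   affecting the category.
3. A fill of a regimen drug on or before the line's provisional end
   (rule 4a) continues the line.
4. The line ends at the earlier of (a) the last supply end of the
   counting drugs plus ``G`` days, or (b) the dispense date of the first
   non-backbone drug outside the regimen arriving after the combination
   window — which starts the next line on that same date.
5. Lines running past the data cutoff are truncated there and flagged
   censored.

"Counting" drugs for rule 4a are the non-backbone members, except in a
vintage line (all member classes hormonal) where every member counts:
otherwise a continuous castration backbone would keep every line open
forever.  Missing days-supplied values are imputed with
``default_supply``.  By default rule 4a anchors on the last day of the
dispensed quantity; ``end_anchor="dispense_date"`` switches to the last
dispense date for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .regimen import (
    DrugDictionary,
    NO_THERAPY,
    VINTAGE_CLASSES,
    ADT,
    classify_regimen,
)

# line ordinals
PRE = "pre"
HISTORY = "history"
LATER = "later"
POST_ORDINALS = ("1L", "2L", "3L", "4L", "5L")


@dataclass
class Fill:
    """One dispensing event (days_supplied already imputed)."""

    drug: str
    date: date
    days_supplied: int

    @property
    def supply_end(self) -> date:
        return self.date + timedelta(days=self.days_supplied)


@dataclass
class TreatmentLine:
    patient_id: str
    start: date
    end: date
    regimen: str
    drugs: tuple[str, ...]
    n_fills: int
    censored: bool = False
    ordinal: str | None = None
    fills: list[Fill] = field(default_factory=list, repr=False)

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days


class _OpenLine:
    """Mutable state of the line currently being assembled."""

    def __init__(self, patient_id: str, start: date, gap_days: int, backbone: frozenset[str]):
        self.patient_id = patient_id
        self.start = start
        self.gap = timedelta(days=gap_days)
        self.backbone = backbone
        self.members: dict[str, str] = {}  # drug -> class
        self.anchor: dict[str, date] = {}  # drug -> last supply end (or dispense date)
        self.fills: list[Fill] = []

    @property
    def classes(self) -> set[str]:
        return set(self.members.values())

    @property
    def is_vintage(self) -> bool:
        return self.classes <= VINTAGE_CLASSES

    def counting_drugs(self) -> list[str]:
        if self.is_vintage:
            return list(self.members)
        return [d for d, c in self.members.items() if c not in self.backbone]

    def provisional_end(self) -> date:
        counting = self.counting_drugs()
        return max(self.anchor[d] for d in counting) + self.gap

    def add(self, fill: Fill, cls: str, anchor: date) -> None:
        self.members[fill.drug] = cls
        self.anchor[fill.drug] = max(self.anchor.get(fill.drug, anchor), anchor)
        self.fills.append(fill)

    def close(self, end: date, cutoff: date, regimen_backbone: frozenset[str]) -> TreatmentLine:
        censored = end > cutoff
        if censored:
            end = cutoff
        end = max(end, self.start)
        return TreatmentLine(
            patient_id=self.patient_id,
            start=self.start,
            end=end,
            regimen=classify_regimen(self.classes, regimen_backbone),
            drugs=tuple(sorted(self.members)),
            n_fills=len(self.fills),
            censored=censored,
            fills=list(self.fills),
        )


def _prepare_fills(
    rx: Iterable[tuple[str, date, int | None]] | pd.DataFrame,
    default_supply: int,
) -> list[Fill]:
    """Normalize raw fills: impute supply, collapse same-day duplicates."""
    if isinstance(rx, pd.DataFrame):
        rows = (
            (str(r.drug_id), _as_date(r.date), r.days_supplied)
            for r in rx.itertuples(index=False)
        )
    else:
        rows = iter(rx)
    best: dict[tuple[date, str], int] = {}
    for drug, when, supply in rows:
        if supply is None or pd.isna(supply):
            supply = default_supply
        supply = int(supply)
        if supply <= 0:
            raise ValueError(f"non-positive days_supplied for {drug} on {when}")
        key = (when, drug)
        best[key] = max(best.get(key, 0), supply)
    return [Fill(drug, when, supply) for (when, drug), supply in sorted(best.items())]


def _as_date(value) -> date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()


def build_lines(
    rx,
    dictionary: DrugDictionary,
    *,
    patient_id: str = "",
    window_days: int = 30,
    gap_days: int = 90,
    default_supply: int = 30,
    data_cutoff: date,
    end_anchor: str = "supply_end",
) -> list[TreatmentLine]:
    """Build the ordered treatment lines for one patient.

    ``rx`` is either a DataFrame with columns drug_id/date/days_supplied
    or an iterable of ``(drug_id, date, days_supplied)`` tuples, holding
    prostate-cancer medications only.
    """
    if end_anchor not in ("supply_end", "dispense_date"):
        raise ValueError(f"unknown end_anchor {end_anchor!r}")
    fills = _prepare_fills(rx, default_supply)
    for f in fills:
        if dictionary.classify(f.drug) == "non_pc":
            raise ValueError(f"non-PC drug {f.drug!r} must be pre-filtered")
    if not fills:
        return []

    window = timedelta(days=window_days)
    backbone = dictionary.backbone
    lines: list[TreatmentLine] = []
    open_line: _OpenLine | None = None

    def anchor_of(f: Fill) -> date:
        return f.supply_end if end_anchor == "supply_end" else f.date

    # group fills by calendar date
    by_date: dict[date, list[Fill]] = {}
    for f in fills:
        by_date.setdefault(f.date, []).append(f)

    for day in sorted(by_date):
        todays = by_date[day]
        if open_line is not None:
            end_a = open_line.provisional_end()
            if day > end_a:
                lines.append(open_line.close(end_a, data_cutoff, backbone))
                open_line = None
        if open_line is not None:
            newcomers = [
                f
                for f in todays
                if f.drug not in open_line.members
                and dictionary.classify(f.drug) not in backbone
            ]
            if newcomers and day > open_line.start + window:
                # rule 4b: a new non-backbone drug breaks the line; all of
                # today's fills (member refills included) seed the next line
                lines.append(open_line.close(day, data_cutoff, backbone))
                open_line = _OpenLine(patient_id, day, gap_days, backbone)
        if open_line is None:
            open_line = _OpenLine(patient_id, day, gap_days, backbone)
        for f in todays:
            open_line.add(f, dictionary.classify(f.drug), anchor_of(f))

    lines.append(open_line.close(open_line.provisional_end(), data_cutoff, backbone))
    return lines


def adt_exposure_intervals(
    rx,
    dictionary: DrugDictionary,
    *,
    gap_days: int = 90,
    default_supply: int = 30,
) -> list[tuple[date, date]]:
    """Union of ADT dispensing intervals, merging gaps of at most ``gap_days``.

    Each fill covers ``[dispense_date, dispense_date + days_supplied]``;
    the merged intervals define "during ADT treatment" for the PSA
    progression rule.
    """
    fills = _prepare_fills(rx, default_supply)
    spans = sorted(
        (f.date, f.supply_end) for f in fills if dictionary.classify(f.drug) == ADT
    )
    merged: list[tuple[date, date]] = []
    gap = timedelta(days=gap_days)
    for lo, hi in spans:
        if merged and lo <= merged[-1][1] + gap:
            prev_lo, prev_hi = merged[-1]
            merged[-1] = (prev_lo, max(prev_hi, hi))
        else:
            merged.append((lo, hi))
    return merged


def find_index2(
    lines: Sequence[TreatmentLine],
    *,
    met_date: date,
    crpc_date: date,
    crpc_mechanism: str,
) -> date | None:
    """Start date of the first line after the mCRPC qualification.

    For a code-based CRPC diagnosis the qualification date is normalized
    to the last day of the claim month, so a line starting anywhere in
    that month already counts as post-mCRPC (the published convention
    reports such same-month durations as 0).  The search threshold is
    therefore max(metastasis date, first day of the CRPC code month) for
    the code mechanism and max(metastasis date, PSA progression date)
    otherwise.
    """
    crpc_floor = crpc_date.replace(day=1) if crpc_mechanism == "code" else crpc_date
    threshold = max(met_date, crpc_floor)
    for line in sorted(lines, key=lambda l: l.start):
        if line.start >= threshold:
            return line.start
    return None


def label_lines(lines: Sequence[TreatmentLine], index2: date) -> list[TreatmentLine]:
    """Assign ordinals relative to the 1L start date (``index2``).

    The line starting exactly at ``index2`` is 1L and later lines are
    numbered sequentially (beyond 5L they aggregate as ``later``).  The
    latest line starting before ``index2`` is the pre-mCRPC treatment;
    any earlier lines are kept as ``history``.
    """
    ordered = sorted(lines, key=lambda l: l.start)
    starts = [l.start for l in ordered]
    if index2 not in starts:
        raise ValueError(f"no line starts at index2 {index2}")
    pivot = starts.index(index2)
    out: list[TreatmentLine] = []
    for i, line in enumerate(ordered):
        if i < pivot:
            ordinal = PRE if i == pivot - 1 else HISTORY
        else:
            k = i - pivot
            ordinal = POST_ORDINALS[k] if k < len(POST_ORDINALS) else LATER
        out.append(replace(line, ordinal=ordinal))
    return out


def lines_to_frame(lines: Iterable[TreatmentLine]) -> pd.DataFrame:
    """Flatten lines into the delimited-text export schema."""
    rows = [
        {
            "patient_id": l.patient_id,
            "ordinal": l.ordinal if l.ordinal is not None else "",
            "start": l.start.isoformat(),
            "end": l.end.isoformat(),
            "duration_days": l.duration_days,
            "censored": l.censored,
            "regimen": l.regimen,
            "drugs": "|".join(l.drugs),
            "n_fills": l.n_fills,
        }
        for l in lines
    ]
    columns = [
        "patient_id",
        "ordinal",
        "start",
        "end",
        "duration_days",
        "censored",
        "regimen",
        "drugs",
        "n_fills",
    ]
    return pd.DataFrame(rows, columns=columns)
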