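"""Brute-force day-by-day reference implementation of the line rules.

Walks every calendar day from the first fill to beyond the last possible
line end, applying the initiation / combination-window / continuation /
termination rules literally to a mutable state.  Deliberately naive and
independent of the event-driven builder in the package; used as the
oracle for equivalence testing on small random instances.
"""

from __future__ import annotations

from datetime import date, timedelta

from mcrpcseq.regimen import VINTAGE_CLASSES, classify_regimen


def brute_force_lines(
    fills,
    dictionary,
    *,
    window_days=30,
    gap_days=90,
    default_supply=30,
    data_cutoff,
):
    """fills: iterable of (drug_id, date, days_supplied|None) tuples."""
    # normalize: impute supply, collapse same-day duplicates to max supply
    dedup: dict[tuple[date, str], int] = {}
    for drug, when, supply in fills:
        s = default_supply if supply is None else int(supply)
        dedup[(when, drug)] = max(dedup.get((when, drug), 0), s)
    if not dedup:
        return []
    events: dict[date, list[tuple[str, int]]] = {}
    for (when, drug), s in dedup.items():
        events.setdefault(when, []).append((drug, s))

    one = timedelta(days=1)
    gap = timedelta(days=gap_days)
    window = timedelta(days=window_days)
    backbone = dictionary.backbone

    first_day = min(events)
    horizon = max(when + timedelta(days=s) for (when, _), s in dedup.items()) + gap + one

    lines = []
    state = None  # dict(start, members{drug: cls}, supply_end{drug: date}, fills)

    def rule_a_end(st):
        vintage = set(st["members"].values()) <= VINTAGE_CLASSES
        counting = [
            d for d, c in st["members"].items() if vintage or c not in backbone
        ]
        return max(st["supply_end"][d] for d in counting) + gap

    def close(st, end):
        censored = end > data_cutoff
        if censored:
            end = data_cutoff
        lines.append(
            {
                "start": st["start"],
                "end": max(end, st["start"]),
                "regimen": classify_regimen(set(st["members"].values()), backbone),
                "drugs": tuple(sorted(st["members"])),
                "n_fills": st["fills"],
                "censored": censored,
            }
        )

    def open_line(day_):
        return {"start": day_, "members": {}, "supply_end": {}, "fills": 0}

    def add(st, drug, s, day_):
        cls = dictionary.classify(drug)
        st["members"][drug] = cls
        end = day_ + timedelta(days=s)
        st["supply_end"][drug] = max(st["supply_end"].get(drug, end), end)
        st["fills"] += 1

    day = first_day
    while day <= horizon:
        if state is not None:
            end_a = rule_a_end(state)
            if day > end_a:
                close(state, end_a)
                state = None
        todays = events.get(day, [])
        if todays:
            if state is not None:
                new_breaking = [
                    d
                    for d, _ in todays
                    if d not in state["members"]
                    and dictionary.classify(d) not in backbone
                ]
                if new_breaking and day > state["start"] + window:
                    close(state, day)
                    state = None
            if state is None:
                state = open_line(day)
            for drug, s in todays:
                add(state, drug, s, day)
        day += one
    if state is not None:
        close(state, rule_a_end(state))
    return lines
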