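"""Line-of-therapy construction: windows, gaps, termination, labelling."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from mcrpcseq.lines import (
    adt_exposure_intervals,
    build_lines,
    find_index2,
    label_lines,
)

D0 = date(2018, 1, 1)


def day(n: int) -> date:
    return D0 + timedelta(days=n)


def build(fills, dictionary, cutoff=365 * 3, **kw):
    return build_lines(
        [(drug, day(n), supply) for drug, n, supply in fills],
        dictionary,
        data_cutoff=day(cutoff),
        **kw,
    )


def test_single_fill_terminates_at_supply_end_plus_grace(dictionary):
    (line,) = build([("enzalutamide", 0, 30)], dictionary)
    assert (line.start, line.end) == (day(0), day(120))  # 30 supply + 90 grace
    assert line.regimen == "enzalutamide"
    assert not line.censored


def test_new_drug_after_window_breaks_line_adjacently(dictionary):
    lines = build([("enzalutamide", 0, 30), ("abiraterone", 40, 30)], dictionary)
    assert [(l.regimen, l.start, l.end) for l in lines] == [
        ("enzalutamide", day(0), day(40)),
        ("abiraterone", day(40), day(160)),
    ]


def test_co_start_within_window_is_combination(dictionary):
    (line,) = build([("docetaxel", 0, 30), ("enzalutamide", 20, 30)], dictionary)
    assert line.regimen == "combination"
    assert line.start == day(0)


@pytest.mark.parametrize(
    "second_fill, n_lines",
    [(115, 1), (120, 1), (125, 2)],  # gap from supply end: 85, 90, 95 vs G=90
)
def test_continuation_gap_boundary(second_fill, n_lines, dictionary):
    lines = build([("enzalutamide", 0, 30), ("enzalutamide", second_fill, 30)], dictionary)
    assert len(lines) == n_lines


@pytest.mark.parametrize("added_day, expect", [(30, 1), (31, 2)])
def test_combination_window_boundary_inclusive(added_day, expect, dictionary):
    lines = build([("docetaxel", 0, 30), ("enzalutamide", added_day, 30)], dictionary)
    assert len(lines) == expect


def test_backbone_joins_silently_and_does_not_extend(dictionary):
    # ADT refills continue past the ARSI supply end but the line still
    # terminates relative to the non-backbone drug
    lines = build(
        [
            ("enzalutamide", 0, 30),
            ("leuprorelin", 0, 30),
            ("leuprorelin", 30, 30),
            ("leuprorelin", 60, 30),
        ],
        dictionary,
    )
    (line,) = lines
    assert line.regimen == "enzalutamide"
    assert line.end == day(120)  # enzalutamide supply end 30 + 90
    assert "leuprorelin" in line.drugs


def test_adt_only_line_is_vintage_and_extends(dictionary):
    (line,) = build([("leuprorelin", 0, 30), ("leuprorelin", 30, 30)], dictionary)
    assert line.regimen == "vintage"
    assert line.end == day(150)  # its own fills count in a vintage line


def test_censoring_at_cutoff(dictionary):
    (line,) = build([("enzalutamide", 0, 30)], dictionary, cutoff=100)
    assert line.end == day(100)
    assert line.censored


def test_same_day_duplicates_are_idempotent(dictionary):
    once = build([("enzalutamide", 0, 30)], dictionary)
    twice = build([("enzalutamide", 0, 30), ("enzalutamide", 0, 30)], dictionary)
    assert [(l.start, l.end, l.regimen) for l in once] == [
        (l.start, l.end, l.regimen) for l in twice
    ]


def test_translation_invariance(dictionary):
    fills = [("enzalutamide", 0, 30), ("abiraterone", 40, 30), ("docetaxel", 200, 21)]
    base = build(fills, dictionary)
    shift = 37
    moved = build([(d, n + shift, s) for d, n, s in fills], dictionary, cutoff=365 * 3 + shift)
    for a, b in zip(base, moved):
        assert b.start - a.start == timedelta(days=shift)
        assert b.end - a.end == timedelta(days=shift)
        assert a.regimen == b.regimen


def test_missing_supply_imputed_with_default(dictionary):
    (line,) = build([("enzalutamide", 0, None)], dictionary, default_supply=30)
    assert line.end == day(120)


def test_dispense_date_anchor_toggle(dictionary):
    (line,) = build([("enzalutamide", 0, 30)], dictionary, end_anchor="dispense_date")
    assert line.end == day(90)  # last dispense + G, ignoring supply


def test_empty_input(dictionary):
    assert build([], dictionary) == []


def test_non_pc_drug_is_contract_violation(dictionary):
    with pytest.raises(ValueError):
        build([("amoxicillin", 0, 30)], dictionary)


def test_prescription_conservation(dictionary):
    fills = [
        ("enzalutamide", 0, 30), ("enzalutamide", 30, 30),
        ("abiraterone", 200, 30), ("docetaxel", 500, 21), ("enzalutamide", 500, 30),
    ]
    lines = build(fills, dictionary)
    assert sum(l.n_fills for l in lines) == len(fills)


def test_adt_exposure_merges_within_grace(dictionary):
    rx = [("leuprorelin", day(0), 30), ("leuprorelin", day(100), 30)]
    assert adt_exposure_intervals(rx, dictionary) == [(day(0), day(130))]
    rx = [("leuprorelin", day(0), 30), ("leuprorelin", day(200), 30)]
    assert adt_exposure_intervals(rx, dictionary) == [
        (day(0), day(30)),
        (day(200), day(230)),
    ]
    assert adt_exposure_intervals([("enzalutamide", day(0), 30)], dictionary) == []


def test_label_lines_ordinals(dictionary):
    fills = [("leuprorelin", -400, 30), ("enzalutamide", 0, 30), ("abiraterone", 200, 30)]
    lines = build_lines(
        [(d, day(n), s) for d, n, s in fills], dictionary, data_cutoff=day(600)
    )
    labeled = label_lines(lines, day(0))
    assert [l.ordinal for l in labeled] == ["pre", "1L", "2L"]


def test_label_lines_no_pre(dictionary):
    lines = build([("enzalutamide", 0, 30)], dictionary)
    labeled = label_lines(lines, day(0))
    assert [l.ordinal for l in labeled] == ["1L"]


def test_label_lines_history_before_pre(dictionary):
    fills = [
        ("docetaxel", -900, 21), ("leuprorelin", -400, 30),
        ("enzalutamide", 0, 30),
    ]
    lines = build_lines(
        [(d, day(n), s) for d, n, s in fills], dictionary, data_cutoff=day(600)
    )
    labeled = label_lines(lines, day(0))
    assert [l.ordinal for l in labeled] == ["history", "pre", "1L"]


def test_find_index2_code_mechanism_uses_claim_month_floor(dictionary):
    # a 1L starting in the CRPC code month qualifies even though the
    # normalized CRPC date is the month end
    lines = build_lines(
        [("enzalutamide", date(2018, 5, 20), 30)], dictionary, data_cutoff=date(2019, 1, 1)
    )
    idx2 = find_index2(
        lines,
        met_date=date(2017, 3, 10),
        crpc_date=date(2018, 5, 31),
        crpc_mechanism="code",
    )
    assert idx2 == date(2018, 5, 20)
    assert (
        find_index2(
            lines,
            met_date=date(2017, 3, 10),
            crpc_date=date(2018, 5, 31),
            crpc_mechanism="psa",
        )
        is None
    )
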