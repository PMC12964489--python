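# Methods

This note documents the analytical conventions, the synthetic-data
model, and the design choices made where the underlying rules admit
more than one reading. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Phenotyping conventions

**Date granularity.** Diagnosis claims in DPC-style hospital data are
reliable to the month. A code-based CRPC diagnosis is therefore dated
on the **last day of its claim month**. Two consequences are handled
explicitly: (a) the code-mechanism comparison against index date 1 is
made at calendar-month precision ("same or any subsequent month"), and
(b) a first-line start inside the CRPC claim month precedes the
normalized CRPC date; the search threshold for the 1L line therefore
uses the *first* day of the claim month, and the reported
mCRPC-to-index-2 duration clamps negatives to 0. PSA-based CRPC dates
are day-precise and need no adjustment.

**PSA progression rule.** Both thresholds (> 1 ng/mL absolute and
> 25 % relative above the nadir) must hold on the *same* measurement.
The nadir is the running minimum of PSA values observed during ADT
exposure strictly before that measurement; a measurement with no prior
on-ADT value cannot qualify. Qualification is by a single measurement —
no confirmatory second rise is required; a confirmation requirement
would only delay (never prevent) detection on monotone trajectories
like the simulator's. ADT exposure is the union of dispensing intervals
(date → date + days supplied) of ADT-class drugs, merged across gaps of
at most G days — the same grace period the line rules use, so one gap
convention governs the whole analysis.

**Criteria order and boundaries.** All day-count comparisons are
inclusive: "within 90 days" admits exactly 90, "minimum 180-day"
admits exactly 180. The exclusion reason recorded per patient is the
first failed criterion in the published order (PC diagnosis, age, CRPC,
metastasis, 1L record, baseline, follow-up, other malignancy, late
initiation), which makes attrition tables comparable across runs. The
other-malignancy scan covers the whole study window and exempts the PC
codes, the CRPC claim codes, and the configured metastasis codes —
those are how PC metastases are recorded, not independent primaries.
Ages are completed years computed as year(date) − birth year, the
claims convention for birth-year-only demographics.

## Line-of-therapy algorithm

Parameters: combination window `W = 30` days (anchored to line
initiation; it does not restart when a drug joins), continuation grace
`G = 90` days, default days-supplied imputation 30 days. Rule (a)
terminates a line at the last counting supply end + `G`; rule (b)
terminates it on the dispense date of the first non-backbone,
non-member drug after the window, which starts the next line the same
day (adjacent, non-overlapping).

Choices where the rules are underdetermined:

* **Backbone.** ADT fills join lines silently, never trigger rule (b),
  and do not extend a non-vintage line past its last non-backbone
  supply end — otherwise continuous castration would make every line
  endless. In a vintage line (all member classes hormonal) every member
  counts. `backbone_mode: strict` disables all of this for sensitivity
  analysis, in which case ADT + ARSI classifies as a combination.
* **Continuation is line-level.** The per-drug phrasing ("the same
  medication within 90 days of its supply end") is ambiguous for
  multi-drug lines, where a member drug can return inside the line's
  active window but more than G after its own supply end. A member-drug
  fill continues the line iff it falls on or before the line's
  provisional rule-(a) end. For monotherapy the two readings coincide;
  the brute-force reference in the tests applies the identical
  convention day by day.
* **Rule (a) anchor.** "90 days after the last prescription" is read
  as the last day of the dispensed quantity (supply end), consistent
  with the continuation clause; `line_end_anchor: dispense_date`
  switches to the dispense date.
* **Same-day ties.** If a regimen-drug refill and a new non-backbone
  drug share a date, the break applies and the refill joins the new
  line's combination window.
* **Ordinals.** The line starting at index 2 is 1L; the latest earlier
  line is the pre-mCRPC treatment; older lines are kept as `history`
  and excluded from aggregates; lines beyond 5L aggregate as `later`.
  Same-day duplicate fills collapse (idempotence).

## Aggregation

Percentages are round-half-up to one decimal (`decimal`-based, so
0.25 → 0.3, never banker's rounding). Conditional transition panels use
the conditioning category as denominator. Annual trends bucket a line
by its own start year (`pre_year_basis: index2` switches the pre stage
to the 1L year); patients without a line at a stage carry no year and
are excluded from that trend's denominator. Censored lines (running
into the data cutoff) contribute their observed duration and a separate
censored count — no survival modelling, since the summaries are plain
descriptives. Metastatic-site flags are not mutually exclusive and may
sum past 100 %. With one observation the standard deviation is reported
as 0 (configurable to blank).

## Synthetic cohort model

The generator emits the four input tables (diagnoses, prescriptions,
labs, patients) plus the embedded truth. Defaults are the study
conditions: window 2015-01-01 to 2023-06-30, PSA series for 10 % of
patients (the PSA-available minority typical of hospital claims; these
patients qualify for CRPC via a PSA trajectory, the rest via a claim
code, giving a ≈ 90/10 code/PSA split), a pre-mCRPC vintage share
declining linearly 0.90 → 0.40 across 2015–2022 with the remainder
split among ARSIs/docetaxel/others, a first-line mix led by
enzalutamide (0.43) and abiraterone (0.28), comorbidity rates set to
the published baseline prevalences, 75 % Subgroup-1 patients, and a
70 % continuous-ADT backbone fraction. Treatment-line sizing uses
category-specific mean durations (e.g. vintage ≈ 600 days pre-mCRPC,
enzalutamide ≈ 500 days at 1L) with 30-day fills. Where the source
material gives no distributional detail these are conventions, not
estimates.

Two design points matter for interpretation:

* **Quota allocation.** Calendar years are assigned round-robin and
  categories by seeded largest-remainder quotas (within year for the
  pre stage; within pre-category for 1L, after zeroing the clinically
  impossible same-agent transition and renormalizing —
  `SimScenario.effective_transition_matrix()` exposes the resulting
  declared matrix). Realized mixes therefore equal configured mixes to
  ±1 patient: the generator *guarantees* its scenario rather than
  sampling it, and recovery tests measure pipeline correctness, not
  binomial luck.
* **Clean mode** (default) makes the line rules unambiguous by
  construction: between-line gaps strictly exceed G, refill gaps stay
  strictly below it, combination partners co-start on one day, backbone
  co-fills align with their line's fills, and a pre-line drug never
  reappears at 1L. Under these conditions exact recovery of every
  (start, end, regimen, ordinal) tuple is a hard requirement and is
  asserted at n = 2000.

Excluded patients are generated by targeted defects (no metastasis
code, 1L delayed past 90 days, follow-up truncated at index 2, a second
primary malignancy, age 19), but the recorded truth label is *derived*
from the constructed records with the same ordered criteria the
pipeline applies — so a defect that happens to trip an earlier
criterion is labelled by that criterion, keeping truth and pipeline
comparable by construction.

What the simulator does **not** emulate: real coding dialects beyond
the configured lists, cross-hospital fragmentation (one hospital per
patient, as in the source data), dose/route detail, death or
discontinuation reasons, non-monotone PSA trajectories, and
free-spacing refill behaviour outside the configured gap distributions.
Passing recovery tests therefore demonstrates algorithmic correctness
under the stated conventions, not robustness to every artefact of real
claims. Opt-in noise (duplicate fills, missing days-supplied,
out-of-window strays, PSA jitter) probes the first steps of that
robustness and is always manifest-logged.

## Problem sizes and numerical notes

The suite exercises: 1000 random ≤ 12-fill patients against the
day-by-day reference; a 2000-patient fixed-seed clean cohort for exact
recovery and conservation; a 4000-patient all-included cohort for
aggregate recovery (annual mixes within 4 points, transition cells
within 2 points — comfortably met because quotas remove allocation
variance). PSA threshold comparisons are strict floating-point `>`;
the simulator places qualifying rises at least 0.05 ng/mL clear of the
thresholds so no test rides a representation edge. Empty inputs yield
empty outputs throughout; an empty cohort is a warning (CLI exit 3),
not an error.

## Known limitations

* The shipped ICD-10 and drug lists are documented reconstructions;
  real deployments should supply their own via configuration.
* Phenotype validation against chart review is out of scope; the
  package validates recovery of its own stated rules.
* No statistical testing across years or categories is provided, and
  Sankey output is data (nodes/links), not rendered figures.
* The month-end CRPC convention can place index 2 before the mCRPC
  date; downstream consumers of `phenotypes.csv` should use the
  clamped `mcrpc_to_index2_days` column for durations.
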