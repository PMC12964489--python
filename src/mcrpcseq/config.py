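"""Run configuration: code lists, line parameters, schemas, toggles.

Every named constant of the analysis lives here — the study window, the
combination window W, the continuation grace period G, the 90-day
initiation rule, the 180-day baseline/follow-up minima, the ICD-10 code
lists and the drug dictionary — so a single YAML file can retarget the
pipeline to a different coding dialect.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .regimen import DEFAULT_DRUG_CLASSES, DEFAULT_BACKBONE, DrugDictionary

# --- default code lists -------------------------------------------------
# The study's verbatim code lists are not public; these defaults follow
# standard ICD-10 usage and are fully configurable.

#: prostate-cancer diagnosis codes (prefix match on dot-stripped codes)
DEFAULT_PC_CODES = ("C61",)

#: claim codes that record a CRPC diagnosis (exact match)
DEFAULT_CRPC_CODES = ("8848040", "8851347")

#: metastasis codes by site (prefix match)
DEFAULT_MET_CODES: dict[str, tuple[str, ...]] = {
    "bone": ("C795",),
    "lymph_node": ("C77",),
    "lung": ("C780",),
    "liver": ("C787",),
}

#: comorbidity groups as (letter, low, high) ICD-10 ranges plus exact prefixes
COMORBIDITY_RANGES: dict[str, list[tuple[str, int, int]]] = {
    "liver": [("K", 70, 77)],
    "kidney": [("N", 0, 39), ("N", 99, 99)],
    "cardiovascular": [("I", 0, 99)],
    "metabolic": [("E", 0, 90)],
    "prostatic": [("N", 40, 42)],
}
#: extra exact-prefix members outside the numeric ranges
COMORBIDITY_PREFIXES: dict[str, tuple[str, ...]] = {"prostatic": ("N510",)}

COMORBIDITY_GROUPS = tuple(COMORBIDITY_RANGES)

METASTASIS_SITES = tuple(DEFAULT_MET_CODES)


def normalize_code(code: str) -> str:
    """Canonical ICD-10 form: uppercase, dot removed."""
    return str(code).replace(".", "").strip().upper()


class LineParams(BaseModel):
    """Tunable day-count parameters of the line algorithm and cohort rules."""

    combination_window_days: int = 30  # W
    continuation_gap_days: int = 90  # G
    default_supply_days: int = 30
    initiation_window_days: int = 90  # max mCRPC -> 1L delay
    baseline_days: int = 180
    followup_days: int = 180

    @field_validator(
        "combination_window_days",
        "continuation_gap_days",
        "default_supply_days",
        "initiation_window_days",
        "baseline_days",
        "followup_days",
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("day parameters must be positive")
        return v


class RunConfig(BaseModel):
    """Full configuration of one pipeline run."""

    diagnoses: Path | None = None
    prescriptions: Path | None = None
    labs: Path | None = None
    patients: Path | None = None
    output_dir: Path = Path("mcrpcseq_out")

    study_start: date = date(2015, 1, 1)
    study_end: date = date(2023, 6, 30)

    pc_codes: tuple[str, ...] = DEFAULT_PC_CODES
    crpc_codes: tuple[str, ...] = DEFAULT_CRPC_CODES
    met_codes: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_MET_CODES)
    )
    drug_classes: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_DRUG_CLASSES)
    )

    params: LineParams = Field(default_factory=LineParams)

    backbone_mode: Literal["collapse", "strict"] = "collapse"
    line_end_anchor: Literal["supply_end", "dispense_date"] = "supply_end"
    pre_year_basis: Literal["line_start", "index2"] = "line_start"
    on_bad_row: Literal["drop", "error"] = "drop"

    seed: int = 0

    @model_validator(mode="after")
    def _window_valid(self) -> "RunConfig":
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        return self

    def dictionary(self) -> DrugDictionary:
        backbone = DEFAULT_BACKBONE if self.backbone_mode == "collapse" else frozenset()
        return DrugDictionary(mapping=dict(self.drug_classes), backbone=backbone)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_manifest(self) -> dict:
        data = self.model_dump(mode="json")
        return data
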