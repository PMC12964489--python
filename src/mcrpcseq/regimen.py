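"""Drug classification and regimen-category labelling.

Prostate-cancer prescriptions are mapped in two steps: a drug dictionary
takes an arbitrary drug identifier to a drug *class* (the castration
backbone, first-generation antiandrogens, estrogens, the novel agents, or
``other_pc``/``non_pc``), and :func:`classify_regimen` takes the set of
classes co-prescribed in a treatment line to one of the category labels
used throughout the sequence analyses:

* ``vintage`` — ADT alone, combined androgen blockade (ADT plus a
  first-generation antiandrogen) or estrogen therapy;
* one label per novel agent (ARSI, taxane, radium-223, olaparib) for
  monotherapy on that agent;
* ``combination`` — two or more novel agents started together;
* ``others`` — prostate-cancer drugs outside the named categories;
* ``no_therapy`` — the empty set.

Continuous ADT co-prescription is treated as a backbone: by default it is
removed before labelling, so ADT + enzalutamide reads as enzalutamide
monotherapy rather than a combination.  ``backbone=frozenset()`` (strict
mode) disables the removal for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

# drug classes
ADT = "adt"
FIRST_GEN_AA = "first_gen_antiandrogen"
ESTROGEN = "estrogen"
ENZALUTAMIDE = "enzalutamide"
ABIRATERONE = "abiraterone"
APALUTAMIDE = "apalutamide"
DAROLUTAMIDE = "darolutamide"
DOCETAXEL = "docetaxel"
CABAZITAXEL = "cabazitaxel"
RADIUM223 = "radium223"
OLAPARIB = "olaparib"
OTHER_PC = "other_pc"
NON_PC = "non_pc"

#: classes that make up vintage hormone therapy
VINTAGE_CLASSES = frozenset({ADT, FIRST_GEN_AA, ESTROGEN})

#: the novel agents that define their own monotherapy stratum
NOVEL_CLASSES = frozenset(
    {
        ENZALUTAMIDE,
        ABIRATERONE,
        APALUTAMIDE,
        DAROLUTAMIDE,
        DOCETAXEL,
        CABAZITAXEL,
        RADIUM223,
        OLAPARIB,
    }
)

PC_CLASSES = VINTAGE_CLASSES | NOVEL_CLASSES | {OTHER_PC}

#: default castration backbone (removed before regimen labelling)
DEFAULT_BACKBONE = frozenset({ADT})

# regimen category labels
VINTAGE = "vintage"
COMBINATION = "combination"
OTHERS = "others"
NO_THERAPY = "no_therapy"
NO_THERAPY_OBSERVED = "no_therapy_observed"

#: all category labels a line can carry
CATEGORY_LABELS = (
    VINTAGE,
    ENZALUTAMIDE,
    ABIRATERONE,
    APALUTAMIDE,
    DAROLUTAMIDE,
    DOCETAXEL,
    CABAZITAXEL,
    RADIUM223,
    OLAPARIB,
    COMBINATION,
    OTHERS,
    NO_THERAPY,
)

# Default drug dictionary.  The study's verbatim medication list is not
# public; these defaults cover every agent named in the analysis plus the
# hormone agents routinely dispensed in Japanese practice, and the mapping
# is fully replaceable via configuration.
DEFAULT_DRUG_CLASSES: dict[str, str] = {
    # GnRH agonists / antagonists (castration backbone)
    "leuprorelin": ADT,
    "goserelin": ADT,
    "degarelix": ADT,
    "relugolix": ADT,
    # first-generation antiandrogens
    "bicalutamide": FIRST_GEN_AA,
    "flutamide": FIRST_GEN_AA,
    "chlormadinone": FIRST_GEN_AA,
    # estrogens
    "estramustine": ESTROGEN,
    "ethinylestradiol": ESTROGEN,
    "fosfestrol": ESTROGEN,
    # androgen receptor signaling inhibitors
    "enzalutamide": ENZALUTAMIDE,
    "abiraterone": ABIRATERONE,
    "apalutamide": APALUTAMIDE,
    "darolutamide": DAROLUTAMIDE,
    # taxanes
    "docetaxel": DOCETAXEL,
    "cabazitaxel": CABAZITAXEL,
    # other novel agents
    "radium223": RADIUM223,
    "olaparib": OLAPARIB,
    # other prostate-cancer drugs
    "mitoxantrone": OTHER_PC,
    "ifosfamide": OTHER_PC,
}


@dataclass(frozen=True)
class DrugDictionary:
    """Maps drug identifiers to drug classes.

    Parameters
    ----------
    mapping
        drug identifier -> drug class.  Identifiers absent from the
        mapping classify as ``non_pc``.
    backbone
        classes treated as the castration backbone.  Empty set = strict
        mode (no backbone collapsing).
    """

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_DRUG_CLASSES))
    backbone: frozenset[str] = DEFAULT_BACKBONE

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in PC_CLASSES | {NON_PC}}
        if bad:
            raise ValueError(f"unknown drug classes in dictionary: {sorted(bad)}")

    def classify(self, identifier: str) -> str:
        return self.mapping.get(identifier, NON_PC)

    def is_pc_drug(self, identifier: str) -> bool:
        return self.classify(identifier) != NON_PC

    def is_backbone(self, identifier: str) -> bool:
        return self.classify(identifier) in self.backbone

    def drugs_of_class(self, cls: str) -> list[str]:
        return sorted(d for d, c in self.mapping.items() if c == cls)


def classify_drug(identifier: str, dictionary: DrugDictionary) -> str:
    """Drug class for ``identifier``; unknown identifiers are ``non_pc``."""
    return dictionary.classify(identifier)


def classify_regimen(
    drug_classes: Iterable[str],
    backbone: frozenset[str] = DEFAULT_BACKBONE,
) -> str:
    """Regimen category for a set of co-prescribed drug classes.

    The label depends only on the set (order-free, deterministic).  Any
    subset of the vintage classes is ``vintage``; otherwise the backbone
    is removed and the remaining novel agents decide: one novel agent on
    its own is that agent's monotherapy, more than one (or a novel agent
    mixed with further non-backbone classes) is ``combination``, and sets
    left with only ``other_pc`` are ``others``.

    Raises
    ------
    ValueError
        if the set contains only ``non_pc`` classes (callers must
        pre-filter non-prostate-cancer drugs).
    """
    classes = set(drug_classes)
    if not classes:
        return NO_THERAPY
    if classes <= {NON_PC}:
        raise ValueError("regimen classification called on non-PC drug classes only")
    classes -= {NON_PC}
    if classes <= VINTAGE_CLASSES:
        return VINTAGE
    remaining = classes - backbone
    novel = remaining & NOVEL_CLASSES
    if len(novel) >= 2:
        return COMBINATION
    if len(novel) == 1:
        if remaining == novel:
            return next(iter(novel))
        return COMBINATION
    if remaining <= VINTAGE_CLASSES:
        return VINTAGE
    return OTHERS
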