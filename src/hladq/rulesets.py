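"""Versioned interpretation rule sets for HLA-based coeliac-disease testing.

Five named rule sets are registered:

``CZ2015``
    DQ2.5 or DQ8 present -> associated; everything else excluded.
``CZ2020``
    As 2015, but DQ2.2 alone maps to the intermediate "cannot be excluded"
    category (rare risk).
``CZ2022``
    DQ2.5, DQ2.2 and DQ8 are all fully predisposing; anything else excluded.
``CZ2023``
    As 2022, plus an intermediate category for genotypes carrying DQA1*05
    without any complete heterodimer (rare confirmed cases exist).
``UK_BSHI``
    The UK NEQAS/BSHI reading: only complete heterodimers count; carrying
    only DQA1*05 excludes the diagnosis.

Each rule set is an ordered, total mapping from heterodimer evidence to a
risk category plus the canonical interpretation sentence(s).  The 2023 and
UK texts are the published wording; sentences for the retired 2015/2020/2022
versions are only partially on record and are reconstructed from the printed
fragments (flagged ``reconstructed=True``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "RiskCategory",
    "Evidence",
    "Rule",
    "RuleSet",
    "RULE_SETS",
    "get_ruleset",
]


class RiskCategory(str, Enum):
    """Three-way clinical classification of a DQ genotype."""

    ASSOCIATED = "ASSOCIATED"
    NOT_EXCLUDED = "NOT_EXCLUDED"
    EXCLUDED = "EXCLUDED"


#: ordering used by the monotonicity property: adding a predisposing allele
#: may only move a genotype towards ASSOCIATED
CATEGORY_ORDER = {
    RiskCategory.EXCLUDED: 0,
    RiskCategory.NOT_EXCLUDED: 1,
    RiskCategory.ASSOCIATED: 2,
}


class Evidence(str, Enum):
    """Conditions a rule may test against a detected heterodimer set."""

    ANY_HETERODIMER = "ANY_HETERODIMER"        # DQ2.5 or DQ2.2 or DQ8
    DQ25_OR_DQ8 = "DQ25_OR_DQ8"
    DQ22 = "DQ22"
    DQA1_05_PRESENT = "DQA1_05_PRESENT"
    ALWAYS = "ALWAYS"


@dataclass(frozen=True)
class Rule:
    evidence: Evidence
    category: RiskCategory
    text: str


@dataclass(frozen=True)
class RuleSet:
    """A named, versioned, ordered and total set of interpretation rules.

    Rules are evaluated top-down; the first whose evidence holds wins.  The
    final rule always has ``Evidence.ALWAYS``, which makes the mapping total
    over every possible heterodimer set.
    """

    name: str
    year: int
    rules: tuple[Rule, ...]
    reconstructed: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.rules or self.rules[-1].evidence is not Evidence.ALWAYS:
            raise ValueError(f"rule set {self.name} is not total")


_TEXT_2023_ASSOCIATED = (
    "Detected HLA genotype is associated with the risk of CD. "
    "This result cannot be separately interpreted as a confirmation of CD "
    "due to low specificity."
)
_TEXT_2023_RARE = (
    "Detected HLA genotype is associated with the occurrence of coeliac "
    "disease in rare cases. The diagnosis of CD cannot be excluded."
)
_TEXT_2023_EXCLUDED = (
    "Detected HLA genotype is not associated with the risk of CD. "
    "The result excludes this diagnosis with high probability."
)

# reconstructed wording for the retired versions (fragments only are on
# record; see the rule-set metadata flag)
_TEXT_LEGACY_ASSOCIATED = (
    "Detected HLA genotype is associated with predisposition to coeliac "
    "disease."
)
_TEXT_LEGACY_EXCLUDED = (
    "Detected HLA genotype is not associated with coeliac disease; the "
    "result excludes this diagnosis with high probability."
)
_TEXT_2020_DQ22 = (
    "Detected HLA genotype (DQ2.2) is associated with a rare risk of CD, "
    "the diagnosis could not be excluded."
)
_TEXT_UK_EXCLUDED = (
    "Detected HLA genotype does not encode the DQ2.5, DQ2.2 or DQ8 "
    "heterodimers and excludes a diagnosis of coeliac disease."
)

RULE_SETS: dict[str, RuleSet] = {
    "CZ2015": RuleSet(
        name="CZ2015",
        year=2015,
        reconstructed=True,
        description="DQ2.5 and DQ8 predisposing (ESPGHAN-aligned).",
        rules=(
            Rule(Evidence.DQ25_OR_DQ8, RiskCategory.ASSOCIATED,
                 _TEXT_LEGACY_ASSOCIATED),
            Rule(Evidence.ALWAYS, RiskCategory.EXCLUDED,
                 _TEXT_LEGACY_EXCLUDED),
        ),
    ),
    "CZ2020": RuleSet(
        name="CZ2020",
        year=2020,
        reconstructed=True,
        description="Adds DQ2.2 as a rare-risk (not-excluded) genotype.",
        rules=(
            Rule(Evidence.DQ25_OR_DQ8, RiskCategory.ASSOCIATED,
                 _TEXT_LEGACY_ASSOCIATED),
            Rule(Evidence.DQ22, RiskCategory.NOT_EXCLUDED, _TEXT_2020_DQ22),
            Rule(Evidence.ALWAYS, RiskCategory.EXCLUDED,
                 _TEXT_LEGACY_EXCLUDED),
        ),
    ),
    "CZ2022": RuleSet(
        name="CZ2022",
        year=2022,
        reconstructed=True,
        description="DQ2.5, DQ2.2 and DQ8 all fully predisposing; "
                    "association strength not graded.",
        rules=(
            Rule(Evidence.ANY_HETERODIMER, RiskCategory.ASSOCIATED,
                 _TEXT_LEGACY_ASSOCIATED),
            Rule(Evidence.ALWAYS, RiskCategory.EXCLUDED,
                 _TEXT_LEGACY_EXCLUDED),
        ),
    ),
    "CZ2023": RuleSet(
        name="CZ2023",
        year=2023,
        description="Current three-category recommendation: heterodimers "
                    "associated; DQA1*05 without a heterodimer not excluded; "
                    "everything else excluded.",
        rules=(
            Rule(Evidence.ANY_HETERODIMER, RiskCategory.ASSOCIATED,
                 _TEXT_2023_ASSOCIATED),
            Rule(Evidence.DQA1_05_PRESENT, RiskCategory.NOT_EXCLUDED,
                 _TEXT_2023_RARE),
            Rule(Evidence.ALWAYS, RiskCategory.EXCLUDED,
                 _TEXT_2023_EXCLUDED),
        ),
    ),
    "UK_BSHI": RuleSet(
        name="UK_BSHI",
        year=2023,
        description="UK NEQAS/BSHI reading: DQA1*05 alone excludes CD.",
        rules=(
            Rule(Evidence.ANY_HETERODIMER, RiskCategory.ASSOCIATED,
                 _TEXT_2023_ASSOCIATED),
            Rule(Evidence.ALWAYS, RiskCategory.EXCLUDED, _TEXT_UK_EXCLUDED),
        ),
    ),
}


def get_ruleset(name: str) -> RuleSet:
    """Look up a rule set by name; raises ``KeyError`` with choices listed."""
    try:
        return RULE_SETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown rule set {name!r}; choose from {sorted(RULE_SETS)}"
        ) from None
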