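"""Heterodimer detection and clinical classification of DQ genotypes.

The coeliac-predisposing HLA-DQ molecules are defined by allele co-presence
in the unphased DQA1/DQB1 genotype:

* DQ2.5 — DQB1*02 together with DQA1*05
* DQ2.2 — DQB1*02 together with DQA1*02, *without* DQA1*05
* DQ8   — DQB1*03:02 together with DQA1*03

Detection is deliberately phase-agnostic: trans combinations count, because
the clinical recommendation defines the heterodimers as allele co-presence,
not as cis haplotypes.  Classification maps the detected heterodimer set to
one of three risk categories under a named rule set (see
:mod:`hladq.rulesets`), and :func:`build_report` assembles the three
elements every clinical report must carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nomenclature import (
    AlleleGroup,
    HLAAllele,
    Locus,
    format_allele,
    matches_group,
    parse_allele,
)
from .rulesets import Evidence, RiskCategory, RuleSet, get_ruleset

__all__ = [
    "DQGenotype",
    "HeterodimerSet",
    "InterpretationResult",
    "ClinicalReport",
    "InsufficientResolutionError",
    "REQUIRED_GROUPS",
    "detect_heterodimers",
    "classify",
    "interpret_sample",
    "build_report",
]

# the five allele groups whose correct detection the proficiency scheme
# requires; all interpretation logic is expressed over these
GROUP_DQA1_02 = AlleleGroup(Locus.DQA1, ("02",))
GROUP_DQA1_03 = AlleleGroup(Locus.DQA1, ("03",))
GROUP_DQA1_05 = AlleleGroup(Locus.DQA1, ("05",))
GROUP_DQB1_02 = AlleleGroup(Locus.DQB1, ("02",))
GROUP_DQB1_0302 = AlleleGroup(Locus.DQB1, ("03", "02"))

REQUIRED_GROUPS: tuple[AlleleGroup, ...] = (
    GROUP_DQA1_02,
    GROUP_DQA1_03,
    GROUP_DQA1_05,
    GROUP_DQB1_02,
    GROUP_DQB1_0302,
)


class InsufficientResolutionError(ValueError):
    """Genotype resolution too low to apply the rules (bare DQB1*03)."""


@dataclass(frozen=True)
class DQGenotype:
    """Unphased DQA1/DQB1 genotype of one sample (two alleles per locus)."""

    sample_id: str
    dqa1: tuple[HLAAllele, HLAAllele]
    dqb1: tuple[HLAAllele, HLAAllele]
    dqa1_homozygous: bool = False
    dqb1_homozygous: bool = False

    def __post_init__(self) -> None:
        for a in self.dqa1:
            if a.locus is not Locus.DQA1:
                raise ValueError(f"{format_allele(a)} is not a DQA1 allele")
        for b in self.dqb1:
            if b.locus is not Locus.DQB1:
                raise ValueError(f"{format_allele(b)} is not a DQB1 allele")

    @classmethod
    def from_strings(
        cls,
        sample_id: str,
        dqa1_1: str,
        dqa1_2: str,
        dqb1_1: str,
        dqb1_2: str,
    ) -> "DQGenotype":
        """Build from four allele strings; a blank second allele at a locus
        marks the sample homozygous and duplicates the first allele."""
        a1 = parse_allele(dqa1_1)
        a_hom = not dqa1_2 or not dqa1_2.strip()
        a2 = a1 if a_hom else parse_allele(dqa1_2)
        b1 = parse_allele(dqb1_1)
        b_hom = not dqb1_2 or not dqb1_2.strip()
        b2 = b1 if b_hom else parse_allele(dqb1_2)
        return cls(
            sample_id=sample_id,
            dqa1=(a1, a2),
            dqb1=(b1, b2),
            dqa1_homozygous=a_hom,
            dqb1_homozygous=b_hom,
        )

    @property
    def alleles(self) -> tuple[HLAAllele, ...]:
        return (*self.dqa1, *self.dqb1)

    def group_presence(self) -> dict[str, bool]:
        """Presence/absence of each of the five required groups."""
        return {
            str(g): any(matches_group(a, g) for a in self.alleles)
            for g in REQUIRED_GROUPS
        }


@dataclass(frozen=True)
class HeterodimerSet:
    """Which predisposing DQ heterodimers an unphased genotype can form.

    ``dq22`` honours the "without DQA1*05" qualifier: if DQA1*05 is present
    alongside DQA1*02 and DQB1*02, DQ2.5 is reported and DQ2.2 is not.
    """

    dq25: bool = False
    dq22: bool = False
    dq8: bool = False
    dqa1_05_present: bool = False

    def __post_init__(self) -> None:
        if self.dq22 and self.dqa1_05_present:
            raise ValueError("DQ2.2 is defined as DQB1*02 + DQA1*02 without "
                             "DQA1*05; dq22 and dqa1_05_present conflict")
        if self.dq25 and not self.dqa1_05_present:
            raise ValueError("DQ2.5 requires DQA1*05")

    @property
    def any_heterodimer(self) -> bool:
        return self.dq25 or self.dq22 or self.dq8

    def as_dict(self) -> dict[str, bool]:
        return {"DQ2.5": self.dq25, "DQ2.2": self.dq22, "DQ8": self.dq8}


@dataclass(frozen=True)
class InterpretationResult:
    sample_id: str
    heterodimers: HeterodimerSet
    category: RiskCategory
    ruleset_name: str
    interpretation_text: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClinicalReport:
    """The three elements a complete coeliac HLA report must carry:
    detected predisposing alleles/groups, presence or absence of the
    serological equivalents DQ2.5/DQ2.2/DQ8, and the clinical
    interpretation sentence(s)."""

    sample_id: str
    predisposing_alleles: tuple[str, ...]
    heterodimers: dict[str, bool]
    category: RiskCategory
    interpretation_text: str
    ruleset_name: str
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "predisposing_alleles": list(self.predisposing_alleles),
            "serological_equivalents": {
                name: ("present" if present else "absent")
                for name, present in self.heterodimers.items()
            },
            "category": self.category.value,
            "interpretation": self.interpretation_text,
            "ruleset": self.ruleset_name,
            "warnings": list(self.warnings),
        }

    def to_text(self) -> str:
        alleles = ", ".join(self.predisposing_alleles) or "none detected"
        equivalents = "; ".join(
            f"{name}: {'present' if p else 'absent'}"
            for name, p in self.heterodimers.items()
        )
        lines = [
            f"Sample {self.sample_id} (rule set {self.ruleset_name})",
            f"  Predisposing alleles/groups: {alleles}",
            f"  Serological equivalents: {equivalents}",
            f"  Interpretation: {self.interpretation_text}",
        ]
        for w in self.warnings:
            lines.append(f"  Warning: {w}")
        return "\n".join(lines)


def _check_resolution(g: DQGenotype) -> None:
    for b in g.dqb1:
        if b.fields[0] == "03" and len(b.fields) < 2:
            raise InsufficientResolutionError(
                f"sample {g.sample_id}: {format_allele(b)} is reported at "
                "one-field resolution; DQB1*03 cannot be interpreted "
                "(DQB1*03:02 predisposes, DQB1*03:03 does not)"
            )


def detect_heterodimers(g: DQGenotype) -> HeterodimerSet:
    """Detect DQ2.5/DQ2.2/DQ8 in an unphased genotype.

    Raises :class:`InsufficientResolutionError` if any DQB1 allele in group
    03 lacks a second field, since DQB1*03:02 (predisposing) cannot then be
    told apart from DQB1*03:03 (neutral).
    """
    _check_resolution(g)
    a = g.dqa1
    b = g.dqb1
    a02 = any(matches_group(x, GROUP_DQA1_02) for x in a)
    a03 = any(matches_group(x, GROUP_DQA1_03) for x in a)
    a05 = any(matches_group(x, GROUP_DQA1_05) for x in a)
    b02 = any(matches_group(x, GROUP_DQB1_02) for x in b)
    b0302 = any(matches_group(x, GROUP_DQB1_0302) for x in b)
    return HeterodimerSet(
        dq25=a05 and b02,
        dq22=a02 and b02 and not a05,
        dq8=a03 and b0302,
        dqa1_05_present=a05,
    )


def _evidence_holds(
    ev: Evidence, h: HeterodimerSet, other_predisposing: bool, strict: bool
) -> bool:
    if ev is Evidence.ANY_HETERODIMER:
        return h.any_heterodimer
    if ev is Evidence.DQ25_OR_DQ8:
        return h.dq25 or h.dq8
    if ev is Evidence.DQ22:
        return h.dq22
    if ev is Evidence.DQA1_05_PRESENT:
        if strict:
            return h.dqa1_05_present and not other_predisposing
        return h.dqa1_05_present
    return True  # Evidence.ALWAYS


def classify(
    h: HeterodimerSet,
    ruleset: RuleSet | str,
    *,
    sample_id: str = "",
    other_predisposing_present: bool = False,
    strict_dqa1_05: bool = False,
    warnings: tuple[str, ...] = (),
) -> InterpretationResult:
    """Map a heterodimer set to a risk category under a named rule set.

    ``other_predisposing_present`` signals that a required predisposing
    group besides DQA1*05 is present without completing a heterodimer
    (e.g. a lone DQB1*03:02).  Under the default reading this does not
    block the intermediate "cannot be excluded" category; with
    ``strict_dqa1_05=True`` the intermediate category requires DQA1*05
    strictly alone and such genotypes fall through to excluded.  When the
    two readings diverge a warning is attached either way.
    """
    rs = get_ruleset(ruleset) if isinstance(ruleset, str) else ruleset
    warn = list(warnings)
    for rule in rs.rules:
        if _evidence_holds(rule.evidence, h, other_predisposing_present,
                           strict_dqa1_05):
            if (
                rule.evidence is Evidence.DQA1_05_PRESENT
                and other_predisposing_present
                and not strict_dqa1_05
            ):
                warn.append(
                    "DQA1*05 coexists with another lone predisposing allele; "
                    "a strict reading of the 2023 wording ('solely') would "
                    "classify this genotype as excluded"
                )
            return InterpretationResult(
                sample_id=sample_id,
                heterodimers=h,
                category=rule.category,
                ruleset_name=rs.name,
                interpretation_text=rule.text,
                warnings=tuple(warn),
            )
    raise AssertionError(f"rule set {rs.name} is not total")  # pragma: no cover


def _other_predisposing_present(g: DQGenotype, h: HeterodimerSet) -> bool:
    """A required group other than DQA1*05 present without any heterodimer."""
    if h.any_heterodimer:
        return False
    presence = g.group_presence()
    return any(
        present
        for group, present in presence.items()
        if group != str(GROUP_DQA1_05)
    )


def interpret_sample(
    g: DQGenotype,
    ruleset: RuleSet | str = "CZ2023",
    *,
    strict_dqa1_05: bool = False,
) -> InterpretationResult:
    """Detect heterodimers and classify one genotype in a single call."""
    warnings: list[str] = []
    if g.dqa1_homozygous or g.dqb1_homozygous:
        loci = [
            name
            for name, hom in (("DQA1", g.dqa1_homozygous),
                              ("DQB1", g.dqb1_homozygous))
            if hom
        ]
        warnings.append(
            f"{' and '.join(loci)} reported with a single allele; "
            "treated as homozygous"
        )
    h = detect_heterodimers(g)
    return classify(
        h,
        ruleset,
        sample_id=g.sample_id,
        other_predisposing_present=_other_predisposing_present(g, h),
        strict_dqa1_05=strict_dqa1_05,
        warnings=tuple(warnings),
    )


def build_report(r: InterpretationResult, g: DQGenotype) -> ClinicalReport:
    """Assemble the clinical report for an interpreted sample.

    The predisposing-allele list contains only the genotype's alleles that
    match one of the five required groups (DQA1*02/*03/*05, DQB1*02,
    DQB1*03:02), formatted canonically and de-duplicated.
    """
    seen: list[str] = []
    for allele in g.alleles:
        if any(matches_group(allele, grp) for grp in REQUIRED_GROUPS):
            name = format_allele(allele)
            if name not in seen:
                seen.append(name)
    return ClinicalReport(
        sample_id=g.sample_id,
        predisposing_alleles=tuple(seen),
        heterodimers=r.heterodimers.as_dict(),
        category=r.category,
        interpretation_text=r.interpretation_text,
        ruleset_name=r.ruleset_name,
        warnings=r.warnings,
    )
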