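"""External proficiency testing: panel simulation, error injection, scoring.

An EPT round distributes blinded DNA samples with reference DQA1/DQB1
genotypes to participating laboratories; each lab returns its genotype
calls and a clinical interpretation.  This module simulates such rounds:

* :func:`generate_panel` draws reference genotypes from a haplotype
  frequency table under random mating (two haplotypes per sample), with
  optional enrichment for rare haplotypes — samples with uncommon linkage
  are exactly the ones laboratories tend to get wrong.
* :func:`apply_error_model` corrupts a lab's calls with configurable
  miscall and dropout rules.  The classic, recurrent real-world error is
  reporting DQB1*03:02 (predisposing) in a carrier of DQB1*03:03
  (neutral); the interpretation is recomputed from the corrupted genotype,
  so a genotyping miscall propagates into an interpretation error.
* :func:`score_submission` judges genotype correctness only on the five
  required groups (DQA1*02, *03, *05; DQB1*02; DQB1*03:02) — extra detail
  is never penalised — and interpretation correctness as category match.
* :func:`aggregate_cohort` produces the per-method lab counts and error
  percentages of the familiar EPT summary table; a lab counts as erroneous
  if any of its samples has a genotype or interpretation discrepancy, and
  a lab appears once per method it used.

The per-sample binary scoring scheme (genotype correct yes/no,
interpretation correct yes/no) is this package's own definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interpretation import (
    REQUIRED_GROUPS,
    DQGenotype,
    interpret_sample,
)
from .nomenclature import (
    AlleleGroup,
    HLAAllele,
    Locus,
    format_allele,
    matches_group,
    parse_allele,
)
from .population import HaplotypeFrequencyTable
from .rounding import round_half_up
from .rulesets import RiskCategory, RuleSet, get_ruleset

__all__ = [
    "Method",
    "ReferenceSample",
    "SubmissionEntry",
    "Submission",
    "MiscallRule",
    "DropoutRule",
    "ErrorModel",
    "SampleScore",
    "MethodSummary",
    "CohortSummary",
    "generate_panel",
    "empirical_carrier_fraction",
    "apply_error_model",
    "score_submission",
    "aggregate_cohort",
    "default_error_model",
    "panel_to_frame",
    "panel_from_frame",
    "submissions_to_frame",
    "submissions_from_frame",
    "scores_to_frame",
]

#: threshold below which a haplotype counts as rare (population frequency)
RARE_FREQUENCY_THRESHOLD = 0.05


class Method(str, enum.Enum):
    """DNA typing techniques reported by participating laboratories."""

    PCR_SSP = "PCR-SSP"
    RT_PCR = "RT-PCR"
    SSO = "SSO"
    SANGER = "SANGER"
    NGS = "NGS"


@dataclass(frozen=True)
class ReferenceSample:
    sample_id: str
    true_genotype: DQGenotype
    true_category: RiskCategory
    rare_haplotype_flag: bool = False
    #: labels of the two haplotypes actually drawn (simulation provenance;
    #: unphased genotypes alone cannot recover them once trans combinations
    #: form a heterodimer)
    haplotype_labels: tuple[str, str] = ("", "")


@dataclass(frozen=True)
class SubmissionEntry:
    sample_id: str
    genotype: DQGenotype | None          # None = sample not answered
    category: RiskCategory | None


@dataclass(frozen=True)
class Submission:
    lab_id: str
    method: Method
    entries: tuple[SubmissionEntry, ...]

    def entry_for(self, sample_id: str) -> SubmissionEntry | None:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        return None


@dataclass(frozen=True)
class MiscallRule:
    """Replace an allele matching ``target`` by ``reported`` with prob. p."""

    target: AlleleGroup
    reported: HLAAllele
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("miscall probability outside [0, 1]")


@dataclass(frozen=True)
class DropoutRule:
    """Miss an allele matching ``target`` with prob. p (the other allele at
    the locus is then reported twice, as an apparent homozygote)."""

    target: AlleleGroup
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("dropout probability outside [0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    miscalls: tuple[MiscallRule, ...] = ()
    dropouts: tuple[DropoutRule, ...] = ()
    seed: int | None = None


def default_error_model(
    miscall_p: float = 0.1, dropout_p: float = 0.0, seed: int | None = None
) -> ErrorModel:
    """The empirically dominant error modes: DQB1*03:03 miscalled as the
    predisposing DQB1*03:02, and (optionally) DQB1*03:02 dropout."""
    miscalls = (
        MiscallRule(
            target=AlleleGroup(Locus.DQB1, ("03", "03")),
            reported=parse_allele("DQB1*03:02"),
            probability=miscall_p,
        ),
    )
    dropouts = (
        (DropoutRule(AlleleGroup(Locus.DQB1, ("03", "02")), dropout_p),)
        if dropout_p > 0
        else ()
    )
    return ErrorModel(miscalls=miscalls, dropouts=dropouts, seed=seed)


def _group_to_allele(g: AlleleGroup) -> HLAAllele:
    # complete a one-field group to a representative two-field allele
    fields = g.fields if len(g.fields) == 2 else (g.fields[0], "01")
    return HLAAllele(locus=g.locus, fields=fields)


def generate_panel(
    table: HaplotypeFrequencyTable,
    n_samples: int,
    rare_enrichment: float = 0.0,
    seed: int | np.random.Generator | None = None,
    ruleset: RuleSet | str = "CZ2023",
    rare_threshold: float = RARE_FREQUENCY_THRESHOLD,
) -> list[ReferenceSample]:
    """Draw a reference panel of unphased two-field genotypes.

    Each sample receives two haplotypes drawn independently from the
    (renormalised) table — Hardy-Weinberg random mating.  With probability
    ``rare_enrichment`` a sample instead receives its first haplotype
    uniformly from the rare set (frequency below ``rare_threshold``),
    mimicking the deliberate inclusion of difficult samples in real EPT
    rounds.  ``rare_haplotype_flag`` marks every sample that ended up
    carrying a rare haplotype, however it was drawn.
    """
    if not table.entries:
        raise ValueError("empty haplotype table")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= rare_enrichment <= 1.0:
        raise ValueError("rare_enrichment outside [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    freqs = np.array([e.frequency for e in table.entries], dtype=float)
    if freqs.sum() <= 0:
        raise ValueError("haplotype frequencies sum to zero")
    probs = freqs / freqs.sum()
    rare_idx = np.flatnonzero(freqs < rare_threshold)

    samples: list[ReferenceSample] = []
    for i in range(n_samples):
        if rare_idx.size and rng.random() < rare_enrichment:
            h1 = int(rng.choice(rare_idx))
        else:
            h1 = int(rng.choice(len(probs), p=probs))
        h2 = int(rng.choice(len(probs), p=probs))
        e1, e2 = table.entries[h1], table.entries[h2]
        genotype = DQGenotype(
            sample_id=f"S{i + 1:03d}",
            dqa1=(_group_to_allele(e1.dqa1), _group_to_allele(e2.dqa1)),
            dqb1=(_group_to_allele(e1.dqb1), _group_to_allele(e2.dqb1)),
        )
        result = interpret_sample(genotype, ruleset)
        samples.append(
            ReferenceSample(
                sample_id=genotype.sample_id,
                true_genotype=genotype,
                true_category=result.category,
                rare_haplotype_flag=bool(
                    freqs[h1] < rare_threshold or freqs[h2] < rare_threshold
                ),
                haplotype_labels=(e1.label, e2.label),
            )
        )
    return samples


def empirical_carrier_fraction(
    panel: Sequence[ReferenceSample], table: HaplotypeFrequencyTable
) -> float:
    """Fraction of panel samples drawn with >=1 predisposing haplotype.

    Uses the recorded haplotype labels, so trans combinations that happen
    to form a heterodimer do not inflate the count; under random mating
    this converges to ``carrier_frequency_hwe(total predisposing freq)``.
    """
    predisposing = {e.label for e in table.entries if e.predisposing}
    if not panel:
        raise ValueError("empty panel")
    return sum(
        any(lbl in predisposing for lbl in ref.haplotype_labels)
        for ref in panel
    ) / len(panel)


def _corrupt_locus(
    alleles: tuple[HLAAllele, HLAAllele],
    locus: Locus,
    model: ErrorModel,
    rng: np.random.Generator,
) -> tuple[HLAAllele, HLAAllele]:
    out = list(alleles)
    for slot in range(2):
        for rule in model.miscalls:
            if rule.target.locus is locus and matches_group(out[slot], rule.target):
                if rng.random() < rule.probability:
                    out[slot] = rule.reported
                    break
        for rule in model.dropouts:
            if rule.target.locus is locus and matches_group(out[slot], rule.target):
                if rng.random() < rule.probability:
                    out[slot] = out[1 - slot]
                    break
    return (out[0], out[1])


def apply_error_model(
    panel: Sequence[ReferenceSample],
    model: ErrorModel,
    lab_id: str = "LAB1",
    method: Method = Method.PCR_SSP,
    ruleset: RuleSet | str = "CZ2023",
    seed: int | np.random.Generator | None = None,
) -> Submission:
    """Simulate one laboratory's submission for a panel.

    Every miscall/dropout rule is applied independently per sample per
    matching allele with its stated probability.  The reported
    interpretation is recomputed from the (possibly corrupted) genotype, so
    a genotyping error carries through to the clinical interpretation
    exactly as it does in a real laboratory report.
    """
    if seed is None:
        seed = model.seed
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    entries: list[SubmissionEntry] = []
    for ref in panel:
        g = ref.true_genotype
        dqa1 = _corrupt_locus(g.dqa1, Locus.DQA1, model, rng)
        dqb1 = _corrupt_locus(g.dqb1, Locus.DQB1, model, rng)
        reported = replace(g, dqa1=dqa1, dqb1=dqb1)
        category = interpret_sample(reported, ruleset).category
        entries.append(
            SubmissionEntry(
                sample_id=ref.sample_id, genotype=reported, category=category
            )
        )
    return Submission(lab_id=lab_id, method=method, entries=tuple(entries))


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    genotype_correct: bool
    interpretation_correct: bool
    #: (locus, required group, expected presence, reported presence)
    discrepancies: tuple[tuple[str, str, bool, bool], ...] = ()

    @property
    def fully_correct(self) -> bool:
        return self.genotype_correct and self.interpretation_correct


def _presence_vector(g: DQGenotype) -> dict[AlleleGroup, bool]:
    return {
        grp: any(matches_group(a, grp) for a in g.alleles)
        for grp in REQUIRED_GROUPS
    }


def score_submission(
    panel: Sequence[ReferenceSample],
    submission: Submission,
    ruleset: RuleSet | str = "CZ2023",
) -> list[SampleScore]:
    """Score one submission against the reference panel.

    Genotype correctness compares only the presence/absence of the five
    required groups, so DQA1*05:05 reported where the truth is DQA1*05:01
    is correct (same group), while DQB1*03:02 reported in a DQB1*03:03
    carrier is a discrepancy.  A missing sample scores false on both
    counts.  Sample ids in the submission that are not on the panel raise.
    """
    rs = get_ruleset(ruleset) if isinstance(ruleset, str) else ruleset
    panel_ids = {ref.sample_id for ref in panel}
    for e in submission.entries:
        if e.sample_id not in panel_ids:
            raise ValueError(
                f"submission {submission.lab_id} reports unknown sample "
                f"{e.sample_id!r}"
            )
    scores: list[SampleScore] = []
    for ref in panel:
        entry = submission.entry_for(ref.sample_id)
        true_category = interpret_sample(ref.true_genotype, rs).category
        if entry is None or entry.genotype is None:
            scores.append(
                SampleScore(
                    sample_id=ref.sample_id,
                    genotype_correct=False,
                    interpretation_correct=False,
                    discrepancies=(("-", "missing", True, False),),
                )
            )
            continue
        expected = _presence_vector(ref.true_genotype)
        observed = _presence_vector(entry.genotype)
        discrepancies = tuple(
            (grp.locus.value, str(grp), expected[grp], observed[grp])
            for grp in REQUIRED_GROUPS
            if expected[grp] != observed[grp]
        )
        interp_ok = entry.category is not None and entry.category == true_category
        scores.append(
            SampleScore(
                sample_id=ref.sample_id,
                genotype_correct=not discrepancies,
                interpretation_correct=interp_ok,
                discrepancies=discrepancies,
            )
        )
    return scores


@dataclass(frozen=True)
class MethodSummary:
    method: Method
    labs_n: int
    labs_with_error_n: int
    genotype_error_labs_n: int = 0
    interpretation_error_labs_n: int = 0

    @property
    def error_rate(self) -> float:
        """Percentage of labs with >=1 discrepancy, one-decimal half-up."""
        if self.labs_n == 0:
            return float("nan")
        return round_half_up(100.0 * self.labs_with_error_n / self.labs_n, 1)


@dataclass(frozen=True)
class CohortSummary:
    per_method: tuple[MethodSummary, ...] = field(default_factory=tuple)

    def for_method(self, method: Method) -> MethodSummary | None:
        for m in self.per_method:
            if m.method is method:
                return m
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": [m.method.value for m in self.per_method],
                "labs_n": [m.labs_n for m in self.per_method],
                "labs_with_error_n": [
                    m.labs_with_error_n for m in self.per_method
                ],
                "error_rate_percent": [m.error_rate for m in self.per_method],
                "genotype_error_labs_n": [
                    m.genotype_error_labs_n for m in self.per_method
                ],
                "interpretation_error_labs_n": [
                    m.interpretation_error_labs_n for m in self.per_method
                ],
            }
        )

    def to_dict(self) -> dict:
        return {
            m.method.value: {
                "labs_n": m.labs_n,
                "labs_with_error_n": m.labs_with_error_n,
                "error_rate_percent": m.error_rate,
                "genotype_error_labs_n": m.genotype_error_labs_n,
                "interpretation_error_labs_n": m.interpretation_error_labs_n,
            }
            for m in self.per_method
        }


def aggregate_cohort(
    scores: Mapping[tuple[str, Method], Sequence[SampleScore]],
) -> CohortSummary:
    """Aggregate per-lab scores into the per-method EPT summary table.

    Keys are ``(lab_id, method)`` pairs: a lab that used two methods
    appears under both, matching how real rounds are counted.  A lab is
    erroneous if any of its samples has a genotype or an interpretation
    discrepancy; the two sub-counts are also reported.
    """
    if not scores:
        raise ValueError("no submissions to aggregate")
    methods: dict[Method, dict[str, int]] = {}
    for (lab_id, method), lab_scores in scores.items():
        agg = methods.setdefault(
            method, {"labs": 0, "err": 0, "gerr": 0, "ierr": 0}
        )
        agg["labs"] += 1
        any_g = any(not s.genotype_correct for s in lab_scores)
        any_i = any(not s.interpretation_correct for s in lab_scores)
        agg["err"] += int(any_g or any_i)
        agg["gerr"] += int(any_g)
        agg["ierr"] += int(any_i)
    order = list(Method)
    per_method = tuple(
        MethodSummary(
            method=m,
            labs_n=methods[m]["labs"],
            labs_with_error_n=methods[m]["err"],
            genotype_error_labs_n=methods[m]["gerr"],
            interpretation_error_labs_n=methods[m]["ierr"],
        )
        for m in order
        if m in methods
    )
    return CohortSummary(per_method=per_method)


# ---------------------------------------------------------------------------
# delimited-text round trips (panels, submissions, scores)

def panel_to_frame(panel: Sequence[ReferenceSample]) -> pd.DataFrame:
    rows = []
    for ref in panel:
        g = ref.true_genotype
        rows.append(
            {
                "sample_id": ref.sample_id,
                "dqa1_1": format_allele(g.dqa1[0]),
                "dqa1_2": format_allele(g.dqa1[1]),
                "dqb1_1": format_allele(g.dqb1[0]),
                "dqb1_2": format_allele(g.dqb1[1]),
                "category": ref.true_category.value,
                "rare_haplotype": ref.rare_haplotype_flag,
            }
        )
    return pd.DataFrame(rows)


def panel_from_frame(
    df: pd.DataFrame, ruleset: RuleSet | str = "CZ2023"
) -> list[ReferenceSample]:
    panel = []
    for row in df.itertuples(index=False):
        g = DQGenotype.from_strings(
            str(row.sample_id), row.dqa1_1, row.dqa1_2, row.dqb1_1, row.dqb1_2
        )
        panel.append(
            ReferenceSample(
                sample_id=g.sample_id,
                true_genotype=g,
                true_category=interpret_sample(g, ruleset).category,
                rare_haplotype_flag=bool(getattr(row, "rare_haplotype", False)),
            )
        )
    return panel


def submissions_to_frame(submissions: Iterable[Submission]) -> pd.DataFrame:
    rows = []
    for sub in submissions:
        for e in sub.entries:
            g = e.genotype
            rows.append(
                {
                    "lab_id": sub.lab_id,
                    "method": sub.method.value,
                    "sample_id": e.sample_id,
                    "dqa1_1": format_allele(g.dqa1[0]) if g else "",
                    "dqa1_2": format_allele(g.dqa1[1]) if g else "",
                    "dqb1_1": format_allele(g.dqb1[0]) if g else "",
                    "dqb1_2": format_allele(g.dqb1[1]) if g else "",
                    "category": e.category.value if e.category else "",
                }
            )
    return pd.DataFrame(rows)


def submissions_from_frame(df: pd.DataFrame) -> list[Submission]:
    subs: list[Submission] = []
    for (lab_id, method), chunk in df.groupby(["lab_id", "method"], sort=True):
        entries = []
        for row in chunk.itertuples(index=False):
            if not str(row.dqa1_1).strip() or str(row.dqa1_1) == "nan":
                genotype, category = None, None
            else:
                genotype = DQGenotype.from_strings(
                    str(row.sample_id),
                    row.dqa1_1,
                    "" if pd.isna(row.dqa1_2) else row.dqa1_2,
                    row.dqb1_1,
                    "" if pd.isna(row.dqb1_2) else row.dqb1_2,
                )
                category = (
                    RiskCategory(row.category)
                    if isinstance(row.category, str) and row.category
                    else None
                )
            entries.append(
                SubmissionEntry(
                    sample_id=str(row.sample_id),
                    genotype=genotype,
                    category=category,
                )
            )
        subs.append(
            Submission(
                lab_id=str(lab_id),
                method=Method(method),
                entries=tuple(entries),
            )
        )
    return subs


def scores_to_frame(
    scores: Mapping[tuple[str, Method], Sequence[SampleScore]],
) -> pd.DataFrame:
    rows = []
    for (lab_id, method), lab_scores in scores.items():
        for s in lab_scores:
            rows.append(
                {
                    "lab_id": lab_id,
                    "method": method.value,
                    "sample_id": s.sample_id,
                    "genotype_correct": s.genotype_correct,
                    "interpretation_correct": s.interpretation_correct,
                    "discrepancies": "; ".join(
                        f"{grp}: expected "
                        f"{'present' if exp else 'absent'}, reported "
                        f"{'present' if obs else 'absent'}"
                        for _, grp, exp, obs in s.discrepancies
                    ),
                }
            )
    return pd.DataFrame(rows)
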