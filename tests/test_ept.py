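"""Panel simulation, error injection, scoring and cohort aggregation."""

import numpy as np
import pytest

from hladq import (
    DQGenotype,
    DropoutRule,
    Method,
    MiscallRule,
    ReferenceSample,
    RiskCategory,
    Submission,
    SubmissionEntry,
    aggregate_cohort,
    apply_error_model,
    carrier_frequency_hwe,
    default_error_model,
    empirical_carrier_fraction,
    generate_panel,
    interpret_sample,
    score_submission,
    total_predisposing_frequency,
)
from hladq.ept import (
    ErrorModel,
    panel_from_frame,
    panel_to_frame,
    submissions_from_frame,
    submissions_to_frame,
)
from hladq.nomenclature import AlleleGroup, Locus, parse_allele

from conftest import make_genotype


def _reference(a1, a2, b1, b2, sample_id="S001"):
    g = make_genotype(a1, a2, b1, b2, sample_id=sample_id)
    return ReferenceSample(
        sample_id=sample_id,
        true_genotype=g,
        true_category=interpret_sample(g).category,
    )


def _perfect_submission(panel, lab_id="L01", method=Method.PCR_SSP):
    return apply_error_model(
        panel, ErrorModel(), lab_id=lab_id, method=method, seed=0
    )


# ---------------------------------------------------------------------------
# panel generation


def test_generate_panel_deterministic(czech_table):
    p1 = generate_panel(czech_table, 50, seed=7)
    p2 = generate_panel(czech_table, 50, seed=7)
    assert p1 == p2
    p3 = generate_panel(czech_table, 50, seed=8)
    assert p1 != p3


def test_generate_panel_round_size(czech_table):
    panel = generate_panel(czech_table, 5, seed=1)
    assert len(panel) == 5
    for ref in panel:
        # two-field resolution at both loci
        for a in ref.true_genotype.alleles:
            assert len(a.fields) == 2
        assert ref.true_category is interpret_sample(ref.true_genotype).category


def test_generate_panel_validation(czech_table):
    from hladq import HaplotypeFrequencyTable

    with pytest.raises(ValueError):
        generate_panel(HaplotypeFrequencyTable(entries=()), 5, seed=1)
    with pytest.raises(ValueError):
        generate_panel(czech_table, 0, seed=1)
    with pytest.raises(ValueError):
        generate_panel(czech_table, 5, rare_enrichment=1.5, seed=1)


def test_empirical_carrier_fraction_matches_hwe(czech_table):
    n = 20_000
    panel = generate_panel(czech_table, n, seed=11)
    expected = carrier_frequency_hwe(total_predisposing_frequency(czech_table))
    observed = empirical_carrier_fraction(panel, czech_table)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 3 * se


def test_rare_enrichment_raises_rare_fraction(czech_table):
    plain = generate_panel(czech_table, 3000, seed=3)
    enriched = generate_panel(czech_table, 3000, rare_enrichment=0.5, seed=3)
    rare = lambda p: sum(s.rare_haplotype_flag for s in p) / len(p)
    assert rare(enriched) > rare(plain)


# ---------------------------------------------------------------------------
# error model


def test_headline_miscall_flips_interpretation():
    # DQB1*03:03 carrier with DQA1*03: truth EXCLUDED
    ref = _reference("DQA1*03:01", "DQA1*01:01", "DQB1*03:03", "DQB1*05:01")
    assert ref.true_category is RiskCategory.EXCLUDED
    sub = apply_error_model(
        [ref], default_error_model(miscall_p=1.0), seed=0
    )
    entry = sub.entries[0]
    reported = [str(a) for a in entry.genotype.dqb1]
    assert "DQB1*03:02" in reported and "DQB1*03:03" not in reported
    assert entry.category is RiskCategory.ASSOCIATED  # spurious DQ8
    scores = score_submission([ref], sub)
    assert not scores[0].genotype_correct
    assert not scores[0].interpretation_correct
    assert scores[0].discrepancies == (
        ("DQB1", "DQB1*03:02", False, True),
    )


def test_zero_probability_model_is_identity(czech_table):
    panel = generate_panel(czech_table, 20, seed=5)
    sub = apply_error_model(panel, default_error_model(miscall_p=0.0), seed=9)
    for ref, entry in zip(panel, sub.entries):
        assert entry.genotype == ref.true_genotype
        assert entry.category is ref.true_category
    scores = score_submission(panel, sub)
    assert all(s.fully_correct for s in scores)
    summary = aggregate_cohort({("L01", Method.PCR_SSP): scores})
    assert summary.per_method[0].error_rate == 0.0


def test_miscall_rate_reproduced_within_3_se():
    n = 10_000
    panel = [
        _reference("DQA1*03:01", "DQA1*01:01", "DQB1*03:03", "DQB1*05:01",
                   sample_id=f"S{i:05d}")
        for i in range(n)
    ]
    p = 0.1
    sub = apply_error_model(panel, default_error_model(miscall_p=p), seed=13)
    corrupted = sum(
        1 for e in sub.entries
        if any(str(a) == "DQB1*03:02" for a in e.genotype.dqb1)
    )
    se = np.sqrt(p * (1 - p) / n)
    assert abs(corrupted / n - p) < 3 * se


def test_dropout_reports_apparent_homozygote():
    ref = _reference("DQA1*03:01", "DQA1*01:01", "DQB1*03:02", "DQB1*05:01")
    model = ErrorModel(
        dropouts=(DropoutRule(AlleleGroup(Locus.DQB1, ("03", "02")), 1.0),)
    )
    sub = apply_error_model([ref], model, seed=0)
    reported = [str(a) for a in sub.entries[0].genotype.dqb1]
    assert reported == ["DQB1*05:01", "DQB1*05:01"]
    assert sub.entries[0].category is RiskCategory.EXCLUDED
    scores = score_submission([ref], sub)
    assert not scores[0].genotype_correct
    assert not scores[0].interpretation_correct  # truth is ASSOCIATED (DQ8)


# ---------------------------------------------------------------------------
# scoring


def test_extra_resolution_never_penalised():
    ref = _reference("DQA1*05:01", "DQA1*01:01", "DQB1*02:01", "DQB1*05:01")
    reported = make_genotype(
        "DQA1*05:05", "DQA1*01:02", "DQB1*02:02", "DQB1*05:02",
        sample_id="S001",
    )
    sub = Submission(
        lab_id="L01",
        method=Method.NGS,
        entries=(
            SubmissionEntry("S001", reported,
                            interpret_sample(reported).category),
        ),
    )
    scores = score_submission([ref], sub)
    assert scores[0].genotype_correct      # same required groups
    assert scores[0].interpretation_correct


def test_missing_sample_scores_false_on_both():
    ref = _reference("DQA1*05:01", "DQA1*01:01", "DQB1*02:01", "DQB1*05:01")
    sub = Submission(
        lab_id="L01", method=Method.SSO,
        entries=(SubmissionEntry("S001", None, None),),
    )
    scores = score_submission([ref], sub)
    assert not scores[0].genotype_correct
    assert not scores[0].interpretation_correct


def test_unknown_sample_id_rejected():
    ref = _reference("DQA1*05:01", "DQA1*01:01", "DQB1*02:01", "DQB1*05:01")
    sub = Submission(
        lab_id="L01", method=Method.SSO,
        entries=(SubmissionEntry("SX", None, None),),
    )
    with pytest.raises(ValueError):
        score_submission([ref], sub)


# ---------------------------------------------------------------------------
# aggregation


def _cohort(n_labs, n_bad, method, panel):
    """n_labs submissions of which exactly n_bad carry a forced miscall."""
    bad_model = ErrorModel(
        miscalls=(
            MiscallRule(
                AlleleGroup(Locus.DQB1, ("03", "03")),
                parse_allele("DQB1*03:02"),
                1.0,
            ),
        )
    )
    scores = {}
    for i in range(n_labs):
        model = bad_model if i < n_bad else ErrorModel()
        sub = apply_error_model(
            panel, model, lab_id=f"L{i:02d}", method=method, seed=i
        )
        scores[(sub.lab_id, method)] = score_submission(panel, sub)
    return scores


@pytest.fixture
def miscallable_panel():
    # one DQB1*03:03 carrier guarantees the forced miscall fires
    return [
        _reference("DQA1*03:01", "DQA1*01:01", "DQB1*03:03", "DQB1*05:01",
                   sample_id="S001"),
        _reference("DQA1*05:01", "DQA1*02:01", "DQB1*02:01", "DQB1*02:02",
                   sample_id="S002"),
        _reference("DQA1*01:01", "DQA1*01:02", "DQB1*05:01", "DQB1*06:02",
                   sample_id="S003"),
    ]


@pytest.mark.parametrize(
    "n_labs, n_bad, method, expected_rate",
    [
        (19, 3, Method.PCR_SSP, 15.8),
        (15, 5, Method.SSO, 33.3),
        (10, 0, Method.RT_PCR, 0.0),
    ],
)
def test_aggregate_cohort_worked_examples(
    miscallable_panel, n_labs, n_bad, method, expected_rate
):
    scores = _cohort(n_labs, n_bad, method, miscallable_panel)
    summary = aggregate_cohort(scores)
    m = summary.for_method(method)
    assert m.labs_n == n_labs
    assert m.labs_with_error_n == n_bad
    assert m.error_rate == expected_rate
    assert m.labs_with_error_n <= m.labs_n


def test_lab_counted_once_per_method(miscallable_panel):
    scores = {}
    for method in (Method.PCR_SSP, Method.SSO):
        sub = apply_error_model(
            miscallable_panel, ErrorModel(), lab_id="L01", method=method,
            seed=0,
        )
        scores[("L01", method)] = score_submission(miscallable_panel, sub)
    summary = aggregate_cohort(scores)
    assert {m.method for m in summary.per_method} == {
        Method.PCR_SSP, Method.SSO,
    }
    assert all(m.labs_n == 1 for m in summary.per_method)


def test_aggregate_requires_submissions():
    with pytest.raises(ValueError):
        aggregate_cohort({})


def test_summary_matches_raw_score_recount(miscallable_panel):
    scores = _cohort(8, 2, Method.PCR_SSP, miscallable_panel)
    summary = aggregate_cohort(scores).for_method(Method.PCR_SSP)
    recount = sum(
        any(not (s.genotype_correct and s.interpretation_correct)
            for s in lab_scores)
        for lab_scores in scores.values()
    )
    assert summary.labs_with_error_n == recount


# ---------------------------------------------------------------------------
# round trips and full-pipeline determinism


def test_panel_frame_round_trip(czech_table):
    panel = generate_panel(czech_table, 10, seed=2)
    df = panel_to_frame(panel)
    again = panel_from_frame(df)
    for a, b in zip(panel, again):
        assert a.true_genotype == b.true_genotype
        assert a.true_category is b.true_category
        assert a.rare_haplotype_flag == b.rare_haplotype_flag


def test_submission_frame_round_trip(czech_table):
    panel = generate_panel(czech_table, 5, seed=4)
    subs = [
        apply_error_model(panel, default_error_model(0.5), lab_id=f"L{i}",
                          method=Method.SSO, seed=i)
        for i in range(3)
    ]
    df = submissions_to_frame(subs)
    again = submissions_from_frame(df)
    assert {s.lab_id for s in again} == {s.lab_id for s in subs}
    for orig in subs:
        match = next(s for s in again if s.lab_id == orig.lab_id)
        for e1, e2 in zip(orig.entries, match.entries):
            assert e1.genotype == e2.genotype
            assert e1.category is e2.category


def test_full_pipeline_byte_reproducible(czech_table):
    def run(seed):
        panel = generate_panel(czech_table, 5, rare_enrichment=0.2, seed=seed)
        rng = np.random.default_rng(seed + 1)
        subs = [
            apply_error_model(panel, default_error_model(0.3),
                              lab_id=f"L{i:02d}", method=Method.PCR_SSP,
                              seed=rng)
            for i in range(6)
        ]
        scores = {
            (s.lab_id, s.method): score_submission(panel, s) for s in subs
        }
        summary = aggregate_cohort(scores)
        return (
            panel_to_frame(panel).to_csv(index=False)
            + submissions_to_frame(subs).to_csv(index=False)
            + summary.to_frame().to_csv(index=False)
        )

    assert run(42) == run(42)
    assert run(42) != run(43)
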