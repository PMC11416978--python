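# Methods

## Scope and model

`hladq` operationalises the clinical interpretation of HLA-DQA1/DQB1
genotypes for coeliac disease (CD). The biological model is the standard
one: CD requires an HLA-DQ molecule able to present deamidated gluten
peptides, and those molecules are DQ2.5 (β chain from DQB1\*02, α chain
from DQA1\*05), DQ2.2 (DQB1\*02 + DQA1\*02 without DQA1\*05) and DQ8
(DQB1\*03:02 + DQA1\*03). Detection is performed on the **unphased**
genotype: an α and a β chain encoded on opposite chromosomes still pair,
so allele co-presence — not haplotype phase — is the criterion. Gene-dose
effects (homozygosity, heterodimer combinations) are real but deliberately
outside scope: the interpretation rules implemented here do not grade
association strength.

## Nomenclature

Allele names are parsed as `LOCUS*F1[:F2[:F3[:F4]]]` with an optional
`HLA-` prefix. Only DQA1 and DQB1 are accepted; any other locus is an
error rather than a silent pass-through. One-digit fields in the first two
positions are zero-padded (`DQB1*3:2` → `DQB1*03:02`) to tolerate
hand-typed input without ambiguity. Expression suffixes (N, L, Q, …) are
rejected outright: a null allele silently treated as expressed could flip
a clinical interpretation, and none of the supported workflows produce
them. An *allele group* is a one- or two-field prefix; all rule logic uses
only the five groups whose correct detection the proficiency scheme
requires (DQA1\*02, \*03, \*05; DQB1\*02; DQB1\*03:02), so third and
fourth fields are carried but never decide anything. A bare `DQB1*03` is
accepted by the parser but rejected at detection time with an
"insufficient resolution" error, because the predisposing \*03:02 cannot
be told from the neutral \*03:03 at one-field resolution.

## Rule sets

Rule sets are ordered, total mappings from heterodimer evidence to a risk
category and a canonical sentence pair; the first matching rule wins and a
catch-all final rule guarantees totality. The registered versions:

| name | associated | not excluded | notes |
|---|---|---|---|
| CZ2015 | DQ2.5, DQ8 | — | |
| CZ2020 | DQ2.5, DQ8 | DQ2.2 (rare risk) | |
| CZ2022 | DQ2.5, DQ2.2, DQ8 | — | strength not graded |
| CZ2023 | DQ2.5, DQ2.2, DQ8 | DQA1\*05 without a heterodimer | current default |
| UK_BSHI | DQ2.5, DQ2.2, DQ8 | — | DQA1\*05 alone excludes |

The 2023 and UK sentences are the published wording and are emitted
verbatim; sentences for the retired 2015/2020/2022 versions survive only
as fragments, so the full texts here are reconstructions and the rule sets
carry `reconstructed=True`. Localisation is treated as a configuration
concern, not a rule concern.

**The DQA1\*05-only ambiguity.** The 2023 wording can be read two ways:
the intermediate category applies when DQA1\*05 is present *strictly
alone*, or whenever DQA1\*05 is present without a complete heterodimer
(even if another lone predisposing allele, e.g. DQB1\*03:02 without
DQA1\*03, coexists). The rare confirmed CD cases motivating the category
were DQA1\*05-positive without heterodimers, so the default here is the
broader reading — any DQA1\*05 without a heterodimer is "cannot be
excluded" — and a warning is attached whenever the two readings diverge.
The strict reading is available as `strict_dqa1_05=True`
(`--strict-dqa1-05` on the CLI). Note that the broader reading keeps
classification monotone: adding a predisposing allele never moves a
genotype away from *associated*, which the strict reading violates.

**DQ2.2 precedence.** When DQA1\*05, DQA1\*02 and DQB1\*02 co-occur, the
report states DQ2.5 present and DQ2.2 absent (the "without DQA1\*05"
qualifier); the category is unaffected.

## Population arithmetic

The carrier proportion of the predisposing haplotype class with total
frequency *f* is the Hardy–Weinberg form `1 − (1 − f)²`, i.e. random
mating and independence of the two parental haplotypes. For the Czech
class frequency f = 0.244 this gives 0.4285, displayed as ≈43% (headline
percentages round half-up to the whole percent; tabulated percentages to
one decimal). Whether the published ~43% was originally computed this way
or from typed-population data is not stated; the HWE formula reproduces it
and is adopted as a documented assumption.

Predictive values use exact 2×2 arithmetic. Inputs: prevalence (default
0.01), sensitivity = P(carrier | CD) (default 0.99 — reported non-carrier
patients are rare but exist, and no published point estimate is adopted as
fact, hence a required-with-default parameter), and the population carrier
frequency. The control-group carrier frequency is recovered by
de-mixing, `(carrier_pop − prev·sens)/(1 − prev)`, and NPV/PPV follow. The
implementation is checked in the tests against an independent
finite-population contingency oracle at N = 10⁷.

## The packaged Czech haplotype table

`hladq/data/czech_haplotypes.csv` carries the three published predisposing
frequencies (9.2%, 8.3%, 6.9%; sum 24.4%). The remaining 75.6% is a
**synthetic completion** over plausible neutral haplotypes so that the
table sums to one and can drive genotype simulation. It purposely includes
DQA1\*03~DQB1\*03:03 (3%) and DQA1\*02~DQB1\*03:03 (1%), so the recurrent
\*03:03→\*03:02 miscall has carriers to hit, and DQA1\*05~DQB1\*03:01
(14%, the common DR11/DR12-type linkage), so DQA1\*05-only genotypes
arise. The neutral frequencies are realistic for a central-European
population but are this package's own choices, not published estimates;
only the predisposing block and its sum should be read as data.

## EPT simulation and scoring

**Panels.** `generate_panel` draws two haplotypes per sample independently
from the (renormalised) table — Hardy–Weinberg random mating — and records
the unphased genotype at two-field resolution (one-field groups are
completed with `:01`, e.g. DQB1\*02 → DQB1\*02:01). The drawn haplotype
labels are kept on each reference sample because the unphased genotype
alone cannot recover them once a trans combination forms a heterodimer;
the empirical carrier fraction is measured from these labels and converges
on the closed form. `rare_enrichment` draws the first haplotype of that
fraction of samples uniformly from haplotypes below a frequency threshold
(default 0.05), mimicking the deliberate inclusion of difficult
rare-linkage samples in real rounds; enrichment biases the panel away from
HWE by design, so consistency checks use `rare_enrichment=0`. The default
round size is five samples, the size of a real EPT round.

**Error model.** Miscall rules (allele matching a target group reported as
a stated wrong allele) and dropout rules (allele missed; the other allele
at the locus is reported twice, as an apparent homozygote) are applied
independently per sample per matching allele with stated probabilities,
all through one seeded generator. The default model is the empirically
dominant failure: DQB1\*03:03 reported as DQB1\*03:02. The submitted
interpretation is recomputed from the corrupted genotype, so a genotyping
error propagates into an interpretation error whenever it changes the
category — with DQA1\*03 present, the \*03:03→\*03:02 miscall fabricates
DQ8 and flips an otherwise excluded genotype to associated.

**Scoring.** Per sample, two booleans: `genotype_correct` iff reported and
true genotypes agree on the presence/absence of each of the five required
groups (extra resolution or extra non-required alleles are never
penalised; a missing sample fails both), and `interpretation_correct` iff
the reported category matches the reference category under the round's
rule set. This binary per-sample scheme is this package's own definition.
A laboratory is erroneous if any sample fails either criterion;
`aggregate_cohort` reports per-method lab counts and the error percentage
(one decimal, half-up), with a lab counted once per method it used, plus
separate genotype-only and interpretation-only error counts.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; every pipeline stage is bit-reproducible for a fixed seed.
* Percentages round half-up (`decimal`), matching clinical-table
  presentation; Python's banker's rounding is never used for display.
* Frequency tables may be partial (sum ≤ 1) for bookkeeping, but
  simulation renormalises and the packaged table sums to one.
* Genotype CSV parsing collects *all* row errors before failing, so a
  malformed submission file is reported in one pass with row numbers.
* Problem sizes in the checks — 100,000 genotypes for the HWE consistency
  check, 10,000 replicates for the binomial miscall check, exhaustive
  enumeration (210 genotypes) for classifier/oracle agreement — were
  chosen so that three standard errors give sub-percent resolution while
  the whole suite stays interactive.

## What the synthetic data does and does not show

The simulator reproduces the structural features that drive real EPT
outcomes: haplotype-frequency-driven genotype composition, rare-haplotype
difficulty, the dominant miscall mode and its propagation into
interpretation, and per-method aggregation. It does not model typing
chemistry (PCR-SSP/RT-PCR/SSO/NGS differ only as submission metadata),
kit-specific failure profiles, inter-laboratory correlation, or year
effects; real per-year cohort outcomes beyond the worked table cells are
therefore not reproducible from this package and are covered instead by
the property-based checks of the machinery. Passing tests demonstrate the
arithmetic and the rules, not the behaviour of any real laboratory.

## Known limitations

* No G/P-group handling, no GL-String ambiguity (`/`) parsing, no loci
  beyond DQA1/DQB1, no phasing or EM haplotype estimation.
* Serology integration, paediatric no-biopsy pathway logic and gene-dose
  risk stratification are out of scope.
* The 2015/2020/2022 interpretation sentences are reconstructions (flagged
  as such); only the 2023 and UK texts are verbatim.
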