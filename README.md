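# hladq

HLA-DQ genotype interpretation for coeliac-disease (CD) genetic testing.

Susceptibility to coeliac disease requires specific HLA-DQ molecules whose
α and β chains are encoded at two loci, *HLA-DQA1* and *HLA-DQB1*:

* **DQ2.5** — DQB1\*02 together with DQA1\*05
* **DQ2.2** — DQB1\*02 together with DQA1\*02 (without DQA1\*05)
* **DQ8** — DQB1\*03:02 together with DQA1\*03

Co-presence of the alleles in the unphased genotype is what counts (trans
pairings form functional heterodimers too). Because roughly 43% of a
central-European population carries at least one predisposing DQ haplotype
while CD prevalence is ~1%, a positive HLA test can never confirm the
disease — but a negative one excludes it with high probability. `hladq`
implements this reasoning end to end for diagnostic laboratories and the
external proficiency-testing (EPT) schemes that audit them:

* **nomenclature** — parsing, normalising and prefix (allele-group)
  matching of DQA1/DQB1 allele names (`DQB1*03:02`, `HLA-DQA1*05`, …).
* **interpretation** — heterodimer detection and three-category clinical
  classification (*associated* / *cannot be excluded* / *excluded*) under
  five versioned rule sets (`CZ2015`, `CZ2020`, `CZ2022`, `CZ2023`,
  `UK_BSHI`), plus assembly of the complete clinical report.
* **population** — haplotype-frequency tables, the Hardy–Weinberg carrier
  proportion `1 − (1 − f)²`, and Bayes negative/positive predictive values.
* **ept** — a seeded simulator and scorer for proficiency-testing rounds:
  reference panels drawn under random mating, configurable laboratory
  error modes (most importantly the recurrent miscall that reports the
  predisposing DQB1\*03:02 in carriers of the neutral DQB1\*03:03), binary
  per-sample scoring at the required resolution, and the per-method lab
  error-rate summary table.

## Worked example

Genotypes come in as delimited text, one sample per row (a blank second
allele marks a homozygote):

```csv
sample_id,dqa1_1,dqa1_2,dqb1_1,dqb1_2
S1,DQA1*05:01,DQA1*03:01,DQB1*02:01,DQB1*03:02
S2,DQA1*05:05,DQA1*01:01,DQB1*03:01,DQB1*05:01
S3,DQA1*03:01,DQA1*01:01,DQB1*03:03,DQB1*05:01
```

```console
$ hladq interpret genotypes.csv --text
Sample S1 (rule set CZ2023)
  Predisposing alleles/groups: DQA1*05:01, DQA1*03:01, DQB1*02:01, DQB1*03:02
  Serological equivalents: DQ2.5: present; DQ2.2: absent; DQ8: present
  Interpretation: Detected HLA genotype is associated with the risk of CD. This result cannot be separately interpreted as a confirmation of CD due to low specificity.

Sample S2 (rule set CZ2023)
  Predisposing alleles/groups: DQA1*05:05
  Serological equivalents: DQ2.5: absent; DQ2.2: absent; DQ8: absent
  Interpretation: Detected HLA genotype is associated with the occurrence of coeliac disease in rare cases. The diagnosis of CD cannot be excluded.

Sample S3 (rule set CZ2023)
  Predisposing alleles/groups: DQA1*03:01
  Serological equivalents: DQ2.5: absent; DQ2.2: absent; DQ8: absent
  Interpretation: Detected HLA genotype is not associated with the risk of CD. The result excludes this diagnosis with high probability.
```

S1 forms both DQ2.5 and DQ8 and is associated with CD risk. S2 carries
DQA1\*05 without any complete heterodimer — under the current `CZ2023`
rules the diagnosis cannot be excluded (under `--ruleset UK_BSHI` the same
genotype is excluded). S3 carries the neutral DQB1\*03:03: excluded — and
exactly the genotype that a typing kit miscalling \*03:03 as \*03:02 would
wrongly flip to *associated*, which is why the simulator treats that
miscall as its headline error mode. Omit `--text` (and add `-o`) for JSON
reports following `src/hladq/data/report.schema.json`.

Population arithmetic with the packaged Czech haplotype table
(DQA1\*05~DQB1\*02 9.2%, DQA1\*02~DQB1\*02 8.3%, DQA1\*03~DQB1\*03:02 6.9%):

```console
$ hladq popfreq
Predisposing haplotype frequency: 24.4%
Carrier proportion (Hardy-Weinberg): 42.8% (~43%)
NPV at prevalence 0.01, sensitivity 0.99: 99.98%
PPV: 2.31%
```

Proficiency-round simulation is fully seeded:

```bash
hladq ept simulate -n 5 --seed 1 -o panel.csv \
    --labs 10 --miscall-p 0.1 --submissions-out subs.csv
hladq ept score --panel panel.csv --submissions subs.csv -o scores.csv
hladq ept summarize --scores scores.csv --json summary.json
```

The same operations are available as library functions
(`hladq.generate_panel`, `hladq.apply_error_model`,
`hladq.score_submission`, `hladq.aggregate_cohort`, …).

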