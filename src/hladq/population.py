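"""Haplotype-frequency bookkeeping, carrier arithmetic and predictive values.

The carrier proportion of the predisposing DQ haplotype class follows from
random mating (Hardy-Weinberg): with total class frequency *f*, a person
carries at least one predisposing haplotype with probability 1 - (1 - f)^2.
For the Czech table (DQA1*05~DQB1*02 9.2%, DQA1*02~DQB1*02 8.3%,
DQA1*03~DQB1*03:02 6.9%, together 24.4%) this gives ~43% of the general
population — which is why a positive HLA test can never confirm coeliac
disease, while a negative one excludes it with high probability.

Predictive values use standard 2x2 Bayes arithmetic with the disease
prevalence, the test sensitivity (fraction of patients carrying a
predisposing genotype) and the population carrier frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .nomenclature import AlleleGroup, Locus, parse_group
from .rounding import percent

__all__ = [
    "HaplotypeEntry",
    "HaplotypeFrequencyTable",
    "PredictiveValueResult",
    "total_predisposing_frequency",
    "carrier_frequency_hwe",
    "predictive_values",
    "read_frequency_table",
    "write_frequency_table",
    "load_czech_table",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class HaplotypeEntry:
    """One DQA1~DQB1 haplotype with its population frequency."""

    dqa1: AlleleGroup
    dqb1: AlleleGroup
    frequency: float
    predisposing: bool

    def __post_init__(self) -> None:
        if self.dqa1.locus is not Locus.DQA1:
            raise ValueError(f"{self.dqa1} is not a DQA1 group")
        if self.dqb1.locus is not Locus.DQB1:
            raise ValueError(f"{self.dqb1} is not a DQB1 group")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(
                f"haplotype {self.label} frequency {self.frequency} "
                "outside [0, 1]"
            )

    @property
    def label(self) -> str:
        return f"{self.dqa1}~{self.dqb1}"


@dataclass(frozen=True)
class HaplotypeFrequencyTable:
    """A (possibly partial) table of DQA1~DQB1 haplotype frequencies."""

    entries: tuple[HaplotypeEntry, ...]
    population_label: str = ""

    def __post_init__(self) -> None:
        total = sum(e.frequency for e in self.entries)
        if total > 1.0 + _SUM_TOL:
            raise ValueError(
                f"haplotype frequencies sum to {total:.4f} > 1"
            )

    @property
    def total_frequency(self) -> float:
        return sum(e.frequency for e in self.entries)

    @property
    def predisposing(self) -> tuple[HaplotypeEntry, ...]:
        return tuple(e for e in self.entries if e.predisposing)


def total_predisposing_frequency(table: HaplotypeFrequencyTable) -> float:
    """Summed frequency of the haplotypes flagged predisposing."""
    if not table.entries:
        raise ValueError("empty haplotype table")
    return sum(e.frequency for e in table.predisposing)


def carrier_frequency_hwe(f: float) -> float:
    """Proportion carrying >=1 haplotype of a class with total frequency *f*.

    Hardy-Weinberg random mating: ``1 - (1 - f)**2``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"haplotype frequency {f} outside [0, 1]")
    return 1.0 - (1.0 - f) ** 2


@dataclass(frozen=True)
class PredictiveValueResult:
    prevalence: float
    sensitivity: float
    carrier_freq_population: float
    carrier_freq_controls: float
    npv: float
    ppv: float

    def to_dict(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "sensitivity": self.sensitivity,
            "carrier_freq_population": self.carrier_freq_population,
            "carrier_freq_controls": self.carrier_freq_controls,
            "npv": self.npv,
            "ppv": self.ppv,
            "npv_percent": percent(self.npv, 2),
            "ppv_percent": percent(self.ppv, 2),
        }


def predictive_values(
    prevalence: float,
    sensitivity: float,
    carrier_freq_population: float,
) -> PredictiveValueResult:
    """Negative and positive predictive value of the HLA carrier test.

    ``sensitivity`` is P(carrier | CD) — the fraction of coeliac patients
    carrying a predisposing genotype; it is close to, but by rare reported
    cases not exactly, 1.  The control-group carrier frequency is recovered
    from the population mixture::

        carrier_controls = (carrier_pop - prevalence * sensitivity) / (1 - prevalence)

    and NPV/PPV follow from the 2x2 table.
    """
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("carrier_freq_population", carrier_freq_population)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if prevalence * sensitivity > carrier_freq_population + _SUM_TOL:
        raise ValueError(
            "carrier frequency in patients exceeds the population carrier "
            "frequency: prevalence*sensitivity > carrier_freq_population"
        )
    if prevalence == 1.0:
        carrier_controls = 0.0
    else:
        carrier_controls = (
            (carrier_freq_population - prevalence * sensitivity)
            / (1.0 - prevalence)
        )
    carrier_controls = min(max(carrier_controls, 0.0), 1.0)

    neg_healthy = (1.0 - prevalence) * (1.0 - carrier_controls)
    neg_diseased = prevalence * (1.0 - sensitivity)
    pos_healthy = (1.0 - prevalence) * carrier_controls
    pos_diseased = prevalence * sensitivity

    npv = 1.0 if neg_healthy + neg_diseased == 0 else (
        neg_healthy / (neg_healthy + neg_diseased)
    )
    ppv = 0.0 if pos_healthy + pos_diseased == 0 else (
        pos_diseased / (pos_diseased + pos_healthy)
    )
    return PredictiveValueResult(
        prevalence=prevalence,
        sensitivity=sensitivity,
        carrier_freq_population=carrier_freq_population,
        carrier_freq_controls=carrier_controls,
        npv=npv,
        ppv=ppv,
    )


PathLike = Union[str, Path, IO[str]]


def read_frequency_table(
    source: PathLike, population_label: str = ""
) -> HaplotypeFrequencyTable:
    """Read a delimited table with header ``dqa1,dqb1,frequency,predisposing``.

    The delimiter (comma or tab) is sniffed by pandas.  Raises ``ValueError``
    on missing columns, unparseable allele groups, negative frequencies or a
    frequency sum above one.
    """
    df = pd.read_csv(source, sep=None, engine="python",
                     dtype={"dqa1": str, "dqb1": str})
    missing = {"dqa1", "dqb1", "frequency", "predisposing"} - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        predisposing = str(row.predisposing).strip().lower() in (
            "true", "1", "yes", "t",
        )
        entries.append(
            HaplotypeEntry(
                dqa1=parse_group(row.dqa1),
                dqb1=parse_group(row.dqb1),
                frequency=float(row.frequency),
                predisposing=predisposing,
            )
        )
    return HaplotypeFrequencyTable(entries=tuple(entries),
                                   population_label=population_label)


def write_frequency_table(
    table: HaplotypeFrequencyTable, dest: PathLike
) -> None:
    """Write the table back out in the same CSV layout (lossless round trip)."""
    df = pd.DataFrame(
        {
            "dqa1": [str(e.dqa1) for e in table.entries],
            "dqb1": [str(e.dqb1) for e in table.entries],
            "frequency": [e.frequency for e in table.entries],
            "predisposing": [
                "true" if e.predisposing else "false" for e in table.entries
            ],
        }
    )
    df.to_csv(dest, index=False)


def load_czech_table() -> HaplotypeFrequencyTable:
    """The packaged Czech haplotype-frequency table.

    The three predisposing entries carry the published Czech frequencies
    (9.2%, 8.3%, 6.9%); the remaining mass is distributed over common
    neutral haplotypes, including DQA1*03~DQB1*03:03 (the recurrent miscall
    target) and DQA1*05~DQB1*03:01 (which yields DQA1*05 without any
    heterodimer), so that the table sums to one.  The neutral frequencies
    are plausible for a central-European population but are a synthetic
    completion, not published estimates.
    """
    ref = resources.files("hladq.data").joinpath("czech_haplotypes.csv")
    with resources.as_file(ref) as path:
        return read_frequency_table(path, population_label="Czech")
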