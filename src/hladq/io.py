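"""Reading genotype tables and writing clinical reports.

Genotype input is delimited text (comma or tab) with the columns
``sample_id, dqa1_1, dqa1_2, dqb1_1, dqb1_2``; a blank second allele at a
locus means the sample is homozygous there.  Reports are emitted as JSON
(one object per sample; schema in ``hladq/data/report.schema.json``) or as
a plain-text rendering.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .interpretation import ClinicalReport, DQGenotype
from .nomenclature import AlleleParseError

__all__ = ["GenotypeInputError", "read_genotypes", "write_reports_json",
           "write_reports_text"]

PathLike = Union[str, Path, IO[str]]

_COLUMNS = ("sample_id", "dqa1_1", "dqa1_2", "dqb1_1", "dqb1_2")


class GenotypeInputError(ValueError):
    """Malformed genotype file; carries per-row error messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("\n".join(errors))


def read_genotypes(source: PathLike) -> list[DQGenotype]:
    """Parse a genotype table; collects all row errors before raising."""
    try:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise GenotypeInputError(["genotype file is empty"]) from None
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise GenotypeInputError(
            [f"missing columns: {', '.join(sorted(missing))}"]
        )
    df = df.fillna("")
    genotypes: list[DQGenotype] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            genotypes.append(
                DQGenotype.from_strings(
                    str(row.sample_id).strip(),
                    row.dqa1_1, row.dqa1_2, row.dqb1_1, row.dqb1_2,
                )
            )
        except (AlleleParseError, ValueError) as exc:
            errors.append(f"row {i} ({row.sample_id}): {exc}")
    if errors:
        raise GenotypeInputError(errors)
    if not genotypes:
        raise GenotypeInputError(["genotype file contains no samples"])
    return genotypes


def write_reports_json(reports: Iterable[ClinicalReport], dest: PathLike) -> None:
    payload = [r.to_dict() for r in reports]
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        json.dump(payload, dest, indent=2)
        dest.write("\n")


def write_reports_text(reports: Iterable[ClinicalReport], dest: PathLike) -> None:
    text = "\n\n".join(r.to_text() for r in reports) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
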