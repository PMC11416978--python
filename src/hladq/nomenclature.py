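"""Parsing, normalisation and group matching of HLA-DQA1/DQB1 allele names.

Allele names follow WHO HLA nomenclature: ``LOCUS*FF:FF[:FF[:FF]]`` with an
optional ``HLA-`` prefix on input (e.g. ``HLA-DQA1*05:01``).  Only the two
loci encoding the HLA-DQ heterodimer chains, DQA1 (alpha) and DQB1 (beta),
are accepted; coeliac-disease susceptibility is defined entirely over them.

An :class:`AlleleGroup` is a one- or two-field prefix such as ``DQA1*05`` or
``DQB1*03:02``; a group with *k* fields matches every allele whose first *k*
fields equal it.  All interpretation logic downstream works on the five
groups that define the clinically required resolution (DQA1*02, *03, *05;
DQB1*02; DQB1*03:02), so higher fields are carried through but never change
a classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Locus",
    "HLAAllele",
    "AlleleGroup",
    "AlleleParseError",
    "parse_allele",
    "format_allele",
    "parse_group",
    "matches_group",
]


class Locus(str, Enum):
    """The two HLA loci handled by this package."""

    DQA1 = "DQA1"
    DQB1 = "DQB1"


class AlleleParseError(ValueError):
    """Raised when an allele or group string cannot be parsed."""


# null / low / questionable expression suffixes are deliberately rejected:
# silently dropping them could flip a clinical interpretation
_EXPRESSION_SUFFIXES = ("N", "L", "S", "C", "A", "Q")

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Za-z0-9]+)\*(.+)$")


@dataclass(frozen=True)
class HLAAllele:
    """A parsed, normalised allele name.

    ``fields`` holds 1-4 numeric field strings with leading zeros preserved
    (one-digit input fields are left-padded to two digits).  ``raw`` keeps
    the original input string for error reporting and report rendering.
    """

    locus: Locus
    fields: tuple[str, ...]
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not f or not f.isdigit():
                raise AlleleParseError(f"non-numeric allele field {f!r}")

    def __str__(self) -> str:
        return format_allele(self)


@dataclass(frozen=True)
class AlleleGroup:
    """A 1- or 2-field allele-name prefix, e.g. DQA1*05 or DQB1*03:02."""

    locus: Locus
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 2:
            raise AlleleParseError(
                f"allele group must have 1-2 fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not f or not f.isdigit():
                raise AlleleParseError(f"non-numeric group field {f!r}")

    def __str__(self) -> str:
        return f"{self.locus.value}*{':'.join(self.fields)}"

    def matches(self, allele: HLAAllele) -> bool:
        return matches_group(allele, self)


def _split_fields(locus_token: str, body: str, text: str) -> tuple[str, ...]:
    body = body.strip()
    if body and body[-1].upper() in _EXPRESSION_SUFFIXES and not body[-1].isdigit():
        raise AlleleParseError(
            f"expression suffix {body[-1]!r} in {text!r} is not supported"
        )
    parts = body.split(":")
    out: list[str] = []
    for i, part in enumerate(parts):
        part = part.strip()
        if not part or not part.isdigit():
            raise AlleleParseError(
                f"malformed field {part!r} in allele name {text!r}"
            )
        # normalise hand-typed one-digit fields ("3:2" -> "03:02"); only the
        # first two fields are ever consulted by interpretation rules
        if len(part) == 1 and i < 2:
            part = "0" + part
        out.append(part)
    return tuple(out)


def _parse_locus(token: str, text: str) -> Locus:
    try:
        return Locus(token.upper())
    except ValueError:
        raise AlleleParseError(
            f"unknown locus {token!r} in {text!r}: only DQA1 and DQB1 are supported"
        ) from None


def parse_allele(text: str) -> HLAAllele:
    """Parse an allele name such as ``"DQB1*03:02"`` or ``"HLA-DQA1*05"``.

    Whitespace is trimmed, an ``HLA-`` prefix is stripped, and one-digit
    fields are zero-padded.  Raises :class:`AlleleParseError` on a blank
    string, a missing ``*``, an unknown locus, a non-numeric field, or an
    expression suffix (N/L/Q/...).
    """
    original = text
    text = text.strip()
    if not text:
        raise AlleleParseError("blank allele name")
    m = _ALLELE_RE.match(text)
    if m is None:
        raise AlleleParseError(
            f"malformed allele name {original!r}: expected 'LOCUS*FF:FF'"
        )
    locus = _parse_locus(m.group(1), original)
    fields = _split_fields(m.group(1), m.group(2), original)
    if len(fields) > 4:
        raise AlleleParseError(f"too many fields in {original!r}")
    return HLAAllele(locus=locus, fields=fields, raw=original)


def format_allele(a: HLAAllele) -> str:
    """Canonical form ``LOCUS*FF:FF...`` (never with the ``HLA-`` prefix)."""
    return f"{a.locus.value}*{':'.join(a.fields)}"


def parse_group(text: str) -> AlleleGroup:
    """Parse a 1- or 2-field allele group such as ``"DQA1*05"``."""
    a = parse_allele(text)
    if len(a.fields) > 2:
        raise AlleleParseError(
            f"allele group {text!r} may have at most two fields"
        )
    return AlleleGroup(locus=a.locus, fields=a.fields)


def matches_group(a: HLAAllele, g: AlleleGroup) -> bool:
    """True iff loci agree and ``a``'s leading fields equal ``g``'s fields.

    A two-field group distinguishes second-field variants: DQB1*03:03 does
    not match the group DQB1*03:02 even though both sit in DQB1*03.
    """
    if a.locus is not g.locus:
        return False
    if len(a.fields) < len(g.fields):
        return False
    return a.fields[: len(g.fields)] == g.fields


def any_matches(alleles: Iterable[HLAAllele], g: AlleleGroup) -> bool:
    """Convenience: does any allele in the collection match the group?"""
    return any(matches_group(a, g) for a in alleles)
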