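"""Chemical-formula mass arithmetic, residue-range bookkeeping and sequence utilities.

These helpers validate construct metadata: the mass added by a click-chemistry
triazole linkage, the lengths of expression constructs given their residue
ranges, and the lengths of nucleosome-positioning DNA fragments.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "ElementalFormula",
    "ResidueRangeSet",
    "parse_formula",
    "formula_mass",
    "range_length",
    "sequence_length",
    "read_fasta",
]

# Atomic mass table.
#
# Monoisotopic masses: CODATA/AME values for the principal isotope.
# Average masses: IUPAC 2005/2007 conventional standard atomic weights —
# the table used by the common proteomics search engines (Mascot/Unimod).
# Note these deliberately predate the current interval-based IUPAC weights:
# modification masses in MS workflows are reported against this table.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Se": 79.9165218,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Cl": 34.96885271,
    "Fe": 55.9349421,
    "Zn": 63.9291466,
}
AVERAGE: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
    "P": 30.973762,
    "Se": 78.96,
    "Na": 22.98977,
    "K": 39.0983,
    "Cl": 35.453,
    "Fe": 55.845,
    "Zn": 65.409,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)\(?(\d*)\)?")


class FormulaError(ValueError):
    """Raised for formulas with unknown elements or malformed syntax."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. ``C10H13N5O5``.

    Counts are non-negative integers over the documented mass table.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(f"element count must be a non-negative integer: {element}={count}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ElementalFormula(dict(merged))

    def __str__(self) -> str:
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in sorted(self.counts.items()) if n)


def parse_formula(formula: str | ElementalFormula) -> ElementalFormula:
    """Parse a plain-string formula such as ``C10H13N5O5`` or ``C(10)H(13)N(5)O(5)``.

    The parser is Hill-order agnostic; repeated element symbols accumulate.
    """
    if isinstance(formula, ElementalFormula):
        return formula
    text = formula.replace(" ", "").replace("+", "")
    if not text:
        raise FormulaError("empty formula")
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula near {text[pos:]!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] += int(digits) if digits else 1
    if pos != len(text):
        raise FormulaError(f"unparseable formula near {text[pos:]!r}")
    return ElementalFormula(dict(counts))


def formula_mass(
    formula: str | ElementalFormula,
    mode: Literal["monoisotopic", "average"] = "monoisotopic",
) -> float:
    """Mass of an elemental formula in Da, reported to 4 decimals.

    ``mode="monoisotopic"`` sums principal-isotope masses; ``mode="average"``
    sums conventional standard atomic weights.
    """
    parsed = parse_formula(formula)
    if mode == "monoisotopic":
        table = MONOISOTOPIC
    elif mode == "average":
        table = AVERAGE
    else:
        raise ValueError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")
    mass = sum(count * table[element] for element, count in parsed.counts.items())
    return round(mass, 4)


@dataclass(frozen=True)
class ResidueRangeSet:
    """Ordered, non-overlapping, 1-based inclusive residue intervals.

    Example: the N-terminally truncated deacetylase construct spanning
    aa 1–3 plus aa 82–747 is ``ResidueRangeSet([(1, 3), (82, 747)])``.
    """

    intervals: tuple[tuple[int, int], ...]

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        ivs = tuple((int(a), int(b)) for a, b in intervals)
        for start, end in ivs:
            if start < 1:
                raise ValueError(f"residue numbering is 1-based; got start {start}")
            if end < start:
                raise ValueError(f"interval end < start: ({start}, {end})")
        for (a1, b1) in ivs:
            for (a2, b2) in ivs:
                if (a1, b1) != (a2, b2) and a1 <= b2 and a2 <= b1:
                    raise ValueError(f"overlapping intervals: ({a1},{b1}) and ({a2},{b2})")
        object.__setattr__(self, "intervals", ivs)

    def __contains__(self, residue: int) -> bool:
        return any(a <= residue <= b for a, b in self.intervals)

    def __iter__(self):
        for a, b in self.intervals:
            yield from range(a, b + 1)


def range_length(ranges: ResidueRangeSet | Iterable[tuple[int, int]]) -> int:
    """Total residue count of a range set: sum of (end - start + 1)."""
    if not isinstance(ranges, ResidueRangeSet):
        ranges = ResidueRangeSet(ranges)
    return sum(end - start + 1 for start, end in ranges.intervals)


_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")
_DECORATIONS = re.compile(r"^5'-|-3'$|^5’-|-3’$")


class SequenceError(ValueError):
    """Raised on characters outside the declared alphabet."""


def clean_sequence(seq: str, alphabet: Literal["dna", "protein"] = "dna") -> str:
    """Strip whitespace and 5'-/-3' decorations; validate the alphabet."""
    text = re.sub(r"\s+", "", seq)
    text = _DECORATIONS.sub("", text)
    text = _DECORATIONS.sub("", text)  # both ends
    text = text.upper()
    allowed = _DNA_ALPHABET if alphabet == "dna" else _PROTEIN_ALPHABET
    bad = set(text) - allowed
    if bad:
        raise SequenceError(f"illegal {alphabet} characters: {sorted(bad)}")
    if not text:
        raise SequenceError("empty sequence")
    return text


def sequence_length(seq: str, alphabet: Literal["dna", "protein"] = "dna") -> int:
    """Character count of a sequence after stripping decorations and whitespace."""
    return len(clean_sequence(seq, alphabet))


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (whitespace stripped)."""
    from Bio import SeqIO

    return {record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")}
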