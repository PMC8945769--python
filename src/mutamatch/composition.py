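"""Nucleotide composition: per-base percentages and A+T content.

A+T content is the second mutability factor: genes whose full-length
nucleotide sequence exceeds the human genome-wide average of 59% A+T are
considered more mutation-prone.  Composition can come from a supplied
sequence (FASTA) or from printed per-base percentages; classification
always uses the unrounded A+T value, and rounding to the integer style of
the reference tables happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "CompositionResult",
    "base_composition",
    "at_from_printed",
    "read_fasta_compositions",
    "round_half_up",
]

_UNAMBIGUOUS = frozenset("ACGT")
_AMBIGUOUS = frozenset("RYSWKMBDHVN")  # IUPAC ambiguity codes


@dataclass(frozen=True)
class CompositionResult:
    """Base counts and percentages over the unambiguous part of a sequence."""

    a_count: int
    c_count: int
    g_count: int
    t_count: int
    n_ambiguous: int
    length: int  # unambiguous length (denominator)

    @property
    def a_pct(self) -> float:
        return 100.0 * self.a_count / self.length

    @property
    def c_pct(self) -> float:
        return 100.0 * self.c_count / self.length

    @property
    def g_pct(self) -> float:
        return 100.0 * self.g_count / self.length

    @property
    def t_pct(self) -> float:
        return 100.0 * self.t_count / self.length

    @property
    def a_plus_t(self) -> float:
        """Unrounded A+T percentage (exactly a_pct + t_pct)."""
        return self.a_pct + self.t_pct

    @property
    def gc(self) -> float:
        return self.c_pct + self.g_pct


def base_composition(sequence: str) -> CompositionResult:
    """Tally A/C/G/T over a nucleotide string.

    Whitespace is ignored; case-insensitive; U is treated as T (RNA input).
    IUPAC ambiguity codes are counted in ``n_ambiguous`` and excluded from
    the percentage denominator.  Raises ``ValueError`` for an empty or
    entirely ambiguous sequence, or for a character outside the IUPAC
    nucleotide alphabet (the error names the offending position).
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    n_ambiguous = 0
    n_seen = 0
    for pos, ch in enumerate(sequence):
        if ch.isspace():
            continue
        base = ch.upper()
        if base == "U":
            base = "T"
        if base in _UNAMBIGUOUS:
            counts[base] += 1
        elif base in _AMBIGUOUS:
            n_ambiguous += 1
        else:
            raise ValueError(f"illegal nucleotide {ch!r} at position {pos}")
        n_seen += 1
    if n_seen == 0:
        raise ValueError("empty sequence: composition undefined")
    length = n_seen - n_ambiguous
    if length == 0:
        raise ValueError("sequence entirely ambiguous: composition undefined")
    return CompositionResult(
        a_count=counts["A"], c_count=counts["C"], g_count=counts["G"],
        t_count=counts["T"], n_ambiguous=n_ambiguous, length=length,
    )


def at_from_printed(a_pct: float, t_pct: float) -> float:
    """Combine printed per-base A and T percentages into A+T content."""
    if a_pct < 0 or t_pct < 0:
        raise ValueError(f"negative percentage: A={a_pct}, T={t_pct}")
    total = a_pct + t_pct
    if total > 100:
        raise ValueError(f"A+T exceeds 100%: A={a_pct}, T={t_pct}")
    return total


def read_fasta_compositions(path: str | Path) -> dict[str, CompositionResult]:
    """Per-record composition of a (multi-)FASTA file, keyed by record id.

    Gene symbols are matched to record ids case-insensitively downstream;
    keys here are upper-cased for that purpose.
    """
    results: dict[str, CompositionResult] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        results[rec.id.upper()] = base_composition(str(rec.seq))
    if not results:
        raise ValueError(f"{path}: no FASTA records found")
    return results


def round_half_up(value: float) -> int:
    """Round to the nearest integer with .5 going up (report style)."""
    import math

    return int(math.floor(value + 0.5))
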