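"""Two-factor mutability classification and matching-rate summaries.

Each gene is tested against two thresholds:

* F(i)  — telomere proximity strictly below 50 Mb;
* F(ii) — A+T content strictly above 59% (the human genome-wide average).

Genes fall into four categories — BOTH, FI_ONLY, FII_ONLY, NONE — and a
cohort's *matching rate* is the fraction meeting at least one factor.
BOTH genes are predicted most mutable (least attractive drug targets),
NONE genes least mutable.  Strictness of either comparison is
configurable for sensitivity analysis; strict is the default because it
reproduces the published drug-target classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .composition import round_half_up
from .records_io import GeneRecord

__all__ = [
    "FactorThresholds",
    "FactorCall",
    "CohortSummary",
    "CATEGORIES",
    "classify_gene",
    "classify_cohort",
    "summarize_cohort",
    "prioritize",
]

CATEGORIES = ("BOTH", "FI_ONLY", "FII_ONLY", "NONE")


@dataclass(frozen=True)
class FactorThresholds:
    """The two cutoffs and the strictness of their comparisons."""

    proximity_cutoff: float = 50.0  # Mb
    at_cutoff: float = 59.0        # percent
    strict_fi: bool = True         # True: proximity <  cutoff; False: <=
    strict_fii: bool = True        # True: A+T      >  cutoff; False: >=

    def __post_init__(self) -> None:
        if self.proximity_cutoff <= 0 or self.at_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class FactorCall:
    symbol: str
    meets_fi: bool
    meets_fii: bool
    category: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if self.meets_fi and self.meets_fii:
            cat = "BOTH"
        elif self.meets_fi:
            cat = "FI_ONLY"
        elif self.meets_fii:
            cat = "FII_ONLY"
        else:
            cat = "NONE"
        object.__setattr__(self, "category", cat)


@dataclass(frozen=True)
class CohortSummary:
    """Category counts and the matching rate for one gene cohort."""

    n: int
    counts: dict[str, int]
    either_count: int
    matching_rate: float  # fraction in [0, 1]
    matching_pct: int     # round-half-up integer percent
    fi_count: int
    fii_count: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n
        assert self.either_count == self.n - self.counts["NONE"]


def classify_gene(record: GeneRecord, thresholds: FactorThresholds | None = None) -> FactorCall:
    """Apply both factor thresholds to one gene."""
    t = thresholds or FactorThresholds()
    if record.proximity is None:
        raise ValueError(f"{record.symbol}: proximity missing, cannot test F(i)")
    if record.a_plus_t is None:
        raise ValueError(f"{record.symbol}: A+T content missing, cannot test F(ii)")
    if t.strict_fi:
        meets_fi = record.proximity < t.proximity_cutoff
    else:
        meets_fi = record.proximity <= t.proximity_cutoff
    if t.strict_fii:
        meets_fii = record.a_plus_t > t.at_cutoff
    else:
        meets_fii = record.a_plus_t >= t.at_cutoff
    return FactorCall(symbol=record.symbol, meets_fi=meets_fi, meets_fii=meets_fii)


def classify_cohort(
    records: Sequence[GeneRecord], thresholds: FactorThresholds | None = None
) -> list[FactorCall]:
    return [classify_gene(rec, thresholds) for rec in records]


def summarize_cohort(calls: Sequence[FactorCall]) -> CohortSummary:
    """Category counts and matching rate over a non-empty cohort."""
    if not calls:
        raise ValueError("empty cohort: matching rate undefined")
    counts = {cat: 0 for cat in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n = len(calls)
    either = n - counts["NONE"]
    rate = either / n
    return CohortSummary(
        n=n,
        counts=counts,
        either_count=either,
        matching_rate=rate,
        matching_pct=round_half_up(100.0 * rate),
        fi_count=counts["BOTH"] + counts["FI_ONLY"],
        fii_count=counts["BOTH"] + counts["FII_ONLY"],
    )


def prioritize(
    records: Sequence[GeneRecord],
    calls: Sequence[FactorCall],
    group: str,
    k: int,
) -> list[str]:
    """Rank the BOTH (most mutable) or NONE (least mutable) genes.

    BOTH is ranked most-mutable-first: A+T descending, then proximity
    ascending, then symbol.  NONE is ranked least-mutable-first: A+T
    ascending, then proximity descending, then symbol.  Returns the first
    ``k`` symbols.
    """
    if group not in ("BOTH", "NONE"):
        raise ValueError(f"group must be 'BOTH' or 'NONE', got {group!r}")
    if k < 0:
        raise ValueError("k must be >= 0")
    by_symbol = {}
    for rec, call in zip(records, calls):
        if call.category == group:
            by_symbol.setdefault(call.symbol, rec)
    members = list(by_symbol.values())
    if group == "BOTH":
        members.sort(key=lambda r: (-(r.a_plus_t or 0), r.proximity or 0, r.symbol))
    else:
        members.sort(key=lambda r: (r.a_plus_t or 0, -(r.proximity or 0), r.symbol))
    return [r.symbol for r in members[:k]]
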