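"""Distance from a gene to its nearest telomere, and linkage status.

Telomere proximity is the first mutability factor.  A chromosome is
idealized as the interval [0, L] Mb with telomeres at both termini (p at
0, q at L); a gene is a point locus.  Genetic-map distance is converted at
the 1 cM ~ 1 Mbp heuristic, and two loci within 50 cM are "linked" —
hence a gene within 50 Mb of a telomere is telomere-proximal.

Explicit telomere intervals (BED) may replace the {0, L} idealization, in
which case the distance is to the nearest interval edge (0 inside an
interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records_io import ChromosomeMap

__all__ = [
    "ProximityResult",
    "CM_PER_MB",
    "LINKAGE_CUTOFF_CM",
    "distance_to_given_telomere",
    "nearest_telomere_distance",
    "distance_to_intervals",
    "linkage_status",
    "mb_to_cm",
]

CM_PER_MB = 1.0          # 1 cM ~ 1 Mbp conversion heuristic
LINKAGE_CUTOFF_CM = 50.0  # loci within 50 cM are linked


@dataclass(frozen=True)
class ProximityResult:
    distance: float  # Mb
    arm: str         # "p" or "q"
    linked: bool     # distance (as cM) <= 50


def mb_to_cm(distance_mb: float) -> float:
    return distance_mb * CM_PER_MB


def linkage_status(distance_cm: float) -> str:
    """'linked' iff the genetic-map distance is <= 50 cM, else 'unlinked'."""
    if distance_cm < 0:
        raise ValueError(f"distance must be >= 0, got {distance_cm}")
    return "linked" if distance_cm <= LINKAGE_CUTOFF_CM else "unlinked"


def distance_to_given_telomere(gene_locus: float, telomere_locus: float) -> float:
    """|gene - telomere| in Mb, both measured from the p-terminus."""
    if gene_locus < 0 or telomere_locus < 0:
        raise ValueError(
            f"loci must be >= 0, got gene {gene_locus}, telomere {telomere_locus}"
        )
    # round to the printed decimal resolution to avoid float dust (e.g.
    # 138.1 - 138 -> 0.09999... prints as 0.1)
    return round(abs(gene_locus - telomere_locus), 6)


def nearest_telomere_distance(
    gene_locus: float, chromosome: int | str, chrom_map: ChromosomeMap
) -> ProximityResult:
    """Distance to the nearer chromosome terminus.

    Arm is "p" when the p-terminus (coordinate 0) is nearer; exact ties go
    to "p".  Raises for a locus beyond the chromosome length or an unknown
    chromosome.
    """
    from .records_io import normalize_chromosome

    chrom = chromosome if isinstance(chromosome, int) else normalize_chromosome(chromosome)
    length = chrom_map[chrom]
    if gene_locus < 0 or gene_locus > length:
        raise ValueError(
            f"locus {gene_locus} Mb outside chromosome {chromosome} (length {length} Mb)"
        )
    d_p = gene_locus
    d_q = length - gene_locus
    if d_p <= d_q:
        distance, arm = d_p, "p"
    else:
        distance, arm = d_q, "q"
    distance = round(distance, 6)
    return ProximityResult(
        distance=distance,
        arm=arm,
        linked=linkage_status(mb_to_cm(distance)) == "linked",
    )


def distance_to_intervals(
    gene_locus: float, intervals: Sequence[tuple[float, float]]
) -> float:
    """Distance (Mb) from a point locus to the nearest interval edge.

    Used when explicit telomere intervals override the {0, length}
    idealization; a locus inside an interval is at distance 0.
    """
    if not intervals:
        raise ValueError("no telomere intervals supplied")
    best = None
    for start, end in intervals:
        if start <= gene_locus <= end:
            d = 0.0
        else:
            d = min(abs(gene_locus - start), abs(gene_locus - end))
        best = d if best is None else min(best, d)
    return round(best, 6)
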