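"""Reading and writing gene-record tables and genomic reference files.

Gene records carry the per-gene quantities the two-factor mutability
analysis needs: chromosome, gene locus and reference telomere locus in
megabases (Mb), distance to that telomere ("proximity"), per-base A and T
percentages, their sum (A+T content), and the full-length nucleotide size
in base pairs.  Two table dialects are supported:

* ``table1_2`` — the drug-target table layout (columns ``Drug``,
  ``Target Gene``, ``Chr``, ``Gene Loci``, ``Telomere Loci``,
  ``Proximity (Mb)``, ``A,T (%)``, ``A+T (%)``, ``FL Size (bp)``), where
  the A/T composition is a comma-joined integer pair and thousands
  separators appear in base-pair counts.
* ``generic`` — a plain machine-friendly TSV/CSV with one column per field.

Two reference tables from the published drug-target survey (11 ion-channel
genes, 20 GPCR genes) ship with the package and are loadable via
:func:`load_table1` and :func:`load_table2`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "GeneRecord",
    "ChromosomeMap",
    "SchemaError",
    "RowParseError",
    "read_gene_table",
    "read_chrom_sizes",
    "read_telomere_bed",
    "write_results_table",
    "load_table1",
    "load_table2",
    "GRCH38_CHROM_MB",
]

PROTEIN_CLASSES = ("ion_channel", "gpcr", "other")

# Printed gene cells sometimes use a trade/alias name; map to the official
# HGNC symbol.  "X or Y" cells resolve to the second (official) name first.
_SYMBOL_ALIASES = {
    "HERG": "KCNH2",
    "S1PR11": "S1PR1",  # printed with a trailing 1; prose uses S1PR1
    "HCRT2": "HCRTR2",
    "GIRK2": "KCNJ6",
    "CANA1C": "CACNA1C",
}

# Approximate GRCh38 chromosome lengths in Mb; X is stored as 23.
GRCH38_CHROM_MB: dict[int, float] = {
    1: 248.96, 2: 242.19, 3: 198.30, 4: 190.21, 5: 181.54, 6: 170.81,
    7: 159.35, 8: 145.14, 9: 138.39, 10: 133.80, 11: 135.09, 12: 133.28,
    13: 114.36, 14: 107.04, 15: 101.99, 16: 90.34, 17: 83.26, 18: 80.37,
    19: 58.62, 20: 64.44, 21: 46.71, 22: 50.82, 23: 156.04,
}


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RowParseError(ValueError):
    """A data cell could not be parsed; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass
class GeneRecord:
    """One gene's coordinates, composition, length and protein class.

    Megabase coordinates are decimal floats as printed (no re-rounding);
    chromosome X is encoded as 23 with the original label preserved in
    ``chrom_label``.
    """

    symbol: str
    chromosome: int
    drug: str | None = None
    protein_class: str = "other"
    gene_locus: float | None = None      # Mb from the p-terminus
    telomere_locus: float | None = None  # Mb, reference telomere (table mode)
    proximity: float | None = None       # Mb to the reference/nearest telomere
    a_pct: float | None = None
    t_pct: float | None = None
    a_plus_t: float | None = None
    fl_size: int | None = None           # full-length size, bp
    chrom_label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom_label:
            self.chrom_label = "X" if self.chromosome == 23 else str(self.chromosome)
        self.validate()

    def validate(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.chromosome not in range(1, 24):
            raise ValueError(
                f"{self.symbol}: chromosome must be 1-23 (23 = X), got {self.chromosome}"
            )
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValueError(f"{self.symbol}: unknown protein class {self.protein_class!r}")
        for name in ("a_pct", "t_pct", "a_plus_t"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.symbol}: {name} must lie in [0, 100], got {v}")
        if self.a_pct is not None and self.t_pct is not None and self.a_plus_t is not None:
            # printed integer columns round independently; allow 1-point slack
            if abs(self.a_plus_t - (self.a_pct + self.t_pct)) > 1.0:
                raise ValueError(
                    f"{self.symbol}: A+T {self.a_plus_t} inconsistent with "
                    f"A {self.a_pct} + T {self.t_pct}"
                )
        if self.proximity is not None and self.proximity < 0:
            raise ValueError(f"{self.symbol}: proximity must be >= 0")
        if self.gene_locus is not None and self.gene_locus < 0:
            raise ValueError(f"{self.symbol}: gene locus must be >= 0")
        if self.fl_size is not None and self.fl_size < 1:
            raise ValueError(f"{self.symbol}: full-length size must be >= 1 bp")


@dataclass
class ChromosomeMap:
    """Chromosome-name -> length (Mb), p-terminus fixed at coordinate 0."""

    lengths_mb: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths_mb.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")

    def __contains__(self, chromosome: int) -> bool:
        return chromosome in self.lengths_mb

    def __getitem__(self, chromosome: int) -> float:
        try:
            return self.lengths_mb[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome} not in chromosome map") from None

    @classmethod
    def grch38(cls) -> "ChromosomeMap":
        """Built-in approximate human chromosome sizes (no download needed)."""
        return cls(dict(GRCH38_CHROM_MB))


def normalize_chromosome(name: str) -> int:
    """Map 'chr12'/'12' -> 12 and 'chrX'/'X' -> 23."""
    label = str(name).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() == "X":
        return 23
    try:
        chrom = int(label)
    except ValueError:
        raise ValueError(f"unrecognized chromosome name {name!r}") from None
    return chrom


def _parse_number(cell: str) -> float:
    return float(str(cell).strip().replace(",", ""))


def _official_symbol(cell: str) -> str:
    """Extract the official gene symbol from a printed 'Target Gene' cell."""
    text = cell.strip().strip("*")
    # "HERG (KCNH2)" -> KCNH2; "NK1R or TACR1" -> TACR1
    m = re.search(r"\(([^)]+)\)", text)
    if m:
        text = m.group(1)
    if " or " in text:
        text = text.split(" or ")[-1]
    text = text.strip().strip("*")
    return _SYMBOL_ALIASES.get(text, text)


_TABLE1_2_COLUMNS = {
    "Drug": "drug",
    "Target Gene": "symbol",
    "Chr": "chromosome",
    "Gene Loci": "gene_locus",
    "Telomere Loci": "telomere_locus",
    "Proximity (Mb)": "proximity",
    "A,T (%)": "at_pair",
    "A+T (%)": "a_plus_t",
    "FL Size (bp)": "fl_size",
}

_GENERIC_COLUMNS = {
    "drug": "drug",
    "gene": "symbol",
    "chr": "chromosome",
    "gene_locus_mb": "gene_locus",
    "telomere_locus_mb": "telomere_locus",
    "proximity_mb": "proximity",
    "a_pct": "a_pct",
    "t_pct": "t_pct",
    "at_pct": "a_plus_t",
    "fl_size_bp": "fl_size",
}
_GENERIC_REQUIRED = ("gene", "chr")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_gene_table(
    path: str | Path,
    dialect: str = "generic",
    protein_class: str = "other",
) -> list[GeneRecord]:
    """Read a delimited gene table into :class:`GeneRecord` objects.

    Parameters
    ----------
    path:
        TSV or CSV file with a header row (delimiter sniffed from the header).
    dialect:
        ``"table1_2"`` for the printed drug-target layout, ``"generic"``
        for the plain per-field layout.
    protein_class:
        Class assigned to every record (the tables do not carry one).
    """
    if dialect not in ("table1_2", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open(newline="") as handle:
        first = handle.readline()
        if not first.strip():
            raise SchemaError(f"{path}: empty file, header row required")
        delim = _sniff_delimiter(first)
        handle.seek(0)
        reader = csv.DictReader(handle, delimiter=delim)
        header = reader.fieldnames or []
        colmap = _TABLE1_2_COLUMNS if dialect == "table1_2" else _GENERIC_COLUMNS
        required = tuple(colmap) if dialect == "table1_2" else _GENERIC_REQUIRED
        for column in required:
            if column not in header:
                raise SchemaError(f"{path}: missing required column {column!r}")
        records: list[GeneRecord] = []
        for i, row in enumerate(reader):
            if all((v is None or not str(v).strip()) for v in row.values()):
                continue
            records.append(_parse_row(row, i, dialect, protein_class))
    return records


def _parse_row(row: Mapping[str, str], index: int, dialect: str, protein_class: str) -> GeneRecord:
    fields: dict[str, object] = {"protein_class": protein_class}
    colmap = _TABLE1_2_COLUMNS if dialect == "table1_2" else _GENERIC_COLUMNS
    try:
        for column, name in colmap.items():
            cell = row.get(column)
            if cell is None or not str(cell).strip():
                continue
            cell = str(cell).strip()
            if name == "symbol":
                fields["symbol"] = _official_symbol(cell) if dialect == "table1_2" else cell
            elif name == "drug":
                fields["drug"] = cell
            elif name == "chromosome":
                fields["chrom_label"] = cell[3:] if cell.lower().startswith("chr") else cell
                fields["chromosome"] = normalize_chromosome(cell)
            elif name == "at_pair":
                a_txt, t_txt = cell.split(",")
                fields["a_pct"] = float(a_txt)
                fields["t_pct"] = float(t_txt)
            elif name == "fl_size":
                fields["fl_size"] = int(_parse_number(cell))
            else:
                fields[name] = _parse_number(cell)
        if dialect == "generic" and "protein_class" in row and str(row["protein_class"]).strip():
            fields["protein_class"] = str(row["protein_class"]).strip()
        return GeneRecord(**fields)  # type: ignore[arg-type]
    except (ValueError, TypeError) as exc:
        raise RowParseError(index, str(exc)) from exc


def read_chrom_sizes(path: str | Path) -> ChromosomeMap:
    """Read a UCSC-style two-column chrom.sizes file (name, length in bp)."""
    lengths: dict[int, float] = {}
    path = Path(path)
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected two columns, got {line!r}")
            chrom = normalize_chromosome(parts[0])
            length_bp = int(parts[1])
            if length_bp <= 0:
                raise ValueError(f"{path}:{line_no}: non-positive length {length_bp}")
            if chrom in lengths:
                raise ValueError(f"{path}:{line_no}: duplicate chromosome {parts[0]!r}")
            lengths[chrom] = length_bp / 1e6
    return ChromosomeMap(lengths)


def read_telomere_bed(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    """Read BED3 telomere intervals (0-based half-open, bp) into Mb intervals."""
    intervals: dict[int, list[tuple[float, float]]] = {}
    path = Path(path)
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED3 needs chrom, start, end")
            chrom = normalize_chromosome(parts[0])
            start, end = int(parts[1]), int(parts[2])
            if end <= start or start < 0:
                raise ValueError(f"{path}:{line_no}: invalid interval [{start}, {end})")
            intervals.setdefault(chrom, []).append((start / 1e6, end / 1e6))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


_OUTPUT_COLUMNS = (
    "drug", "gene", "protein_class", "chr", "gene_locus_mb", "telomere_locus_mb",
    "proximity_mb", "a_pct", "t_pct", "at_pct", "fl_size_bp",
    "meets_fi", "meets_fii", "category",
)


def write_results_table(records: Sequence[GeneRecord], calls: Sequence, path: str | Path) -> None:
    """Write records with their factor calls as a generic-dialect TSV.

    The output round-trips through ``read_gene_table(..., "generic")``:
    every parsed field survives, and re-classifying the parsed records
    reproduces the categories written here.
    """
    if len(records) != len(calls):
        raise ValueError("records and calls must align one-to-one")
    for rec, call in zip(records, calls):
        if rec.symbol != call.symbol:
            raise ValueError(f"no factor call attached for gene {rec.symbol}")
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_OUTPUT_COLUMNS)
        for rec, call in zip(records, calls):
            writer.writerow([
                rec.drug or "",
                rec.symbol,
                rec.protein_class,
                rec.chrom_label,
                _fmt(rec.gene_locus),
                _fmt(rec.telomere_locus),
                _fmt(rec.proximity),
                _fmt(rec.a_pct),
                _fmt(rec.t_pct),
                _fmt(rec.a_plus_t),
                "" if rec.fl_size is None else rec.fl_size,
                int(call.meets_fi),
                int(call.meets_fii),
                call.category,
            ])


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:g}"


def _load_fixture(filename: str, protein_class: str) -> list[GeneRecord]:
    with resources.as_file(resources.files("mutamatch.data") / filename) as p:
        return read_gene_table(p, dialect="table1_2", protein_class=protein_class)


def load_table1() -> list[GeneRecord]:
    """The 11 ion-channel genes targeted by approved drugs."""
    return _load_fixture("table1_ion_channels.tsv", "ion_channel")


def load_table2() -> list[GeneRecord]:
    """The 20 GPCR genes targeted by approved drugs."""
    return _load_fixture("table2_gpcrs.tsv", "gpcr")
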