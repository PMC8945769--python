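"""End-to-end two-factor analysis: fill, classify, summarize, test, report.

The pipeline takes a gene cohort (read from a table or generated
synthetically), fills in any missing telomere proximity (from a
chromosome map or explicit telomere intervals) or A+T content (from
sequences or printed A/T percentages), classifies every gene against the
two factor thresholds, and assembles an :class:`AnalysisReport`:
per-gene calls, the cohort matching-rate summary, FL-size correlations,
size-bin ANOVA/Tukey statistics, prioritized BOTH/NONE candidate lists,
and a provenance block.  Values already present in the input table take
precedence over recomputation, and the per-field source is recorded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .classify import (
    CohortSummary,
    FactorCall,
    FactorThresholds,
    classify_gene,
    prioritize,
    summarize_cohort,
)
from .composition import CompositionResult, at_from_printed
from .proximity import distance_to_intervals, nearest_telomere_distance
from .records_io import ChromosomeMap, GeneRecord, write_results_table
from .stats import PearsonResult, anova_tukey, assign_size_bin, pearson_with_p

__all__ = ["AnalysisReport", "run_two_factor_analysis", "render_summary_plots"]

logger = logging.getLogger("mutamatch")


@dataclass
class AnalysisReport:
    """Everything one two-factor run produces."""

    records: list[GeneRecord]
    calls: list[FactorCall]
    summary: CohortSummary
    table: pd.DataFrame
    correlations: dict[str, PearsonResult | None]
    size_bin_stats: dict
    priorities: dict[str, list[str]]
    errors: list[tuple[str, str]]          # (symbol, message) per failed gene
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        corr = {
            key: (None if res is None else {"r": res.r, "p": res.p, "n": res.n})
            for key, res in self.correlations.items()
        }
        return {
            "summary": {
                "n": self.summary.n,
                "counts": self.summary.counts,
                "either_count": self.summary.either_count,
                "matching_rate": self.summary.matching_rate,
                "matching_pct": self.summary.matching_pct,
                "fi_count": self.summary.fi_count,
                "fii_count": self.summary.fii_count,
            },
            "correlations": corr,
            "size_bins": self.size_bin_stats,
            "priorities": self.priorities,
            "errors": [list(e) for e in self.errors],
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
        """Write genes.tsv (or .json) plus summary.json; deterministic."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        if fmt == "tsv":
            genes_path = out_dir / "genes.tsv"
            write_results_table(self.records, self.calls, genes_path)
        elif fmt == "json":
            genes_path = out_dir / "genes.json"
            genes_path.write_text(
                self.table.to_json(orient="records", indent=2) + "\n"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written.append(genes_path)
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        written.append(summary_path)
        return written


def _fill_proximity(
    rec: GeneRecord,
    chrom_map: ChromosomeMap | None,
    telomeres: Mapping[int, list[tuple[float, float]]] | None,
) -> tuple[float, str]:
    if rec.proximity is not None:
        return rec.proximity, "table"
    if rec.gene_locus is None:
        raise ValueError("no proximity and no gene locus to compute it from")
    if telomeres and rec.chromosome in telomeres:
        return distance_to_intervals(rec.gene_locus, telomeres[rec.chromosome]), "telomere_bed"
    if rec.telomere_locus is not None:
        from .proximity import distance_to_given_telomere

        return distance_to_given_telomere(rec.gene_locus, rec.telomere_locus), "telomere_locus"
    if chrom_map is not None:
        result = nearest_telomere_distance(rec.gene_locus, rec.chromosome, chrom_map)
        return result.distance, "chrom_sizes"
    raise ValueError("no proximity path: supply proximity, telomere locus, BED or chrom.sizes")


def _fill_at(rec: GeneRecord, compositions: Mapping[str, CompositionResult] | None) -> tuple[float, str]:
    if rec.a_plus_t is not None:
        return rec.a_plus_t, "table"
    if rec.a_pct is not None and rec.t_pct is not None:
        return at_from_printed(rec.a_pct, rec.t_pct), "printed_pair"
    if compositions is not None:
        comp = compositions.get(rec.symbol.upper())
        if comp is not None:
            return comp.a_plus_t, "sequence"
    raise ValueError("no A+T path: supply A+T, an A/T pair, or a sequence")


def run_two_factor_analysis(
    records: Sequence[GeneRecord],
    thresholds: FactorThresholds | None = None,
    chrom_map: ChromosomeMap | None = None,
    compositions: Mapping[str, CompositionResult] | None = None,
    telomeres: Mapping[int, list[tuple[float, float]]] | None = None,
    top_k: int = 5,
) -> AnalysisReport:
    """Run the full two-factor mutability analysis over a cohort.

    Genes whose proximity or A+T content can neither be read nor computed
    are collected as per-gene errors; the run fails only if every gene
    fails.  Correlations and size-bin statistics are skipped (with a
    logged notice) when the cohort is too small or degenerate for them.
    """
    thresholds = thresholds or FactorThresholds()
    usable: list[GeneRecord] = []
    calls: list[FactorCall] = []
    sources: list[tuple[str, str]] = []
    errors: list[tuple[str, str]] = []

    for rec in records:
        try:
            prox, prox_src = _fill_proximity(rec, chrom_map, telomeres)
            at, at_src = _fill_at(rec, compositions)
            filled = GeneRecord(
                symbol=rec.symbol, chromosome=rec.chromosome, drug=rec.drug,
                protein_class=rec.protein_class, gene_locus=rec.gene_locus,
                telomere_locus=rec.telomere_locus, proximity=prox,
                a_pct=rec.a_pct, t_pct=rec.t_pct, a_plus_t=at,
                fl_size=rec.fl_size, chrom_label=rec.chrom_label,
            )
            call = classify_gene(filled, thresholds)
            usable.append(filled)
            calls.append(call)
            sources.append((prox_src, at_src))
            logger.debug(
                "%s: proximity %.3g Mb (%s), A+T %.3g%% (%s) -> %s",
                rec.symbol, prox, prox_src, at, at_src, call.category,
            )
        except (ValueError, KeyError) as exc:
            errors.append((rec.symbol, str(exc)))
            logger.debug("%s: skipped (%s)", rec.symbol, exc)

    if records and not usable:
        raise ValueError(f"no gene could be analyzed; first error: {errors[0]}")
    summary = summarize_cohort(calls)
    logger.info(
        "cohort of %d genes: %d meet either factor (%d%%); NONE = %d",
        summary.n, summary.either_count, summary.matching_pct, summary.counts["NONE"],
    )

    table = pd.DataFrame({
        "gene": [r.symbol for r in usable],
        "drug": [r.drug for r in usable],
        "protein_class": [r.protein_class for r in usable],
        "chr": [r.chrom_label for r in usable],
        "proximity_mb": [r.proximity for r in usable],
        "at_pct": [r.a_plus_t for r in usable],
        "fl_size_bp": [r.fl_size for r in usable],
        "size_bin": [None if r.fl_size is None else assign_size_bin(r.fl_size) for r in usable],
        "meets_fi": [c.meets_fi for c in calls],
        "meets_fii": [c.meets_fii for c in calls],
        "category": [c.category for c in calls],
        "proximity_source": [s[0] for s in sources],
        "at_source": [s[1] for s in sources],
    })

    correlations = _run_correlations(table)
    size_bin_stats = _run_size_bins(table)
    priorities = {
        "BOTH": prioritize(usable, calls, "BOTH", top_k),
        "NONE": prioritize(usable, calls, "NONE", top_k),
    }
    diagnostics = {
        # strict vs non-strict F(ii) counts — the cutoff sits exactly on
        # some printed values (59%), so both readings are surfaced
        "fii_count_strict": int(sum(1 for r in usable if r.a_plus_t > thresholds.at_cutoff)),
        "fii_count_inclusive": int(sum(1 for r in usable if r.a_plus_t >= thresholds.at_cutoff)),
        "outside_fi_count": summary.n - summary.fi_count,
        "outside_fii_count": summary.n - summary.fii_count,
    }
    provenance = {
        "package": "mutamatch",
        "version": _pkg_version,
        "n_input": len(records),
        "n_classified": len(usable),
        "n_errors": len(errors),
        "thresholds": {
            "proximity_cutoff_mb": thresholds.proximity_cutoff,
            "at_cutoff_pct": thresholds.at_cutoff,
            "strict_fi": thresholds.strict_fi,
            "strict_fii": thresholds.strict_fii,
        },
    }
    return AnalysisReport(
        records=usable, calls=calls, summary=summary, table=table,
        correlations=correlations, size_bin_stats=size_bin_stats,
        priorities=priorities, errors=errors,
        diagnostics=diagnostics, provenance=provenance,
    )


def _run_correlations(table: pd.DataFrame) -> dict[str, PearsonResult | None]:
    out: dict[str, PearsonResult | None] = {}
    for key, col in (("fl_vs_proximity", "proximity_mb"), ("fl_vs_at", "at_pct")):
        sub = table[["fl_size_bp", col]].dropna()
        try:
            out[key] = pearson_with_p(sub["fl_size_bp"], sub[col])
        except ValueError as exc:
            logger.info("correlation %s not computed: %s", key, exc)
            out[key] = None
    return out


def _run_size_bins(table: pd.DataFrame) -> dict:
    sub = table.dropna(subset=["fl_size_bp"])
    bin_counts = sub["size_bin"].value_counts().to_dict()
    stats: dict = {"counts": {int(k): int(v) for k, v in sorted(bin_counts.items())}}
    for key, col in (("proximity_by_size", "proximity_mb"), ("at_by_size", "at_pct")):
        groups, labels = [], []
        for b in (1, 2, 3):
            vals = sub.loc[sub["size_bin"] == b, col].dropna().to_numpy()
            if vals.size >= 2:
                groups.append(vals)
                labels.append(f"bin{b}")
        if len(groups) < 2:
            logger.info("size-bin ANOVA %s not computed: fewer than 2 usable groups", key)
            stats[key] = None
            continue
        res = anova_tukey(groups, labels)
        stats[key] = {
            "F": res.F,
            "p_overall": res.p_overall,
            "pairwise": [
                {
                    "group_a": c.group_a, "group_b": c.group_b,
                    "mean_diff": c.mean_diff, "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in res.pairwise
            ],
        }
    return stats


def render_summary_plots(
    report: AnalysisReport,
    out_dir: str | Path,
    thresholds: FactorThresholds | None = None,
) -> list[Path]:
    """Write the three summary figures plus a metadata sidecar.

    Produces scatter plots of proximity and A+T per gene with the factor
    cutoff lines, and a chromosome/proximity/A+T heat strip.  A
    ``plot_metadata.json`` sidecar records the threshold-line positions
    so figure content is machine-checkable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if not report.records:
        raise ValueError("empty report: nothing to plot")
    thresholds = thresholds or FactorThresholds()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = report.table
    idx = np.arange(len(table))
    written: list[Path] = []

    specs = (
        ("proximity_scatter.png", "proximity_mb", thresholds.proximity_cutoff,
         "Proximity to telomere (Mb)", "tab:green"),
        ("at_scatter.png", "at_pct", thresholds.at_cutoff,
         "A+T content (%)", "tab:brown"),
    )
    for filename, col, cutoff, ylabel, color in specs:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.scatter(idx, table[col], s=18, color=color)
        ax.axhline(cutoff, linestyle="--", color="black", linewidth=1)
        ax.set_xlabel("gene index")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = out_dir / filename
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    # heat strip: chromosome, proximity and A+T per gene as three rows
    strip = np.vstack([
        table["chr"].map(lambda c: 23 if str(c).upper() == "X" else int(c)).to_numpy(float) / 23.0,
        table["proximity_mb"].to_numpy(float) / max(table["proximity_mb"].max(), 1.0),
        table["at_pct"].to_numpy(float) / 100.0,
    ])
    fig, ax = plt.subplots(figsize=(6, 2))
    ax.imshow(strip, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_yticks([0, 1, 2], ["chr", "proximity", "A+T"])
    ax.set_xlabel("gene index")
    fig.tight_layout()
    heat_path = out_dir / "heat_strip.png"
    fig.savefig(heat_path, dpi=110)
    plt.close(fig)
    written.append(heat_path)

    meta_path = out_dir / "plot_metadata.json"
    meta_path.write_text(json.dumps({
        "proximity_cutoff_mb": thresholds.proximity_cutoff,
        "at_cutoff_pct": thresholds.at_cutoff,
        "n_genes": len(table),
        "files": [p.name for p in written],
    }, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
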