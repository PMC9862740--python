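"""Cross-analysis synthesis: top-set intersection, gene mapping, island overlap.

A marker is a putative selection signal when it sits in the top percentile of
*both* between-group scans (smoothed F_ST and normalized XP-EHH); such
markers are mapped onto annotated genes by closed-interval containment
(optionally padded by ``flank_bp``).  Within-group ROH islands from the two
groups are additionally compared for positive-length interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_data import GeneInterval
from .roh import ROHIsland

__all__ = [
    "SelectionReport",
    "intersect_top_sets",
    "map_snps_to_genes",
    "islands_overlap",
    "build_report",
    "write_report",
]


@dataclass
class SelectionReport:
    top_fst: pd.DataFrame
    top_xpehh: pd.DataFrame
    shared: pd.DataFrame
    genes_fst: set[str]
    genes_xpehh: set[str]
    genes_shared: set[str]
    islands_by_group: dict[str, list[ROHIsland]] = field(default_factory=dict)
    shared_islands: list[tuple[ROHIsland, ROHIsland, tuple[str, int, int]]] = field(
        default_factory=list
    )
    gene_flank_bp: int = 0


def intersect_top_sets(top_fst: pd.DataFrame, top_xpehh: pd.DataFrame) -> pd.DataFrame:
    """Markers in both top sets, ordered by (chrom, bp); match is by marker id."""
    shared_ids = set(top_fst["id"]) & set(top_xpehh["id"])
    out = top_fst[top_fst["id"].isin(shared_ids)][["chrom", "bp", "id"]].copy()
    out = out.merge(
        top_xpehh[["id"] + [c for c in ("z",) if c in top_xpehh.columns]], on="id", how="left"
    )
    return out.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)


def map_snps_to_genes(
    markers: pd.DataFrame, genes: list[GeneInterval], flank_bp: int = 0
) -> tuple[pd.DataFrame, set[str]]:
    """Map each marker (chrom, bp) to genes whose padded span contains it.

    Intervals are 1-based closed; a marker maps to every gene with
    ``start - flank <= bp <= end + flank`` on its chromosome.  Returns the
    per-marker table (column ``genes``, comma-joined, empty when none) and
    the deduplicated gene-symbol set.
    """
    rows = []
    all_genes: set[str] = set()
    for _, rec in markers.iterrows():
        hits = sorted(
            g.symbol for g in genes if g.contains(str(rec["chrom"]), int(rec["bp"]), flank_bp)
        )
        all_genes.update(hits)
        rows.append(",".join(hits))
    out = markers.copy()
    out["genes"] = rows
    return out, all_genes


def islands_overlap(
    islands_a: list[ROHIsland], islands_b: list[ROHIsland]
) -> list[tuple[ROHIsland, ROHIsland, tuple[str, int, int]]]:
    """All cross-group island pairs with positive-length closed-interval overlap."""
    pairs = []
    for ia in islands_a:
        for ib in islands_b:
            if ia.chrom != ib.chrom:
                continue
            lo = max(ia.start_bp, ib.start_bp)
            hi = min(ia.end_bp, ib.end_bp)
            if hi > lo:  # positive length
                pairs.append((ia, ib, (ia.chrom, lo, hi)))
    return pairs


def build_report(
    fst_df: pd.DataFrame,
    xpehh_df: pd.DataFrame,
    genes: list[GeneInterval],
    islands_by_group: dict[str, list[ROHIsland]] | None = None,
    gene_flank_bp: int = 0,
) -> SelectionReport:
    """Assemble the full cross-analysis report from the two scan tables."""
    top_fst = fst_df[fst_df["is_top"]].copy()
    top_xpehh = xpehh_df[xpehh_df["is_top"]].copy()
    shared = intersect_top_sets(top_fst, top_xpehh)
    _, genes_fst = map_snps_to_genes(top_fst, genes, gene_flank_bp)
    _, genes_xp = map_snps_to_genes(top_xpehh, genes, gene_flank_bp)
    shared_mapped, _ = map_snps_to_genes(shared, genes, gene_flank_bp)
    islands_by_group = islands_by_group or {}
    shared_islands = []
    if len(islands_by_group) == 2:
        ga, gb = sorted(islands_by_group)
        shared_islands = islands_overlap(islands_by_group[ga], islands_by_group[gb])
    return SelectionReport(
        top_fst=top_fst,
        top_xpehh=top_xpehh,
        shared=shared_mapped,
        genes_fst=genes_fst,
        genes_xpehh=genes_xp,
        genes_shared=genes_fst & genes_xp,
        islands_by_group=islands_by_group,
        shared_islands=shared_islands,
        gene_flank_bp=gene_flank_bp,
    )


def write_report(report: SelectionReport, out_dir: str | Path) -> None:
    """Write the report tables and a plain-text summary, deterministically ordered."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.top_fst.to_csv(out / "top_fst.tsv", sep="\t", index=False)
    report.top_xpehh.to_csv(out / "top_xpehh.tsv", sep="\t", index=False)
    report.shared.to_csv(out / "shared_snps.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": sorted(report.genes_shared)}).to_csv(
        out / "genes_shared.tsv", sep="\t", index=False
    )
    isl_rows = []
    for group in sorted(report.islands_by_group):
        for isl in report.islands_by_group[group]:
            isl_rows.append(
                dict(group=group, chrom=isl.chrom, start_bp=isl.start_bp, end_bp=isl.end_bp,
                     n_top_snps=isl.n_top_snps, peak_h_score=isl.peak_h_score)
            )
    pd.DataFrame(isl_rows, columns=["group", "chrom", "start_bp", "end_bp", "n_top_snps",
                                    "peak_h_score"]).to_csv(out / "islands.tsv", sep="\t", index=False)
    sh_rows = []
    for ia, ib, (chrom, lo, hi) in report.shared_islands:
        sh_rows.append(
            dict(chrom=chrom, overlap_start=lo, overlap_end=hi,
                 a_start=ia.start_bp, a_end=ia.end_bp, b_start=ib.start_bp, b_end=ib.end_bp)
        )
    pd.DataFrame(sh_rows, columns=["chrom", "overlap_start", "overlap_end", "a_start",
                                   "a_end", "b_start", "b_end"]).to_csv(
        out / "shared_islands.tsv", sep="\t", index=False
    )
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"gene_flank_bp\t{report.gene_flank_bp}\n")
        fh.write(f"n_top_fst_snps\t{len(report.top_fst)}\n")
        fh.write(f"n_top_xpehh_snps\t{len(report.top_xpehh)}\n")
        fh.write(f"n_shared_snps\t{len(report.shared)}\n")
        fh.write(f"n_genes_fst\t{len(report.genes_fst)}\n")
        fh.write(f"n_genes_xpehh\t{len(report.genes_xpehh)}\n")
        fh.write(f"n_genes_shared\t{len(report.genes_shared)}\n")
        for group in sorted(report.islands_by_group):
            fh.write(f"n_islands_{group}\t{len(report.islands_by_group[group])}\n")
        fh.write(f"n_shared_islands\t{len(report.shared_islands)}\n")
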