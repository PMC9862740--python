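"""End-to-end pipeline: QC -> structure -> ROH -> F_ST -> XP-EHH -> report.

Stages communicate through plain TSV/VCF artifacts so any one of them can be
re-run in isolation or swapped against an external tool's output.  A run
manifest records the configuration hash and seed for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .core_data import (
    GenotypePanel,
    HaplotypePanel,
    read_gene_table,
    read_ped_map,
    read_phased_vcf,
    write_bed,
    write_ped_map,
)
from .fst import fst_scan
from .report import build_report, write_report
from .roh import ROHParams, detect_roh, h_scores, top_hscore_islands
from .structure import classical_mds, ibs_distance
from .xpehh import EhhParams, xpehh_from_panels

log = logging.getLogger("dogsel")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place; echoed to the output dir."""

    ped: str = ""
    map: str = ""
    vcf: str = ""
    genes: str = ""
    out_dir: str = "dogsel_out"
    groups: dict[str, str] = field(default_factory=dict)  # breed -> group
    group_a: str = "LGD"  # XP-EHH numerator group
    group_b: str = "HSD"
    qc: qc_mod.QCParams = field(default_factory=qc_mod.QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    ehh: EhhParams = field(default_factory=EhhParams)
    smoothing_flank: int = 5
    top_fraction: float = 0.01
    island_merge_gap_bp: int = 500_000
    min_island_snps: int = 3
    gene_flank_bp: int = 0
    subsample: dict[str, int] = field(default_factory=dict)  # breed -> n_keep
    mds_components: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0,1)")
        if self.qc.min_maf > 0.5:
            raise ValueError("min_maf > 0.5 is not a minor-allele threshold")
        if self.smoothing_flank < 0:
            raise ValueError("smoothing_flank must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("qc", qc_mod.QCParams), ("roh", ROHParams), ("ehh", EhhParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    panel: GenotypePanel | None = None,
    hap: HaplotypePanel | None = None,
) -> dict:
    """Run every stage in order; returns a dict of in-memory stage results.

    ``panel``/``hap`` may be passed directly (library use); otherwise they
    are read from ``config.ped``/``config.map``/``config.vcf``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if panel is None:
        log.info("reading PED/MAP: %s %s", config.ped, config.map)
        panel = read_ped_map(config.ped, config.map, groups=config.groups)
    if hap is None and config.vcf:
        breeds = {s.id: s.breed for s in panel.samples}
        hap = read_phased_vcf(config.vcf, groups=config.groups, breeds=breeds)

    # --- QC ---------------------------------------------------------------
    panel, report = qc_mod.run_qc(panel, config.qc)
    for breed, n_keep in config.subsample.items():
        panel = qc_mod.subsample_group(panel, breed, n_keep, seed=config.seed)
    write_ped_map(panel, out / "qc.ped", out / "qc.map")
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"samples_in\t{report.n_samples_in}\n")
        fh.write(f"snps_in\t{report.n_snps_in}\n")
        fh.write(f"samples_retained\t{report.n_samples_retained}\n")
        fh.write(f"snps_retained\t{report.n_snps_retained}\n")
        for sid, reason in report.samples_removed:
            fh.write(f"sample_removed:{sid}\t{reason}\n")
        for name, count in report.snps_removed.items():
            fh.write(f"snps_removed:{name}\t{count}\n")
    if hap is not None:
        keep_ids = set(panel.sample_ids())
        keep_idx = [i for i, s in enumerate(hap.samples) if s.id in keep_ids]
        rows = [r for i in keep_idx for r in (2 * i, 2 * i + 1)]
        marker_keep = {(m.chrom, m.bp) for m in panel.markers}
        cols = [j for j, m in enumerate(hap.markers) if (m.chrom, m.bp) in marker_keep]
        hap = HaplotypePanel(
            samples=[hap.samples[i] for i in keep_idx],
            markers=[hap.markers[j] for j in cols],
            alleles=hap.alleles[np.ix_(rows, cols)],
        )
    log.info("QC: %d samples, %d SNPs retained", panel.n_samples, panel.n_markers)

    # --- population structure --------------------------------------------
    dist = ibs_distance(panel)
    mds = classical_mds(dist, k=config.mds_components)
    pd.DataFrame(dist.values, index=dist.ids, columns=dist.ids).to_csv(
        out / "distances.tsv", sep="\t"
    )
    mds_df = pd.DataFrame(
        mds.coordinates, columns=[f"C{i + 1}" for i in range(mds.coordinates.shape[1])]
    )
    mds_df.insert(0, "group", panel.groups())
    mds_df.insert(0, "sample", panel.sample_ids())
    mds_df.to_csv(out / "mds.tsv", sep="\t", index=False)

    # --- ROH and islands per group ----------------------------------------
    segments = detect_roh(panel, config.roh)
    seg_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in segments],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "n_missing"],
    )
    seg_df.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    islands_by_group = {}
    hs_frames = []
    for group in sorted({s.group for s in panel.samples}):
        track = h_scores(segments, panel, group)
        hs_frames.append(pd.Series(track, name=group))
        islands_by_group[group] = top_hscore_islands(
            track, panel.markers, group=group, top_fraction=config.top_fraction,
            merge_gap_bp=config.island_merge_gap_bp, min_island_snps=config.min_island_snps,
        )
    hs_df = pd.concat(hs_frames, axis=1)
    hs_df.insert(0, "bp", panel.bp())
    hs_df.insert(0, "chrom", panel.chroms())
    hs_df.to_csv(out / "hscores.tsv", sep="\t", index=False)
    write_bed(
        [
            (i.chrom, i.start_bp, i.end_bp, f"{g}_island")
            for g, isls in sorted(islands_by_group.items())
            for i in isls
        ],
        out / "islands.bed",
    )

    # --- between-group scans ----------------------------------------------
    fst_df = fst_scan(
        panel, config.group_a, config.group_b,
        flank=config.smoothing_flank, top_fraction=config.top_fraction,
    )
    fst_df.to_csv(out / "fst.tsv", sep="\t", index=False)

    xpehh_df = None
    if hap is not None:
        xpehh_df = xpehh_from_panels(
            hap, config.group_a, config.group_b, params=config.ehh,
            top_fraction=config.top_fraction,
        )
        xpehh_df.to_csv(out / "xpehh.tsv", sep="\t", index=False)

    # --- report -------------------------------------------------------------
    genes = read_gene_table(config.genes) if config.genes else []
    if xpehh_df is not None:
        sel_report = build_report(
            fst_df, xpehh_df, genes, islands_by_group, gene_flank_bp=config.gene_flank_bp
        )
        write_report(sel_report, out / "report")
    else:
        sel_report = None

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": panel.n_samples,
        "n_markers": panel.n_markers,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    return {
        "panel": panel,
        "hap": hap,
        "qc_report": report,
        "mds": mds,
        "segments": segments,
        "islands": islands_by_group,
        "fst": fst_df,
        "xpehh": xpehh_df,
        "report": sel_report,
        "manifest": manifest,
    }
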