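"""Synthetic two-group, multi-breed SNP panels with known ground truth.

The generator emulates the study design the pipeline targets: two groups of
dog breeds (livestock guardians vs herding shepherds) genotyped on a dense
SNP array, with three kinds of structure injected on top of neutral drift:

* breed-level differentiation from a shared ancestral allele-frequency pool
  under the Balding-Nichols model (Beta-distributed breed frequencies with
  drift parameter ``F``),
* linkage disequilibrium from a founder-mosaic copying model: each sample
  haplotype is a crossover mosaic of a finite founder pool, so extended
  haplotype homozygosity decays with distance at a rate set by
  ``recomb_rate`` — a deliberate, documented non-biological stand-in for a
  coalescent simulation,
* localized signals with recorded truth: *sweeps* (one core haplotype copied
  to a chosen frequency in one group) and *autozygosity* (a chosen fraction
  of one group's samples made runs-of-homozygosity carriers over an
  interval).

Every draw is controlled by a single seed; identical parameters and seed
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import (
    MISSING,
    GenotypePanel,
    HaplotypePanel,
    Marker,
    SampleRecord,
    write_ped_map,
    write_phased_vcf,
)

__all__ = [
    "SimulationParams",
    "SweepSpec",
    "AutozygositySpec",
    "draw_breed_freqs",
    "sample_mosaic_haplotypes",
    "inject_sweep",
    "inject_autozygosity",
    "simulate_dataset",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Deterministic carrier-count rounding: 0.5 always rounds up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SweepSpec:
    """A near-fixed core haplotype private to one group.

    ``carrier_freq`` is the frequency of the shared core haplotype among the
    target group's haplotypes over ``[center_bp - span_bp/2, center_bp +
    span_bp/2]``; ``background_freq`` its frequency in the other group.
    """

    chrom: str
    center_bp: int
    span_bp: int
    target_group: str
    carrier_freq: float
    background_freq: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_freq < self.carrier_freq <= 1.0):
            raise ValueError(
                f"need 0 <= background_freq < carrier_freq <= 1, got "
                f"{self.background_freq}, {self.carrier_freq}"
            )

    @property
    def start_bp(self) -> int:
        return self.center_bp - self.span_bp // 2

    @property
    def end_bp(self) -> int:
        return self.center_bp + self.span_bp // 2


@dataclass(frozen=True)
class AutozygositySpec:
    """A homozygous-by-descent interval shared by part of one group."""

    chrom: str
    start_bp: int
    end_bp: int
    target_group: str
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_fraction <= 1.0):
            raise ValueError(f"carrier_fraction must be in (0,1], got {self.carrier_fraction}")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass(frozen=True)
class SimulationParams:
    """Generator configuration.

    ``breeds`` lists (breed code, group, n samples).  Defaults mirror the
    target study's cohort: four livestock-guardian and five herding breeds,
    ~72 dogs per group, on a dense autosomal SNP map.
    """

    breeds: tuple[tuple[str, str, int], ...] = (
        ("MARM", "LGD", 20), ("MANN", "LGD", 12), ("SILA", "LGD", 14), ("FONN", "LGD", 30),
        ("DORO", "HSD", 15), ("APUA", "HSD", 19), ("BERG", "HSD", 15),
        ("PALA", "HSD", 10), ("LUGI", "HSD", 23),
    )
    n_chrom: int = 2
    chrom_length_bp: int = 20_000_000
    n_snp_per_chrom: int = 2_000
    fst_drift: float = 0.1  # per-breed Balding-Nichols F
    founder_pool_size: int = 100  # founder haplotypes per breed
    recomb_rate: float = 1e-8  # switch points per bp in the mosaic sampler
    missing_rate: float = 0.0  # per-call missingness injected into genotypes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_drift < 1.0):
            raise ValueError("fst_drift must be in [0,1)")
        if self.n_chrom < 1 or self.n_snp_per_chrom < 1 or self.founder_pool_size < 1:
            raise ValueError("counts must be positive")
        for _, _, n in self.breeds:
            if n < 1:
                raise ValueError("breed sample counts must be positive")


def draw_breed_freqs(
    ancestral_freq: np.ndarray | float, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw of breed allele frequencies.

    Beta with mean ``p`` and variance ``F*p*(1-p)``; ``F=0`` returns the
    ancestral frequencies exactly.
    """
    p = np.atleast_1d(np.asarray(ancestral_freq, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral_freq must be in (0,1)")
    if not (0.0 <= F < 1.0):
        raise ValueError(f"F must be in [0,1), got {F}")
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def sample_mosaic_haplotypes(
    founder_pool: np.ndarray,
    n: int,
    recomb_rate: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` haplotypes as crossover mosaics of a founder pool.

    Switch points along the chromosome arrive as a Poisson process with rate
    ``recomb_rate`` per bp; between switches the haplotype copies one
    uniformly chosen founder.  ``recomb_rate=0`` returns exact founder
    copies.
    """
    founder_pool = np.asarray(founder_pool, dtype=np.int8)
    if founder_pool.ndim != 2 or founder_pool.shape[0] == 0:
        raise ValueError("founder pool must be a nonempty 2-D haplotype array")
    n_founders, n_snp = founder_pool.shape
    positions = np.asarray(positions, dtype=np.int64)
    length = int(positions[-1] - positions[0]) if n_snp > 1 else 0

    out = np.empty((n, n_snp), dtype=np.int8)
    for i in range(n):
        n_switch = rng.poisson(recomb_rate * length) if length > 0 and recomb_rate > 0 else 0
        if n_switch == 0:
            out[i] = founder_pool[rng.integers(n_founders)]
            continue
        cuts = np.sort(rng.integers(positions[0], positions[-1] + 1, size=n_switch))
        bounds = np.searchsorted(positions, cuts, side="right")
        segs = np.concatenate(([0], bounds, [n_snp]))
        for s0, s1 in zip(segs[:-1], segs[1:]):
            if s1 > s0:
                out[i, s0:s1] = founder_pool[rng.integers(n_founders), s0:s1]
    return out


def _span_columns(panel: HaplotypePanel, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
    bp = panel.bp() if hasattr(panel, "bp") else np.array([m.bp for m in panel.markers])
    chroms = np.array([m.chrom for m in panel.markers])
    return np.flatnonzero((chroms == chrom) & (bp >= start_bp) & (bp <= end_bp))


def inject_sweep(panel: HaplotypePanel, spec: SweepSpec, seed: int) -> HaplotypePanel:
    """Copy one donor haplotype over the sweep span onto a fraction of each group.

    The donor is the first target-group haplotype; ``round_half_up(freq * n)``
    haplotypes per group (chosen without replacement, seeded) receive the
    donor's alleles inside the span.  Haplotypes are untouched outside it.
    """
    cols = _span_columns(panel, spec.chrom, spec.start_bp, spec.end_bp)
    if cols.size < 2:
        raise ValueError(
            f"sweep span {spec.chrom}:{spec.start_bp}-{spec.end_bp} covers "
            f"{cols.size} markers; need >= 2"
        )
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    target_rows = panel.group_rows(spec.target_group)
    if target_rows.size == 0:
        raise ValueError(f"no samples in target group {spec.target_group!r}")
    other_rows = np.setdiff1d(
        np.arange(alleles.shape[0]), target_rows, assume_unique=False
    )
    donor = alleles[target_rows[0], cols].copy()
    for rows, freq in ((target_rows, spec.carrier_freq), (other_rows, spec.background_freq)):
        k = round_half_up(freq * rows.size)
        if k == 0:
            continue
        chosen = rng.choice(rows, size=k, replace=False)
        alleles[np.ix_(chosen, cols)] = donor
    return HaplotypePanel(samples=list(panel.samples), markers=list(panel.markers), alleles=alleles)


def inject_autozygosity(
    panel: HaplotypePanel, spec: AutozygositySpec, seed: int
) -> tuple[HaplotypePanel, list[str]]:
    """Make a seeded fraction of target-group samples homozygous over an interval.

    For each chosen carrier, haplotype row ``2k+1`` is overwritten by row
    ``2k`` across the interval's markers.  Returns the modified panel and the
    carrier sample ids.
    """
    cols = _span_columns(panel, spec.chrom, spec.start_bp, spec.end_bp)
    if cols.size == 0:
        raise ValueError(
            f"autozygosity interval {spec.chrom}:{spec.start_bp}-{spec.end_bp} covers 0 markers"
        )
    rng = np.random.default_rng(seed)
    target_idx = np.array(
        [i for i, s in enumerate(panel.samples) if s.group == spec.target_group], dtype=np.intp
    )
    if target_idx.size == 0:
        raise ValueError(f"no samples in target group {spec.target_group!r}")
    k = round_half_up(spec.carrier_fraction * target_idx.size)
    carriers = np.sort(rng.choice(target_idx, size=k, replace=False))
    alleles = panel.alleles.copy()
    for i in carriers:
        alleles[np.ix_([2 * i + 1], cols)] = alleles[np.ix_([2 * i], cols)]
    out = HaplotypePanel(samples=list(panel.samples), markers=list(panel.markers), alleles=alleles)
    return out, [panel.samples[i].id for i in carriers]


def _make_markers(params: SimulationParams, rng: np.random.Generator) -> list[Marker]:
    markers: list[Marker] = []
    for c in range(1, params.n_chrom + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, params.chrom_length_bp + 1),
                size=params.n_snp_per_chrom,
                replace=False,
            )
        )
        for j, bp in enumerate(pos):
            bp = int(bp)
            markers.append(
                Marker(
                    chrom=str(c),
                    bp=bp,
                    id=f"snp{c}_{j}",
                    alleles=("A", "G"),
                    cm=bp * 1e-6,  # 1 cM/Mb
                )
            )
    return markers


def simulate_dataset(
    params: SimulationParams,
    sweeps: Sequence[SweepSpec] = (),
    autozygosity_specs: Sequence[AutozygositySpec] = (),
    out_dir: str | Path | None = None,
) -> tuple[HaplotypePanel, GenotypePanel, dict]:
    """Generate a full two-group dataset with recorded truth.

    Returns the phased haplotype panel, the matching dosage panel (with
    missingness injected at ``params.missing_rate``), and a truth record
    listing sweep/autozygosity intervals and carrier sample ids.  When
    ``out_dir`` is given, writes ``data.ped``/``data.map``, ``data.vcf``,
    ``truth.tsv`` and a parameter echo.
    """
    rng = np.random.default_rng(params.seed)
    markers = _make_markers(params, rng)
    n_markers = len(markers)
    chrom_labels = np.array([m.chrom for m in markers])
    positions = np.array([m.bp for m in markers], dtype=np.int64)

    anc = rng.uniform(0.05, 0.95, size=n_markers)
    samples: list[SampleRecord] = []
    hap_blocks: list[np.ndarray] = []
    for breed, group, n in params.breeds:
        breed_freq = draw_breed_freqs(anc, params.fst_drift, rng)
        founders = (rng.random((params.founder_pool_size, n_markers)) < breed_freq).astype(np.int8)
        # A sample's two haplotypes draw from disjoint founder halves so the
        # copying model itself never creates within-individual autozygosity:
        # injected ROH truth stays exact.
        half = max(1, params.founder_pool_size // 2)
        rows = np.empty((2 * n, n_markers), dtype=np.int8)
        for c in np.unique(chrom_labels):
            cols = np.flatnonzero(chrom_labels == c)
            rows[np.ix_(np.arange(0, 2 * n, 2), cols)] = sample_mosaic_haplotypes(
                founders[:half][:, cols], n, params.recomb_rate, positions[cols], rng
            )
            rows[np.ix_(np.arange(1, 2 * n, 2), cols)] = sample_mosaic_haplotypes(
                founders[half:][:, cols], n, params.recomb_rate, positions[cols], rng
            )
        hap_blocks.append(rows)
        samples += [SampleRecord(id=f"{breed}{k:03d}", breed=breed, group=group) for k in range(n)]

    hap = HaplotypePanel(samples=samples, markers=markers, alleles=np.vstack(hap_blocks))

    truth: dict = {"sweeps": [], "autozygosity": [], "overlap_flags": []}
    derive = np.random.default_rng(params.seed + 1)
    for spec in sweeps:
        hap = inject_sweep(hap, spec, seed=int(derive.integers(2**31)))
        truth["sweeps"].append(dataclasses.asdict(spec))
    for spec in autozygosity_specs:
        hap, carriers = inject_autozygosity(hap, spec, seed=int(derive.integers(2**31)))
        rec = dataclasses.asdict(spec)
        rec["carriers"] = carriers
        truth["autozygosity"].append(rec)
    for sw in sweeps:
        for az in autozygosity_specs:
            if sw.chrom == az.chrom and sw.start_bp <= az.end_bp and az.start_bp <= sw.end_bp:
                truth["overlap_flags"].append(
                    f"sweep@{sw.chrom}:{sw.start_bp}-{sw.end_bp} overlaps "
                    f"autozygosity@{az.chrom}:{az.start_bp}-{az.end_bp}"
                )

    geno = hap.collapse()
    if params.missing_rate > 0:
        mask = derive.random(geno.dosage.shape) < params.missing_rate
        dosage = geno.dosage.copy()
        dosage[mask] = MISSING
        geno = GenotypePanel(samples=geno.samples, markers=geno.markers, dosage=dosage)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ped_map(geno, out / "data.ped", out / "data.map")
        write_phased_vcf(hap, out / "data.vcf")
        _write_truth(truth, out / "truth.tsv")
        with open(out / "params.txt", "w") as fh:
            fh.write(repr(params) + "\n")

    return hap, geno, truth


def _write_truth(truth: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tchrom\tstart_bp\tend_bp\ttarget_group\tparam\tcarriers\tflags\n")
        for s in truth["sweeps"]:
            start = s["center_bp"] - s["span_bp"] // 2
            end = s["center_bp"] + s["span_bp"] // 2
            fh.write(
                f"sweep\t{s['chrom']}\t{start}\t{end}\t{s['target_group']}\t"
                f"carrier_freq={s['carrier_freq']};background_freq={s['background_freq']}\t.\t.\n"
            )
        for a in truth["autozygosity"]:
            fh.write(
                f"autozygosity\t{a['chrom']}\t{a['start_bp']}\t{a['end_bp']}\t"
                f"{a['target_group']}\tcarrier_fraction={a['carrier_fraction']}\t"
                f"{','.join(a['carriers'])}\t.\n"
            )
        for flag in truth["overlap_flags"]:
            fh.write(f"flag\t.\t.\t.\t.\t.\t.\t{flag}\n")
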