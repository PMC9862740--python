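"""Domain types and file I/O for the selection-signature pipeline.

Genotypes travel as a :class:`GenotypePanel` (samples x markers alt-allele
dosage matrix, values 0/1/2 with ``MISSING = -1``), phased haplotypes as a
:class:`HaplotypePanel` (2*samples x markers binary matrix, rows ``2k`` and
``2k+1`` belonging to sample ``k``).  Coordinates are 1-based inclusive base
pairs throughout, matching PLINK MAP files and standard gene tables; BED
output converts to 0-based half-open at write time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "Marker",
    "SampleRecord",
    "GenotypePanel",
    "HaplotypePanel",
    "GeneInterval",
    "PedMapError",
    "VcfFormatError",
    "GeneTableError",
    "read_ped_map",
    "write_ped_map",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_gene_table",
    "write_bed",
]


class PedMapError(ValueError):
    """Malformed PLINK text PED/MAP input."""


class VcfFormatError(ValueError):
    """VCF record violates the phased-biallelic contract."""


class GeneTableError(ValueError):
    """Malformed gene annotation table."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP on an autosome.

    ``cm`` is the genetic position in centimorgans; ``None`` means the panel
    operates in physical-distance mode.
    """

    chrom: str
    bp: int
    id: str
    alleles: tuple[str, str] = ("A", "B")  # (ref, alt)
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"marker {self.id}: bp must be >= 1, got {self.bp}")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"marker {self.id}: ref and alt alleles must differ")


@dataclass(frozen=True)
class SampleRecord:
    """A genotyped dog: sample id, breed code, and comparison group."""

    id: str
    breed: str
    group: str


@dataclass(frozen=True)
class GeneInterval:
    """A gene's span on the reference assembly, 1-based inclusive."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, bp: int, flank: int = 0) -> bool:
        return chrom == self.chrom and self.start - flank <= bp <= self.end + flank


def _check_marker_order(markers: Sequence[Marker]) -> None:
    for a, b in zip(markers, markers[1:]):
        if a.chrom == b.chrom and b.bp <= a.bp:
            raise ValueError(
                f"markers not strictly increasing within chromosome {a.chrom}: "
                f"{a.id}@{a.bp} before {b.id}@{b.bp}"
            )


@dataclass
class GenotypePanel:
    """Samples x markers matrix of alt-allele dosages with sample metadata."""

    samples: list[SampleRecord]
    markers: list[Marker]
    dosage: np.ndarray  # int8, shape (n_samples, n_markers), values {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        _check_marker_order(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    def breeds(self) -> np.ndarray:
        return np.array([s.breed for s in self.samples])

    def bp(self) -> np.ndarray:
        return np.array([m.bp for m in self.markers], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers])

    def subset_samples(self, keep: Sequence[int]) -> "GenotypePanel":
        keep = list(keep)
        return GenotypePanel(
            samples=[self.samples[i] for i in keep],
            markers=self.markers,
            dosage=self.dosage[keep, :].copy(),
        )

    def subset_markers(self, keep: Sequence[int]) -> "GenotypePanel":
        keep = list(keep)
        return GenotypePanel(
            samples=self.samples,
            markers=[self.markers[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: rows 2k and 2k+1 are sample k's two haplotypes."""

    samples: list[SampleRecord]
    markers: list[Marker]
    alleles: np.ndarray  # int8, shape (2*n_samples, n_markers), values {0,1}

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.markers)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"2*{len(self.samples)} x {len(self.markers)}"
            )
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1 (phased, complete)")
        _check_marker_order(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def bp(self) -> np.ndarray:
        return np.array([m.bp for m in self.markers], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers])

    def collapse(self) -> GenotypePanel:
        """Sum row pairs into the matching dosage panel."""
        dosage = (self.alleles[0::2, :] + self.alleles[1::2, :]).astype(np.int8)
        return GenotypePanel(samples=list(self.samples), markers=list(self.markers), dosage=dosage)

    def group_rows(self, group: str) -> np.ndarray:
        """Haplotype-row indices belonging to samples of ``group``."""
        idx = [i for i, s in enumerate(self.samples) if s.group == group]
        return np.array([r for i in idx for r in (2 * i, 2 * i + 1)], dtype=np.intp)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    groups: dict[str, str] | None = None,
) -> GenotypePanel:
    """Read a PLINK text fileset into a :class:`GenotypePanel`.

    The alt allele at each marker is defined as the minor allele among
    non-missing calls (tie: the lexicographically larger allele is alt, i.e.
    the smaller is ref).  The PED family-ID column is taken as the breed code;
    ``groups`` maps breed code to comparison group (default: breed itself).

    Raises :class:`PedMapError` on allele-count mismatches against the MAP or
    on tri-allelic markers.
    """
    map_rows: list[tuple[str, str, float | None, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedMapError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, mid, cm_s, bp_s = parts
            cm = float(cm_s)
            map_rows.append((chrom, mid, cm if cm != 0 else None, int(bp_s)))
    n_markers = len(map_rows)

    sample_ids: list[str] = []
    breeds: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PedMapError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"(6 metadata + 2 alleles x {n_markers} markers), got {len(parts)}"
                )
            breeds.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n_samples = len(sample_ids)
    alleles = np.array(allele_rows, dtype="U8").reshape(n_samples, n_markers, 2) if n_samples else np.empty((0, n_markers, 2), dtype="U8")

    dosage = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    markers: list[Marker] = []
    for j, (chrom, mid, cm, bp) in enumerate(map_rows):
        col = alleles[:, j, :]
        miss = (col == "0").any(axis=1)
        observed = sorted(set(col[~miss].ravel().tolist()))
        if len(observed) > 2:
            raise PedMapError(f"marker {mid}: more than 2 distinct non-missing alleles: {observed}")
        if len(observed) == 0:
            ref, alt = "A", "B"  # all-missing marker: placeholder orientation
        elif len(observed) == 1:
            ref, alt = observed[0], "B" if observed[0] != "B" else "A"
        else:
            a, b = observed
            na = int((col == a).sum())
            nb = int((col == b).sum())
            if na > nb or (na == nb and a < b):
                ref, alt = a, b
            else:
                ref, alt = b, a
        markers.append(Marker(chrom=chrom, bp=bp, id=mid, alleles=(ref, alt), cm=cm))
        if n_samples:
            dosage[~miss, j] = (col[~miss] == alt).sum(axis=1)

    if groups is None:
        groups = {}
    samples = [
        SampleRecord(id=sid, breed=br, group=groups.get(br, br))
        for sid, br in zip(sample_ids, breeds)
    ]
    return GenotypePanel(samples=samples, markers=markers, dosage=dosage)


def write_ped_map(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as a PLINK text fileset (breed code in the family column)."""
    with open(map_path, "w") as fh:
        for m in panel.markers:
            cm = m.cm if m.cm is not None else 0
            fh.write(f"{m.chrom}\t{m.id}\t{cm:g}\t{m.bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [s.breed, s.id, "0", "0", "0", "-9"]
            row = panel.dosage[i]
            for j, m in enumerate(panel.markers):
                ref, alt = m.alleles
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [ref, ref]
                elif d == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    vcf_path: str | Path,
    groups: dict[str, str] | None = None,
    breeds: dict[str, str] | None = None,
) -> HaplotypePanel:
    """Read a phased biallelic VCF into a :class:`HaplotypePanel`.

    Every GT must use the phased ``|`` separator and be fully called; records
    with ``/`` raise :class:`VcfFormatError` instructing the user to phase
    upstream.  ``breeds``/``groups`` attach sample metadata by sample id and
    breed code respectively.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    markers: list[Marker] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise VcfFormatError(
                f"{var.CHROM}:{var.POS}: multi-allelic record (ALT={var.ALT}); biallelic input required"
            )
        gts = np.asarray(var.genotype.array())  # columns: allele0, allele1, phased flag
        if (gts[:, :2] < 0).any():
            raise VcfFormatError(
                f"{var.CHROM}:{var.POS}: missing GT call; phased complete haplotypes required"
            )
        if not gts[:, 2].all():
            raise VcfFormatError(
                f"{var.CHROM}:{var.POS}: unphased '/' genotype separator; "
                "phase the data upstream (e.g. with BEAGLE) before haplotype analysis"
            )
        markers.append(
            Marker(chrom=var.CHROM, bp=var.POS, id=var.ID or f"{var.CHROM}:{var.POS}",
                   alleles=(var.REF, var.ALT[0]))
        )
        cols.append(gts[:, :2].reshape(-1).astype(np.int8))
    vcf.close()

    breeds = breeds or {}
    groups = groups or {}
    samples = []
    for sid in sample_ids:
        br = breeds.get(sid, "NA")
        samples.append(SampleRecord(id=sid, breed=br, group=groups.get(br, br)))
    alleles = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypePanel(samples=samples, markers=markers, alleles=alleles)


def write_phased_vcf(panel: HaplotypePanel, vcf_path: str | Path) -> None:
    """Write a haplotype panel as a minimal phased VCF v4.2."""
    chrom_order: list[str] = []
    for m in panel.markers:
        if m.chrom not in chrom_order:
            chrom_order.append(m.chrom)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dogsel\n")
        for c in chrom_order:
            last = max(m.bp for m in panel.markers if m.chrom == c)
            fh.write(f"##contig=<ID={c},length={last + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(s.id for s in panel.samples) + "\n")
        for j, m in enumerate(panel.markers):
            col = panel.alleles[:, j]
            gts = "\t".join(f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(panel.n_samples))
            fh.write(f"{m.chrom}\t{m.bp}\t{m.id}\t{m.alleles[0]}\t{m.alleles[1]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene tables and BED output
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneInterval]:
    """Read a headered CSV/TSV gene table (symbol, chrom, start, end).

    Returns intervals sorted by (chrom, start).  Non-integer coordinates
    (including stray thousands separators) and start > end records raise
    :class:`GeneTableError` with the offending line number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".bed") else ","
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GeneTableError(f"{path}: empty file, header required")
        names = [h.strip().lower() for h in header.split(sep)]
        try:
            i_sym = names.index("symbol")
            i_chr = names.index("chrom")
            i_start = names.index("start")
            i_end = names.index("end")
        except ValueError as exc:
            raise GeneTableError(f"{path}: header must contain symbol, chrom, start, end") from exc
        genes: list[GeneInterval] = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(sep)]
            try:
                start = int(parts[i_start])
                end = int(parts[i_end])
            except (ValueError, IndexError) as exc:
                raise GeneTableError(f"{path}:{lineno}: malformed coordinate field") from exc
            if start > end:
                raise GeneTableError(f"{path}:{lineno}: start {start} > end {end}")
            genes.append(GeneInterval(symbol=parts[i_sym], chrom=parts[i_chr], start=start, end=end))
    genes.sort(key=lambda g: (_chrom_key(g.chrom), g.start))
    return genes


def _chrom_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (10**6, chrom)


def packaged_gene_table() -> list[GeneInterval]:
    """The packaged CanFam3.1 gene fixture (29 genes shared by both scans)."""
    return read_gene_table(Path(__file__).parent / "data" / "canfam31_genes.csv")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write 1-based inclusive (chrom, start, end, name) intervals as BED.

    BED is 0-based half-open: start becomes start-1, end stays.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
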