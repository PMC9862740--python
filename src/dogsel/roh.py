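"""Runs of homozygosity, per-marker H-scores, and ROH islands.

An ROH is called directly from its defining criteria, not from a sliding
window heuristic: a maximal stretch of consecutive markers that (i) contains
at least ``min_snps`` homozygous SNPs, (ii) spans at least ``min_length_bp``,
(iii) averages no more than ``max_bp_per_snp`` per homozygous SNP, and
(iv) never jumps more than ``max_gap_bp`` between consecutive markers.
``max_het`` heterozygous calls (default 0) and ``max_missing`` missing calls
(default 5) are tolerated inside a run; run bounds are always homozygous
markers.

The H-score of a marker within a group is the fraction of the group's
individuals whose ROH cover it.  Islands are clusters of top-percentile
H-score markers, merged within ``merge_gap_bp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import MISSING, GenotypePanel, Marker

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHIsland",
    "detect_roh_sample",
    "detect_roh",
    "h_scores",
    "top_hscore_islands",
    "nearest_rank_threshold",
]


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 50
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 100_000
    max_bp_per_snp: int = 50_000  # density >= 1 SNP per 50 kb
    max_het: int = 0
    max_missing: int = 5

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_length_bp, self.max_gap_bp, self.max_bp_per_snp) <= 0:
            raise ValueError("ROH length/density parameters must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het and max_missing must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int  # homozygous markers in the run
    n_missing: int


@dataclass(frozen=True)
class ROHIsland:
    group: str
    chrom: str
    start_bp: int
    end_bp: int
    n_top_snps: int
    peak_h_score: float


def _chrom_blocks(markers: list[Marker]) -> list[tuple[str, int, int]]:
    """(chrom, start_index, stop_index) per chromosome, in marker order."""
    blocks = []
    start = 0
    for j in range(1, len(markers) + 1):
        if j == len(markers) or markers[j].chrom != markers[start].chrom:
            blocks.append((markers[start].chrom, start, j))
            start = j
    return blocks


def detect_roh_sample(
    dosage_row: np.ndarray, markers: list[Marker], params: ROHParams | None = None,
    sample_id: str = "?",
) -> list[ROHSegment]:
    """Call ROH segments for one sample.

    Markers must be sorted by (chrom, bp); segments never span a gap larger
    than ``max_gap_bp`` and their bounds are the first/last homozygous marker
    of the run.
    """
    params = params or ROHParams()
    dosage_row = np.asarray(dosage_row)
    bp = np.array([m.bp for m in markers], dtype=np.int64)
    segments: list[ROHSegment] = []
    for chrom, c0, c1 in _chrom_blocks(list(markers)):
        if np.any(np.diff(bp[c0:c1]) <= 0):
            raise ValueError(f"markers unsorted on chromosome {chrom}")
        # split at oversized gaps, then scan each piece
        gap_breaks = c0 + 1 + np.flatnonzero(np.diff(bp[c0:c1]) > params.max_gap_bp)
        pieces = np.split(np.arange(c0, c1), gap_breaks - c0)
        for piece in pieces:
            if piece.size == 0:
                continue
            segments += _scan_piece(dosage_row, bp, piece, params, chrom, sample_id)
    return segments


def _scan_piece(
    dosage: np.ndarray, bp: np.ndarray, idx: np.ndarray, params: ROHParams,
    chrom: str, sample_id: str,
) -> list[ROHSegment]:
    """Maximal windows with <= max_het het and <= max_missing missing calls."""
    d = dosage[idx]
    is_het = d == 1
    is_miss = d == MISSING
    n = idx.size
    out: list[ROHSegment] = []
    r = 0
    het = miss = 0
    prev_r = -1
    for l in range(n):
        if r < l:
            r = l
            het = miss = 0
        while r < n:
            nh = het + int(is_het[r])
            nm = miss + int(is_miss[r])
            if nh > params.max_het or nm > params.max_missing:
                break
            het, miss = nh, nm
            r += 1
        if r > prev_r and r > l:  # maximal window [l, r)
            seg = _trim_and_check(d, bp[idx], l, r, params, chrom, sample_id)
            if seg is not None and (not out or seg != out[-1]):
                out.append(seg)
            prev_r = r
        if r > l:
            het -= int(is_het[l])
            miss -= int(is_miss[l])
    return out


def _trim_and_check(
    d: np.ndarray, pos: np.ndarray, l: int, r: int, params: ROHParams,
    chrom: str, sample_id: str,
) -> ROHSegment | None:
    hom = (d == 0) | (d == 2)
    span_idx = np.flatnonzero(hom[l:r])
    if span_idx.size == 0:
        return None
    a, b = l + span_idx[0], l + span_idx[-1]  # trim to homozygous ends
    n_hom = int(hom[a : b + 1].sum())
    n_miss = int((d[a : b + 1] == MISSING).sum())
    span = int(pos[b] - pos[a] + 1)
    if n_hom < params.min_snps:
        return None
    if span < params.min_length_bp:
        return None
    if span / n_hom > params.max_bp_per_snp:
        return None
    return ROHSegment(
        sample_id=sample_id, chrom=chrom, start_bp=int(pos[a]), end_bp=int(pos[b]),
        n_snps=n_hom, n_missing=n_miss,
    )


def detect_roh(panel: GenotypePanel, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH for every sample in the panel."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for i, s in enumerate(panel.samples):
        segments += detect_roh_sample(panel.dosage[i], panel.markers, params, sample_id=s.id)
    return segments


def h_scores(
    segments: list[ROHSegment], panel: GenotypePanel, group: str
) -> np.ndarray:
    """Per-marker H-score for one group.

    H-score = (number of group members whose ROH cover the marker) divided by
    the group size; marker coverage is closed-interval on bp.
    """
    members = [s.id for s in panel.samples if s.group == group]
    if not members:
        raise ValueError(f"no samples in group {group!r}")
    member_row = {sid: k for k, sid in enumerate(members)}
    bp = panel.bp()
    chroms = panel.chroms()
    covered = np.zeros((len(members), panel.n_markers), dtype=bool)
    for seg in segments:
        k = member_row.get(seg.sample_id)
        if k is None:
            continue
        cols = (chroms == seg.chrom) & (bp >= seg.start_bp) & (bp <= seg.end_bp)
        covered[k, cols] = True
    return covered.sum(axis=0) / len(members)


def nearest_rank_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Nearest-rank top-percentile cut of the empirical distribution.

    The top set holds exactly the ceil(top_fraction * n) largest values (plus
    ties); the threshold returned is the smallest of those, so membership is
    ``value >= threshold``.  E.g. values 1..1000 at 1% -> threshold 991.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty value array")
    k = int(np.ceil(top_fraction * n))  # size of the top set
    k = min(max(k, 1), n)
    return float(v[n - k])


def top_hscore_islands(
    track: np.ndarray,
    markers: list[Marker],
    group: str = "",
    top_fraction: float = 0.01,
    merge_gap_bp: int = 500_000,
    min_island_snps: int = 3,
) -> list[ROHIsland]:
    """Merge top-percentile H-score markers into ROH islands.

    The threshold is the nearest-rank (1 - top_fraction) quantile of the
    group's per-marker H-scores; markers at or above it are island members.
    Same-chromosome members closer than ``merge_gap_bp`` merge; islands with
    fewer than ``min_island_snps`` members are dropped.
    """
    track = np.asarray(track, dtype=float)
    if track.max() == 0:
        warnings.warn("all H-scores are zero; no islands", stacklevel=2)
        return []
    thr = nearest_rank_threshold(track, top_fraction)
    member = track >= thr
    if thr == 0:
        member = track > 0  # degenerate threshold: only covered markers qualify
    bp = np.array([m.bp for m in markers], dtype=np.int64)
    chroms = np.array([m.chrom for m in markers])
    idx = np.flatnonzero(member)
    islands: list[ROHIsland] = []
    cluster: list[int] = []

    def flush(cluster: list[int]) -> None:
        if len(cluster) >= min_island_snps:
            islands.append(
                ROHIsland(
                    group=group,
                    chrom=str(chroms[cluster[0]]),
                    start_bp=int(bp[cluster[0]]),
                    end_bp=int(bp[cluster[-1]]),
                    n_top_snps=len(cluster),
                    peak_h_score=float(track[cluster].max()),
                )
            )

    for j in idx:
        if cluster and (chroms[j] != chroms[cluster[-1]] or bp[j] - bp[cluster[-1]] > merge_gap_bp):
            flush(cluster)
            cluster = []
        cluster.append(int(j))
    if cluster:
        flush(cluster)
    return islands
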