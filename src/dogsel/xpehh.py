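"""Cross-population extended haplotype homozygosity (XP-EHH).

EHH at a boundary marker is the probability that two haplotypes drawn
without replacement from the group are identical over the whole stretch
from the core to the boundary (inclusive):

    EHH = sum_h C(n_h, 2) / C(n, 2)

over the distinct extended haplotypes ``h``.  iHH integrates the group's
EHH decay curve (trapezoid rule over physical or genetic distance) outward
from the core in both directions, stopping where the *pooled* two-group EHH
falls below ``cutoff`` so both groups share identical integration
boundaries.  The raw statistic is ln(iHH_A / iHH_B), z-normalized over all
defined cores genome-wide; large positive scores mean unusually long
haplotypes (a putative sweep) in group A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import HaplotypePanel
from .roh import nearest_rank_threshold

__all__ = ["EhhParams", "ehh_at", "ihh", "xpehh_scan", "xpehh_from_panels"]


@dataclass(frozen=True)
class EhhParams:
    cutoff: float = 0.05  # pooled-EHH stopping threshold
    max_extend_bp: int = 1_000_000
    max_gap_bp: int = 200_000
    distance_mode: str = "physical"  # or "genetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0,1)")
        if self.max_extend_bp <= 0 or self.max_gap_bp <= 0:
            raise ValueError("extents must be positive")
        if self.distance_mode not in ("physical", "genetic"):
            raise ValueError("distance_mode must be 'physical' or 'genetic'")


def _pair_homozygosity(counts: np.ndarray, n: int) -> float:
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def ehh_at(haplotypes: np.ndarray, core_index: int, boundary_index: int) -> float:
    """EHH of one group from ``core_index`` out to ``boundary_index`` (inclusive)."""
    hap = np.asarray(haplotypes)
    n = hap.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    lo, hi = sorted((core_index, boundary_index))
    _, counts = np.unique(hap[:, lo : hi + 1], axis=0, return_counts=True)
    return _pair_homozygosity(counts, n)


def _extend(
    alleles: np.ndarray,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    core: int,
    step: int,
    c_lo: int,
    c_hi: int,
    pos: np.ndarray,
    params: EhhParams,
) -> tuple[list[float], list[float], list[float], str]:
    """Walk outward from the core; returns (distances, ehh_a, ehh_b, stop reason).

    The walk shares one pooled partition: group EHH values are read off the
    same haplotype grouping, so both integrals use identical boundaries.
    """
    n_pool = alleles.shape[0]
    na, nb = rows_a.size, rows_b.size
    labels = np.zeros(n_pool, dtype=np.int64)
    dist: list[float] = []
    ehh_a: list[float] = []
    ehh_b: list[float] = []
    j = core
    reason = "cutoff"
    while True:
        labels = labels * 2 + alleles[:, j]
        _, labels = np.unique(labels, return_inverse=True)
        cnt_pool = np.bincount(labels)
        cnt_a = np.bincount(labels[rows_a], minlength=cnt_pool.size)
        cnt_b = np.bincount(labels[rows_b], minlength=cnt_pool.size)
        dist.append(abs(float(pos[j]) - float(pos[core])))
        ehh_a.append(_pair_homozygosity(cnt_a, na))
        ehh_b.append(_pair_homozygosity(cnt_b, nb))
        if _pair_homozygosity(cnt_pool, n_pool) < params.cutoff:
            break
        nxt = j + step
        if nxt < c_lo or nxt >= c_hi:
            reason = "chrom_end"
            break
        if abs(int(pos[nxt]) - int(pos[core])) > params.max_extend_bp:
            reason = "max_extend"
            break
        if abs(int(pos[nxt]) - int(pos[j])) > params.max_gap_bp:
            reason = "max_gap"
            break
        j = nxt
    return dist, ehh_a, ehh_b, reason


def _trapezoid(dist: list[float], ehh: list[float]) -> float:
    total = 0.0
    for k in range(1, len(dist)):
        total += 0.5 * (ehh[k] + ehh[k - 1]) * (dist[k] - dist[k - 1])
    return total


def ihh(
    group_haplotypes: np.ndarray,
    pooled_haplotypes: np.ndarray,
    core_index: int,
    params: EhhParams | None = None,
    positions: np.ndarray | None = None,
) -> tuple[float, str]:
    """Integrated EHH of one group at a core, with pooled-EHH stopping.

    ``group_haplotypes`` must be a row-subset of ``pooled_haplotypes``
    (matched by row content, in any order).  Returns (iHH, stop flag); the
    flag is "chrom_end" when either direction hit the chromosome end before
    the pooled EHH decayed below the cutoff.
    """
    params = params or EhhParams()
    pooled = np.asarray(pooled_haplotypes)
    group = np.asarray(group_haplotypes)
    if positions is None:
        positions = np.arange(pooled.shape[1], dtype=float)
    # locate the group rows inside the pool by first-match row identity
    used = np.zeros(pooled.shape[0], dtype=bool)
    rows = []
    for g in group:
        hit = np.flatnonzero(~used & (pooled == g).all(axis=1))
        if hit.size == 0:
            raise ValueError("group haplotypes are not a subset of the pooled panel")
        rows.append(hit[0])
        used[hit[0]] = True
    rows_g = np.array(rows, dtype=np.intp)
    other = np.flatnonzero(~used)

    total = 0.0
    skipped = ""
    for step in (-1, +1):
        if step == +1 and core_index == pooled.shape[1] - 1:
            skipped = "chrom_end"
            continue
        if step == -1 and core_index == 0:
            skipped = "chrom_end"
            continue
        dist, ehh_g, _, reason = _extend(
            pooled, rows_g, other if other.size else rows_g, core_index, step,
            0, pooled.shape[1], positions, params,
        )
        total += _trapezoid(dist, ehh_g)
        if reason == "chrom_end":
            skipped = "chrom_end"
    return total, skipped


def xpehh_from_panels(
    panel: HaplotypePanel, group_a: str, group_b: str,
    params: EhhParams | None = None, top_fraction: float = 0.01,
    two_sided: bool = False,
) -> pd.DataFrame:
    """XP-EHH scan from one combined haplotype panel with group labels."""
    rows_a = panel.group_rows(group_a)
    rows_b = panel.group_rows(group_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("each group needs at least one sample (2 haplotypes)")
    keep = np.concatenate([rows_a, rows_b])
    alleles = panel.alleles[keep]
    new_a = np.arange(rows_a.size)
    new_b = np.arange(rows_a.size, rows_a.size + rows_b.size)
    chroms = np.array([m.chrom for m in panel.markers])
    if params is not None and params.distance_mode == "genetic":
        if any(m.cm is None for m in panel.markers):
            raise ValueError("genetic distance mode requires cM on every marker")
        pos = np.array([m.cm for m in panel.markers], dtype=float)
    else:
        pos = np.array([m.bp for m in panel.markers], dtype=float)
    df = xpehh_scan(
        alleles, new_a, new_b, chroms, pos, params=params,
        top_fraction=top_fraction, two_sided=two_sided,
    )
    df.insert(0, "id", [m.id for m in panel.markers])
    df.insert(0, "bp", [m.bp for m in panel.markers])
    df.insert(0, "chrom", chroms)
    return df


def xpehh_scan(
    alleles: np.ndarray,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    params: EhhParams | None = None,
    top_fraction: float = 0.01,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-core XP-EHH over a haplotype matrix.

    Returns a DataFrame with ihh_a, ihh_b, raw (= ln iHH_A/iHH_B), the
    genome-wide z score, top-set membership, and a ``skipped`` reason code
    for undefined cores.  Refuses to normalize with fewer than 10 defined
    cores.
    """
    params = params or EhhParams()
    alleles = np.asarray(alleles, dtype=np.int8)
    n_markers = alleles.shape[1]
    rows_a = np.asarray(rows_a, dtype=np.intp)
    rows_b = np.asarray(rows_b, dtype=np.intp)
    pos = np.asarray(positions, dtype=float)

    ihh_a = np.full(n_markers, np.nan)
    ihh_b = np.full(n_markers, np.nan)
    skipped = np.array([""] * n_markers, dtype=object)

    # chromosome blocks
    change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n_markers]))
    for c_lo, c_hi in zip(starts, stops):
        for core in range(c_lo, c_hi):
            ia = ib = 0.0
            flag = ""
            for step in (-1, +1):
                dist, ea, eb, reason = _extend(
                    alleles, rows_a, rows_b, core, step, c_lo, c_hi, pos, params
                )
                ia += _trapezoid(dist, ea)
                ib += _trapezoid(dist, eb)
                if reason == "chrom_end":
                    flag = "chrom_end"
            if flag:
                skipped[core] = flag
            elif ia <= 0 or ib <= 0:
                skipped[core] = "zero_ihh"
            else:
                ihh_a[core] = ia
                ihh_b[core] = ib

    with np.errstate(divide="ignore", invalid="ignore"):
        # log difference (not log of the ratio) so a group swap negates
        # every score bit-exactly
        raw = np.log(ihh_a) - np.log(ihh_b)
    defined = np.isfinite(raw)
    if defined.sum() < 10:
        raise ValueError(f"only {int(defined.sum())} defined cores; refusing to normalize")
    mu = raw[defined].mean()
    sd = raw[defined].std(ddof=0)
    z = np.full(n_markers, np.nan)
    if sd > 0:
        z[defined] = (raw[defined] - mu) / sd
    else:
        z[defined] = 0.0

    score = np.abs(z) if two_sided else z
    thr = nearest_rank_threshold(score[defined], top_fraction)
    is_top = defined & (score >= thr)
    return pd.DataFrame(
        {
            "ihh_a": ihh_a,
            "ihh_b": ihh_b,
            "raw": raw,
            "z": z,
            "is_top": is_top,
            "skipped": skipped,
        }
    )
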