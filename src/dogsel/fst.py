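"""Per-SNP two-population Weir & Cockerham F_ST with windowed smoothing.

The estimator is the 1984 Weir & Cockerham variance-components form for
r = 2 populations (the default of the standard whole-genome tools), using
*observed* heterozygote frequencies.  Per marker it yields components
``a`` (among-population), ``b`` (among-individual within population) and
``c`` (within-individual), with theta = a / (a + b + c).

To damp single-SNP outliers, each marker's theta is averaged with up to
five flanking markers on each side on the same chromosome; the top set is
the nearest-rank top percentile of the smoothed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MISSING, GenotypePanel
from .roh import nearest_rank_threshold

__all__ = ["wc_fst_snp", "wc_fst_components", "smooth_stat", "top_fraction_set", "fst_scan"]


def wc_fst_snp(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float, float]:
    """Weir & Cockerham variance components for one SNP, two populations.

    Inputs per population: diploid sample size ``n`` (non-missing), alt-allele
    frequency ``p``, observed heterozygote frequency ``h``.  Returns
    ``(a, b, c, theta)``; theta is NaN when a + b + c = 0 or either n < 2.
    """
    a, b, c = wc_fst_components(
        np.array([n1]), np.array([p1]), np.array([h1]),
        np.array([n2]), np.array([p2]), np.array([h2]),
    )
    tot = a[0] + b[0] + c[0]
    theta = a[0] / tot if tot != 0 and np.isfinite(tot) else float("nan")
    return float(a[0]), float(b[0]), float(c[0]), float(theta)


def wc_fst_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized W&C components across markers (r = 2)."""
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    undefined = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[undefined] = np.nan
    return a, b, c


def smooth_stat(values: np.ndarray, chroms: np.ndarray, flank: int = 5) -> np.ndarray:
    """Windowed mean over the marker and <= ``flank`` neighbours each side.

    Windows never cross a chromosome boundary and shrink at chromosome ends;
    NaN values are excluded from window means (a window of all-NaN stays NaN).
    """
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    out = np.full_like(values, np.nan)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        v = values[idx]
        n = v.size
        for k in range(n):
            lo, hi = max(0, k - flank), min(n, k + flank + 1)
            window = v[lo:hi]
            good = ~np.isnan(window)
            if good.any():
                out[idx[k]] = window[good].mean()
    return out


def top_fraction_set(values: np.ndarray, fraction: float = 0.01) -> tuple[float, np.ndarray]:
    """Nearest-rank top-``fraction`` membership over defined values.

    Returns (threshold, boolean member flags); NaN values are never members
    and are excluded from the percentile base.
    """
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("no defined values")
    thr = nearest_rank_threshold(values[defined], fraction)
    members = defined & (values >= thr)
    if np.nanmin(values) == np.nanmax(values):
        warnings.warn("all values equal; degenerate top set contains every marker", stacklevel=2)
    return thr, members


def fst_scan(
    panel: GenotypePanel, group_a: str, group_b: str, flank: int = 5,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP F_ST scan between two groups with smoothing and top-set flags.

    Returns a DataFrame with columns chrom, bp, id, a, b, c, theta,
    theta_smoothed, is_top.
    """
    groups = panel.groups()
    ia = np.flatnonzero(groups == group_a)
    ib = np.flatnonzero(groups == group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")

    def stats(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = panel.dosage[rows]
        ok = d != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, d, 0).sum(axis=0) / (2.0 * n)
            h = np.where(ok, d == 1, False).sum(axis=0) / n
        return n, p, h

    n1, p1, h1 = stats(ia)
    n2, p2, h2 = stats(ib)
    a, b, c = wc_fst_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = a + b + c
        theta = np.where(tot != 0, a / tot, np.nan)

    chroms = panel.chroms()
    theta_s = smooth_stat(theta, chroms, flank=flank)
    thr, is_top = top_fraction_set(theta_s, top_fraction)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "bp": panel.bp(),
            "id": [m.id for m in panel.markers],
            "a": a, "b": b, "c": c,
            "theta": theta,
            "theta_smoothed": theta_s,
            "is_top": is_top,
        }
    ).assign(top_threshold=thr)
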