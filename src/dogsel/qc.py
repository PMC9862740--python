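"""Quality control: call-rate and MAF filters, relatedness pruning, subsampling.

Filter conventions follow how the thresholds are usually stated for SNP-chip
studies of this kind: sample and SNP call rates are *inclusive* (retain at
``>= threshold``), the minor-allele-frequency filter is *strict*
(retain at ``MAF > min_maf``), and only autosomes are kept.  Relatedness is
measured with the KING-robust method-of-moments kinship coefficient; pairs at
or above the first-degree cutoff (0.177) are greedily pruned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core_data import MISSING, GenotypePanel

__all__ = [
    "QCParams",
    "QCReport",
    "filter_samples_by_call_rate",
    "filter_snps",
    "king_kinship",
    "kinship_matrix",
    "prune_related",
    "subsample_group",
    "run_qc",
]

FIRST_DEGREE_KINSHIP = 0.177  # KING-robust cutoff between 1st and 2nd degree


@dataclass(frozen=True)
class QCParams:
    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    autosomes_only: bool = True
    kinship_threshold: float = FIRST_DEGREE_KINSHIP

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    """Bookkeeping for one QC run; retained + removed always sum to the input."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    snps_removed: dict[str, int] = field(default_factory=dict)  # filter name -> count
    n_samples_retained: int = 0
    n_snps_retained: int = 0

    def check(self) -> None:
        assert self.n_samples_retained + len(self.samples_removed) == self.n_samples_in
        assert self.n_snps_retained + sum(self.snps_removed.values()) == self.n_snps_in


def _sample_call_rates(panel: GenotypePanel) -> np.ndarray:
    return (panel.dosage != MISSING).mean(axis=1)


def filter_samples_by_call_rate(
    panel: GenotypePanel, threshold: float = 0.95
) -> tuple[GenotypePanel, list[tuple[str, str]]]:
    """Retain samples whose call rate is >= threshold (inclusive)."""
    if panel.n_samples == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0,1]")
    cr = _sample_call_rates(panel)
    keep = np.flatnonzero(cr >= threshold)
    removed = [
        (panel.samples[i].id, f"call_rate={cr[i]:.4f}<{threshold}")
        for i in np.flatnonzero(cr < threshold)
    ]
    return panel.subset_samples(keep), removed


_AUTOSOMES = {str(i) for i in range(1, 39)}  # dog autosomes: CFA 1..38


def _is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOMES


def filter_snps(panel: GenotypePanel, params: QCParams) -> tuple[GenotypePanel, dict[str, int]]:
    """Apply marker filters in order: autosomes -> call rate (>=) -> MAF (>).

    MAF is the folded frequency min(p, 1-p) computed on non-missing calls of
    the current (post-sample-filter) panel.
    """
    removed: dict[str, int] = {"non_autosome": 0, "snp_call_rate": 0, "maf": 0}
    keep = np.ones(panel.n_markers, dtype=bool)

    if params.autosomes_only:
        auto = np.array([_is_autosome(m.chrom) for m in panel.markers])
        removed["non_autosome"] = int((~auto).sum())
        keep &= auto

    nonmiss = panel.dosage != MISSING
    cr = nonmiss.mean(axis=0)
    fail_cr = keep & (cr < params.min_snp_call_rate)
    removed["snp_call_rate"] = int(fail_cr.sum())
    keep &= ~fail_cr

    with np.errstate(invalid="ignore"):
        alt_count = np.where(nonmiss, panel.dosage, 0).sum(axis=0)
        n_alleles = 2 * nonmiss.sum(axis=0)
        p = np.divide(alt_count, n_alleles, out=np.zeros(panel.n_markers), where=n_alleles > 0)
    maf = np.minimum(p, 1.0 - p)
    fail_maf = keep & ~(maf > params.min_maf)
    removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    return panel.subset_markers(np.flatnonzero(keep)), removed


def king_kinship(panel: GenotypePanel, i: int, j: int) -> float:
    """KING-robust kinship between samples ``i`` and ``j``.

    phi = (N_het,het - 2*N_opp_hom) / (N_het,i + N_het,j), counted over
    markers non-missing in both.  A zero denominator is undefined and
    returned as NaN (treated downstream as unrelated).
    """
    di, dj = panel.dosage[i], panel.dosage[j]
    ok = (di != MISSING) & (dj != MISSING)
    if not ok.any():
        raise ValueError(f"samples {i},{j} share no non-missing markers")
    di, dj = di[ok], dj[ok]
    het_i = di == 1
    het_j = dj == 1
    n_hh = int((het_i & het_j).sum())
    n_opp = int((((di == 0) & (dj == 2)) | ((di == 2) & (dj == 0))).sum())
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        return float("nan")
    return (n_hh - 2 * n_opp) / denom


def kinship_matrix(panel: GenotypePanel) -> np.ndarray:
    """All-pairs KING-robust kinship (NaN on the diagonal and undefined pairs)."""
    n = panel.n_samples
    phi = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        phi[i, j] = phi[j, i] = king_kinship(panel, i, j)
    return phi


def prune_related(
    panel: GenotypePanel, threshold: float = FIRST_DEGREE_KINSHIP
) -> tuple[GenotypePanel, list[tuple[str, str, float]]]:
    """Greedily remove one member of each related pair until none remain.

    While any pair has kinship >= threshold, the pair with the largest
    kinship is resolved by dropping the member with the lower call rate
    (tie: the later sample in panel order).  Deterministic.
    """
    phi = kinship_matrix(panel)
    cr = _sample_call_rates(panel)
    active = np.ones(panel.n_samples, dtype=bool)
    removed: list[tuple[str, str, float]] = []
    while True:
        masked = np.where(np.isnan(phi), -np.inf, phi).copy()
        masked[~active, :] = -np.inf
        masked[:, ~active] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < threshold:
            break
        if cr[i] < cr[j] or (cr[i] == cr[j] and i > j):
            drop, keep_ = i, j
        else:
            drop, keep_ = j, i
        active[drop] = False
        removed.append((panel.samples[drop].id, panel.samples[keep_].id, float(phi[i, j])))
    return panel.subset_samples(np.flatnonzero(active)), removed


def subsample_group(panel: GenotypePanel, breed: str, n_keep: int, seed: int) -> GenotypePanel:
    """Seeded uniform subsampling of one breed; other samples untouched.

    Used for group-size balancing when one breed is over-represented
    (e.g. keeping 24 of 30 FONN so breed sizes within a group are uniform).
    """
    idx = [i for i, s in enumerate(panel.samples) if s.breed == breed]
    if n_keep > len(idx):
        raise ValueError(f"n_keep={n_keep} exceeds breed {breed!r} size {len(idx)}")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(idx, size=n_keep, replace=False).tolist())
    keep = [i for i in range(panel.n_samples) if panel.samples[i].breed != breed or i in chosen]
    return panel.subset_samples(keep)


def run_qc(panel: GenotypePanel, params: QCParams | None = None) -> tuple[GenotypePanel, QCReport]:
    """Full QC pass: sample call rate -> SNP filters -> relatedness pruning."""
    params = params or QCParams()
    report = QCReport(n_samples_in=panel.n_samples, n_snps_in=panel.n_markers)
    panel, removed_cr = filter_samples_by_call_rate(panel, params.min_sample_call_rate)
    report.samples_removed += removed_cr
    panel, snp_removed = filter_snps(panel, params)
    report.snps_removed = snp_removed
    panel, removed_rel = prune_related(panel, params.kinship_threshold)
    report.samples_removed += [
        (sid, f"related_to={other};phi={phi:.3f}") for sid, other, phi in removed_rel
    ]
    report.n_samples_retained = panel.n_samples
    report.n_snps_retained = panel.n_markers
    report.check()
    return panel, report
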