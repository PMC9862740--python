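import numpy as np
import pytest

from dogsel.core_data import GenotypePanel, HaplotypePanel, Marker, SampleRecord


def make_markers(positions, chrom="1", alleles=("A", "G"), cm=None):
    return [
        Marker(chrom=chrom, bp=int(bp), id=f"snp{chrom}_{j}", alleles=alleles,
               cm=(bp * 1e-6 if cm == "auto" else None))
        for j, bp in enumerate(positions)
    ]


def make_panel(dosage, positions=None, groups=None, chrom="1"):
    """GenotypePanel from a dosage matrix; groups is a per-sample label list."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    if groups is None:
        groups = ["G1"] * n
    samples = [SampleRecord(id=f"s{i}", breed=groups[i], group=groups[i]) for i in range(n)]
    return GenotypePanel(samples=samples, markers=make_markers(positions, chrom), dosage=dosage)


def make_hap_panel(alleles, positions=None, groups=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n2, m = alleles.shape
    assert n2 % 2 == 0
    n = n2 // 2
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    if groups is None:
        groups = ["G1"] * n
    samples = [SampleRecord(id=f"s{i}", breed=groups[i], group=groups[i]) for i in range(n)]
    return HaplotypePanel(samples=samples, markers=make_markers(positions, chrom), alleles=alleles)


def mendelian_family(n_pairs, n_snps, seed):
    """Parent-offspring duos: parents from HWE at uniform freqs, child by transmission.

    Returns (panel, pair index list) where each pair is (parent_row, child_row).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_snps)
    rows = []
    pairs = []
    for k in range(n_pairs):
        pa = rng.binomial(1, p, size=(2, n_snps))  # parent a's two haplotypes
        pb = rng.binomial(1, p, size=(2, n_snps))  # unsampled mate
        child = pa[rng.integers(2, size=n_snps), np.arange(n_snps)] + \
            pb[rng.integers(2, size=n_snps), np.arange(n_snps)]
        rows.append(pa.sum(axis=0))
        rows.append(child)
        pairs.append((2 * k, 2 * k + 1))
    return make_panel(np.array(rows)), pairs


@pytest.fixture
def small_panel():
    return make_panel(
        [[0, 1, 2, 0, 1], [2, 1, 0, 0, 0], [1, 1, 1, 2, 2]],
        positions=[100, 2000, 35000, 60000, 90000],
    )
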