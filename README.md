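# dogsel

Selection-signature scans for SNP-chip panels of two dog breed groups —
built for the comparison of livestock-guardian (LGD) and herding-shepherd
(HSD) dogs, and reusable for any two-group biallelic genotype panel.

Dog breeds selected for different work (guarding flocks vs actively herding
them) diverge both within-group — selection sweeps leave long runs of
homozygosity (ROH) shared by many dogs — and between groups, where allele
frequencies and haplotype lengths differentiate. `dogsel` implements the
full analysis stack for detecting both kinds of signal:

- **QC** — sample/SNP call-rate filters (inclusive ≥ 0.95), MAF filter
  (strict > 0.01), autosomes only (CFA 1–38), KING-robust relatedness
  pruning (first-degree cutoff φ̂ ≥ 0.177), and seeded breed subsampling
  for group-size balance.
- **Population structure** — identity-by-state distances
  (1 − allele-sharing fraction) and classical Torgerson MDS.
- **ROH islands** (within-group) — per-sample ROH called directly from the
  four defining criteria (≥ 50 homozygous SNPs, ≥ 1 Mb, ≥ 1 SNP / 50 kb,
  gaps ≤ 100 kb, no heterozygotes); the per-marker *H-score* is the
  fraction of a group's dogs whose ROH cover that marker; top-1% H-score
  markers merge into islands.
- **F_ST scan** (between-group) — per-SNP Weir & Cockerham (1984) variance
  components a, b, c with θ = a/(a+b+c), smoothed over ±5 flanking SNPs,
  top 1% flagged.
- **XP-EHH scan** (between-group) — extended haplotype homozygosity
  EHH = Σ_h C(n_h,2)/C(n,2) integrated outward from each core until the
  pooled two-group EHH decays below 0.05; the statistic is
  ln iHH_A − ln iHH_B, z-normalized genome-wide.
- **Report** — intersection of the two top-1% sets, SNP→gene mapping
  against a packaged CanFam3.1 gene table, and between-group ROH-island
  overlap.
- **Synthetic data** — a seeded generator (Balding–Nichols breed drift +
  founder-mosaic haplotypes) that injects sweeps and autozygous intervals
  with recorded truth, so every stage is testable without real genotypes.

## Worked example

`python examples/xpehh_sweep_scan.py` simulates two groups of 25 dogs
(1,200 SNPs on a 15 Mb chromosome) with a 500 kb core haplotype at 90%
frequency in LGD vs 10% in HSD, then scans:

```
cores scanned              : 1200 (1186 defined)
z mean / sd (contract 0,1) : +0.00e+00 / 1.000000
mean z inside sweep span   : 4.29
top-1% cores inside sweep  : 12 of 12
```

Every core in the genome-wide top 1% of z lies inside the injected sweep:
positive z means longer extended haplotypes in LGD at that core. The other
examples show ROH-island recovery of an injected autozygous interval
(interior H-score exactly the 0.5 carrier fraction, island bounds within
one marker spacing of truth), SNP→gene mapping (a probe at
chr30:31,700,000 returns *MAP2K5*), and the full pipeline via
`run_pipeline` / the `dogsel` CLI.

The command-line entry point mirrors the library:

```sh
dogsel simulate --out sim --seed 3
dogsel run --config pipeline.yaml       # qc -> structure -> roh -> fst -> xpehh -> report
dogsel fst --ped sim/data.ped --map sim/data.map --groups groups.yaml --out out
```

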