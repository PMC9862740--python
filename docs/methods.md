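# Methods

This note documents the statistical models, conventions and design choices
behind `dogsel`, and what the synthetic-data validation does and does not
demonstrate about real SNP-chip data.

## Data model and conventions

Genotypes are alt-allele dosages in {0, 1, 2} with a distinguished missing
sentinel; phased haplotypes are binary matrices with rows 2k/2k+1 belonging
to sample k, assumed complete (phasing is upstream of this package, e.g.
BEAGLE; the VCF reader rejects unphased or missing GT calls rather than
guessing). All coordinates are 1-based inclusive base pairs, matching PLINK
MAP files and published gene tables; BED output converts to 0-based
half-open at write time. The alt allele is defined at PED read time as the
minor allele (ties: the lexicographically smaller allele is ref). F_ST and
XP-EHH are invariant to this orientation; only report columns depend on it.

## Quality control

Filters run in the order samples → autosomes → SNP call rate → MAF, with
MAF computed on post-sample-filter, non-missing calls. Boundaries follow
the usual reading of the thresholds: call rates are inclusive (a sample
with exactly 95% calls is retained), the MAF filter is strict (exactly 1%
is removed). Relatedness uses the KING-robust method-of-moments kinship

    φ̂ = (N_het,het − 2 N_opp,hom) / (N_het,i + N_het,j)

over markers called in both samples; duplicates give 0.5, parent–offspring
≈ 0.25, and the first-degree cutoff is 0.177. Pruning is greedy and
deterministic: the worst pair is resolved by dropping the lower-call-rate
member (ties: the later sample). KING-robust was chosen because it needs no
external allele-frequency reference and is testable by Mendelian
simulation; other relatedness estimators would prune slightly different
sets. Breed subsampling (e.g. trimming an over-represented breed to match
its group's other breeds) is uniform without replacement under the run
seed, as no principled selection rule is available.

## IBS / MDS

IBS similarity between two diploids is the allele-sharing fraction,
computed as mean((2 − |d_i − d_j|)/2) over markers called in both
(pairwise-complete, no imputation); distance is 1 − similarity. Classical
(Torgerson) MDS double-centers the squared distances and scales the top
eigenvectors by √eigenvalue. Components are sign-fixed so the
largest-magnitude loading is positive — a convention chosen because it is
invariant to sample order, unlike "first loading positive". Requests for
more components than positive eigenvalues truncate with a warning.

## ROH and islands

ROH are called directly from their defining criteria rather than through a
sliding-window hit-rate heuristic: maximal stretches of homozygous-or-
missing markers (≤ 0 heterozygotes by default; ≤ 5 missing calls
tolerated per run, a pragmatic allowance since chip data lose sporadic
calls), split wherever consecutive markers are > 100 kb apart, trimmed to
homozygous endpoints, and reported iff they contain ≥ 50 homozygous SNPs,
span ≥ 1 Mb, and average ≤ 50 kb per homozygous SNP. With zero
heterozygotes allowed this coincides with window-based callers on clean
data while remaining exactly testable at each criterion's boundary.

The H-score of a marker within a group is the number of distinct group
members whose ROH cover it (closed-interval on bp) divided by group size.
Islands are built from markers at or above the top-1% H-score cut;
same-chromosome members within 500 kb merge, and islands with fewer than 3
member SNPs are dropped. The merge gap and minimum size are exposed in
configuration because island counts are sensitive to them and no standard
exists; the defaults keep a 1.5 Mb injected signal in one piece at chip
density without bridging independent signals Mb apart.

Top-percentile sets everywhere use the nearest-rank convention in which the
top set holds exactly ceil(f·n) values (plus ties of the cut value):
values 1..1000 at 1% give threshold 991. A degenerate all-equal input
flags every marker and warns; an all-zero H-score track yields no islands.

## Weir & Cockerham F_ST

Per SNP, the two-population (r = 2) variance components of Weir &
Cockerham (1984) are computed from the per-group non-missing diploid count
n, alt frequency p and *observed* heterozygote frequency h:

    a  among-population, b  among-individual, c  within-individual,
    θ = a / (a + b + c)

θ is undefined (NaN) when either group has n < 2 or the components sum to
zero, and undefined values propagate: they are excluded from smoothing
windows and from the percentile base. Smoothing averages each marker with
up to 5 flanking markers per side on the same chromosome (windows shrink at
ends), and the top 1% is taken on smoothed values — smoothing exists to
damp single-SNP outliers, so thresholding after it is the coherent order.
Under two independent Balding–Nichols demes the ratio-of-sums estimator
recovers the drift parameter F (the textbook W&C property) while the mean
of per-SNP θ is smaller (≈ 0.15 at F = 0.2); the acceptance script reports
both so the calibration is explicit.

## XP-EHH

EHH of a group at boundary j from core c is the probability that two
haplotypes drawn without replacement agree on the whole stretch c..j
(inclusive): Σ_h C(n_h,2)/C(n,2) over distinct extended haplotypes. From
each core the scan walks outward in both directions until the *pooled*
two-group EHH drops below 0.05, the chromosome ends, the walk exceeds 1 Mb
from the core, or an inter-marker gap exceeds 200 kb; pooling makes both
groups share identical integration boundaries, so the ratio statistic is
not biased by asymmetric truncation. iHH is the trapezoid integral of the
group's EHH curve over the traversed distance (bp by default; cM when the
map provides it — under the generator's 1 cM/Mb map the two differ only by
scale, which the log-ratio cancels).

The raw statistic is ln iHH_A − ln iHH_B, computed as a difference of logs
rather than the log of a ratio so that swapping the groups negates every
score bit-exactly. z-normalization is genome-wide over all defined cores
(frequency-binned normalization is an alternative; genome-wide is the
common default for XP-EHH) and refuses to run with fewer than 10 defined
cores. The top 1% is one-sided on z — large positive z means longer
haplotypes, i.e. a putative sweep, in group A — with a two-sided option
available since sidedness is a reporting choice. Cores whose walk hits a
chromosome end before the pooled EHH decays are flagged and excluded, as
their integrals are right-censored.

## Cross-analysis report

A marker is a shared signal when it is in the top 1% of both smoothed F_ST
and normalized XP-EHH (intersection by marker id). SNP→gene mapping is
closed-interval containment against a gene table, with an optional flank
padding (default 0 bp). The flank is the single largest unverifiable knob
in any such analysis — "a region containing a gene" has no standard extent
— so it is surfaced in the report header. The packaged gene table carries
29 CanFam3.1 genes; two of its printed source coordinates contained
misplaced thousands separators and were normalized to the evident intended
values (SSBP2 start 25,616,824; EPB41L1 end 25,046,776). Two groups' ROH
islands are "shared" on any positive-length closed-interval overlap; the
overlap interval itself is reported so users can apply stricter notions.

## Synthetic-data generator

The generator emulates the target study design: two groups of 4–5 dog
breeds (~70 dogs per group at defaults), dense autosomal SNPs, breed-level
drift from a shared ancestral pool, and localized signals with recorded
truth. Ancestral frequencies are uniform on (0.05, 0.95); each breed draws
Balding–Nichols frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with mean p and
variance F·p(1−p) (default F = 0.1 per breed; F = 0 returns p exactly).
Haplotypes are crossover mosaics of a per-breed founder pool (default 100
founders; switch points Poisson at 1e-8 per bp), which produces EHH decay
and haplotype sharing at desk scale without a coalescent simulator — a
deliberate non-biological stand-in. Two idealizations matter:

- a sample's two haplotypes draw from disjoint founder-pool halves, so the
  copying model itself never creates within-individual autozygosity and
  injected ROH truth is exact (baseline H-scores are 0);
- founder haplotypes are site-independent draws from breed frequencies, so
  background LD is entirely pool-driven; samples sharing a founder
  haplotype look like close relatives to KING, which the QC stage then
  prunes — visible in full-pipeline runs, absent in stage-level tests.

Sweeps copy one donor haplotype over a span onto round-half-up(freq × n)
haplotypes per group (chosen without replacement, seeded); autozygosity
overwrites haplotype 2k+1 with 2k over the interval for a round-half-up
carrier fraction of the target group's samples. Rounding is half-up purely
for determinism. Missingness is optional uniform per-call (default 0).
Everything — marker placement, drift, mosaics, injections — derives from
one seed; identical parameters and seed give byte-identical output files.

Passing tests on this generator demonstrate estimator correctness and
signal recovery under clean, known conditions. They do not demonstrate
robustness to genotyping error beyond uniform missingness, array
ascertainment bias, phasing error (haplotypes are generated phased), or
real LD structure.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: 1,200–5,000 SNPs on one
15–50 Mb chromosome, 25–30 dogs per group, 20 seeded replicates for
stochastic recovery checks — sizes at which every recovery criterion is
comfortably detectable while the full suite completes in well under a
minute of compute per module. Exact-arithmetic checks (EHH pair counting,
W&C components vs an independent transcription of the algebra, windowed
means vs brute force) are asserted at 1e-12 or bit-exact; stochastic
recovery rates are asserted at ≥ 19/20 replicates; moment checks
(Mendelian kinship 0.25 ± 0.02, Beta moments) use the tolerances implied
by their Monte-Carlo standard errors.
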