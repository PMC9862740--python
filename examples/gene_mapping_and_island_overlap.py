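"""Map SNPs onto the packaged CanFam3.1 gene table and compare islands.

Uses the packaged 29-gene fixture (genes flagged by both between-group scans
in Italian shepherd-dog breeds) for closed-interval containment mapping, and
shows positive-length interval overlap between two groups' ROH islands.
"""

import pandas as pd

from dogsel.core_data import packaged_gene_table
from dogsel.report import islands_overlap, map_snps_to_genes
from dogsel.roh import ROHIsland

genes = packaged_gene_table()
print(f"packaged gene table: {len(genes)} genes on CanFam3.1")

probes = pd.DataFrame({
    "chrom": ["30", "30", "4", "15"],
    "bp": [31_700_000, 31_664_563, 3_400_000, 12_000_000],
    "id": ["p1", "p2", "p3", "p4"],
})
mapped, gene_set = map_snps_to_genes(probes, genes, flank_bp=0)
for _, row in mapped.iterrows():
    print(f"  chr{row.chrom}:{row.bp:,} -> {row.genes or '(no gene)'}")
print(f"gene set hit: {sorted(gene_set)}")

lgd = [ROHIsland("LGD", "1", 60_722_335, 61_921_241, 50, 0.6)]
hsd = [ROHIsland("HSD", "1", 60_722_335, 62_055_218, 55, 0.5)]
for a, b, (chrom, lo, hi) in islands_overlap(lgd, hsd):
    print(f"shared island on chr{chrom}: {lo:,}-{hi:,} ({hi - lo + 1:,} bp overlap)")
print()
print("A marker maps to a gene when it falls inside the gene's 1-based closed")
print("span (optionally padded); islands are 'shared' on any positive overlap.")
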