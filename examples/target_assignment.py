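"""Assigning peaks to target genes with a strand-aware TSS window.

A gene is a target when a peak summit falls within 3 kb of its TSS;
distances are signed, positive downstream in gene orientation.
"""

import chipexpr as ce

genes = [
    ce.GeneModel("geneA", "chr1", "+", 10_000, 18_000),   # TSS 10,000
    ce.GeneModel("geneB", "chr1", "-", 30_000, 40_000),   # TSS 39,999
    ce.GeneModel("geneC", "chr1", "+", 80_000, 90_000),   # TSS 80,000
]
peaks = [
    ce.Peak(ce.GenomicInterval("chr1", 8_050, 8_450), "p1", 8_250, 15.0),
    ce.Peak(ce.GenomicInterval("chr1", 40_900, 41_300), "p2", 41_100, 22.0),
    ce.Peak(ce.GenomicInterval("chr1", 60_000, 60_400), "p3", 60_200, 9.0),
]

tmap = ce.assign_targets(peaks, genes, window=3000)
for gene_id in sorted(tmap.target_genes):
    for idx, dist in tmap.assignments[gene_id]:
        print(f"{gene_id}: peak {peaks[idx].name} at {dist:+d} bp from TSS")

# geneA is hit 1,750 bp upstream of its TSS; geneB (minus strand) is hit
# 1,101 bp upstream (the sign is flipped into gene orientation); geneC's
# nearest summit is 20 kb away, so it is not a target.
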