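# chipexpr

Integrative analysis of transcription-factor binding (ChIP-seq peaks) and
knockdown expression data, for regulatory-genomics analysts who want to go
from *where a factor binds* to *what it does*: which genes it targets, with
which partner factors it co-occupies promoters, and whether it activates or
represses the genes that respond to its knockdown.

## What it computes

**Target assignment.** A gene is a target of a factor when some peak summit
*s* satisfies |*s* − TSS| ≤ *w* (default *w* = 3 kb), with the TSS taken
strand-aware and distances signed in gene orientation. Peak locations are
also classified genome-wide (promoter / 5′UTR / 3′UTR / coding exon /
intron / intergenic).

**Co-occupancy.** Peaks pass a fold-enrichment filter (> 10 by default),
factor A's peaks are partitioned into *ensemble* (≥ 1 bp interval overlap
with a factor-B peak) and *solo* groups, and target-set overlaps are scored
with the hypergeometric upper tail
p = Σ_{i≥k} C(|A|,i)·C(N−|A|,|B|−i)/C(N,|B|).

**Signal profiles.** Binned mean coverage in a ±3 kb window around TSSs or
summits (strand-aware), signal-ordered heatmap rows, per-bin average
profiles for ensemble vs solo peaks, and a 100-gene sliding-average
smoother for the expression track alongside a heatmap.

**Differential expression.** Microarray-style preprocessing (background
subtraction floored at 0.5, log2, quantile normalization), a per-gene
pooled-variance Student's t-test of knockdown vs control, Benjamini–
Hochberg adjustment, and decreased/increased gene sets at a configurable
alpha.

**Activator/repressor inference** (the core statistic). For a DE gene set
*S* and background *B*, with per-gene distances d(g) = min over peaks of
|summit − TSS|, the one-sided two-sample Kolmogorov–Smirnov statistic

    D+ = sup_x [ F_S(x) − F_B(x) ],    p = exp(−2 · n_eff · D+²),
    n_eff = mn/(m+n)

is positive when *S* lies stochastically **closer** to the factor's peaks
than background. A significant decreased-after-knockdown set is *activator
evidence*; a significant increased set is *repressor evidence*; both can
hold. A regulatory-potential score RP(g) = Σ_i exp(−(0.5 + 4·d_i/Δ))
(Δ = 100 kb) combines with DE rank to select the top active/repressive
targets.

**Motif enrichment.** Peaks are trimmed/extended to 600-bp summit-centred
windows; a PWM (consensus-derived REST/NRSE and E2F1 matrices ship with the
package) is scanned on both strands, and window hit rates are compared to
random background windows with a one-sided Fisher exact test.

**Synthetic data.** `chipexpr.generate()` builds a complete toy study —
genome FASTA, refFlat annotation, three factors' narrowPeak sets with a
controlled co-binding fraction, bedGraph coverage, a knockdown expression
matrix with effects decaying in peak-to-TSS distance, and planted motif
instances — together with the ground truth needed to score recovery.

## Worked example

`python examples/run_synthetic_pipeline.py` generates the default synthetic
study (500 genes, 300 peaks/factor, 4 + 4 arrays) and runs every stage:

```
target genes (3 kb TSS window): 146
ensemble / solo peaks:          42 / 202
target-set overlap p (hypergeom): 0.0333
DE after knockdown: 21 decreased, 24 increased
KS p decreased set: 1.15e-10
KS p increased set: 1.36e-07
direction labels:   ['activator evidence', 'repressor evidence']
motif enrichment p: 7.31e-18 (36 fg vs 0 bg hits)
```

146 of 500 genes carry a filtered peak summit within 3 kb of a TSS; 42 of
the 244 fold-filtered peaks are co-bound by the partner factor. Both DE
sets sit far closer to the factor's summits than background (tiny KS p),
so the factor is called both activator and repressor — which is exactly
what the generator planted — and the partner's motif is strongly enriched
under co-bound summits. The other scripts in `examples/` each demonstrate
one capability in isolation.

A CLI mirrors the library (`chipexpr run`, `targets`, `cooccupy`,
`diffexpr`, `activity`, `motif`, `synth`); see `chipexpr --help`.

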