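# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) internally; refFlat
and WIG inputs are converted on read. The TSS of a plus-strand transcript
is `tx_start`, of a minus-strand transcript `tx_end − 1` (the first
transcribed base). Chromosome names are matched by exact string equality —
no `chr`-prefix aliasing — so a naming mismatch between inputs surfaces as
missing data rather than being silently patched.

## Target assignment

A gene is a target of a factor iff some peak summit lies within
`tss_window` (default 3,000 bp, boundary inclusive) of a TSS. Distance is
measured TSS-to-summit rather than TSS-to-peak-edge: the summit is the
caller's best point estimate of the binding position, and a point-to-point
rule is unambiguous for wide peaks. Whole-peak distance would only widen
the capture window by half the peak width; the choice is config-exposed
(`use_summit_distance`). For genes with multiple transcripts, the gene is a
target if any transcript's TSS qualifies and its reported distance is the
minimum over transcripts, matching gene-level expression data downstream.

Peak-location classification assigns each summit one category with
precedence promoter > 5′UTR > 3′UTR > coding exon > intron > intergenic,
where "promoter" means within `tss_window` of any TSS. Fractions sum to 1
by construction.

## Co-occupancy

Fold filtering keeps peaks with fold enrichment strictly greater than
`fold_threshold` (default 10, narrowPeak column 7). Ensemble membership
requires ≥ `min_overlap_bp` (default 1) of interval overlap with a partner
peak — the simplest reproducible rule; half-open adjacency is not
co-binding. Target-set overlap significance is the hypergeometric upper
tail with the observed overlap included; the universe defaults to all
annotated genes and may be restricted to expressed genes. To compare
average signal between ensemble and solo peaks, the larger group is
down-sampled to the smaller's size uniformly without replacement from the
run seed.

## Signal profiles

`profile_matrix` averages per-base coverage into uniform bins across
`±heatmap_halfwindow` (default 3 kb, 120 bins of 50 bp — the bin width is a
resolution/robustness tradeoff, config-exposed). Minus-strand anchors have
their bins reversed so every row reads 5′→3′. Bin values are exact
interval means computed from a run-length prefix integral, so total signal
mass is conserved to rounding error. Window portions beyond a chromosome
end contribute only their covered bases to the bin mean. Heatmap rows are
ordered by mean signal in the central ±500 bp, ties broken by anchor id.
The expression smoother is a moving average in "valid" mode; the default
window is 100 genes with stride 1 (a stride-100 variant exists for the
coarser reading of a "step"), which produces a smooth trend along the
signal-ordered gene list.

## Differential expression

Raw two-channel intensities are background-corrected as
`max(signal − background, 0.5)` — the 0.5 floor guarantees strictly
positive intensities so the subsequent log2 is defined — then
quantile-normalized between arrays (each column's sorted values replaced by
the row means of the column-sorted matrix; ties receive the mean of the
quantile values their ranks span). The log2 transform sits between
correction and normalization and can be disabled. Probe-to-gene collapsing,
when needed, takes the per-gene median after normalization.

Per gene, a two-sample pooled-variance Student's t-test compares control
vs knockdown; zero pooled variance with equal means yields t = 0, p = 1.
Multiple testing uses Benjamini–Hochberg step-up by default (Bonferroni by
flag); "adjusted p" in the literature of such experiments rarely names the
procedure, and BH is the field default. Decreased/increased sets are
`{p < alpha, Δ < 0}` / `{p < alpha, Δ > 0}` with Δ = mean(knockdown) −
mean(control).

**Small-design caveat.** With `n` arrays per condition the pooled t has
`2n − 2` degrees of freedom. At the synthetic default of 4 + 4 arrays (6
df) the smallest raw p realistically attainable is ~1e-5, so BH-adjusted
p never reaches a stringent alpha like 0.001 over hundreds of genes and
adjusted-p DE sets are empty regardless of effect size. `de_sets` and the
pipeline therefore expose `de_use_adjusted`: large multi-array designs
should threshold adjusted p (the default); small designs threshold raw p
at the same alpha, which is how the package's own replicate studies and
acceptance script run. The null-calibration study confirms the raw-p count
at alpha is binomially calibrated.

## Activator/repressor inference

For gene set S and background B, each gene's distance is the minimum
|summit − TSS| over the factor's same-chromosome peaks; genes with no peak
on their chromosome carry an infinite sentinel and are excluded from ECDFs
(their count is reported, never imputed — imputation would distort the
tail). The one-sided statistic is D+ = sup_x [F_S(x) − F_B(x)], positive
when S is stochastically closer to the TSS, with asymptotic
p = exp(−2·n_eff·D+²), n_eff = mn/(m+n) — the standard one-sided
two-sample tail; an exact label-permutation p (add-one estimator) is
available by flag and agrees with the asymptotic form to ~0.04 absolute at
sample sizes ≤ 30 (the asymptotic tail carries O(1/n) bias on top of
Monte-Carlo error). The background defaults to expressed genes outside
both DE sets; an all-genes option exists because the appropriate universe
is context-dependent.

A factor receives *activator evidence* when the decreased-after-knockdown
set's KS p is below `ks_alpha` (default 0.01) and *repressor evidence*
likewise for the increased set; the labels are deliberately
`decreased_after_kd`/`increased_after_kd` rather than "up/down-regulated",
which flips meaning depending on whether one speaks of the knockdown or
the factor.

Regulatory potential is RP(g) = Σ over peaks within `rp_horizon` (100 kb)
of exp(−(0.5 + 4·d/Δ)) with Δ = `rp_decay_distance` = 100 kb: smooth,
additive over peaks, strictly decreasing in distance, and zero exactly
when no peak is in the horizon. Any monotone decay preserves the module's
guarantees; this form makes a TSS-proximal peak worth e⁻⁰·⁵ ≈ 0.61 and a
peak at Δ worth e⁻⁴·⁵ ≈ 0.011. Top active/repressive targets are chosen
per direction by the product of tie-aware average ranks of DE p and of RP
(descending), ties broken by gene id, so constant RP reduces the selection
to the DE ranking and vice versa.

## Motif enrichment

Only known-motif (PWM) enrichment is implemented — de novo discovery is a
different tool's job and out of scope. Windows are `motif_window` (600 bp)
centred on summits, truncated at chromosome bounds. Scoring is log2-odds
against the PWM background at every offset on both strands; `N` bases
contribute 0. The default hit threshold is 80% of the PWM's maximum
achievable score (common practice, config-exposed). Enrichment is a
one-sided Fisher exact test of the per-window hit indicator, foreground
(peak windows) vs background (count-matched random same-width windows from
the same chromosomes, seeded); the odds ratio uses a Haldane 0.5 correction
when a cell is zero. The shipped REST/NRSE (21 bp) and E2F1 (8 bp) matrices
are *consensus-derived synthetic stand-ins* built from the published
consensus sequences (dominant base ~94% per position), not curated database
matrices; they are adequate for planted-motif recovery and for consensus
scanning but should be replaced by curated matrices (JASPAR-format text is
accepted) for real data.

## Synthetic data generator

The generator emulates the statistical structure of a three-factor
promoter co-binding study with a knockdown readout. Defaults: 2
chromosomes × 5 Mb, 500 genes placed with ≥ 10 kb TSS spacing, 300 peaks
per factor of which 60% have summits within ±3 kb of a TSS (truncated
normal, sd 1 kb) and the rest are intergenic; fold enrichment ~
Uniform(2, 50); a co-binding fraction of 0.2 of factor-A peaks receives a
partner peak with ≤ 100 bp summit jitter (mirroring the ~0.21 ensemble
fraction such studies report), while non-co-bound partner peaks are kept
≥ 1 kb from every factor-A summit so the planted solo/ensemble labels are
exact. Coverage is a sum of triangular kernels (half-width 300 bp, height
= fold), whose discrete mass is exactly 300 × fold — read-level simulation
is deliberately out of scope since the profile code consumes coverage.

Expression is generated directly on the log2 scale (control mean ~
N(8, 1), iid N(0, 0.5) noise per sample, 4 control + 4 knockdown arrays);
the background-correction/normalization stage is exercised on its own
fixtures instead, keeping planted effect sizes interpretable. Each
factor-A-bound gene is assigned an activated or repressed role (50/50 when
both effects are enabled) and its knockdown mean shifts by
∓effect·exp(−d/2000 bp) — a 2.0 log2-unit effect at the summit decaying
over promoter scale. The NRSE consensus is planted under ensemble summits
at rate 0.8 and in recorded background windows at rate 0.1. All randomness
flows from one seed; a fixed seed reproduces byte-identical files.

What the generator does **not** emulate: read-count noise, fragment-length
effects, probe-level microarray structure, correlated gene expression,
chromatin-state confounding, and realistic genome composition. Passing the
recovery studies therefore demonstrates the pipeline's statistical
machinery is correct and calibrated under its stated model, not that the
biological conclusions transfer to any particular real dataset.

## Replicate studies and problem sizes

The package's own validation runs at desk scale, chosen so the full suite
completes in well under a minute of compute per study: null calibration
uses 50 replicates of the 500-gene design with zero effects and noise sd
1.0 (raw-p DE count binomially consistent with alpha × n_genes; no
direction label at KS alpha 0.05 in ≥ 90% of replicates), and parameter
recovery uses 100 replicates of the activator-only design (decreased-set
KS p < 0.01 in ≥ 95%) plus 20 dual-role replicates (both labels). The
full-scale figures reported in the motivating literature (tens of
thousands of peaks, thousands of DE genes, p-values like 1e-266) require
the original raw datasets and are outside what synthetic desk-scale runs
can or should reproduce.

## Known limitations

- The ensemble/solo truth is defined against the unfiltered partner peak
  set; when the pipeline fold-filters partner peaks, planted-ensemble
  peaks whose only partner fails the filter are (correctly) classified
  solo, so ensemble "accuracy" against the planted flags is slightly
  below 1 in filtered runs.
- The asymptotic one-sided KS p is anti-conservative by O(1/n) for very
  small sets; use the permutation method for sets of a dozen genes or
  fewer when the call is borderline.
- The feature classifier resolves overlapping genes by category
  precedence, not by transcript expression; UTR calls require CDS bounds
  in the annotation.
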