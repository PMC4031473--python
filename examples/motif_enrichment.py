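"""PWM motif enrichment in summit-centred windows.

Scans the shipped consensus-derived REST/NRSE matrix over 600-bp windows
around ensemble-peak summits and compares the hit rate against random
background windows with a one-sided Fisher exact test.
"""

import chipexpr as ce

ds = ce.generate(ce.SyntheticConfig(seed=5))
part = ce.partition_solo_ensemble(ds.peaks["TF_A"], ds.peaks["TF_B"])

pwm = ce.load_builtin_pwm("rest_nrse")
fg = ce.summit_windows(part.ensemble, 600, ds.chrom_lengths)
bg = ce.random_background_windows(ds.chrom_lengths, 600, len(fg), seed=5)
res = ce.motif_enrichment_test(fg, bg, ds.genome, pwm)

print(f"windows: {res['fg_total']} ensemble vs {res['bg_total']} background")
print(f"hits: {res['fg_hits']} vs {res['bg_hits']} "
      f"(threshold {res['threshold_bits']:.1f} bits)")
print(f"odds ratio {res['odds_ratio']:.1f}, one-sided Fisher p = "
      f"{res['p_value']:.3g}")

# The generator plants the NRSE consensus under most ensemble summits
# and rarely in background, so the ensemble windows are strongly
# enriched — the same check used to tie a co-binding partner's motif to
# a factor's functional peaks.
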