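"""Estimate the effective promoter size and test for 'stacked' binding sites.

Two spatial questions about promoter architecture: (1) how far from the TSS
does binding-site enrichment persist before decaying into background?  The
boundary estimator sweeps window half-widths, smooths mean count vs width,
and finds where the derivative becomes constant.  (2) Are sites mutually
overlapping ('stacked') near the TSS?  The stacking test compares pairwise
overlap percentages against a within-promoter positional randomization.
"""

import numpy as np

from promarch import (
    SyntheticConfig,
    estimate_boundary,
    gen_annotation,
    gen_peaks,
    gen_richness,
    map_peaks_to_windows,
    promoter_window,
    stacking_test,
)

cfg = SyntheticConfig(seed=5, n_transcripts=1500)
annotations = gen_annotation(cfg)
richness = gen_richness(cfg)
peaks, _ = gen_peaks(cfg, annotations, richness)

est = estimate_boundary(annotations, peaks)
print("window half-width :", list(est.grid))
print("mean sites/window :", [round(m, 2) for m in est.mean_counts])
print(f"estimated promoter boundary: {est.boundary} bp from the TSS "
      f"(planted enrichment scale: {cfg.enrichment_scale} bp)")

# plant a fully stacked arrangement and detect it
stacked_cfg = cfg.with_(stacking_weight=1.0, n_transcripts=400)
s_anns = gen_annotation(stacked_cfg)
s_rich = np.maximum(gen_richness(stacked_cfg), 2)
s_peaks, _ = gen_peaks(stacked_cfg, s_anns, s_rich)
windows = [promoter_window(tx, 500) for tx in s_anns]
mapped = map_peaks_to_windows(windows, s_peaks)
pairs = [(w, mapped[w.tx_id]) for w in windows if len(mapped[w.tx_id]) >= 2]
res = stacking_test(pairs, n_randomizations=1, seed=1)
print(f"stacking: observed overlap {res.observed_mean_overlap_pct:.1f}% vs "
      f"randomized {res.null_mean_overlap_pct:.1f}% (p = {res.p_value:.1e}, "
      f"{res.n_pairs} pairs)")
# Observed >> randomized means sites pile up on each other at the TSS rather
# than scattering across the promoter.
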