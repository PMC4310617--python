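# promarch

Promoter architecture and expression breadth: does the transcription-factor
binding repertoire of a proximal promoter predict where — and how broadly — a
gene is expressed?

`promarch` is a Python library for regulatory genomicists working with
clustered ChIP-seq peak sets (ENCODE-style BED with 0–1000 quality scores and
a TF label per peak) and CAGE-style TPM expression tables (FANTOM5-style,
rows = transcripts, columns = tissues/primary cells/cell lines). It
implements the metrics and statistical procedures needed to link the two:

- **TFBS count metrics.** Peaks are mapped into a symmetric proximal-promoter
  window around the TSS (default ±500 bp, peaks with score > 500). Four
  variants are computed per transcript: total sites (*TfbsNo.*), distinct TF
  labels, and both with RNA-polymerase-class labels excluded.
- **Breadth of expression.** BoE = fraction of samples with TPM > 10
  (≈3 mRNA copies/cell at 300,000 mRNAs/cell), with the derived classes
  *unexpressed* / *narrow* (BoE ≤ 0.33) / *intermediate* / *housekeeping*
  (BoE > 0.66), level summaries across all samples and conditioned on the
  'on' samples only, and the preferential expression measure
  PEM(g, s) = TPM(g, s) / mean_s TPM(g, ·).
- **Association machinery.** Pearson/Spearman/Kendall correlations with their
  t-form tests, Spearman partial correlations via the precision matrix, a
  promoter-shuffle permutation null for the r(TfbsNo, BoE) t-statistic,
  correlation-distance (1 − r) hierarchical clustering with Newick export,
  and a radial-kernel SVM (cost = 1, γ = 0.01, ε = 0.1) predicting BoE or PEM
  from per-TF count vectors, with scrambled and retained controls.
- **Spatial structure.** An effective-promoter-size estimator (the window
  half-width where the growth of the mean count linearizes into background)
  and a "stacking" randomization test for mutually overlapping, TSS-piled
  binding sites.
- **Paralog divergence.** Jaccard index JI = |X ∩ Y| / |X ∪ Y| of two
  paralogs' TF repertoires versus their co-expression, pair enumeration
  (C(n,2) per family), youngest-pair selection, duplication-age
  stratification with Wilcoxon/Holm tests, and event classification
  (housekeeping-conserved / tissue-specific-conserved / transformative).
- **Synthetic data.** A fully seeded generator planting each of these
  effects (heavy-tailed counts, TSS-proximal enrichment decaying at 3 kb,
  stacking, a monotone count→breadth link, age-graded paralog divergence) so
  every stage is testable without any data download.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
$ python examples/02_breadth_vs_architecture.py
r(TfbsNo, BoE) = 0.460  (t = 32.8, df = 3998, p = 6.53e-209)
shuffled-promoter null: mean t = -0.0024, empirical p = 0.0010
breadth classes: {'narrow': 0.41, 'housekeeping': 0.24, 'intermediate': 0.19, 'unexpressed': 0.15}
```

The first line is the Pearson correlation between the number of binding
sites in the ±500 bp promoter (score > 500) and the breadth of expression at
the 10 TPM cutoff on 4,000 synthetic transcripts whose planted coupling
targets r ≈ 0.45. The second line shows that the permutation null (promoters
reassigned to transcripts at random) is centred at t ≈ 0 and that the
observed statistic is outside all 1,000 replicates. The third line is the
breadth-class composition of the simulated transcriptome.

```bash
$ python examples/03_promoter_boundary_and_stacking.py
estimated promoter boundary: 3000 bp from the TSS (planted enrichment scale: 3000 bp)
stacking: observed overlap 77.2% vs randomized 21.7% (p = 0.0e+00, 51652 pairs)
```

The boundary estimator recovers the planted 3 kb enrichment scale from the
linearization point of the count-growth derivative, and the stacking test
detects a fully TSS-piled arrangement against the within-promoter positional
randomization.

## Pipeline CLI

The same stages are runnable from a shell:

```bash
promarch simulate --seed 7 --out run/
promarch profile  --input-dir run/ --out run/profile
promarch associate --input-dir run/ --out run/assoc
```

Subcommands: `simulate`, `profile`, `breadth`, `associate`, `boundary`,
`stacking`, `paralogs`, `predict`. Each writes its tables plus a manifest
(config hash, seed, version) and accepts a YAML config
(`promarch <cmd> --config cfg.yaml`); defaults are ±500 bp windows, score
cutoff 500, TPM cutoffs 10/100/1000.

## Documentation

`docs/methods.md` describes the models, estimators, default parameters, the
synthetic generator's assumptions, and known limitations.
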