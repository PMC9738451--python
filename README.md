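# regenatlas

Binary temporal expression-pattern atlas and baseline-subtracted
gene-set enrichment for regeneration time-course RNA-seq.

## What problem this solves

Bulk RNA-seq time courses of regenerating tissue — the motivating case
is central-nervous-system regeneration in the solitary ascidian
*Polycarpa mytiligera*, sampled at an uncut control and 2, 7, 14 and 21
days post-amputation — pose a simple question with an awkward shape:
*at which stages is each gene "on"?* Pairwise differential-expression
calls between stages answer a different question (is A higher than B?),
and a gene tested across all stage pairs yields a tangle of up/down
calls that can even disagree.

`regenatlas` turns that tangle into a single per-gene summary. For each
gene, its significant pairwise calls induce a **hierarchy** of directed
relations "higher at *a* than at *b*" between timepoints. Every binary
pattern *p* ∈ {0,1}^T over the T timepoints (1 = dynamically high,
0 = dynamically low) is scored against the hierarchy:

  score(p) = (# up/down timepoint labels the pattern shares with the
  hierarchy) − (# labels on which they disagree),

i.e. each relation (a, b) contributes +1 if p<sub>a</sub> = 1 else −1,
and +1 if p<sub>b</sub> = 0 else −1. The best-scoring pattern (exhaustive
enumeration; ties broken toward fewest 1s, then lexicographically)
becomes the gene's row in a **binary gene × timepoint matrix** — an
atlas of when each gene is dynamically active.

On top of the atlas, gene-set activity per timepoint is measured as the
percentage of a set's genes active at *t*, compared against a
hypergeometric null: a random size-*s* draw from the *N*-gene universe
with K<sub>t</sub> active genes has expectation 100·K<sub>t</sub>/N and
1-SD halfwidth 100·√(s·(K<sub>t</sub>/N)(1−K<sub>t</sub>/N)(N−s)/(N−1))/s.
The baseline (and band) is subtracted and negative values are clamped to
0%, giving **adjusted enrichment curves**; an upper-tail hypergeometric
ORA with Benjamini–Hochberg correction covers the discrete question
"is this set over-represented among dynamic genes?".

The package ships a negative-binomial simulator (planted patterns,
planted-enrichment gene sets, full ground truth) so the entire pipeline
is testable at desk scale, plus pairwise DE (a calibrated NB Wald-type
stand-in behind a pluggable direction-call contract), TSV/GMT readers
and writers, a reproducible end-to-end pipeline with a checksummed run
manifest, and a CLI. See `docs/methods.md` for models and choices.

## Worked example

```python
import regenatlas as ra
from regenatlas.de import run_all_pairwise

config = ra.SimulationConfig(n_genes=1000, frac_patterned=0.3, fold_change=8.0,
                             dispersion_range=(0.05, 0.05), seed=42)
counts, truth = ra.simulate_counts(config)

filtered = ra.filter_genes(counts)              # drop low-count genes
de_results = run_all_pairwise(filtered)          # 10 pairwise comparisons
atlas = ra.binarize_all(de_results, config.design)

gene = truth.patterned_genes()[0]
print("true pattern:     ", truth.genes.set_index("gene_id").loc[gene, "pattern"])
print("recovered pattern:", "".join(str(b) for b in atlas.values.loc[gene]))

planted, _ = ra.simulate_genesets(truth, 1, 40, "7dpa", purity=0.8, seed=43)
print(ra.enrichment_curve(atlas, planted[0]).table.round(2).to_string(index=False))
```

prints

```
true pattern:      01010
recovered pattern: 01010
timepoint  raw_percent  baseline_percent  band_low_percent  band_high_percent  adjusted_percent
  control         47.5             14.93               0.0               5.52             32.57
     2dpa         40.0             14.93               0.0               5.52             25.07
     7dpa         80.0             15.73               0.0               5.64             64.27
    14dpa         35.0             17.74               0.0               5.92             17.26
    21dpa         40.0             16.73               0.0               5.79             23.27
```

The gene's planted on/off profile (high at 2 and 14 dpa) is recovered
exactly from the DE calls alone. The gene set, planted so that 80% of
its members are truly active at 7 dpa, peaks there: 80% of its genes are
active against a 15.7% random-draw baseline, an adjusted enrichment of
64.3% — far outside the 1-SD band (5.6%). The elevation at other
timepoints is real, not an artifact: genes drawn by "active at 7 dpa"
are active elsewhere too, because planted patterns couple timepoints
(see `exclusive=True` in `simulate_genesets` and `docs/methods.md`).

The same run as a shell pipeline:

```sh
regenatlas simulate --n-genes 1000 --fold-change 8 --seed 42 --out-dir demo/
regenatlas de --counts demo/counts.tsv --design demo/design.tsv --out-dir demo/de/
regenatlas binarize --de-dir demo/de --design demo/design.tsv --out demo/atlas.tsv
```

or, end to end with a YAML config and a checksummed manifest,
`regenatlas run --config pipeline.yaml --out-dir run/`.

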