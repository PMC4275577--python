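# interleave

Gene-order architecture analysis for interleaved genomes — built around
the budding-yeast situation in which coding transcripts (ORF-Ts), stable
and cryptic non-coding transcripts (SUTs, CUTs) and metabolic-cycle
(YMC)-phased genes are packed so tightly that orientation, 3'-end overlap
and neighbourhood become regulatory variables in their own right.

The package answers two families of questions:

1. **Who switches?**  Given normalized nascent-transcription levels in
   two conditions (e.g. glucose → galactose), classify every feature by
   fold change (`>3×` up, `>3×` down, unchanged), compare against a
   steady-state RNA source to separate transcription-driven from
   stability-driven changes, and measure set overlaps (e.g. switched
   genes vs OX/RC-phase genes) with hypergeometric tails.

2. **Is the arrangement non-random?**  Build adjacent-pair relations
   (tandem / convergent / divergent, signed gaps, a 1,000-bp eligibility
   rule), call convergent 3'-end overlaps, class cycling genes by their
   cycling neighbours — and test *any* such statistic against a
   **constrained shuffle null**: feature intervals stay fixed (all
   inter-gene distances preserved), while strand, feature class and YMC
   phase are permuted within each chromosome and expression vectors are
   resampled from the recorded pool.  For a statistic `T` the engine
   reports the enrichment ratio `T_obs / mean(T_null)` and add-one
   empirical p-values `(1 + #{T_null ≥ T_obs}) / (n_iter + 1)`.

A synthetic-genome generator with plantable effects (convergent-overlap
excess, YMC clustering, phase-linked switching, antisense signal, factor
occupancy) provides ground truth for every claim the test suite makes.

## Worked example

```python
import interleave as il

params = il.SyntheticGenomeParams.yeastlike(seed=42,
                                            planted_overlap_enrichment=3.0)
table, truth = il.generate_genome(params)

switches = il.classify_switch(table, "glu", "gal")
print(il.switch_counts(switches))

model = il.ShuffleNullModel(
    table,
    {"conv_overlap": il.count_convergent_overlaps},
    il.ShuffleConfig(n_iter=2000, seed=7),
)
res = model.fit()
print(res.summary().round(3).to_string())
print(il.ymc_adjacency_counts(table))
```

prints

```
{'UP3': 680, 'DOWN3': 422, 'UNCHANGED': 5458}
              observed  null_mean  null_sd  null_q025  null_q975  enrichment_ratio  p_greater  p_less  n_iter
key
conv_overlap     344.0    109.152    8.905       92.0      127.0             3.152        0.0     1.0    2000
{'FLANKED_NONCYCLING': 736, 'SINGLE_PARTNER': 1226, 'DOUBLE_PARTNER': 542}
```

Reading it: of 6,560 features, 680 rise and 422 fall more than threefold
on the glucose→galactose shift.  The genome contains 344 convergent
gene pairs whose 3' ends overlap; under 2,000 within-chromosome shuffles
the expected count is ≈109, so convergent overlaps occur ≈3.2× more
often than chance arrangement would produce (the generator planted a 3×
excess) — `p_greater` is at its floor, 1/2001 (printed 0.0 at 3
decimals).  Among cycling genes, 736 are flanked by non-cycling genes,
1,226 have one cycling partner and 542 two.

The same stages run from the shell:

```sh
interleave simulate --seed 42 --out-dir sim/
interleave all --features sim/features.tsv --out-dir report/ \
    --n-iter 2000 --seed 7
```

`report/summary.json` holds the machine-readable results; TSVs hold the
per-feature tables.  See `docs/methods.md` for the model, its
assumptions and the generator's scope.

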