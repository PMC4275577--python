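# Methods

## The question the package answers

Budding-yeast transcription is heavily interleaved: coding transcripts
(ORF-Ts) sit next to and on top of non-coding transcripts (SUTs, CUTs),
3' ends of convergent gene pairs read into the same stretch of DNA, and
genes whose transcripts cycle with the yeast metabolic cycle (YMC; phases
OX, RB, RC, with NC for non-cycling) are clustered along chromosomes.
`interleave` asks, for any such feature of gene organisation, *does the
observed genome show more (or less) of it than expected?* — where
"expected" is defined by a constrained permutation null rather than a
parametric model.

## The shuffle null

A null genome keeps every feature interval exactly where it is (so all
inter-gene distances are preserved) and permutes, within each chromosome,
the per-gene attribute tuples (strand, feature class, YMC phase) over the
interval slots.  Per-chromosome totals per strand, per class and per phase
are therefore conserved by construction.  Expression vectors — all
conditions of one gene together — are resampled with replacement from the
pool of recorded vectors (genome-wide by default; per-chromosome as an
option).  For a statistic *T* the engine reports, over `n_iter`
permutations (default 10,000):

* the observed value and the null mean, SD and 2.5%/97.5% quantiles;
* the enrichment ratio `observed / null_mean` ("times more than
  expected");
* add-one empirical p-values
  `p_greater = (1 + #{T_null >= T_obs}) / (n_iter + 1)` and the analogous
  `p_less`.  Ties count as at least as extreme, so p is never below
  `1/(n_iter + 1)` and the estimator is valid for discrete statistics.

Design choices that were genuinely open:

* **Joint vs independent shuffling.** The attribute tuple moves as one
  unit by default, preserving within-gene correlations between strand,
  class and phase while still satisfying all marginal constraints;
  `joint=False` permutes fields independently for sensitivity analysis.
* **Expression pool scope.** Resampling is genome-wide by default;
  per-chromosome pooling is available (`expression_pool="chromosome"`).
* **Fixed slots, moving attributes.** Moving genes while preserving gap
  multisets would preserve distances only as a multiset; fixing intervals
  preserves every pairwise distance exactly, which is the stronger and
  simpler reading of "distances between genes kept constant".
* **Reproducibility.** One master seed; per-iteration generators are
  spawned from a `SeedSequence`, so runs are deterministic and iterations
  independent of evaluation order.

The engine is exposed in the model/results idiom: `ShuffleNullModel(table,
statistics, config).fit()` returns a `ShuffleNullResults` with `summary()`
(one row per statistic key), `to_tsv()` and `plot_null()`.

## Pair geometry

Coordinates are 1-based, fully closed (GFF3 convention); BED input is
converted at the boundary.  For genomically ordered neighbours the gap is
`second.start − first.end − 1`: touching genes have gap 0, overlapping
ones a negative gap.  Pairs more than 1,000 bp apart are kept in the
relation table but flagged ineligible and excluded from category counts —
the neighbourhood analyses concern genes that actually have a close
neighbour.  Orientation is tandem (same strand), convergent ((+,−) in
genomic order) or divergent ((−,+)).

A **convergent 3'-overlap** requires opposite strands, a non-empty
interval intersection, and — under the default strict rule — both genes'
3'-terminal bases inside the intersection; that is the geometry in which
two polymerases read through each other's 3' regions.  The relaxed rule
(`strict=False`) accepts any opposite-strand intersection.  The strict
rule is the default because an opposite-strand intersection at 5' ends
(divergent promoters sharing a nucleosome-free region) is a different
biological object.

**YMC adjacency** classes each cycling gene by how many of its eligible
neighbours (ORF-Ts by default) also cycle: flanked by non-cycling genes,
one cycling partner, or cycling partners on both sides.  Chromosome-
terminal genes have one neighbour at most and can reach only the
single-partner class; this slightly favours the lower classes but affects
2 genes per chromosome.

## Switch classification

Fold change is `(expr_gal + c) / (expr_glu + c)` with pseudocount
`c = 0.5`, keeping ratios defined at zero signal and exactly reciprocal
under condition swap.  A gene is UP3 above threefold, DOWN3 below
one-third, else UNCHANGED; the boundary is strict.  When a second
(steady-state) fold-change source is supplied, a gene is
transcription-driven if both sources cross the threshold in the same
direction, stability-driven if only the steady-state source crosses it or
the directions disagree, and indeterminate otherwise.  The rule is an
operationalisation — only the outcome fraction, not the rule, is standard
in the literature — so both the threshold and the rule live behind one
function.

Set overlaps (e.g. OX+RC genes vs switched genes) carry a hypergeometric
upper-tail p-value; a permutation p from the shuffle engine can be used
instead when the categorical structure matters.

## Antisense quantification

Sense signal is same-strand per-base coverage summed over the feature
interval, antisense the opposite-strand sum over the same interval, with
no flank extension.  Inputs are per-base 3'OH-clipped nascent-transcription
signals, so sums are signal mass, not read counts.

## Factor enrichment

Binary occupancy (factors × gene promoters) is tested per factor with the
hypergeometric upper tail against the matrix's gene universe; a factor is
flagged at raw p < 0.01, mirroring the criterion used for the published
202-factor compendium.  Benjamini–Hochberg q-values are reported alongside
but deliberately do not drive the flag.

## The synthetic genome generator

The generator emulates the structure of a yeast annotation-plus-NET-seq
table; it does **not** simulate sequence, reads or alignment.

* **Geometry.** Log-normal gene lengths (median 1.2 kb, σ=0.55 on the log
  scale, floor 60 bp) and gaps (median 220 bp, σ=0.9), so most neighbours
  fall within the 1 kb eligibility window, as in yeast.
* **Classes and phases.** Features are ORF_T/SUT/CUT/OTHER at
  0.70/0.15/0.12/0.03 and OX/RB/RC/NC at 0.20/0.05/0.31/0.44 — scale
  echoes of the yeast annotation (~6,600 features, ~2,700 OX+RC genes,
  ~1,800 SUTs+CUTs), not fitted values.  Cycling status runs along gene
  order as a first-order Markov chain with persistence `ymc_clustering`
  (default 0.3, a moderate clustering; 0 = independent), preserving the
  stationary cycling fraction.
* **Convergent-overlap excess.** Strands are i.i.d., so a random adjacent
  pair is convergent with probability 1/4.  Convergent pairs overlap with
  probability `convergent_overlap_rate` (default 0.2) and the other
  orientations with a background rate `p_c(4−r)/(3r)`, which makes the
  shuffle-null enrichment ratio of the strict convergent-overlap count
  equal to the requested `planted_overlap_enrichment` r.  r=1 (default)
  gives a fully exchangeable genome — the null's own regime; r>4 is
  geometrically impossible (even if every intersecting slot were
  convergent the ratio could not exceed 4) and is rejected.  Overlap
  lengths are log-normal with median 92 bp, clipped below both partners'
  lengths so features never nest.
* **Expression.** Per gene a log-normal baseline (median 12, σ=0.9)
  shared across conditions; a `phase_response_rate` (0.5) fraction of
  OX/RC genes receive a planted log fold change (−1.32 for OX, +1.32 for
  RC, i.e. ~3.7-fold down/up in galactose) split evenly across the two
  conditions, plus per-condition log-noise σ=0.3.  The partial response
  rate reproduces the observation that only a minority of cycling genes
  switch more than threefold on the carbon-source shift.
* **Coverage.** Per feature, Poisson per-base signal on its own strand
  with total mass `coverage_depth × expression`, and opposite-strand mass
  `f/(1−f)` times that, so the expected antisense *fraction* of the
  feature's total signal is exactly `f = antisense_fraction` (default
  0.2).  (Scaling antisense mass by `f` directly would make the fraction
  `f/(1+f)` and the planted value unrecoverable by the estimator the
  antisense module defines.)
* **Factors.** Bernoulli occupancy at `factor_baseline_rate` (0.10) over
  ORF-T promoters; planted entries multiply the binding odds inside a
  chosen gene set.

What the generator does *not* emulate — and what passing tests therefore
do not show: mappability artefacts, copy-number and rDNA regions,
overlapping transcription on the *same* strand (read-through/di-cistronic
units), condition-dependent antisense, correlations between feature class
and phase, and real chromosome-length heterogeneity.  Recovery results on
synthetic genomes validate the statistical machinery, not the biology of
any particular genome.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use: 100 small genomes for the
conservation check; 60,000 draws on a 3-slot chromosome for permutation
uniformity (±3 SE); 1,000 yeast-scale replicate genomes at n_iter=200 for
p-value calibration (Kolmogorov–Smirnov distance < 0.05) — yeast-scale
genomes keep the discrete overlap-count null fine-grained enough for the
add-one p-values to be near-uniform; a 2,000-feature genome at
n_iter=2,000 for planted-effect recovery (within 20% of the planted 3×);
and 100 occupancy replicates for factor power.  Medians of even-sized
groups are the mean of the two central values.  Empty categories are
omitted from summaries; in null aggregation a missing category key
contributes the model's `fill_value` (0 for counts).  Ratios with a zero
null mean are reported as NaN rather than infinity.

## Known limitations

* The neighbour graph uses the sorted-order adjacency; for nested
  features (one inside another) "nearest on each side" is resolved by the
  (start, end, id) sort key.  The generator never produces nested
  features.
* The strict 3'-overlap rule ignores opposite-strand pairs whose
  intersection excludes a 3' end (e.g. a short antisense unit inside a
  gene body); use `strict=False` for those.
* Expression resampling breaks any phase–expression coupling in the null;
  statistics that depend on that coupling (category medians by phase)
  test the joint hypothesis "placement and coupling random", not
  placement alone.
* Hypergeometric factor tests assume exchangeable promoters; no
  correction is made for promoter sharing by divergent gene pairs.
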