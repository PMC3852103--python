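# Methods

## Statistical model and procedure

The package targets the cancer-outlier regime of two-group expression
analysis: a feature (miRNA probe) is differentially expressed in a
fraction π of tumour samples only, with the remaining tumours
indistinguishable from normals. On the log scale, the working model per
feature is

    x_i ~ N(0, σ²)                      (normals, i = 1..n1)
    y_j ~ N(Δ_j, σ²)                    (tumours, j = 1..n2)

with Δ_j = ±μ for the shifted subset (|subset| = max(1, round(π·n2))) and
Δ_j = 0 otherwise. The six statistics score the evidence for such a shift;
all are evaluated one-sided toward over-expression and, by default, also on
the negated matrix so under-expression is scored through the identical code
path — per feature the direction with the larger magnitude wins, and the
sign of the reported score carries it. The t statistic is inherently
two-sided and keeps its own sign.

### Shared numerical conventions

These matter because the OS/ORT cutoffs sit on quantiles:

- scaled MAD: `madn(v) = 1.4826 · median(|v − median(v)|)` (normal-
  consistent constant; a monotone rescaling that cannot change top-quantile
  selections);
- quantiles: linear interpolation between order statistics at 1-based
  position `1 + (n−1)p` (numpy's `method="linear"`);
- outlier-set membership: strict `>` — values tied with the cutoff are
  excluded;
- zero-scale fallback: when the madn is exactly 0 the scale becomes
  `1.4826 · mean(|v − median(v)|)`; if that is also 0 the feature is
  flagged degenerate, scored 0, and excluded from selection. Degenerate
  flags shrink a method's selection pool (`ceil(q·m)` counts non-degenerate
  features only) rather than penalising other methods;
- LSOSS pooled variance uses df = n1 + n2 − 3 (two means fitted within the
  tumour group, one within normals) and breaks SSE ties at the smallest
  break point k;
- MOST standardisation uses Monte-Carlo moments (B = 10 000 by default) of
  the sums of the k largest of n2 iid standard normals. The table is cached
  per (n2, B, seed) and seeded independently of the simulation seed (seed 0
  by default) so that scoring a dataset is a pure function of the data.

A naive, loop-based scalar implementation of every statistic lives in the
test suite and is the normative reference: the vectorised code must agree
with it to 1e-9.

## Consensus framework

Selection is "top quantile": the `ceil(q·m)` features with the largest
|score|, q = 0.05 by default, ties at the boundary broken by lexicographic
feature ID. The alternative reading — thresholding at the 95th percentile
of the score distribution — differs only at ties and can return empty or
method-incomparable sets, so the count-based rule is used.

Putative outliers are features selected by ≥ k_m methods (k_m = 3 of 6);
method accuracy is the percentage of the method's own selection that is
putative; methods are ranked by median accuracy across datasets, ties by
smaller sample SD (ddof = 1), then name. Median-before-SD is a choice the
tie order of the underlying evaluation protocol leaves open; it is fixed
here and exposed through the ranking object. The winner's per-dataset
selections feed the target stage.

Cross-dataset consensus is computed at the gene level by default: per
dataset, the union of target genes of its selected miRNAs; then genes
present in ≥ k_d (default 3) of the per-dataset sets, with an exact
multiplicity breakdown whose tail sums reproduce the ≥k count. A
miRNA-level mode (consensus on the miRNAs first, targets second) is also
implemented because the two variants answer different questions and the
protocol literature uses both; gene-level is the default.

Target tables from several prediction tools are combined by pair-wise
intersection (a pair survives only if every tool reports it); a primary
curated map takes precedence, with the intersection filling in miRNAs the
primary map lacks.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) (the
standard convention, including the observed overlap) and Benjamini–
Hochberg step-up FDR. The gene universe is explicit: a generated collection
carries its full universe; a GMT read from disk defaults to the union of
its member genes, and callers are expected to pass the real background when
they have one, because the universe choice dominates hypergeometric p
values. Filtering applies the 0.001 cutoff to the FDR by default and to the
raw p value for KEGG-style collections, matching the thresholds the
protocol reports.

## The synthetic scenario generator

The generator emulates a four-dataset, multi-platform miRNA compendium:

- panels of 500 features per dataset drawn from a global namespace, with a
  common core sized so that every pairwise overlap |A∩B|/min(|A|,|B|)
  falls in (0.4, 0.6) — the loosely reported cross-platform probe overlap.
  The min-denominator overlap is a concrete measurable stand-in for that
  loose figure;
- group sizes 20 normals / 40 tumours, inside the 12–113 per-group range of
  the real datasets the structure mimics;
- de_fraction = 0.05 so that the planted DE count equals the top-5%
  selection size — the matched design in which recall is interpretable;
  π = 0.2, μ = 2, σ = 1 as the heterogeneous base condition;
- 70% of each dataset's DE features are shared across datasets (drawn from
  the core), the rest private — so cross-dataset consensus has both signal
  and distractors;
- a 2000-gene universe with a 120-gene signal pool; every miRNA gets 15
  targets, shared DE-miRNAs draw 80% of theirs from the signal pool; 20
  gene sets of 40 genes, of which 5 are planted (70% signal genes) and 15
  are decoys built from non-signal genes.

Baseline expression is mean-zero Gaussian on the log scale. The statistics
are location/scale-based, so a realistic baseline mean or per-probe
intensity structure would be invisible to them; the generator therefore
omits probe effects, batch effects, platform-specific normalisation and
mean–variance trends. Passing tests consequently demonstrate correctness
of the statistics and the consensus machinery under the assumed outlier
model, not robustness to microarray artefacts. `direction="mixed"` splits
DE features half up-, half down-shifted (odd counts: one extra up).

Standalone `generate_dataset` draws its panel loosely from a double-size
pool; only `generate_scenario` enforces the overlap-range construction.

## Determinism and problem sizes

Every random choice flows from `numpy.random.default_rng` seeded by the
configuration ((seed, stream) pairs for per-dataset and per-predictor
streams), and rerunning any pipeline with the same configuration produces
byte-identical output files (floats are written at full round-trip
precision; JSON keys are sorted; stage timings go to the console logger
only, never into output files). The benchmark problem sizes — 20 seeds of
a 1000-feature, 25 + 25-sample dataset for the power comparison, 20
four-dataset scenarios for the ranking study, 10 for pathway recovery —
were chosen to keep the whole suite and the acceptance script in the
tens-of-seconds range while leaving the binomial noise on the reported
rates well below the effect sizes being demonstrated.

## Known limitations

- OS loses power as π grows (its cutoff is computed over all samples, so a
  large shifted subset inflates its own threshold); this is a property of
  the statistic, visible in the benchmarks, not a defect of the
  implementation. COPA and OS likewise fade at π = 1 where the t-test is
  optimal.
- The putative-outlier "accuracy" measures cross-method agreement, not
  truth recovery; a method can be accurate by agreeing with five wrong
  methods. The simulation benchmarks report truth-based recall alongside
  it for exactly this reason.
- Enrichment treats gene sets as flat sets: no ontology topology,
  gene-length or multiplicity weighting.
- ID harmonisation across platforms is assumed done upstream (shared
  global feature IDs); features private to one dataset are reported but
  simply cannot reach the cross-dataset consensus.
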