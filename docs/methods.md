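# Methods notes

This note documents the statistical models, the tunable parameters, the
synthetic-data generator, and the design decisions taken where the procedure
admitted more than one reasonable reading. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed throughout

Two genotypes (lean wild-type `WT`, obese `OB`), an oral glucose bolus after
fasting, sampling at 0/20/60/120/240 min with n = 5 replicates per genotype
and time point. The 0-min sample is the within-genotype baseline for every
contrast. Abundances are non-negative; a missing cell means non-detection,
never zero. Three omic layers are handled: metabolites and phosphosites
(continuous, lognormal-like noise) and gene counts (overdispersed,
RNA-seq-like).

## Responsiveness calling

* **Detection filter.** A molecule is dropped when, at any *post-bolus* time
  point in either genotype, fewer than `min_detected_fraction` (default 0.5)
  of replicates are non-missing. The inequality is strict ("less than
  half"), so exactly half survives. Baseline missingness does not trigger
  removal, but a molecule whose baseline mean is zero or undefined gets no
  fold change and can never be called.
* **Per-time tests.** Metabolites/phosphosites: two-tailed Welch's *t* with
  Satterthwaite degrees of freedom (delegated to scipy's distributions, with
  explicit conventions: both groups constant and equal → p = 1; constant but
  unequal, or fewer than two values → undefined and flagged). Genes: a
  pluggable count test registered by name; the default scales each sample by
  its library size to the per-layer median total and applies Welch on
  log₂(count + 1). The registry exists because exact negative-binomial
  testing is a deliberate non-goal; any callable `f(a, b) -> p` can be
  registered and selected through `PipelineConfig.count_test_method`.
* **Multiple testing.** Storey q-values with pi0 estimated on the lambda
  grid 0.05…0.95 (step 0.05) by a cubic polynomial smoother evaluated at the
  largest lambda, clamped to (1/m, 1]. A fixed-lambda mode (single-point
  estimate) exists for exactly checkable unit tests, and `pi0 = 1` reduces
  the procedure to Benjamini–Hochberg exactly. q-values are pooled across
  molecules **per time point** within one layer × genotype (the most common
  reading of per-time-point testing); a pooled-across-times mode sits behind
  `qvalue_pooling="pooled"`.
* **Call rule.** Responsive ⇔ q ≤ 0.1 and |log₂FC| ≥ 0.585 at any post-bolus
  time; direction is the fold-change sign at the earliest significant time.
* **T₁/₂.** Computed on the log₂ fold-change trace (baseline 0 at t = 0):
  amplitude is the extremum of the trace in the called direction over the
  sampled grid, and T₁/₂ is the first crossing of half that amplitude,
  linearly interpolated between samples, scanning left to right. The log₂
  scale is the same scale on which responsiveness and amplitude are defined,
  and it makes the generator's planted half-times exactly recoverable in the
  noise-free limit. Two estimator properties worth knowing: (i) linear
  interpolation of a concave saturating curve biases the crossing slightly
  upward between widely spaced samples (≈ +3 min at t_half = 35 on this
  grid), and (ii) the grid extremum underestimates the asymptotic amplitude
  for slow responses. Both effects are small relative to the 20/60-min
  class boundaries. Speed classes: rapid < 20 min, slow > 60 min; the
  boundary values 20 and 60 fall in the intermediate class. A flat trace on
  a responsive molecule leaves T₁/₂ undefined with a logged warning.

## Clustering and TF inference

* Metabolite traces are divided by the geometric mean of the two genotype
  fasting means and log₂-transformed; gene traces are z-scored over the
  concatenated (WT, OB) mean trace. Clustering input is replicate-averaged
  (mean traces), Ward linkage on Euclidean distances via scipy.
* Genes enter the clustering when their baseline WT-vs-OB contrast has
  q < 0.1 **or** any post-bolus time has q < 0.1 in either genotype (no fold
  threshold here). In practice this keeps most of the panel, which matches
  the permissiveness of the published filter and is intentional: the filter
  exists to bound the test count, not to call responders.
* Motif enrichment is evaluated at **every** dendrogram node with at least
  `min_cluster_size_for_enrichment` (100) genes — not only at a fixed cut —
  because the child-exclusion rule needs parent/descendant comparisons. The
  2×2 table contrasts motif presence inside the node against the rest of
  the clustering background; p-values are one-tailed (enrichment) Fisher,
  BH-adjusted across all (TF, node) pairs.
* **Child-cluster exclusion.** A TF is assigned to an enriched node unless
  some large descendant node has a *strictly greater* odds ratio for the
  motif; ties keep the parent (a p-value comparator is available behind
  `enrichment_comparator="p"`). Odds ratios use no continuity correction;
  zero cells give exact 0 or inf so tie behavior stays transparent.
* One-tailed Fisher p-values are computed as exact integer hypergeometric
  tail sums for universes up to 500 elements (cached binomial table) and by
  scipy's hypergeometric survival function above that; tests compare both
  routes against independent oracles.

## Network assembly

* Layer identity (which ids are TFs, metabolic enzyme genes, signaling
  molecules) comes from the knowledge tables and must be disjoint.
  Responsive metabolites populate the Metabolite layer; enzymes and TFs
  enter through either a responsive transcript or responsive
  phosphorylation. When both routes fire, the transcript governs the node's
  direction; the origin is recorded in `direction_source`.
* Reactions exist only when regulated: by a responsive enzyme
  (enzyme→reaction), a responsive allosteric effector (mode preserved), or a
  responsive substrate/product (reversibility unknown, so both count). A
  metabolite that is both an allosteric effector and a substrate of the same
  reaction contributes two edges of distinct types. Reaction-target edges
  are unsigned and inherit the regulator's response class.
* Signed edges (kinase→TF, kinase→enzyme, TF→enzyme-gene) exist for a
  genotype only when both endpoints respond in it; the sign is direction
  concordance. The edge's genotype class is derived by conjunction:
  WT-only / OB-only / both-with-equal-signs (common) / both-with-opposite
  signs (opposite). TF repressor status (from the knowledge tables' GO-style
  annotation) rides along as an edge attribute and never flips the
  concordance sign.
* Regulation summaries count, per genotype, reactions regulated by enzymes
  only / metabolites only / both (these three always partition the regulated
  reactions); reactions reached per T₁/₂ bin; and the regulators covering
  strictly more than 15 reactions (TFs counted through their enzyme
  targets).

## Condensation

* The association test for (regulator, pathway) uses the universe of **all**
  knowledge-base reactions (not only responsive ones), one-tailed Fisher,
  BH across all tested pairs, significance at q ≤ 0.01. Metabolites and TFs
  are tested; enzymes are summarized through coverage instead.
* Pathway selection is the union of (i) significant association with any
  regulator and (ii) top-10% regulated-reaction coverage by metabolites or
  by enzyme genes (gene route only — phospho-only enzyme regulation does not
  count toward coverage, matching the condensed enzyme layer definition).
  The 10% cutoff is `ceil(0.10 × pathways with ≥ 1 regulated reaction)` with
  boundary ties included, which keeps the rule order-independent.
* Metabolite→pathway edges need ≥ 5 covered reactions; the TF criterion
  (≥ 5) applies to the TF's total regulated reactions, not per edge. The
  methods-versus-legend ambiguity between "five metabolic reactions" and
  "five metabolic enzymes" is resolved toward reactions by default, with
  `tf_min_basis="enzymes"` as the alternative. A reaction belonging to
  several pathways contributes to each.

## Synthetic data generator

The generator is the package's test bed; its defaults *are* the emulated
study conditions.

* **Trajectories.** A planted responder deviates on the log₂ scale by
  d(t) = A·(1 − 2^(−t/t_half)), so the continuous log₂ trace crosses half
  its amplitude at exactly `t_half`. Default |A| = 1.5 log₂ units
  (comfortably above the 0.585 calling threshold). Planted T₁/₂ values are
  drawn from rapid (5–15 min), intermediate (30–50) and slow (90–200)
  ranges.
* **Noise.** Metabolites/phosphosites: multiplicative lognormal with CV 0.2.
  Genes: negative binomial with dispersion 0.05 around the scaled mean.
  Missingness is missing-completely-at-random (default 2% on metabolites
  only). All randomness flows from one seed through named per-table
  generators, so individual tables regenerate in isolation.
* **Default study composition** (`generate_study_bundle`): 104 metabolites
  with 29 planted responders — 21 WT-specific decreases, 4 OB-specific
  increases, 4 OB-specific decreases — mirroring the emulated metabolome,
  including one strong rapid ketone-body-like decrease whose expected 20-min
  fold change is exactly 0.13 (A = log₂0.13 / (1 − 2^(−20/6)), t_half = 6).
  Ten phosphoproteins span common/specific/opposite patterns over six
  signaling molecules, two TFs and two enzymes. The gene panel holds three
  planted TF-driven clusters of 120 genes; co-regulated cluster genes share
  one transcriptional wave (one pattern and one representative T₁/₂ per
  cluster: 10/40/140 min), which is what makes the planted cluster a
  coherent dendrogram node. Planted TFs carry their motif in 40% of cluster
  genes versus 5% elsewhere. A 480-gene background contains 60 scattered
  responders with randomized patterns and speeds. Nine responsive
  metabolites are wired as currency-like hubs concentrated in one pathway
  each (70% of its reactions), giving the association and condensation
  stages realistic structure. The gene panel is deliberately small (~850
  genes versus tens of thousands in a real transcriptome) — the package's
  chosen test scale; all thresholds operate unchanged at full scale.
* **Planted network truth.** The exact edge set an assembler must produce is
  derived inside the generator by direct set comprehensions over the truth
  labels and knowledge tables — an independent code path from the assembly
  module — so exact-recovery tests compare two implementations of the rules.
* **What the generator does not emulate:** kinetic metabolic dynamics (no
  ODEs), compositional/normalization artifacts of real RNA-seq, batch
  effects, correlated noise between molecules, and annotation errors in the
  knowledge tables. Passing recovery tests therefore demonstrates the
  statistical contracts of the pipeline under the declared noise model, not
  performance on real data.

## Numerical and degenerate-input conventions

* Welch: both groups constant and equal → p = 1; constant unequal → NaN
  (flagged); under two replicates → NaN.
* Storey pi0 clamped to (1/m, 1]; q-values clipped at 1; input order
  preserved.
* Odds ratios report exact 0/inf on zero cells; a doubly degenerate table
  (0·d and b·0 both zero) yields NaN.
* `q_threshold = 0` is legal and yields an empty network without error.
* All pipeline outputs are sorted deterministically; rerunning with the same
  inputs gives byte-identical artifacts.

## Known limitations

* The count test is a pragmatic default, not a negative-binomial exact test;
  power on low counts differs from dedicated RNA-seq machinery.
* T₁/₂ on 5-point grids carries the interpolation bias noted above; with
  CV 0.2 noise, class accuracy on planted data plateaus near 0.87 —
  crossing-time jitter near the 60-min boundary is the dominant error mode.
* The TF→cluster recovery criterion (every planted cluster covered with
  recall ≥ 0.9 and purity ≥ 0.5 by the TF's assigned targets) accepts
  assignments at a node slightly larger than the planted cluster, which is
  the correct behavior when background genes co-cluster with a planted wave.
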