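# Methods

This note documents the statistical model, the rules, the synthetic-data
generator and the numerical choices behind `anoxmeta`, together with the
rationale for the decisions that were genuinely open.

## Regularized differential expression

**Model.** Expression values are assumed log2-scale and approximately
Gaussian within replicate groups (the situation after GC-RMA-style
variance-stabilizing normalization of array data). With few replicates
(2–4 per group in the motivating compendia) per-gene variance estimates
are unstable, so each group's variance is shrunk toward a *local
background*: the root-mean-square standard deviation of the
`window_size` genes nearest in rank of group mean expression, centered on
the gene and truncated at the array edges. This exploits the
mean–variance coupling of array intensities without assuming a parametric
mean–variance curve.

**Shrinkage.** The regularized variance is the convex combination

    σ̃² = (v₀·σ₀² + (n−1)·s²) / (v₀ + n − 1),

where `v₀` acts as a prior sample size in pseudo-replicates. This
denominator convention (`v₀ + n − 1` rather than the `v₀ + n − 2` seen in
some regularized-t implementations) is deliberate: it makes σ̃² an exact
weighted average of `σ₀²` and `s²` — so shrinkage can never leave the
interval `[min(σ₀², s²), max(σ₀², s²)]` — and makes `v₀ = 0` reduce
*exactly* to the classical Welch statistic with no special casing. Both
properties are asserted by tests. With the default `v₀ = 10` and `n = 3`
the two conventions differ by a factor 12/11 on σ̃², immaterial next to
the choice of `v₀` itself.

**Test.** `t = (m_b − m_a)/sqrt(σ̃_a²/n_a + σ̃_b²/n_b)` referred to
Student's t with `n_a + n_b − 2 + 2·v₀` degrees of freedom — the prior
contributes `v₀` pseudo-observations per group. A `df_mode="classical"`
switch (plain `n_a + n_b − 2`) is provided for comparison.

**Defaults.** `window_size = 101` and `v₀ = 10` are the long-standing
web-server defaults of this test family; both are exposed in
`CyberTParams` and the YAML config. Observed variances are floored at
`1e-8` before shrinkage so tied (zero-variance) genes remain testable;
when `v₀ = 0` *and* every gene has zero observed variance there is
nothing to test and the model raises instead. p-values are clipped to
`[1e-300, 1]`.

**Calibration.** Under the null (pure replicate noise, 3 vs 3) the
statistic is slightly conservative — the shrunk variance is nearly the
truth while the reference distribution has only 24 df — giving an
empirical p<0.05 rate of ≈0.04. The null-calibration test asserts the
rate within 3 Monte-Carlo standard errors of 0.05 on 2,000 genes.

## PPDE: beta-uniform mixture

The contrast's p-values are modelled as

    f(p) = λ + (1−λ)·a·p^(a−1),   0 < p ≤ 1,  a ∈ (0, 1],

a uniform null component of weight λ plus a Beta(a, 1) alternative
concentrated near 0. PPDE(p) is the posterior weight of the alternative.
The fit is maximum likelihood via EM, which has closed-form M-steps
(λ ← 1 − mean(w);  a ← −Σw / Σ(w·log p) for posterior alternative weights
w), with 10 seeded restarts. p-values are clipped to `[1e-12, 1]` before
fitting.

Two numerical realities shape the implementation:

* **Ridge unidentifiability.** When the data are (close to) uniform the
  likelihood is flat along a → 1, where λ is meaningless (at a = 1 every λ
  gives the same density). The fitted mixture is therefore compared by
  BIC against the zero-parameter pure-uniform model; when the mixture
  does not earn its two parameters, the all-null fit (λ = 1, PPDE ≡ 0) is
  returned. This makes the PPDE conservative on null data — exactly the
  behaviour wanted from an FDR surrogate — and leaves genuine mixtures
  untouched (the BIC margin is thousands of log-likelihood units in the
  planted-effect settings).
* **Convergence.** EM creeps along the ridge (~1e-8 log-likelihood per
  iteration), so convergence is declared when the log-likelihood
  improves by < 1e-6 *or* the parameters move by < 1e-9 — precision far
  below any inferential relevance (the recovery test demands ±0.05).
  Failure from every restart raises an error carrying the last iterate.

PPDE is fitted **per contrast**, not compendium-wide: the null proportion
differs strongly between, say, an early germination step and an anoxia
switch, and per-contrast fitting keeps the FDR surrogate local.

## The three-part call

A gene is called up when all of: linear fold > 2 (strictly, i.e.
|log2fc| > 1), p < 0.05, PPDE > 0.96; symmetrically down; otherwise ns.
Fold-change is the difference of group means **on the log2 scale**
("mean of logs"), matching variance-stabilized input, and is computed
from raw (unshrunk) group means. A `ContrastSpec.orientation` of −1 flips
the reported log2 fold-change for comparisons that were published the
other way around, so "up" always means the response to the stress; the
t-statistic keeps its analysis orientation.

## Over-representation analysis

Per contrast, the up- and down-regulated sets are tested **separately**
(never pooled) against every bin of the annotation hierarchy — a gene
counts toward all ancestors of its bins — restricted to bins with at
least one background member. The test is the two-sided Fisher exact
probability of the 2×2 table [[k, n−k], [K−k, N−K−n+k]] (scipy's
`fisher_exact`; tests verify it against exact-rational enumeration of all
tables with N ≤ 12), converted to a signed z:

    z = Φ⁻¹(1 − p/2),  sign + if k/n > K/N, − if k/n < K/N, 0 if equal,

with |z| > 1.96 (two-sided p < 0.05) flagging significance. A discrete
edge case: when the observed table is the most probable one, p = 1 and
z = 0 even if the proportions differ slightly — z = 0 therefore means "no
evidence of deviation", not necessarily "proportions exactly equal".

**Background.** The background is the set of genes surviving the
detection filter in the study at hand, not the whole array: enrichment is
judged relative to what was measurable. Enlarging the background with
genes outside a bin can only increase that bin's z (tested property).

**Multiplicity.** No correction across bins by default — the 1.96 rule is
the convention this analysis style reports — with an optional Bonferroni
switch (applied to p before the z conversion) for stricter screens.

## Consensus rules

Throughout, "over-represented in a direction" means an enrichment row for
that direction's gene set with z > +1.96; significant
*under*-representation never satisfies a positive clause, and the
"not over-represented" exclusion clauses mean "not significant in the
same direction" (a bin significantly depleted in the excluded comparison
does not disqualify).

* **Conserved categories** (germination-trio style): bins
  over-represented in the stated direction in *every* study of a set;
  for step-wise studies each bin carries the contrast names and interval
  indices where it responded, and a `timing_match` flag reports whether
  two designated studies responded at the same interval index.
* **Condition-specific categories**: (target ∩ co-required) \ ∪excluded,
  same direction throughout — e.g. over-represented both against the
  aerobic control and over the anaerobic time course, while never over
  the aerobic time course.
* **Species consensus**: per bin and direction, count the comparisons per
  species where the bin is over-represented. `a_only` requires the k_a
  quorum in species A (default 3-of-4) *and zero* hits in species B;
  `b_only` symmetric (default 4-of-5); `both` requires ≥1 hit per
  species; otherwise `neither`. "Both" deliberately demands only one hit
  per species while species-specificity demands a quorum plus total
  absence elsewhere — specificity claims are stronger than sharing
  claims. Both quorums are configurable.
* **Overlap counts**: |DE(lowox_i) ∩ DE(abiotic_j)| per pair of
  comparisons. The default `any_direction` mode intersects full DE sets;
  a `matched` mode (same direction in both) is also emitted, since the
  direction convention of published overlap counts is ambiguous.
  Orientation is applied upstream, so both modes see the response to the
  stress.
* **Marker genes**: called up with linear fold > 50 in ≥ k comparisons of
  the low-oxygen set (k = 2 of 4 for species A, 3 of 5 for species B by
  default), using the maximum fold across passing comparisons for
  ranking. The abiotic-exclusion clause (drop genes up-regulated under
  any of cold/drought/salt/heat) defaults **on for species A and off for
  species B**, mirroring the asymmetry of the rule as usually stated;
  both are config switches. With fold_min = 2, k = 1 and exclusion off
  the operation degenerates to the union of up-called genes (tested
  identity).

## Orthology

Ortholog pairs are **inputs** (the pipeline never computes alignments):
one similarity-based table and one Inparanoid-style table, combined by
union — a pair supported by either source is accepted, with provenance
(similarity / inparanoid / both) recorded. The relation is many-to-many
and direction-agnostic; percent-identity values are carried as annotation
only, never used as a filter. Projection of a gene set into the partner
species reports, per (source gene, ortholog) pair, the ortholog's log2fc
and call in every foreign contrast, with genes absent from a foreign
result marked `not_detected` — distinct from a measured `ns`.

## Synthetic data

The generator emulates the *design* of a low-oxygen compendium, not the
biology of one:

* replicate value = per-gene baseline N(8, 2) + condition effect +
  N(0, noise_sd), all on the log2 scale, noise_sd = 0.25 by default;
* planted DE effects: magnitude uniform on a log2 interval (default 1–6,
  i.e. 2-fold to 64-fold; the marker planting uses 6.5 ≈ 90-fold), random
  sign, exactly `round(n_genes·de_fraction)` genes;
* time courses: planted step responders shift once at their designated
  interval and are otherwise flat;
* the two-species fixture (default 2,000 genes/species, 3 replicates,
  4 low-oxygen + 4 abiotic comparisons in species A, 5 + 4 in species B,
  2% background responders per contrast) plants: 300 ortholog pairs with
  conserved_up/conserved_down/divergent/opposite/unrelated classes (plus
  a few extra cross-pairs so the relation is genuinely many-to-many, and
  each evidence table holding ~80% of pairs so the union rule is
  exercised); two conserved enriched bins, one A-only bin (up in 3 of 4 A
  comparisons, never planted in B) and one B-only bin (4 of 5); three A
  markers, two B markers, and three decoys — one induced under salt
  (exclusion rule), one at ~37-fold (below the 50-fold cutoff), one
  missing the quorum. Planted roles live in reserved index blocks and
  background responders are drawn outside them, so truth labels are
  unambiguous;
* bins beyond the planted ones form a random two-level hierarchy
  (~30 bins, sizes log-uniform 10–200);
* detection calls are present except a configurable absent fraction
  (0.05 for single studies, 0 in the pair fixture).

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so sub-streams are independently reproducible and outputs are
bit-identical across runs.

**What passing tests do and do not show.** The generator's Gaussian,
gene-independent noise contains no batch effects, no probe-level
artifacts, no correlated co-expression blocks and no heavy tails (a
heavier-tailed option exists for robustness checks). Recovery of planted
truth therefore validates the *logic and calibration* of the pipeline —
thresholds, set rules, quorums — not its behaviour under real-world
confounding. A noted statistical subtlety: the per-gene "recover the
planted effect by group-mean differencing" bound of 3 standard deviations
of a difference of means (3·noise_sd·√(2/reps)) is a ~99.7% band, so with
hundreds of planted genes a few excursions are expected by construction;
the test asserts ≥98% coverage plus a median well inside, rather than a
universal bound no Gaussian sample satisfies.

## Problem sizes and runtime

Tests and the acceptance script use 2,000-gene studies (3 vs 3) for
calibration and power, 20,000 p-values for mixture recovery, exhaustive
Fisher enumeration to N = 12, 500 randomized instances per consensus
operation, and the default two-species fixture for end-to-end recovery —
sizes at which every Monte-Carlo band in the tests is meaningful while
the whole suite completes in well under a minute of compute.

## Known limitations

* The DE model is strictly two-group; no paired designs, no multi-group
  ANOVA-style extension.
* The PPDE mixture uses a single beta component; p-value distributions
  with mass near 1 (e.g. from discrete tests) would fit poorly.
* Fisher's test treats genes as exchangeable; inter-gene correlation
  inflates enrichment significance on real data, as it does for all ORA
  of this style.
* The consensus rules operate on significance flags, so they inherit the
  threshold behaviour of the upstream stages; near-threshold bins can
  flip classification between reruns of *different* data (not between
  reruns of the same data, which are deterministic).
* Normalization (MAS5/GC-RMA), probe-to-gene mapping and retrieval of
  public accessions are out of scope: the pipeline consumes
  already-normalized matrices and pre-computed ortholog tables.
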