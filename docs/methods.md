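# Methods

## Study design and data model

The pipeline assumes a factorial bulk-sequencing design: two organs
(generically A and B; in the motivating auditory setting the cochlear
sensory epithelium and the superior olivary complex), an ordered triple of
timepoints with the first acting as the embryonic baseline (E16 → P0 → P16,
generically T0/T1/T2), and ≥ 2 — typically 3 — replicates per
(organ, timepoint) condition. Inputs are integer feature × sample count
matrices with a sample sheet, a two-column miRNA → predicted-target map,
and optional GMT gene sets. Feature identifiers are opaque strings; no
annotation lookup happens anywhere.

## Normalization, detection, profiles

Counts are scaled per sample to counts per million (CPM). Detection uses
the strict rule "over *c* CPM in ≥ *r* replicates of at least one
condition", with (c, r) = (0.5, 3) for mRNA and (1, 2) for miRNA; "over"
is read as a strict inequality and the boundary case is tested. The rule
is evaluated within each (organ, timepoint) condition, mirroring the
per-timepoint phrasing of the mRNA rule.

Condition profiles are per-feature means over replicates in each of the six
conditions, ordered organ-major (A-T0 … B-T2). Standardization acts on
log₂(mean CPM + 1) — the scale on which expression shapes are
conventionally compared — and divides by the population SD (divisor n).
Zero-variance features are flagged and excluded from the standardized
table rather than silently zeroed.

PCA QC runs on log₂(CPM + 1) of the 500 most-variable features, centered
and unscaled. This is an annotation-free stand-in for the
variance-stabilized PCA common in count-based QC; variance fractions are
reported over all components and sum to 1.

## Differential expression

Each later timepoint is contrasted against the baseline within one organ
(four contrasts total). The test is a two-group negative-binomial Wald
test with the NB2 parameterization (variance μ + αμ²):

- **Size factors** — median-of-ratios over features with all-positive
  counts. Note these capture *relative* depth only: uniformly doubling
  every sample's counts legitimately shifts p-values in the third decimal
  through the Poisson share of the variance, and a test asserts that this
  is the only leak.
- **Dispersion** — per-feature method of moments on normalized counts,
  α = (v − m)/m² with v the pooled within-group variance and m the overall
  mean. Raw moment estimates at 3 + 3 replicates are extremely noisy, and
  their *underestimates* are what destroy Wald calibration (a feature
  whose sample variance happens to fall below its mean is treated as
  Poisson and produces spuriously tiny p-values; measured null
  p < 0.05 fraction ≈ 0.12). Each estimate is therefore floored at the
  median estimate across all features — a pooled lower bound, not a
  fitted mean–dispersion trend — which restores the null fraction to
  ≈ 0.05 while leaving genuinely overdispersed features their own larger
  estimates. An absolute floor of 1e-8 guards degenerate (noise-free)
  inputs.
- **Group means** — maximum likelihood under a log link with size-factor
  offsets, solved by damped Newton iteration on the per-group score
  equation, vectorized over features. Fitted means are floored at 1e-8 on
  the normalized scale so that a group with all-zero counts yields a large
  finite fold change rather than ±∞.
- **Wald statistic** — (ln q₁ − ln q₀) / SE with SE from the observed
  Fisher information Σ μᵢ/(1 + αμᵢ) per group; two-sided normal p-value.
  Features with zero counts everywhere get NA and are excluded from the
  multiple-testing denominator.

Deliberately **not** implemented: dispersion-trend and fold-change
shrinkage, independent filtering, outlier refitting. The downstream calls
act only on (p, fold change, consistency), and the plain test's
calibration and power are verified by simulation instead. A `backend`
hook on `fit_nb_test` allows substituting an external NB engine.

The three-criterion call requires, jointly: Benjamini–Hochberg FDR below α
(mRNA 1%, miRNA 5%; BH applied per contrast within feature kind), model
|log₂ fold change| above log₂(FC_min) (mRNA 2.5, miRNA 1.5), and
direction consistency — every later-timepoint replicate's CPM on the same
side of the baseline condition mean, with exact ties failing. Consistency
compares against the baseline *mean* because replicates are unpaired
across litters. A feature's direction for clustering is its DE direction
in any contrast; conflicts across contrasts are resolved by the larger
|log₂FC| and flagged. miRNAs are DE if the criteria hold at either later
timepoint, matching the union phrasing of the miRNA rule.

## Clustering and labeling

Up- and down-regulated DEGs are clustered separately on their standardized
profiles with k-means (Euclidean distance, which on standardized rows is
monotone in correlation distance), k scanned over 2–12 with 10 seeded
restarts and chosen by maximal mean silhouette. Two post-passes reproduce
the observable contract of homogeneity-driven clustering tools used for
this kind of data: members with Pearson r < 0.7 to their centroid are
moved to UNASSIGNED, and clusters below 20 members are dissolved. The
homogeneity threshold and minimum size are conventions exposed as
parameters, not published values.

Cluster labels are rule-based on the cluster's mean standardized profile:
per organ the three points are classified up / down / flat (|T2 − T0|
below 0.5 standardized units) or transient (the T1 value an extremum
exceeding both endpoints by the same tolerance); identical nonzero trends
in both organs give "shared-up/down", a trend in exactly one organ gives
"<organ>-specific", any transient organ tags the cluster "transient", and
a "high-<organ>" qualifier is added when one organ's mean CPM over
members exceeds the other's by 2×. Unrecognised shapes are "unlabeled".

## Enrichment

For universe N, set size K (within the universe), cluster size n and
overlap k, EF = (k/n)/(K/N) and p = P(X ≥ k) under
X ~ Hypergeometric(N, K, n), computed exactly via the log-gamma survival
function (no normal approximation; p-values down to ~1e-300 remain
meaningful). The default universe is all features passing the detection
filter of the matching kind; BH is applied across each invocation's full
(cluster × set) batch, and the raw p is retained because the screen
threshold acts on it.

## Regulator screen

Only DE miRNAs enter. For each (miRNA, cluster) pair the target set is
tested for over-representation as above, and the miRNA's standardized
6-condition profile is correlated (Pearson, both organs jointly) with the
mean standardized profile of its predicted targets inside the cluster. A
candidate passes when p < 0.01 (strict) and r < −0.4 (strict) with at
least 5 targets in the cluster — the floor prevents correlations computed
on one or two genes and is exposed as a parameter. The full table,
including failing pairs, is emitted. Tightening any threshold can only
remove candidates; a test asserts this monotonicity.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not reads, sequences, or biogenesis:

- **Design** — 2 organs × 3 timepoints × 3 replicates (the probed-design
  convention of 3–4 samples per condition).
- **Gene means** — each gene has a baseline log₂ abundance
  ~ Normal(5, 1.5); archetype genes add a 6-condition log₂ offset vector.
  The six default archetypes are shared-down, shared-down-high-A (same
  decline, +1.5 log₂ in organ A), shared-up, A-specific-up, B-specific-up,
  and transient-A (a +2 log₂ pulse at T1), 150 genes each by default; the
  remaining 1100 genes are flat. Amplitudes of 2 log₂ units per organ make
  the planted fold changes comfortably, but not trivially, above the 2.5×
  call threshold at the default noise.
- **Counts** — NB2 with dispersion α = 0.1 around library-scaled expected
  fractions; library sizes log-normal (sd 0.3 on the log scale) around
  5×10⁶ (mRNA) and 1×10⁶ (miRNA). With α = 0 the generator returns the
  rounded expected means — a deterministic noise-free limit used by the
  separable-recovery tests. Since no observed dispersion or depth is
  published for the motivating libraries, these are conventions chosen
  once as realistic bulk values.
- **Regulators** — 6 planted miRNAs, each coupled to one archetype: the
  miRNA's log₂ profile is the sign-flipped, centered archetype shape
  scaled to `coupling_strength` (default 1.5) log₂ units of amplitude, so
  its expression anti-correlates with its targets' mean pattern.
  `coupling_strength = 0` silences the planted signal entirely (used for
  null calibration). Each regulator's 100 true targets are drawn from its
  archetype's genes; every miRNA additionally receives 50 uniform decoy
  targets, emulating prediction false positives without structure. A
  fifth of the bystander miRNAs ride a random un-flipped archetype so the
  miRNA compartment is not implausibly flat.
- **Gene set** — a 40-gene "deafness-like" set, 30 members inside the
  shared-down-high-A archetype, for end-to-end enrichment checks.
- **Reproducibility** — one RNG stream per output (structure, library
  sizes, mRNA counts, miRNA counts), derived from the master seed by fixed
  offsets, so enlarging the miRNA compartment never perturbs mRNA draws;
  fixed seeds give byte-identical fixtures.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: batch effects and litter structure,
compositional coupling beyond library normalization, sequence-driven
target-prediction bias (decoys are uniform), miRNA-family redundancy,
isoform structure, and any relationship between expression level and
dispersion. Results on real studies additionally depend on annotation
quality, which is out of scope by design.

## Problem sizes and runtime choices

Monte-Carlo verifications (test suite and acceptance machinery) run the
full pipeline at the default scale — 2000 genes, 300 miRNAs, 18 samples —
over 20 seeds, and the acceptance script summarises one pipeline run plus
a 10-seed null-calibration loop; these sizes recover all planted structure
while keeping a complete run in the low minutes on one core.

## Known limitations

- The NB test's pooled dispersion floor trades a little power on genuinely
  low-dispersion features for calibration; with many replicates a pure
  per-feature estimate would be preferable.
- Silhouette-selected k-means recovers well-separated archetypes but is
  not a substitute for graph-based homogeneity clustering when cluster
  shapes overlap heavily; the UNASSIGNED mechanism mitigates, not solves,
  this.
- The screen's false positives are dominated by decoy targets that land in
  a cluster by chance while the miRNA's noisy profile happens to
  anti-correlate; at the default thresholds this contributes ~0–3 false
  candidates per study-sized dataset.
- Cluster labels describe monotone 3-point trends; denser time courses
  would need a richer shape vocabulary.
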