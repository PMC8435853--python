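# Methods

This note documents the statistical model behind `cernaforge`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## The ceRNA inference chain

**Differential screen.** Each layer (mRNA, lncRNA, miRNA) is screened
between the two patient groups with the Wilcoxon rank-sum test at raw
P < 0.05 (Welch's t optional; Benjamini–Hochberg optional and off by
default). Rank-based testing was chosen because all downstream statistics
are correlation- or rank-based and log expression is heavy-tailed. No
fold-change cutoff is applied. Features with zero pooled variance get
p = 1 and are flagged rather than dropped.

**Evidence filter.** lncRNA–miRNA records pass on miRcode OR
experimentally supported LncBase (the union rule; intersection is a
switch). miRNA–mRNA records need at least `min_mrna_sources = 2` of
{miRDB > 75, TargetScan context percentile > 50, miRanda energy < −15};
the printed thresholds are applied as strict inequalities. The default of
2-of-3 sits between the two readings of "the intersection among these was
used" (all three vs. any supported pair) and is configurable to 1 or 3.
Records naming features outside the differential sets are dropped first.

**Negative-correlation filter.** Every surviving miRNA–target edge must
show Pearson r < 0 with two-sided P < 0.05 (Spearman switchable; p from
the t-distribution with n − 2 df). Pearson is the default because the
generator and TCGA-style log expression are approximately Gaussian and
the co-expression literature for ceRNA discovery uses it.

**Pair statistics.** For each (lncRNA, mRNA) pair with ≥ 1 shared miRNA:

- *Hypergeometric sharing test*, upper tail inclusive of the observed
  overlap: P(X ≥ k), X ~ Hypergeom(M, K, N). The universe M is the set of
  differential miRNAs that survive evidence filtering — the smallest
  defensible reference set; a larger universe only makes the test more
  liberal.
- *Regulation similarity* over the shared miRNAs, default formula
  `1 − mean_i |cL_i − cM_i|/(|cL_i| + |cM_i|)`, threshold 0.5. The
  normalized-absolute-difference form lives on [0, 1], equals 1 exactly
  when the two correlation profiles are identical, and is defined from a
  single shared miRNA. A profile-correlation variant (Pearson between the
  two correlation vectors, needing k ≥ 3) ships behind
  `reg_sim_formula="vector_corr"` since the 0.5 threshold is also
  consistent with a correlation-type statistic. A term with both
  correlations exactly zero contributes 0 (continuity choice, not NaN).
- *Co-expression*: r(lncRNA, mRNA) ≥ 0 with P < 0.05.

All four criteria are applied jointly (they are order-invariant); ties are
never broken — tied candidates are all reported.

**Survival pruning.** Per network mRNA, the cohort is split at median
expression (quantile configurable; median is the convention of the public
survival portals) and the two arms compared with the log-rank test,
implemented from the observed-minus-expected form with the hypergeometric
variance at tied event times; χ² against 1 df. An arm without events
degenerates to p = 1 with a warning; constant features are skipped.
Multivariate Cox regression of clinical covariates is a thin wrapper
around lifelines — routine plumbing, not re-derived.

**TF overlay.** Knockdown-derived transcription-factor analysis reduces to
set membership against a user-supplied TF identifier list plus degree
counting: pairs whose mRNA is a TF are kept and lncRNAs ranked by distinct
TFs reached. Hubs tied at the maximum are all reported in lexicographic
order. The full ranked table is always emitted rather than a hard-coded
top three.

**Enrichment.** Genes are ranked by signal-to-noise
(μ₁ − μ₂)/(σ₁ + σ₂) with each σ floored at max(0.2·|μ|, 0.2) (the classic
GSEA convention), weight exponent 1. The enrichment score is the signed
maximum of the weighted-KS running sum (hits increment |snr|/Σ_hits|snr|,
misses decrement 1/(N − N_hits)). Significance is by phenotype-label
permutation, p = (1 + #{|ES_perm| ≥ |ES_obs|})/(1 + n_perm) — label
permutation, not gene permutation, because the design is two-group with
adequate n. Nominal p only; no NES/FDR machinery. In the pipeline the two
phenotypes are the median split of the hub lncRNA's expression and the
tested set is the pruned network's mRNAs.

**Stemness (OCLR).** The one-class weight vector minimizes

    (1/n) Σ_i log(1 + exp(−w·x_i)) + (λ/2)‖w‖²,   λ = 1 by default,

which is strictly convex, so the optimum is unique; fitting is L-BFGS with
the analytic gradient, relative-objective tolerance 1e−10 and gradient
tolerance 1e−9 (tight on purpose: convexity makes the extra iterations
nearly free and refits from arbitrary starts then agree to ~1e−6). The
per-sample normalization makes λ comparable across reference sizes and
duplicating the reference provably leaves the fit unchanged. Samples are
scored by the Spearman correlation between w and their expression over the
model's features (the mRNAsi convention; Pearson switchable), then min-max
scaled within the cohort. Centering of the reference is the caller's
preprocessing; centering against the one-class reference alone would make
w = 0 optimal, so the shipped generator centers stem profiles against the
pooled stem + tumor feature means, following how the one-class index is
used in practice.

## The synthetic cohort

Defaults (see `SimulationConfig`): 200 patients, 35% in the invasion
group (the phenotype occurs in roughly a quarter to a half of tumors),
300 mRNAs / 60 lncRNAs / 40 miRNAs on the log2 scale with baseline 6 and
unit noise, five planted triplet modules of three miRNAs each, coupling
strength 0.8, a 2-log2 group shift on planted genes, 500 decoy interaction
records, and a log hazard ratio of 0.7 per standardized unit of each
planted mRNA.

Each module owns a latent sponge activity a = z + δ·1[invasion] with
z ~ N(0,1) and δ = de_effect/sponge_strength; its miRNAs load −s·a, its
lncRNA and mRNA +s·a. Three consequences are deliberate:

- the within-module sign pattern (miRNA↓ vs. both targets, targets↑
  together) holds in expectation at any s > 0, and the group shift of
  every planted gene is exactly ±de_effect;
- with the coupling off (s = 0) the planted features revert to pure
  background noise — no correlation structure *and* no group signal, so
  the null condition is a genuine null for the whole chain;
- the invasion shift is shared across all planted features, which
  produces realistic confounded cross-module correlations; decoy edges
  that connect differential features therefore *pass* the correlation
  filter and must be removed by the sharing and similarity tests — this
  is the hard part of the recovery problem, not an artifact.

Each planted triplet couples a small block of dedicated miRNAs (default
3) rather than a single one: a pair sharing one miRNA out of a ~10-miRNA
universe has a hypergeometric floor of ~1/M and can never reach P < 0.05,
so single-miRNA modules would be undetectable by construction at desk
scale. Decoy records draw each score uniformly over a range centered on
its threshold, so every individual criterion passes with probability ≈ 0.5
and a realistic fraction of decoys survives into the statistical filters.

Survival is exponential with the additive Cox log-hazard above and
administrative censoring at 1200 days with baseline hazard 1e−3/day
(~40% censored at defaults). The hub experiment
(`hub_experiment_config`) plants three triplets sharing one lncRNA inside
a background of nine independent triplets with four miRNAs per module
(50 miRNAs total): a hub in a minimal network would occupy nearly the
whole miRNA universe and its own sharing test could not be significant,
mirroring the fact that real hubs are found inside large pruned networks.

The stemness generator builds 40 pluripotent reference profiles and 100
tumor samples on a gradient g ~ U(0,1), with an 80-of-200-gene signature
whose per-gene amplitudes are drawn U(0.5, 4) log2 units (noise sd 0.5).
Heterogeneous amplitudes matter: with one constant amplitude the
rank-based score saturates once every signature gene clears the noise
floor and the gradient ordering is lost among stem-like samples.

**What the generator does not emulate:** count noise and
library-size/normalization artifacts, batch effects, correlated background
co-expression (background genes are independent), copy-number or
mutational structure, competing risks, and single-cell resolution. Passing
recovery experiments therefore demonstrates the correctness and
calibration of the statistical chain under its stated model, not
performance on raw TCGA data; real inputs must arrive as log-scale
matrices (the normalization upstream of that is out of scope and
documented as the caller's responsibility).

## Numerical choices and degenerate inputs

- Correlation p-values from the t-transform with n − 2 df; |r| = 1 maps
  to p = 0; zero-variance features give NaN and their edges are dropped
  with a log entry.
- Hypergeometric tail via the survival function at k − 1 (inclusive).
- Missing expression policy: features > 20% missing dropped, the rest
  median-imputed per feature, counts logged — keeps correlations defined
  without row deletion.
- Expression splits use `numpy.quantile` defaults; membership in the high
  arm (x > cut) is invariant to strictly monotone transforms.
- Enrichment with an all-hit set has no miss decrement and peaks at 1; a
  hit set with zero total weight falls back to equal increments.
- Min-max scaling of a constant score vector returns 0.5 for all samples.
- The run manifest hashes the config (minus the output path), funnel
  counts and SHA-256 of every output file; reruns with the same seed are
  byte-identical.

## Experiment sizes

The validation experiments use 25–100 simulated cohorts per question
(50 for recovery/null/hub rates, 100 for the stemness gradient, 10,000
null cohorts for log-rank calibration, 200 runs for permutation-p
uniformity) — enough for the binomial error of each rate to sit well
inside the acceptance margins while keeping a full run in minutes on one
core.

## Known limitations

- The regulation-similarity formula used by upstream databases is not
  standardized; both shipped variants satisfy the stated 0.5 threshold
  semantics but can disagree on borderline pairs.
- The miRNA universe choice (post-evidence differential miRNAs) is the
  most conservative defensible option; a genome-wide universe would admit
  more pairs.
- Survival screening treats overall survival only (a second time/event
  column pair can be screened, but there is no competing-risks model).
- OCLR stemness assumes the reference was centered against a background
  that includes non-stem samples; feeding raw one-class profiles yields
  near-zero weights.
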