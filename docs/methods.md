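# Methods

This note documents the statistical procedures the package implements,
the choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the numerical details a
maintainer would need.

## Data model

The raw input is a triple of probes × samples matrices — methylated
intensity M, unmethylated intensity U, and detection p values — plus a
sample sheet (sample id, subject id, tissue tumour/normal, chip/batch,
optional clinical covariates) and a probe manifest (position, CpG-island
membership, region class, gene links, QC flags). Matched pairs share a
subject id and are processed on the same chip. Methylation is summarised
as the beta value

    β = M / (M + U + 100),

which lies in [0, 1); the offset of 100 stabilises low-intensity probes
and is configurable for sensitivity analyses.

## Preprocessing

Stages run in this order: detection filter → per-sample control
rescaling → beta computation → blacklist removal → batch adjustment.

* **Detection filter.** A probe is removed when its detection p exceeds
  0.05 in more than `max_failure_fraction` of samples. The default
  fraction is 0 (any failing sample removes the probe): with no stated
  per-sample rule, the strict variant is conservative and deterministic,
  and the fraction is exposed as configuration.
* **Control rescaling.** Each sample's intensities (both channels) are
  multiplied by grand-control-mean / sample-control-mean so that internal
  control probes share a common mean across samples. Rescaling acts on
  intensities *before* beta computation; because the offset of 100 is not
  rescaled, betas are not exactly invariant under the factor, which is the
  documented behaviour.
* **Blacklist.** Sex-chromosome and cross-reactive probes are removed
  regardless of detection performance; control probes never enter the
  analysis set. The removal report counts each probe once, in the order
  control → detection → sex chromosome → cross-reactive.
* **Batch adjustment.** The empirical-Bayes location–scale model:
  probes are standardised using batch-size-weighted means and pooled
  residual variance; per-batch additive (γ) and multiplicative (δ)
  effects are estimated per probe, shrunk towards batch-level priors
  (normal for γ, inverse-gamma for δ, moment-matched), and removed by
  coordinate iteration of the posterior equations (tolerance 1e-8, cap
  500 iterations). Adjustment operates directly on beta values and the
  output is clipped to [0, 1 − 1e-6]. A single batch is returned
  untouched; a batch with one sample is an error because its scale effect
  is undefined. Degenerate priors (zero spread of the moment estimates
  across probes) disable shrinkage rather than dividing by zero.

  A caution that the tests make visible: batch adjustment cannot
  distinguish a true chip effect from biological composition differences
  between chips. If one chip is enriched for heavily methylated tumours,
  part of that biology is removed as if it were a batch effect. The
  synthetic generator therefore uses a balanced chip layout (below);
  real studies should randomise or stratify array assignment.

## Per-CpG differential methylation (SAM)

For probe i, the modified t-statistic is

    d_i = (x̄_tumour,i − x̄_normal,i) / (s_i + s0),

with s_i the pooled two-sample standard error (or the paired standard
error of differences in paired mode). The exchangeability constant s0
damps the statistic at probes with tiny variance. By default s0 is chosen
by coefficient-of-variation minimisation: candidates are the 5th-percentile
grid of s; for each candidate, the spread (median absolute deviation) of d
is computed within up to ten s-quantile windows, and the candidate with
the smallest CV of those spreads wins. A simpler `median(s)` mode and a
fixed-s0 mode are available; the mode used is recorded in the run log.

The permutation FDR follows the published recipe: for each observed |d|
threshold, the expected number of false positives is the mean count of
permuted |d*| at or above the threshold over label permutations; the q
value of probe i is the minimum of expected/observed over thresholds at
or below |d_i| (capped at 1), which makes q non-increasing in |d|. When
the requested permutation count reaches the number of distinct balanced
assignments, enumeration is exhaustive and flagged as such. The default
is 200 permutations with a mandatory seed. The top-K probes by |d|
(two-sided — both gains and losses of methylation feed the clustering)
are selected with lexicographic probe-id tie-breaks for determinism.

The two-class comparison is unpaired by default, matching a
tumour-group-versus-normal-group contrast; a paired mode (sign-flip
permutations) is provided since samples are matched.

## Subtyping

Samples are clustered on the selected probes with Euclidean distance and
complete linkage (scipy's deterministic agglomeration). Because a visual
dendrogram cut is not reproducible, labelling follows a fixed rule:

1. Cut at k = 2. The branch with the lower mean beta over the selected
   probes is normal-like; tumours in it are CIMP-N, normal samples in the
   other branch are flagged and excluded from downstream analysis.
2. Cut the tumour-like branch into three subclusters (raising the global
   cluster count splits one cluster at a time, so the branch partition is
   exact; in the measure-zero case of tied merge heights the branch is
   re-clustered alone). Subclusters ranked by descending mean beta give
   CIMP-H, CIMP-L, CIMP-N, the last merged with normal-branch tumours.

A flat k = 4 cut (lowest-mean cluster treated as normal-like) is
available behind `cut_mode="flat"`. The ranking statistic guarantees the
label ordering CIMP-H ≥ CIMP-L ≥ CIMP-N in cluster mean methylation by
construction.

## Gene-level island calling

For each gene, the probes from its CpG island and island shores are
pooled (shelf and open-sea probes excluded); genes with fewer than
`min_probes` (default 3) probes are dropped and reported. For every
(gene, pair), the per-probe beta differences are tested with the Wilcoxon
signed-rank test:

* zero differences are dropped (standard convention; all-zero → p = 1),
* tied absolute differences receive average ranks,
* the exact null distribution (dynamic-programming convolution of rank
  subset sums, cached per n) is used for n ≤ 25 untied differences;
  two-sided p is the symmetric two-tail sum, capped at 1,
* above the limit or with ties, a normal approximation with tie-corrected
  variance and a 0.5 continuity correction towards the mean is used.

Raw p values are BH-adjusted across genes *within each tumour* by
default; each tumour's calls feed an independent per-tumour count, so
per-tumour adjustment matches the downstream use. A `global` scope
(adjusting the whole gene × tumour matrix at once) is provided because
the alternative reading is defensible; the scope used is recorded.

A gene is called **hyper** in a tumour when adjusted p < 0.005 and
Δβ = mean(tumour) − mean(normal) ≥ δ_min; **hypo** uses the mirrored
criterion (computed for completeness; downstream analyses consume hyper
calls only). Calls are monotone in δ_min by construction: raising the
threshold never adds a call.

δ_min itself is selected by scanning a grid (default 0.05–0.30 in steps
of 0.05): for each candidate the objective is the mean per-tumour hyper
count in CIMP-H minus that in CIMP-N, and the smallest argmax wins. Since
p values do not depend on δ, the scan re-thresholds cached (p, Δβ)
matrices and is cheap.

## Frequency scoring and core sets

Per gene and subtype: count of hyper calls, group size after subtyping
exclusions, and their ratio. The core set at threshold t contains genes
with fraction strictly greater than t for t < 1 and exactly 1 at t = 1 —
this reconciles "more than the specified percentage" semantics with a
meaningful "in 100% of tumours" set. Core sets are nested in t and the
frequency curve is non-increasing, both property-tested.

## Clinical statistics

Fisher's exact test is two-sided by the minimum-likelihood definition
(sum of probabilities of all tables with the observed margins whose point
probability does not exceed the observed one); the doubled-one-tail
variant is available by flag. Welch's t test runs from group summaries
(mean, SD, n) with Welch–Satterthwaite degrees of freedom. Published
clinical tables print p values truncated, not rounded, so the comparison
helper truncates to the printed decimals while full precision is kept
internally. One printed association (proximal tumour location) is
described in prose as a Welch test but reproduces exactly as a Fisher
test on the printed 2×2 counts; the package computes it as Fisher.

The five-gene panel classifier maps the count c of methylated marker
genes to CIMP-H (c ≥ 4), CIMP-L (1 ≤ c ≤ 3), CIMP-N (c = 0); over all 32
flag combinations this partitions as 6 / 25 / 1.

## The synthetic cohort generator

The generator produces data with the statistical structure the analysis
assumes, with full ground truth, deterministic under its seed. The
standard cohort is 40 matched pairs and 2,000 genes — small enough that
the complete pipeline runs in seconds, large enough for BH adjustment and
the frequency analysis to behave as at scale.

**What is planted.**

* **Baselines.** Island/shore probes are nearly unmethylated in normal
  tissue (mean β 0.10), shelf intermediate (0.40), open sea high (0.75),
  with logit-scale probe (SD 0.3) and shared subject (SD 0.2) variation —
  the subject effect cancels in paired tests and inflates unpaired
  variance, as in real data.
* **CIMP programme.** A core set of 132 genes is shifted (gene-wise, all
  island+shore probes together) by Δβ ≈ 0.35 in every CIMP-H tumour,
  ≈ 0.22 in CIMP-L and ≈ 0.08 in CIMP-N — the graded high/low/very-low
  methylation that makes the three subtypes clusterable. The CIMP-N shift
  is bounded below 0.095 so it stays under the calling threshold.
* **Stochastic background.** Each tumour hypermethylates a private random
  set of non-core genes; per-tumour counts are log-normal (σ = 0.8;
  means 100 / 38 / 31 for H / L / N) so counts form a continuum with
  overlapping ranges between adjacent subtypes. Effect sizes are
  log-normal with group medians 0.18 / 0.15 / 0.07: CIMP-H background
  events are mostly strong, CIMP-N events mostly weak. This is what gives
  the δ-threshold scan an interior maximum at 0.1 — below it, weak
  CIMP-N events flood in and shrink the H−N separation; above it, CIMP-H
  background events start failing the threshold.
* **Shared hypomethylation.** All tumours (except the normal-like ones)
  lose methylation (depth ≈ 0.6) at a fixed block of 600 open-sea
  probes, emulating the global hypomethylation of tumour genomes. This is
  what separates weakly hypermethylated CIMP-N tumours from normal tissue
  in the clustering; its size is kept below the point where it would
  dominate branch mean-beta ranking.
* **Normal-like tumours.** Two of the CIMP-N tumours are generated with
  normal-tissue parameters; they land in the normal branch and are
  labelled CIMP-N by the cut rule, mirroring tumours that cluster as
  normal tissue.
* **Technical structure.** Logit-scale measurement noise (SD 0.15,
  ≈ 0.013 on the beta scale at β = 0.1), per-sample intensity scale
  factors (log-normal, σ = 0.10) removed by control rescaling, chip
  effects (global shift SD 0.01 plus per-probe SD 0.005), sporadic
  detection failures (0.2% of probes fail in one sample), sex-chromosome,
  cross-reactive, negative- and internal-control probes. Betas convert to
  intensities by M = β(T + 100), U = T − M with T log-normal around
  5,000 (floored at 2,000), so `compute_beta` inverts the construction
  exactly; the configuration validates that planted betas stay below
  T/(T+100).
* **Chip layout.** Pairs are dealt to chips round-robin within subtype
  (a balanced design). With six pairs per chip and subtype proportions
  35/15/50%, a block layout would let chip composition correlate with
  subtype and the batch adjustment would remove subtype signal; the
  balanced layout reflects what a well-designed study does deliberately.

**What is not emulated.** Infinium I/II chemistry differences and
dye bias, tumour purity and copy-number confounding, realistic manifest
geometry (island sizes, probe spacing, gene density), correlated probe
noise, missing values, and calibrated panel-vs-cluster concordance rates
(the generated clinical covariates echo typical subtype associations but
are not tuned to reproduce any published concordance). Passing tests on
this cohort therefore demonstrate that the pipeline recovers the
structure it models — graded subtype methylation, a planted core,
heavy-tailed background, batch and scale effects — not that it is robust
to every artefact of real arrays.

## Numerical choices

* Coordinates are 1-based closed intervals; distance to an island is the
  minimum over its two edges, 0 meaning containment; shore is 1–2000 bp,
  shelf 2001–3000 bp, open sea beyond. The TSS window is 1500 bp.
* Probes annotated to several genes contribute to each gene
  independently (no de-duplication rule is imposed).
* Tie-breaks are lexicographic by probe id (top-K selection) or by first
  occurrence (threshold scan argmax → smallest δ; cluster ids from
  scipy's deterministic agglomeration order).
* Beta bounds: generator targets clipped to [0.02, 0.93]; measured betas
  floored at 1e-4; batch-adjusted output clipped to [0, 1 − 1e-6].
* The signed-rank exact/approximate switch is at n = 25 (configurable);
  the exact path requires untied ranks.
* All randomness flows from explicit integer seeds (numpy Generator);
  pipeline configs refuse to run without a SAM seed.

## Limitations

* The dendrogram cut rule is a reproducible surrogate for a judgment
  call; on data whose tumour branch does not contain three meaningful
  subclusters it will still force three.
* Per-tumour BH scope treats each tumour's gene family as its own
  multiple-testing universe; pooling all tumours (the `global` scope)
  is stricter for tumours with few signals.
* The batch adjustment assumes batch effects are exchangeable across
  probes; composition-confounded designs are corrupted rather than
  corrected (see above).
* With fewer than ~9 pooled probes the exact signed-rank test cannot
  reach p < 0.005 before adjustment, so genes with small islands are
  effectively untestable at the default stringency; the per-gene minimum
  is configurable but the floor is mathematical, not numerical.
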