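# Methods

This note documents the models, numerical choices and known limitations
of `episig`. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## The synthetic-data generator

The generator fabricates the inputs an array-based episignature study
consumes; its defaults are the study conditions under which all tests
and acceptance checks run.

**Manifest and genome.** `simulate_manifest` lays out a toy genome of
40 kb "locus" units, each carrying a 1 kb CpG island and a 10 kb gene
(alternating strand, three exons). Probes are scattered uniformly, with
a small deterministic set placed at known offsets so every CGI context
(island / shore / shelf / inter-CGI) and every gene context (promoter /
promoter+ / gene body / intergenic) is populated on each autosome. A
~2 % probe fraction sits on chrX/chrY; ~1 % of probes each carry SNP and
cross-reactivity flags. Positions are 1-based in the manifest; all
interval arithmetic is 0-based half-open internally.

**Beta values.** Per-probe baseline methylation is drawn from a
three-mode Beta mixture (weights 0.40/0.20/0.40; Beta(2,18),
Beta(10,10), Beta(18,2), i.e. means ≈ 0.1/0.5/0.9), mimicking the
bimodal marginal distribution of array data without copying any real
manifest. Per-sample values are Beta-distributed around the baseline
with probe-specific precision κ ~ lognormal(log 150, 0.3) (sd ≈ 0.04 at
β = 0.5).

**The implanted signature.** Signature probes are chosen uniformly among
unflagged autosomal probes (never flagged ones, so QC cannot delete the
truth set) or supplied explicitly (e.g. a contiguous run for DMR
experiments, via `find_probe_run`). Each gets a case-only beta-scale
shift of |Δβ| + N(0, effect_sd), signed by direction
(hypo/hyper/mixed), truncated to [0, 1]. Implanted probes' baselines
are redrawn from a window that can express the shift without truncation
(Beta(14,6) clipped to [0.15, 0.85] for hypomethylation, mirrored for
hyper): a probe already near 0 cannot lose 0.10 of methylation, and the
generator's contract is that the mean realized Δβ matches the requested
effect (verified to ±0.03 in tests). A requested Δβ of exactly 0
implants nothing, giving a clean null. Defaults: Δβ = −0.10,
effect_sd = 0.02, direction hypo — a moderate blood episignature
effect.

**Cell-composition confounding.** Six blood-cell proportions (CD4+,
CD8+, NK, monocytes, granulocytes, B cells) are Dirichlet-distributed
around a granulocyte-rich baseline (concentration 120). Case draws are
tilted toward granulocytes in proportion to `confound_strength`
(default 0.3), and a probe subset disjoint from the signature (default
min(200, n/25) probes, kept at intermediate baselines) responds
linearly to the granulocyte fraction. Because the response is linear in
a modelled covariate, adjustment removes it — which is exactly what the
covariate-efficacy test asserts.

**Detection p-values** are Uniform(1e−6, 0.01) with a configurable
failure fraction (default 5 × 10⁻⁴) redrawn from Uniform(0.11, 0.9),
exercising the p > 0.1 filter.

**Ages and sexes** are assigned so each case has ≥ 5 same-sex,
similar-age (σ = 2 y) pool controls, guaranteeing 1:5 matching is
feasible; the remaining pool is free.

**What the generator does not emulate:** raw intensity data and
background correction (the package consumes normalized betas), batch
effects, probe-probe spatial correlation beyond the implanted signal,
SNP genotypes, realistic EPIC coordinates, and age-related methylation
drift. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
arrays.

**Multi-cohort panels.** `simulate_disorder_panel` realizes an exact
pairwise-overlap plan by allocating disjoint shared blocks per cohort
pair and filling the remainder uniquely; triple-wise sharing is not
modelled, so realized pairwise intersections equal the plan exactly.
Studies per cohort are optional (`with_studies`) since truth sets alone
suffice for overlap and tree analyses.

## Preprocessing

Samples are filtered before probes, so a failed sample cannot drag
probes below the detection threshold; a sample is excluded iff its
failed-probe fraction strictly exceeds 5 %. Probes are then removed in
a fixed order — detection failure (p > 0.1 in ≥ 1 retained sample,
the strictest reading of the per-sample rule), chrX/Y, SNP-flagged,
cross-reactive/blocklisted — each counted once under the first
triggering reason, making the QC report a partition.

The logit transform uses offset 0 with betas clamped to
[1e−6, 1 − 1e−6]; this matches the plain logit while keeping M finite,
and round-trips to 1e−12 away from the clamp. The PCA outlier screen
uses robust z-scores (median/1.4826·MAD, SD fallback for zero spread)
on the first 2 components with threshold 3; the threshold is
deliberately loose — the screen reports candidates, it does not drop
samples automatically.

## Matching

Exact on sex and array type, nearest-neighbour on absolute age
difference, without replacement, no caliper. Cases are processed
scarcity-first (fewest compatible controls first) with (gap, sample_id)
tie-breaks, so the result is deterministic and invariant to pool row
order. Greedy matching is not globally optimal, but the brute-force
comparison test shows it recovers planted optima, and mean age gaps
beat random assignment.

## Moderated differential methylation

Per-probe OLS on M-values with the design
(intercept, case indicator, 5 of 6 cell proportions — one dropped
because proportions sum to one). Probes with missing entries are refit
on observed samples with adjusted degrees of freedom; unidentifiable
probes propagate NaN.

Variance moderation follows the standard empirical-Bayes model:
s² | σ² ~ σ²χ²_d/d with a scaled inverse-χ² prior (d₀, s₀²) estimated
by moment-matching the log variances (digamma/trigamma inversion;
Newton iteration for the trigamma inverse). Posterior variance
s̃² = (d₀s₀² + d s²)/(d₀ + d); moderated t uses d₀ + d degrees of
freedom. When the log-variance spread does not exceed its sampling
noise, d₀ = ∞ and s₀² falls back to the arithmetic mean of the
variances, so identical variances leave t at its ordinary value. A
`prior_df=0` override disables shrinkage entirely. The implementation
agrees with R/limma's `eBayes` to ~1e−15 on a shared fixture (a test
that runs whenever `Rscript` is on PATH).

Δβ and group means are computed on the beta scale, where methylation
differences are conventionally quoted, while tests run on the
variance-stabilized M scale.

## Probe selection and the classifier

Score = |Δβ| × (−log10 p_adj), log base 10 (the base only rescales
ranks); p_adj = 0 is clamped to the smallest positive float with a
warning. AUC is direction-folded (max(AUC, 1−AUC)), ties counted ½,
constant rows 0.5. Selection defaults top_k = 500, auc_min = 0.9,
corr_max = 0.9 — recorded in run metadata and configurable; correlation
pruning iterates in descending score order and drops a probe only
against already-kept probes. An empty survivor set raises by default;
`allow_empty=True` supports null-behaviour audits where zero survivors
is the expected answer.

Hierarchical clustering uses average linkage on Euclidean distances
between sample beta vectors, serialized as newick with heights encoded
as branch lengths. MDS is the classical (Torgerson) eigendecomposition
of the double-centred squared-distance matrix; axis signs are fixed by
making the largest-magnitude coordinate positive, and an all-equal
input yields all-zero coordinates.

Leave-one-out cross-validation runs one round per case, rerunning the
model fit and selection without the held-out case, and places the
held-out sample by its distance to the case vs control centroid in that
round's MDS embedding — a deterministic surrogate for visual clustering
judgment.

The classifier is a linear SVM (C = 1, balanced class weights) on
selected-probe betas. Controls are shuffled once (seeded) into four
folds; each fold's model trains on all cases plus 75 % of controls and
scores the held-out 25 %, so every control is a test sample exactly
once while cases are averaged over all four fold models. Margins are
mapped to probabilities by Platt scaling (Newton-optimized, with the
standard target smoothing). The shipped model is refit on all samples,
stores per-sample final-model scores for exact reclassification, and
serializes to JSON (probes, weights, bias, calibration, metadata).
Discordant training candidates can be excluded from discovery via the
`exclude_cases` config list and are then scored as test samples.

## DMR calling

Chaining interprets "at least five adjacent significant CpGs within
1 kb" as consecutive-significant-probe gaps ≤ 1000 bp (bump-chaining
semantics), not total span ≤ 1 kb. Member p-values entering Fisher's
method are the BH-adjusted values — consistent with the upstream
definition of "significant" — with a raw-p variant available
(`use_raw_p`). Fisher's method assumes independent p-values; member
probes are correlated, so region p-values are approximate and no
correlation correction is applied. Candidates are BH-adjusted as a
family and reported below 0.01. Region bounds are 0-based half-open
over member probes.

## Annotation

Shore/shelf bands are closed on the far edge: a position exactly
2000 bp from an island edge is shore, exactly 4000 bp is shelf.
Promoter classes are strand-aware (1 kb and 1–5 kb upstream of the
TSS); precedence is promoter > promoter+ > gene body > intergenic, with
nearest-TSS deciding among overlapping promoter claims and any-gene
containment sufficing for gene body. UTRs, exons, introns and
boundaries are deliberately merged into one gene-body class. The
context test is a Pearson χ² goodness-of-fit of observed category
counts against the background-proportional expectation (df = k − 1). A
region inherits every context any member probe carries, reported as a
fraction breakdown.

## Cohort comparison

Overlap percentages use all DMPs per cohort and are intentionally
asymmetric (denominator = row cohort). The cohort tree restricts each
cohort to its top-500 DMPs by p-value (all DMPs when fewer), builds the
union feature space, represents each cohort by the per-probe median of
its per-sample beta differences — Δ = 0 where a cohort did not measure
a probe, meaning "no evidence of change" — and clusters with average
linkage on Euclidean distance. Beta-scale differences (not M-scale)
feed the distances. Cohorts are processed in sorted-id order, making
the tree invariant to input order.

## Clinical summaries and the pipeline

Frequency cells are formatted "k/n (p%)" with missing entries excluded
from n, a trailing ".0" suppressed, and one decimal otherwise; a
feature with zero assessed entries reports "0/0" with an undefined
percent.

`run_pipeline` derives all stage seeds from one root seed via a single
generator, wraps each stage so failures carry the stage name, and
writes a run manifest (package version, full config, derived seeds)
sufficient to reproduce a run bit-identically. The default end-to-end
configuration (8000 probes, 8 cases, 60-control pool, 100 signature
probes) keeps a full run in the tens of seconds while preserving all
statistical structure; the acceptance checks use the larger canonical
sizes (20,000 probes, 200 implanted, 12 vs 60) where the contract
demands them.

## Known limitations

* Region p-values ignore inter-probe correlation (see DMR section).
* Greedy matching and greedy correlation pruning are deterministic
  heuristics, not global optima.
* The MVP calibration is fit on training margins of a hard-margin-ish
  linear SVM; probabilities are well separated but not strictly proper
  scores.
* The synthetic generator's independence assumptions (probes
  conditionally independent given baseline and covariates) make
  separation easier than on real arrays; reported sensitivity and
  precision characterize the algorithms under this model only.
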