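# Methods

This note documents the models, defaults and design choices behind
`agemeta`, and what the synthetic benchmarks do and do not demonstrate.

## Study design being modeled

The pipeline targets the two-group cross-sectional design used in
multi-study transcriptome compendia of the aging frontal cortex: samples are
bracketed as *younger* (20–40 years) or *older* (60–90 years); samples
outside both brackets are excluded, and a study contributes only if both
groups keep at least 3 samples. The synthetic generator's defaults reproduce
that design: five studies with group sizes 9/12, 13/18, 52/22, 13/13 and
74/90 (young/old), a shared universe of 7,274 genes, and planted up/down
fractions of 625/7274 and 635/7274 so the expected number of truly
age-regulated genes matches the scale of the consensus list such compendia
report.

## Synthetic data

Expression is simulated directly on the log2 scale:

    x[g, s] = baseline[g] + batch[study, g] + effect[g]·1{s is old} + ε

with `baseline ~ N(7, 2²)` (typical log2 microarray intensities),
`batch ~ N(0, study_batch_sd²)` per study and gene (default 0.3, a mild
study-level shift that does not overwhelm the group effect),
`effect = ±effect_size_delta` for planted genes (default 1.0 log2 unit —
a two-fold change, a moderate and detectable aging effect) and
`ε ~ N(0, noise_sd²)` (default 1.0, giving per-study standardized effects
around 1 — noisy enough that single studies disagree, the regime
meta-analysis exists for). Ages are uniform within the bracket; a
`continuous` mode draws ages uniformly on 20–90 and scales the effect
linearly around age 55 for correlation-with-age follow-ups. A `raw` mode
exponentiates and adds multiplicative noise to exercise the normalization
chain. The PPI generator is a planted-partition graph over the planted
genes' community labels (communities of 20 by default, `intra_p=0.3`,
`inter_p=0.01`) with scores uniform in 901–999 so all synthetic edges clear
the >900 confidence threshold unless a test lowers it; designated hubs get
extra random attachments up to a target degree. qPCR tables plant a fold
change as a −log2(fold) shift of the target Ct in the treated group against
a stable reference gene.

What this emulates: multi-study inconsistency, batch offsets, mixed
directions, modular interaction structure, planted enrichment. What it does
not: probe-level artifacts, platform-specific distributions, correlated
gene–gene expression noise, non-Gaussian heavy tails, or real PPI topology
(power-law degree, hub–spoke biology). Passing benchmarks therefore show the
*statistical machinery* is correct and well calibrated under the design's
assumptions, not that real GEO series would yield the same gene lists.

## Preprocessing

Probe-to-gene collapsing uses the mean across probes (median by config).
Normalization applies a generalized-log transform followed by quantile
normalization. The glog step, `glog2(x) = log2((x + √(x² + c²))/2)`, is a
closed-form variance-stabilizing transform that behaves like log2 for
`x ≫ c` and damps small intensities; it stands in for the usual
log2 + model-based VSN fit (the full Huber fit is deliberately out of
scope — the generalized log has the same variance-stabilizing contract,
handles zeros, and is exactly testable). The offset `c` defaults to the 5th
percentile of positive values. Quantile normalization maps each column's
ranks to the mean of sorted columns, averaging the reference values over
ties — this makes the transform idempotent and keeps constant columns
finite. The gene universe across studies defaults to the intersection (the
meta-analysis then has every study's p-value for every gene); a union mode
keeps genes present in ≥ k studies and reduces the per-gene degrees of
freedom downstream. Whether the published 7,274-gene universe was an
intersection or a coverage-thresholded union is not stated in the sources
the pipeline emulates; intersection is the default and the choice is logged.

## Differential expression

The moderated t-test follows the empirical-Bayes linear-model contract:
`(d₀, s₀²)` are estimated by method of moments on `log s²` — mean and
variance of `e = log s² − ψ(d/2) + log(d/2)` give `d₀ = 2·ψ'⁻¹(var −
ψ'(d/2))` and `s₀² = exp(mean + ψ(d₀/2) − log(d₀/2))` — with the inverse
trigamma solved by Newton iteration (tolerance 1e-8, ≤ 50 iterations) and
`d₀` capped at 1e6, treated as infinite shrinkage (normal reference
distribution). The implementation agrees with the reference R implementation
(limma's `eBayes`) to ~1e-14 on shared inputs; that cross-check runs in the
test suite. One subtlety: when all gene variances are exactly equal the
estimator returns `d₀ = ∞` and a prior scale carrying the
`exp(log(d/2) − ψ(d/2))` log-scale correction, so the moderated t is then a
*constant multiple* of the ordinary t rather than identical to it — the
idealized "equal variances are a fixed point" picture holds only up to that
known factor (the reference implementation behaves the same way). Genes
with zero variance in both groups get p = 1 with a warning. Per-study
significance defaults to p < 0.05 AND BH FDR < 0.05 (both thresholds
exposed; which combination the original web tool applied is ambiguous, so
the stricter AND is the default and is logged). BH adjustment is delegated
to `statsmodels.stats.multitest`.

## Meta-analysis

Fisher's method, inverse-variance fixed-effect pooling with Cochran's Q,
and vote counting, as in the README formulas. Conventions chosen where the
sources are loose: zero p-values are clamped to the smallest positive float
with a warning (Fisher's statistic would otherwise be infinite); genes
missing from some studies keep reduced df/k and are dropped entirely when
present in fewer than 2 studies; the vote rule is *votes ≥ 2* (the
sources print both "≥ 2" and "< 2" in different places; the results-facing
convention wins); the fixed-effect effect size is the raw log2 mean
difference (a standardized-difference mode is a config flag away, but raw
log2 differences are what the per-study moderated model estimates);
consensus direction is the sign of the pooled fixed-effect estimate, with
an optional |z| floor below which genes are labeled discordant. The
reporting helper that turns a consensus down/up split into percentages
rounds to one decimal.

## Network analysis

The zero-order network keeps only seed–seed edges with combined score
strictly above the threshold (">0.9" on STRING's 0–1 scale = >900 on the
0–1000 file convention). Betweenness is Brandes' algorithm on the
undirected unweighted graph, unnormalized, each unordered pair counted once
(networkx). Hub selection requires degree ≥ 10 and betweenness rank within
the top 10% — the denominator is the *consensus list size*, not the node
count, since isolated seeds drop out of the graph but not out of the gene
list. Ranking is total: betweenness desc, degree desc, then gene ID, so hub
selection is invariant to input order.

Modules: the largest component (continent) is partitioned by deterministic
greedy-modularity (Clauset–Newman–Moore) community detection; random-walk
alternatives were considered and rejected for determinism. Candidate
modules (communities and islands of size ≥ 5) get a permutation p-value:
`n_perm` (default 999) random node sets of the same size, drawn from the
continent with each member replaced by a node from its log2-degree bin, and
p = (1 + #{perm with ≥ observed internal edges}) / (n_perm + 1), floored at
1/(n_perm+1). This null is a documented stand-in — the web tool the
analysis style comes from does not state its module null — and the output
metadata labels it as such. **Known limitation:** the permutation p is
calibrated for *pre-specified* node sets (on Erdős–Rényi graphs ≤ 10% of
random sets reach p < 0.05, verified in tests), but modularity detection
*selects* dense groups before testing, so selected-module p-values are
optimistically biased on unstructured graphs; treat them as a ranking of
module density, not a familywise error guarantee.

## Enrichment

ORA uses the plain one-sided hypergeometric upper tail (exact, matches
brute-force tail sums to 1e-12), not the EASE jackknifed variant — EASE is
available behind a flag for compatibility with DAVID-style output, since
published fold-enrichment figures typically come from DAVID. The background
defaults to the meta-analyzed gene universe, not the genome: the query was
selected from exactly that universe. Sets with fewer than 2 query hits are
skipped; BH FDR is applied across tested sets. Flat sets only: GO-hierarchy
propagation is out of scope, so GO-style inputs are treated as independent
flat sets. The 2×2 odds-ratio analysis reports OR = ad/bc with the Woolf
log-SE 95% CI and Fisher's exact two-sided p; any zero cell triggers the
Haldane–Anscombe +0.5 correction of OR and CI (flagged in the result; the
exact p always uses the uncorrected table). CI coverage is verified by
Monte-Carlo simulation in the tests (~95% at n=400).

## Validation statistics

2^−ΔΔCt uses the Livak convention: ΔCt = Ct_target − Ct_reference per
sample, calibrated against the *mean control* ΔCt (per-sample calibration
is the other common variant; mean-of-control is the default here), fold =
2^−ΔΔCt, with the two-group test run on ΔCt values where noise is additive.
The computation is exactly invariant to any per-sample constant added to
both target and reference Ct. Spearman correlation uses midranks; for
n ≤ 10 the p-value is an exhaustive permutation tail, otherwise the
t-approximation. Two-group comparisons are classical Student's t by
default with an automatic Welch fallback (warned) when a group variance is
zero.

## Pipeline and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
single config/CLI seed; stage sub-seeds are drawn from one generator. The
run manifest records thresholds, per-stage counts and a SHA-256 checksum of
every output file; identical config + seed reproduces identical checksums.
An unreachable threshold (e.g. votes ≥ 6 with 5 studies) yields an empty
consensus and a completed run with a warning, not a crash.

## Problem sizes in tests and benchmarks

The bundled benchmarks use a scaled compendium — 5 studies × 2,000 genes,
15/15 samples per group, 200 up + 200 down planted at Δ = 1.0 — for
parameter-recovery checks, and 100-seed null replicates for calibration
(KS uniformity of combined p, χ² of Cochran's Q); these sizes give stable
rates while keeping the whole suite fast on one CPU. The analysis drivers
run the full-scale design (7,274 genes × 316 samples). Null-calibration
checks run the *entire* chain (simulate → moderated t → combine) rather
than feeding synthetic uniform p-values, so they would catch miscalibration
anywhere upstream.
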