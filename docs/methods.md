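# Methods

This note documents the models and procedures implemented in regulokit, the
choices made where the design was genuinely open, and what the synthetic-data
benchmarks do and do not demonstrate.

## The GRN regression

For target gene *i* the model is `Y_i = Σ_j β_j e_j a_j + ε` on log-normalized
expression (`ln(1 + 10⁴·count/total)` scale), with one interaction term per
distinct (TF, region) pair whose motif lies in a candidate region assigned to
the target's regulatory window (gene body plus 100 kb upstream of the TSS,
strand-aware; one annotation row per gene, no per-isoform windows).
Accessibility `a` is a probability in [0, 1]; at metacell resolution it is the
cluster-level mean of binarized fragment detection, broadcast so each member
observation carries its cluster's vector.

Choices worth stating:

* **Self-loops are excluded** (a TF never appears as its own predictor); the
  response appearing on both sides is degenerate.
* **TF detection filter**: terms whose TF is expressed (> 0) in fewer than 5%
  of observations are dropped at design time, mirroring the branch-pruning
  rule and avoiding near-constant columns.
* **Rank deficiency**: aliased columns are dropped greedily in term order
  (deterministic) and reported; the reduced model is fit.
* **Significance**: the default Gaussian-GLM back-end tests each coefficient
  with the single-term F test (equal to the two-sided t test in OLS).
  P-values are pooled over **all** targets before one Benjamini–Hochberg
  correction — stricter than per-target correction, and applied globally
  because module construction compares edges across targets. Regularized
  (ridge/lasso/elastic-net) and gradient-boosting back-ends return
  coefficients or importances without p-values.
* **Perfect fits**: with numerically zero residual variance, σ² is floored at
  1e-20 so exactly-null coefficients report p ≈ 1 rather than 0/0.

## Candidate regions

Peaks are width-filtered (strictly more than 20 bp, strictly less than
10,000 bp), clipped to their overlap with conserved elements, exon-overlapping
bases are subtracted from that conserved branch only, cCRE overlaps are added,
and the union is merged. Clipping (rather than keeping whole peaks) makes exon
subtraction well defined; provenance flags record which evidence branch
contributed each merged interval. Gene assignment requires ≥ 1 bp overlap
with the regulatory window; a region may serve several genes, and no
multi-gene down-weighting is applied (the ambiguity is inherited by the
regression, which sees each (gene, region) pair independently).

## Motif scanning

PFMs become log₂-odds matrices via column-normalized
`(counts + pseudocount·background)` with pseudocount 0.8 against a uniform
background by default (a GC-matched background is a parameter). The score
threshold for a p-value is computed by exact dynamic programming over the
score distribution discretized to 0.01-bit bins, so scanning is deterministic
and agrees with an exhaustive per-window scorer; windows containing non-ACGT
bases are skipped, both strands are scored, and all overlapping hits are
reported (downstream modelling uses region-level presence only). Motif-less
TFs inherit motifs from the up-to-three most similar same-family TFs at ≥ 20%
global identity; similarity is Needleman–Wunsch (BLOSUM62, gap open 10,
extend 0.5) identical-column fraction. The substitution matrix and gap
penalties are parameters: the original alignment settings are not published,
so these values are this package's own defaults.

## Coarse graining

A random 30% of cells (count rounded half-up) seed territories of their ten
nearest neighbours (Euclidean, top 20 PCs of z-scaled expression of the 2,000
most variable genes); the seed belongs to its own territory, and cells claimed
by several territories are kept in one chosen uniformly at random from the
documented RNG stream. Expression aggregates by arithmetic mean;
accessibility by the mean of binarized counts. LSI is tf-idf
(count fraction × log(1 + N/df)) followed by SVD with a deterministic sign
convention; component 1 is retained because the synthetic data carry no
depth artefact — dropping it is left to the caller. High-resolution
clustering is Louvain on a k=20 kNN graph (k is unstated in the source
procedure and exposed as a parameter) at resolution 100 by default.

## Branch-specific GRNs

Per region, accessibility probabilities across clusters are residualized
against the per-cluster mean ATAC depth, then z-transformed with mean and
s.d. taken only from residuals **strictly between** the 5th and 95th
percentiles. The strict band is a deliberate reading of "between the
percentiles": a region closed in a whole branch places a point mass of zeros
exactly at the lower percentile value, and only excluding that boundary mass
lets the trimmed moments describe the open clusters — with an inclusive band,
a closed fraction *f* of clusters yields z ≈ −√((1−f)/f), which never reaches
significance for f above a few percent and would make branch-wide closures
undetectable in principle. When ties empty the strict band the inclusive band
is used, and the trimmed s.d. is floored (1e-8) so a constant bulk turns any
departing cluster into an extreme outlier; regions whose residuals are all
identical are degenerate (z = 0).

Close outliers are BH-flagged (FDR < 0.01) on Φ(z) per region across
clusters, open outliers on 1 − Φ(z). The step-wise rule: close outliers
present → accessible everywhere except them; otherwise open outliers if any;
otherwise all clusters. Metacells inherit their cluster's accessibility call.
The χ² depletion test (no Yates correction; Haldane–Anscombe 0.5 for odds
ratios with empty cells; p = 1 on degenerate margins) flags a region
inaccessible in a branch at FDR < 0.01 **and** odds ratio < 0.5. Pruning
removes edges through branch-inaccessible regions, then every edge of TFs
detected in < 5% of the branch's observations ("detected" = expression
strictly positive).

## Module activity

Gene-module scores subtract bin-matched controls: pool genes are ranked into
24 average-expression bins, each module gene draws 100 controls from its bin
with replacement, and the score is the per-observation difference of module
and control means. Because controls are expression-matched, a uniform
additive shift of the module is partially absorbed into bin membership; the
score measures expression relative to similarly-expressed genes, and random
modules centre on zero. Regulatory-module deviations are a simplified
background-matched z: background sets resample regions from mean-accessibility
quantile bins (50 draws, 10 bins) and z = (observed − background mean) /
background s.d. — an approximation of bias-corrected deviation scores, not a
reimplementation of them. Variance decomposition fits activity ~ branch,
~ pseudotime, and ~ both, reporting R². Differential module activity uses a
two-sided Wilcoxon rank-sum over observations above the 0.7 pseudotime
quantile, BH-corrected, up-modules ranked by mean difference, top 15.
Branch-activation scores are per-gene correlations (Pearson default,
Spearman optional) between module gene expression and branch probability,
averaged per module and z-scored across modules with the population (n)
standard deviation; constant genes are skipped and counted.

## Screen statistics

Guide assignment fits a two-component free-variance Gaussian mixture on the
pooled ln of nonzero UMI counts; posterior ≥ 0.5 for the higher-mean
component assigns the guide, zeros are never assigned, and fewer than ten
nonzero values (or a degenerate distribution) falls back to a fixed ln-count
threshold (default ln 10) with a warning.

Perturbation probabilities follow the squared-error-contrast construction:
each of the 500 most variable genes is regressed on [scaled numeric
covariates, dummy-coded categorical covariates, binary guide assignments]
with elastic net (l1 ratio 0.5) and per-gene cross-validated penalty; for a
carrier cell, zeroing its guide column changes predictions by exactly the
guide coefficient, so `SSE₀ − SSE = Σ_i ((r_i + β_{ji})² − r_i²)` summed over
all selected features (the sum is over every selected feature, not only
nonzero-coefficient ones), and `p = logistic(Δ / 2σ²)` with σ² defined as the
mean squared residual of the full fit — the source construction leaves σ²
unspecified. Probabilities are evaluated in-sample, so guides with no true
effect sit slightly above 0.5 rather than at it. Target-level probabilities
take the maximum over the target's guides; guides with fewer than five
carriers are reported missing.

The CMH statistic is the classical one-degree-of-freedom form without
continuity correction, strata with total ≤ 1 skipped, p = 1 when everything
is empty; it is cross-checked in the tests against an independent reference
implementation. Composition analysis tests each (guide, branch) with an
organoid-stratified CMH plus per-organoid Fisher exact tests (each family
BH-corrected); filter 1 requires organoid-level significance (FDR < 0.05) in
more than one organoid with consistent direction, filter 2 a same-direction
partner guide of the same target at CMH FDR < 0.01. Surviving guides pool
into per-target × branch counts N, `LOR = ln[(N_{i,j}/N_{i,¬j}) /
(N_{¬i,j}/N_{¬i,¬j})]` with a 0.5 correction on zero cells (natural log), and
the per-target maximum over branches summarizes composition change.

## Differential tests and track scores

`de_linear` is per-gene OLS with covariates and an F test on the condition
coefficient (identical to the two-sample t test without covariates; aliased
conditions report NA, constant genes p = 1). `de_wilcoxon` is the two-sided
rank-sum with a mean log-difference effect; `da_binomial_lrt` compares
binomial-logit models with and without the condition by a 1-df LRT and flags
non-converged fits. Stage-specific peaks require in-stage detection > 15%
and specificity (in-stage ÷ out-stage detection, out-stage size-weighted when
sizes are given) > 1.5, ranked with zero out-stage detection first, top 5,000.
The gene binding score sums intensity × overlapping bases over the gene body
plus a 2-kb strand-aware upstream promoter extension; a `both_sides` flag adds
the downstream side, since "gene body + 2 kb" is ambiguous.

## Fate graph and branch assignment

Absorption probabilities are rank-transformed per terminal state (average
ranks, divided by n — invariant to monotone transforms). The fate graph
links k = 30 nearest clusters in transition-score space, keeps pairs with
connectivity > 0.2, and orients edges strictly forward in pseudotime
(pseudotime ties drop the edge). Tips default to the node maximizing
rank(score) × rank(pseudotime) per state, or are given explicitly. From each
tip, 10,000 uniform random walks of 200 steps run along reversed edges
(walks at a node with no backward edge terminate, visits counted up to
termination). A node whose top visitation frequency exceeds the runner-up by
more than 100× takes that tip's identity; otherwise all tips within 100× of
the maximum share it, with shared identities renamed through a configurable
merge map (defaulting to the sorted tip names joined by "+", which
generalizes hard-coded merge labels to any number of terminal states).
Unreached nodes inherit from their best-connected labelled neighbour,
iterated to convergence; isolated nodes stay "unassigned".

## The synthetic data

`simulate_regulome` draws pseudotime uniformly, TF expression from smooth
Gaussian-bump trajectories with mild branch modulation and observation-level
jitter (floored at 0), and accessibility from per-region curves with base in
[0.4, 0.8], bump amplitude ±0.15 and jitter 0.05, clipped to [0, 1]; a
configurable fraction of regions (default 10%) is closed (exactly 0) in one
random branch. Target expression is computed exactly through the model and
floored at 0; the first edge of every target is activating (β ∈ [1, 2.5]) so
the linear predictor stays mostly positive and the floor rarely bites —
without this, targets wired only repressively would be identically zero and
unrecoverable. Each target owns a genome block with one region per wired
edge directly upstream of a 2-kb gene body; blocks are spaced 110 kb apart so
regulatory windows do not cross targets, and each wired TF's motif consensus
is written into its region at a recorded offset, guaranteeing scan hits
without threshold tuning. `simulate_screen` gives every cell one true guide
(high log-normal UMI component, mean ln 50) plus Poisson ambient guides (mean
ln 2), branch labels from softmax logits shifted per target effect, and
expression effects on 20 genes per target in non-escaper cells.
`simulate_fate_inputs` builds a trunk-plus-three-branches cluster chain with
absorption probabilities rising along each branch and a well-connected hub at
the branch point.

What the benchmarks show — and do not. The generators use Gaussian noise with
a floor, not count noise: no dropout, no overdispersion, no batch structure,
no doublets, and motif placements are exact consensi. Passing the recovery,
FDR, pruning-exactness and AUROC benchmarks therefore demonstrates the
correctness of the algorithms under their own model assumptions, not
performance on real single-cell data, where collinear TF programs, sparse
detection and imperfect motif models will all degrade recovery.

## Problem sizes in the test-suite benchmarks

Parameter recovery runs at 10 TFs × 200 targets × 500 observations
(noise s.d. 0.1); FDR control at 100 null targets × 20 seeds; region-algebra
and motif-scan oracle checks on 100 × 100-kb toy genomes and 20 × 10-kb
sequences × 5 motifs; pruning exactness at 8 TFs × 60 targets × 400
observations × 10 seeds; the screen at 2,000 cells × 20 targets × 500 genes
(30% escapers); fate assignment at 60 clusters × 10 seeds with 2,000 walks
per tip (the walk count is reduced from the 10,000 default, which changes
under 2% of labels). These sizes were chosen as the smallest at which the
stochastic benchmarks are stable across seeds.
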