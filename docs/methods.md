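# Methods

This note documents the statistical models implemented by `npcrosstalk`,
the assumptions baked into the synthetic-data generator, and the design
choices made where the analysis recipe left room.

## Expression model and preprocessing

All matrices are log2-scale genes × samples. Probe-level matrices are
collapsed to genes by the arithmetic mean over a gene's probes, per sample;
unmapped probes are dropped and gene symbols upper-cased on ingest so
mixed-source lists compare consistently. Datasets of one disease are merged
on the intersection of their gene sets, with the source dataset id becoming
the batch label; colliding sample ids are prefixed with the batch id.

Batch correction implements the parametric empirical-Bayes location/scale
model: per gene g and batch i,

    y_ijg = α_g + X β_g + γ_ig + δ_ig ε_ijg,   ε ~ N(0, σ²_g).

Data are standardized per gene with a design that includes the case/control
indicator (so group signal is protected; correction without protection is
available, and is required when batch and group are confounded 1:1 —
protected correction then raises an error rather than silently absorbing the
group effect). Batch-wise additive effects γ̂ and scale effects δ̂² are
shrunk toward normal / inverse-gamma priors fitted by method of moments and
solved by the standard EB iteration (convergence 1e-4, max 500 iterations),
then removed. A single-batch cohort is returned unchanged with a warning.
The implementation was verified to machine precision against the reference
Bioconductor implementation of the same model on a fixed fixture; those
values are frozen into the unit tests.

PCA QC operates on gene-centered data via SVD; batch effect strength is
summarized as the one-way ANOVA R² of PC1 scores against batch, before and
after correction.

## Differential expression

Per gene, a two-group comparison on the corrected matrix: log2FC is the
difference of group means (case − control). The residual variance is shrunk
toward a common prior fitted by matching moments of log sample variances
(the scaled inverse-chi-square / F-distribution construction): with d_g
residual degrees of freedom and prior (d₀, s₀²),

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
    t_g = log2FC_g / (s̃_g √(1/n₁ + 1/n₂)),   df = d_g + d₀.

When the spread of log variances is no wider than sampling noise the prior
degrees of freedom are infinite and all genes share s₀² (normal reference
distribution). A switch disables shrinkage entirely, in which case the
statistic reduces to the pooled-variance Student t (verified to 1e-10 in
tests). The prior fit was cross-checked against the reference R
implementation; frozen values back the unit tests.

**No multiple-testing correction is applied.** The screening rules filter on
the raw p-value only (p < 0.05 with a fold-change cutoff), matching the
original analysis; this is stated explicitly to avoid silent FDR insertion.
The MDD preset's |log2FC| > 0 filter is implemented literally — it excludes
only genes with exactly zero fold change, making p < 0.05 the operative
criterion. With an inclusive cutoff of exactly 0 the up/down rule would
classify a zero-fold-change gene both ways; the implementation breaks that
tie by requiring a nonzero fold change.

## Crosstalk genes and enrichment

The crosstalk set is the intersection of the two diseases' DEG sets
(directions retained per disease). The pipeline passes the neuropeptide
panel as an exclusion list: the panel is screened by its own downstream
lasso stage and is kept disjoint from the crosstalk set, mirroring the
observed disjointness of the two gene classes in the motivating study. (In
the synthetic data this matters: planted predictive panel genes carry a real
group shift and would otherwise enter the intersection.)

Enrichment is the one-sided hypergeometric over-representation test,
p = P(X ≥ k) for X ~ Hypergeom(N, K, n), with gene sets intersected with
the universe before testing. The enrichment background is not prescribed by
the analysis recipe; the pipeline uses all genes present after merging in
both diseases, and the universe is an explicit argument. Raw p < 0.05 flags
significance; Benjamini-Hochberg adjustment is available but off by default.

## Differential coexpression (DRL)

For each crosstalk–neuropeptide pair within one disease, Pearson
correlations are computed over (a) the case group and (b) all samples of the
disease. The screen keeps pairs with |CC| strictly greater than 0.5. Which
subset the screen uses is configurable (`screen_on: case | all`); the
default is the case group, consistent with reporting case-group correlation
heatmaps, while CC_all in the score always uses all samples of the disease.

Surviving pairs get per-group OLS fits y ~ βx + β₀ (x = crosstalk gene,
y = neuropeptide; each group needs ≥3 samples and a non-constant predictor)
and the score

    DRL = (β_case − β_control) / √(sd²_case + sd²_control) + CC_all,

with sd the standard error of each slope estimate,
sd = s_resid/√Σ(x−x̄)². This reading makes the first term a Wald-type
contrast of the two slopes — the only per-relationship dispersion the
regression yields. Pairs failing preconditions (zero-variance genes,
noise-free fits with both sd = 0) are dropped with a logged reason, never
silently. The sign class is read as consistent (+) versus opposite (−)
regulation; a DRL of exactly 0 is classified "consistent" (boundary
tie-break). Note the additive CC_all term means the sign of DRL is not
strictly the sign of the slope contrast; the score is implemented literally
and the stated interpretation applies to its sign as defined.

## Networks

Topology metrics follow the Cytoscape conventions: per-node degree; average
shortest path length over reachable nodes (unreachable pairs excluded);
betweenness normalized by 2/((N−1)(N−2)); closeness = 1 / (average distance
to reachable nodes); topological coefficient
TC(n) = avg over partners m of (|shared neighbours| + [m adjacent to n])/k(n),
with TC = 0 for nodes without partners. Bridge triples are all
(crosstalk, other, neuropeptide) length-two paths; the one-step extension is
computed on the full supplied graph, not a filtered subgraph. The merged
multi-database interactome of the motivating study is replaced by a single
user-supplied edge list — the algorithms are source-agnostic and database
licensing/versioning is out of scope. All four path-based metrics are tested
against exhaustive brute-force reimplementations (BFS distance fields,
explicit shortest-path enumeration, adjacency-matrix arithmetic).

## Neuropeptide screening

L1-penalized logistic regression of case status on the z-scored panel
matrix over a 50-point log-spaced λ grid anchored at the smallest λ that
zeroes all coefficients, with stratified K-fold cross-validation (10 folds,
reduced to the minority-class count when needed). CV loss is the binomial
deviance by default; squared error on the 0/1 response is available
(`--cv-loss mse`) for literal fidelity to mean-squared-error CV curves, and
a linear-on-label lasso (`--model linear`) is offered since the original
recipe does not state which variant was fitted. λ_min (loss-minimizing) is
the default selection point; λ_1se (largest λ within one standard error) by
flag — the original figures show both dashed lines without stating which
was used. The liblinear solver is run with a fixed internal seed so the CV
curve is bit-reproducible, part of the pipeline's determinism contract.

Single-gene AUC is the rank statistic (probability a random case exceeds a
random control, ties half-weighted), computed from the Mann–Whitney U and
verified to equal trapezoidal integration of the threshold-swept ROC curve.
The positive class is case and no direction flipping is applied, so AUC < 0.5
is reported as-is. Group comparisons use the two-sided Wilcoxon rank-sum
test with boundary-inclusive star codes (≤0.05 \*, ≤0.01 \*\*, ≤0.001
\*\*\*, ≤0.0001 \*\*\*\*; otherwise ns).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Noise model**: i.i.d. Gaussian on the log2 scale per gene (baseline
  N(7, 1), residual SD 1.0 by default) — matching the linear/Pearson/OLS
  machinery applied downstream to log2 microarray intensities.
- **Batch effects**: per-batch, per-gene additive shifts N(0, shift_sd²)
  (default 1.0 log2 units) and multiplicative noise-scale factors
  exp(N(0, scale_sd)) (default 0.1) — exactly the generative model the EB
  correction assumes, so the correction is testable.
- **Cohorts**: MDD 30 case / 33 control over 2 batches; PD 430/139 over 3 —
  the sizes of the motivating study. Batches are balanced across groups by
  round-robin assignment; a batch with fewer than two samples is rejected.
- **Planted DE**: effect ±2.0 log2 units in cases. By default all 35
  planted DE genes per disease are the shared crosstalk set. Disease-unique
  DE genes are available (n_de_up/n_de_down above the crosstalk count), but
  the demo plants only the shared set because the permissive |log2FC| > 0
  rule admits ~5% of the other disease's unique DE genes into the
  intersection by chance, which would make exact truth-ledger recovery a
  coin flip rather than a property.
- **Neuropeptide panel**: 102 genes, disjoint from the DE background, with
  no planted group effect, occupying the last matrix rows. Two planted
  exceptions: (a) 8 panel genes linearly coupled to crosstalk genes with
  group-specific slopes (β_case = 1.5, β_control = −0.5, coupling noise SD
  0.5) — the predictor is centered within each group before the slope is
  applied, so the coupling plants differential coexpression without a group
  mean shift and the panel stays non-DE, as observed for the real panel;
  (b) 4 panel genes with a case shift of 2 residual SDs in both diseases —
  the predictive signal the lasso stage must recover. Panel genes are
  otherwise mutually independent; real panels have correlation structure
  the generator does not emulate.
- **PPI graph**: 400-node Erdős–Rényi background (edge probability 0.01)
  over the crosstalk set, the panel and filler genes, with direct
  crosstalk–neuropeptide edges excluded by construction and 20 planted
  bridge triples through distinct intermediate nodes.
- **Pathways**: 50 sets of 10–40 genes; exactly 5 "mixed" sets contain both
  roles (non-mixed sets never contain a panel gene), so the tripartite
  network's pathway count is checkable.

All randomness derives from the config seed through fixed-key seed streams,
so every artifact is bit-reproducible and each generator operation can be
called independently with consistent planted identities.

**What passing tests show — and don't.** Recovery tests demonstrate the
pipeline's correctness under its own model assumptions (Gaussian log2 noise,
linear couplings, additive/multiplicative batch effects). They do not show
robustness to the pathologies of real microarray cohorts: probe-level
artifacts, heavy-tailed noise, confounded batch/group designs, correlated
panels, or annotation drift between platforms. Headline counts from real
cohorts (DEG totals, 181 screened pairs, 164 bridge pairs, 9/43 lasso
selections) depend on database versions and are not targets of the
synthetic study; the counts the demo reproduces exactly are the ones the
generator plants.

## Numerical choices and degenerate inputs

- Variance-prior fit: trigamma inverse solved by bracketed root finding in
  [1e-8, 1e8]; genes with zero sample variance are excluded from the moment
  fit but receive posterior variances; an all-zero-variance matrix is
  rejected.
- ComBat: pooled variance floored at 1e-12 before standardization; EB
  iteration convergence 1e-4.
- Correlations: exactly collinear inputs give r = ±1 (clipped); a
  zero-variance gene in the chosen subset yields a missing correlation and
  the pair is excluded from screening, with a warning.
- Screen boundary: |CC| > 0.5 is strict; r = 0.5 exactly is excluded.
- DRL with both slope standard errors zero raises (division by zero; occurs
  only on noise-free fixtures).
- Lasso λ grid: 50 points, ratio 1e-3, anchored at the zeroing λ;
  constant features get unit scale instead of division by zero.
- Constant-valued genes in ROC get AUC 0.5 with a warning.
- Deterministic orderings everywhere a stage does not define one
  (lexicographic gene/pair sorting, stable mergesort), so reruns are
  byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the
study's cohort sizes (63 and 569 samples, 2000 genes including the
102-gene panel), DE calibration on 10,000 null genes at n = 15/group,
sensitivity at n = 30/group, lasso recovery on ten replicate studies at
n = 100/group, and graph-metric verification on fifty random graphs of up
to 30 nodes — sizes at which every planted signal is comfortably above its
detection threshold while the whole suite stays fast.
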