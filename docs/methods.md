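# Methods

## Observation models

A compressed Perturb-seq measurement unit mixes several perturbations. The
package models droplet (or cell) `i` on the natural-log scale:

* **cell-pooled** (several single-guide cells per droplet): the droplet's
  expression is treated as the *geometric* mean of its member cells, so
  `E[log y_i] = log c + (1/g_i) * sum_j x_ij beta_j`. The geometric choice
  keeps inference in log-fold-change space, which is symmetric around zero
  (balanced up/down calls); the arithmetic and geometric droplet means of
  the same cells track each other closely (see Limitations for how closely).
  `g_i`, the number of called guides in the droplet, proxies the number of
  member cells. In matrix form the design rows are normalized to sum 1.
* **guide-pooled** (several guides per cell): log effects add,
  `E[log y_i] = log c + sum_j x_ij beta_j`; the design is unnormalized.

When every unit carries exactly one guide the two models coincide; the two
fits are bit-identical in that case (tested).

Assumptions inherited from the model: effects combine additively in log
space within a composite unit; control expression `c` is common to all
cells; the effect matrix `B` is approximately low-rank with few co-functional
perturbations per latent factor — the regime in which composite samples of
order `(q + r) log n` suffice instead of one sample per perturbation.

## Preprocessing

Counts are depth-normalized to TP10K and log-transformed with a pseudocount
of 1: `ln(count/total * 1e4 + 1)`. The control profile `log c` is the
per-gene mean of this quantity over cells whose *only* called guides are
non-targeting; safe-targeting-only cells are excluded from the profile (they
cut DNA, and their rows of `B_hat` serve as a negative-control diagnostic
instead). Technical covariates (total UMIs, mitochondrial fraction,
cell-cycle scores, optionally guides per cell) are mean-centered and
OLS-residualized out of `Y'` gene by gene with an intercept, so per-gene
means are preserved up to the intercept. Centering on `log c` commutes with
intercept-OLS residualization, so the order of the two steps is immaterial
(tested as an algebraic identity).

Cell-cycle scores are signature-minus-background module scores: the mean
normalized expression of the signature genes minus that of a size-matched,
seeded random background set (default seed 12345). This is deliberately
simpler than bin-matched scoring schemes — a covariate only needs to capture
the axis.

## Estimation

Both stages use the *budget* (constraint) form of the L1 problem, because
the method's hyperparameters are budgets, not penalty weights:

* factorize: alternating minimization of `(1/n) sum_i ||y_i - W^T code_i||^2`
  with `||code_i||_1 <= lambda1` — L1-ball-projected FISTA for the codes,
  unconstrained least squares for the dictionary `W` (the codes carry the
  constraint, so `W` is finite and unique up to rank deficiency). The
  dictionary is initialized from `R` seeded random rows of `Y'`
  (unit-normalized); dead atoms are reseeded. Stopping: relative objective
  decrease below 1e-6 or 500 alternations. The objective is non-increasing
  across alternations (tested).
* recover: per-column FISTA on `min ||u~_r - X'u||^2, ||u||_1 <= lambda2`,
  run in Gram form (`X'^T X'` and its largest eigenvalue are permutation
  invariants, computed once and shared across all permutation replicates).
  Solutions match a generic split-variable NLP solver to 1e-6 (tested).

Hyperparameter defaults `R = 10`, `lambda1 = 0.1`, `lambda2 = 10` are the
method's standard settings; results are not very sensitive to them.

### LOESS magnitude correction

Estimated |effects| shrink with the downstream gene's expression level — an
artifact of the pseudocount: at low counts a true log fold change moves
`log(y+1)` by only a fraction of itself. The correction fits a LOESS curve
(span 0.3) of the per-gene mean |effect| against the gene's control
expression level `ln(mean TP10K + 0.01)` and rescales every gene by
`f_ref / f(level)`, with `f_ref` the mean fitted magnitude over genes with
level > 2 (top decile fallback). Two implementation choices:

* the curve is fit to the **log** of the mean magnitude and exponentiated.
  The correction is a ratio of fitted magnitudes, so the trend belongs on
  the log scale; a linear-scale fit can go non-positive at the
  low-expression edge and leaves residual trend. With the log-scale fit the
  post-correction rank correlation between mean |effect| and expression
  level is ~0 (|rho| < 0.01 in simulations).
* the fit uses per-gene mean magnitudes rather than all P x G entries; with
  a level shared by all entries of a gene the two produce the same curve,
  and the per-gene form is cheaper and more stable.

The correction multiplies signal and estimation noise alike, so it removes
magnitude bias at the cost of variance on weakly expressed genes; in
simulations it substantially improves the pooled correlation between
estimated and true effects (heterogeneous attenuation otherwise dominates).

## Significance

Rows of `X'` are permuted (default 500 times); the factorization never sees
`X`, so only recover + compose rerun per replicate. The same data-derived
LOESS factors are applied to every null slice so estimates and nulls share a
scale (and per-gene factors therefore cancel in the p-value). Two-tailed
p-values use the add-one estimator `p = (1 + #{|null| >= |b|}) / (K + 1)`,
which is exactly uniform on its lattice under the global null.

Entries beating all K permutations are refined by a per-entry Azzalini
skew-t fit to the null draws: numerical MLE (Nelder-Mead, moment-based
initialization, df constrained to [2.1, 100] through a logistic
reparameterization), two-tailed p by numerical integration of the fitted
density. Refinement needs at least 50 draws and is skipped below that; a
failed fit falls back to the add-one p with a warning. At ~165 ms per entry
the refinement is intended for the regime it serves — resolving p below
1/(K+1) for a modest number of entries; on signal-dense simulated screens
where tens of thousands of entries beat every permutation it changes no
q < 0.05 call and can be disabled (`refine_tail=False`).

BH FDR is applied over the full flattened matrix.

One property worth knowing: each entry's permutation null is symmetric
around a *non-zero* center — the latent codes have non-zero means, which
pass through `X^T u` for every permutation, and the offset is often several
times the null sd. This does not bias the p-values (the observed statistic
is exchangeable with the null draws under the global null; uniformity is
tested end to end), but "the null is centered at zero" is not an invariant
of this scheme.

## Guide selection

For each perturbed gene all 15 non-empty subsets of its (up to) four guides
are scored: only the focal gene's design column is rebuilt from the subset,
cells are split 50/50 (seeded), the estimator is fit in each half (one
factorization per half is shared across subsets — the factorize step never
sees the design, so this is exact, not an approximation), and the squared
Pearson correlation of the focal gene's effect row between halves is
computed over entries with q < 0.2 in either half. Ties break toward larger
subsets, then lexicographically. Subsets consisting only of inefficient
guides produce no replicable effects and are never chosen; resolving *mixed*
subsets (some live, some dead guides) requires transcriptome-scale gene
panels and tens of thousands of cells, because at desk scale the split-half
correlation is dominated by factorization structure shared between halves
(the live/mixed ordering is consistent but the margins are ~0.005 in R^2).

## Second-order effects

Pairwise: indicator products for perturbation pairs supported by >= 5 cells
(found from the co-occurrence matrix `X^T X`, so the full C(P,2) candidate
set is never materialized), then factorize-recover on the residual
`Y'' = Y' - X'B`. Permutation nulls permute the rows of `X` and `X2` jointly
and re-estimate the first-order effects inside every permutation so their
uncertainty propagates; within each permutation the expression dictionaries
(of `Y'` and of `Y''`) are held fixed and only the coding and recover steps
rerun — re-factorizing the permuted residual each time would be
quadratically more expensive for a second-order change in the null.

Module-level: cells are partitioned by their guide content into control /
one-module-guide / two-module-guide sets (gene-level, from the collapsed
design: a cell with two guides for the *same* module gene counts once;
guide-level multiplicity is not recorded in `X`). "Control guides" are
non-targeting, safe-targeting, and guides for genes without significant
effects on the program (program-level significance = permutation test on the
mean effect over program genes, BH across perturbations, q < 0.05 by
default). Interaction effects are contrasts of mean standardized program
expression: `beta_1 = mu_1 - mu_0`, intra `beta_11 = mu_11 - 2 beta_1 -
mu_0`, inter `beta_12 = mu_12 - beta_1 - beta_2 - mu_0`; p-values permute
set labels (default 10,000), SEs bootstrap within sets (default 1,000).
Cells with more than two module guides belong to no set and are dropped —
the information loss is accepted for fidelity to the contrast definitions.

## Synthetic screens

The generator is first-class, tested code, and defines the study conditions:

* **Truth**: `B = U W`, `U` (P x r) with at most `q` non-zeros per column,
  `W` (r x G) dense with unit-RMS rows; non-zero entries rescaled to RMS
  `effect_scale` (default 0.5 — fold changes of roughly +/-65%, the scale of
  knocking out an active regulator). Defaults P=100, G=2000, r=10, q=10.
* **Control cells**: negative binomial counts (gamma-Poisson) with lognormal
  gene means on the TP10K scale (ln-mean -2, ln-sd 1.5), dispersion 0.3
  (var = mu + 0.3 mu^2), lognormal library sizes (median 5,000 UMIs, sigma
  0.3, mean-corrected). These are stand-ins for resampled real control
  cells; they reproduce overdispersed sparse counts but not gene-gene
  correlation structure, ambient RNA, or doublet artifacts — so passing
  tests demonstrate the estimator's behavior under the stated noise model,
  not under every pathology of real data.
* **Cell-pooling**: `n x m` single-guide cells (each cell a control with
  probability 0.1 — the whole cell, matching the proportion of control
  guides in such libraries); counts of perturbed cells are control draws
  scaled by `exp(beta)`; droplets average m cells and are stochastically
  rounded (expectation-preserving, rather than truncated).
* **Guide-pooling**: each cell carries m distinct perturbations (or is a
  control cell with probability 0.1); counts scale by the product of
  `exp(beta)` over effective perturbations, plus `exp(beta_jk)` for injected
  interaction pairs. Per-guide efficiency flags (Bernoulli) exercise guide
  selection.
* Guide UMI support is drawn as 5 + Poisson(15) per called pair, so calls
  always clear the 5-UMI threshold; every output is bit-reproducible from
  (configuration, seed).

## Problem sizes used in the tests and acceptance script

Parameter recovery runs at the reference scale P=100, G=2000, r=10, q=10,
n=5,000 guide-pooled cells with m=3 and 500 permutations. Null calibration
uses P=98, G=102 (~10^4 entries) — effect rows live in the rank-R factor
span, so a p-value matrix holds about P x R effectively independent
statistics, and smaller panels leave the KS statistic dominated by its own
sampling noise rather than miscalibration. FDR control and module
interaction recovery use 20 replicates of smaller screens (P=20/P=4, G=150,
n=900/1,500). The pooling comparison uses 1,000 droplets of 500 genes per
multiplicity.

## Known limitations

* The arithmetic and geometric droplet pooling laws agree closely as
  profiles (entry-wise correlation 0.99 at m = 2-8), but the *per-gene*
  correlation across droplets is bounded by the Jensen-gap variance of
  overdispersed counts: medians ~0.96 / 0.94 / 0.93 at m = 2/4/8 under
  dispersion 0.3. Per-gene agreement above 0.95 for all m is not attainable
  under this noise model.
* The LOESS correction trades magnitude bias for variance at weakly
  expressed genes; effects on genes with control expression below ~0.1 TP10K
  are essentially unmeasurable either way.
* Skew-t refinement cost scales linearly in the number of
  beyond-permutation-resolution entries (see Significance).
* Guide-subset selection resolves fully dead subsets at any scale, mixed
  subsets only at transcriptome scale (see Guide selection).
* The elastic-net baseline (penalty form, l1 = l2 = 0.00025, pooled
  10-permutation null) is the only baseline; negative-binomial per-gene
  regression is out of scope.
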