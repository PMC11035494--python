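# frperturb

Factorize-recover inference of perturbation effects for **compressed
Perturb-seq** screens — pooled CRISPR screens with a single-cell RNA-seq
readout in which each measurement unit is a *composite sample*: either a
droplet overloaded with several single-guide cells (**cell-pooling**) or a
cell transduced at high MOI with several guides (**guide-pooling**).
Compression trades droplets/cells for statistical structure: when the
perturbation-effect matrix is sparse and low-rank, far fewer composite
samples than perturbations suffice to recover it.

The package is for computational biologists analyzing (or planning) such
screens, and for method developers who need a fully synthetic, seeded test
bed for composite-sample inference.

## The model

Let `Y` be the droplets x genes UMI count matrix and `X` the binary
droplets x (P+2) design (one column per perturbed gene plus non-targeting
and safe-targeting control indicators). With `c` the expected control
expression and `B` the P x G matrix of log fold changes, droplet `i` with
`g_i` guides is modeled on the log scale as

    cell-pooled :  E[log y_i] = log c + (1/g_i) * sum_j x_ij * beta_j
    guide-pooled:  E[log y_i] = log c +           sum_j x_ij * beta_j

so `E[Y'] = X'B`, where rows of `Y'` are `log(TP10K+1)` expression minus the
mean control profile `log c`, and `X'` is `X` row-normalized to sum 1
(cell-pooled) or unnormalized (guide-pooled).

`B` is estimated by **factorize-recover**:

1. *factorize* — sparse factorization `Y' ~ U_tilde @ W` (sparse PCA: an L1
   budget `lambda1` on each row of `U_tilde`, rank `R`);
2. *recover* — budget-form LASSO of each `U_tilde` column on `X'`
   (`||u||_1 <= lambda2`), giving latent effects `U`;
3. *compose* — `B_hat = U @ W`, followed by a LOESS correction that removes
   the global dependence of |effect| on the downstream gene's control
   expression level (an artifact of log-transforming sparse counts).

Defaults `R=10, lambda1=0.1, lambda2=10`. Significance: permutation of the
design rows (only the recover step reruns; 500 permutations by default),
add-one two-tailed p-values, an Azzalini skew-t tail fit for entries beating
every permutation, and Benjamini-Hochberg FDR over all entries. Second-order
(epistatic) effects are estimated pairwise on the residual `Y' - XB` with a
pair-expanded design, and at the module level via interaction contrasts
(`beta_11 = mu_11 - 2*beta_1 - mu_0`) with permutation p-values and
bootstrap standard errors.

## Worked example

```python
import numpy as np
import frperturb as fp

# synthetic guide-pooled screen: 50 perturbations, 500 genes, rank-5 truth,
# 3,000 cells with 3 guides each
truth = fp.make_truth(n_perturbations=50, n_genes=500, rank=5,
                      max_cofunctional=5, effect_scale=0.5, seed=0)
model = fp.make_control_model(500, seed=1)
screen = fp.simulate_guide_pooled(truth, model, n_cells=3000, m_guides=3, seed=2)

Y, profile, _ = fp.prepare_expression(screen.counts, screen.design)
est = fp.FRPerturb(rank=10, mode="guide_pooled", n_permutations=500,
                   refine_tail=False, random_state=0)
est.fit(screen.design, Y, control_level=profile.level)

idx = [truth.perturbation_ids.index(p) for p in screen.design.perturbation_ids]
B_true, B_hat = truth.B_true[idx], est.effects_[:len(idx)]
discoveries = est.q_values_[:len(idx)] < 0.05
nonzero = B_true != 0
r = np.corrcoef(B_true[nonzero], B_hat[nonzero])[0, 1]
sign = (np.sign(B_true[discoveries & nonzero])
        == np.sign(B_hat[discoveries & nonzero])).mean()
print(f"control cells used for log(c): {profile.n_control}")
print(f"effects estimated:             {B_hat.shape[0]} x {B_hat.shape[1]}")
print(f"discoveries (q < 0.05):        {discoveries.sum()}")
print(f"Pearson r vs truth (non-zero): {r:.3f}")
print(f"sign agreement (discoveries):  {sign:.3f}")
```

Output:

```
control cells used for log(c): 158
effects estimated:             50 x 500
discoveries (q < 0.05):        6633
Pearson r vs truth (non-zero): 0.931
sign agreement (discoveries):  0.952
```

158 cells carrying only non-targeting guides define the baseline profile;
6,633 of the 25,000 perturbation-gene effects pass FDR 5%, their estimated
log fold changes correlate at r = 0.93 with the planted truth, and 95% of
the discovered effects have the correct sign.

The same pipeline is available from the shell:

```bash
frperturb simulate --mode guide-pooled --n-droplets 3000 -m 3 --outdir sim/
frperturb fit --counts sim/matrix.mtx --barcodes sim/barcodes.tsv \
    --features sim/features.tsv --guide-umis sim/guide_umis.tsv \
    --guide-map sim/guide_map.tsv --mode guide-pooled --out sim/run
```

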