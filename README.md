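# insider-decomp

Covariate-aware sparse matrix decomposition for bulk RNA expression.

Bulk RNA-seq studies routinely profile samples that differ along several
axes at once — donor, phenotype, tissue, developmental stage — and the
interesting biology is often not any single axis but their *interaction*
(e.g. a disease that alters expression differently in different brain
structures). Standard dimension-reduction tools (PCA, NMF, tensor
decompositions) either ignore the covariate structure or force the data
into a complete tensor, which real cohorts with missing tissue samples
never are. This package decomposes the expression matrix into additive,
per-covariate low-rank contributions that share one gene axis, so each
covariate (and each covariate interaction) gets its own interpretable
latent representation.

## Model

For an expression matrix `Z ∈ ℝ^{N×M}` (N samples, M genes) with covariate
design matrices `X_D` (donor), `X_P` (phenotype), `X_T` (tissue), `X_W`
(phenotype × tissue interaction) and `X_U = I_N` (per-sample), the model is

    Ẑ = (X_D D + X_P P + X_T T + X_W W + X_U U) V

where each factor matrix (`D`, `P`, …) has K rows-per-level latent
coordinates and `V ∈ ℝ^{K×M}` is the shared **metagene** matrix. The fit
minimizes

    ½ Σ_observed (z − ẑ)²  +  ½λ Σ_b ‖B_b‖²_F
      + λ₁ [ ½(1−α)‖V‖²_F + α|V|₁ ]

i.e. masked squared error (missing entries never enter any sum), ridge on
every covariate block, and an elastic net on the gene loadings for
interpretable, sparse metagenes. Optimization is alternating block
coordinate descent: every covariate block has an exact closed-form masked
ridge update; each column of `V` is an elastic-net subproblem solved by
randomized coordinate descent with safe screening (closed form when α = 0).
Arbitrary categorical, interaction, and continuous covariates are
supported; the per-sample block `U` captures variation from unknown
sources. Hyperparameters {K, λ, α} are selected by RMSE on a 10% held-out
set of observed entries.

## Worked example

Simulate data from the model's own generative design (250 samples × 200
genes, rank 5, two crossed categorical covariates plus a per-sample
interaction, 30% of genes silenced, noise sd 0.25) and refit it:

```python
from insider import Hyperparams, fit, observation_block, reconstruct
from insider.simulation import simulate_insider_design, rmse
from insider.downstream import metagene_variance_ranking

sim = simulate_insider_design(delta=0.25, seed=7)
design = list(sim.design) + [observation_block(250, name="interaction")]
hp = Hyperparams(K=5, ridge_lambda=0.1, alpha=0.0, tol=1e-8,
                 max_iter=300, seed=7)
model = fit(sim.Z, design, hp)
print("recovery RMSE vs noiseless signal:",
      round(rmse(reconstruct(model), sim.truth), 4))
print(metagene_variance_ranking(model, "E"))
```

prints

```
recovery RMSE vs noiseless signal: 0.0539
[(1, 4.74), (0, 4.47), (4, 3.54), (2, 3.28), (3, 2.87)]
```

The recovery RMSE of 0.054 means the fitted reconstruction is within a
small fraction of the noise level (sd 0.25) of the true noiseless signal —
the interaction block is essential here; dropping it leaves an irreducible
error of ≈ 1.7 (the RMS of the unmodeled interaction signal). The ranking
lists metagenes by their variance across the 50 levels of covariate `E`,
the ordering used to pick "most variable" metagenes for downstream
interpretation and to exclude near-constant ones.

The same workflow is available from the shell:

```sh
insider simulate --design insider --delta 0.25 --seed 7 --out sim/
insider fit --expression sim/Z.tsv --covariates sim/covariates.tsv \
    --categorical E,F --observation-block on --rank 5 --lam 0.1 \
    --seed 7 --out fit/
insider adjust --fit fit/ --block F --exclude-low-var 2 \
    --contrast F_0,F_1 --quantile 0.025 --out profiles/
```

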