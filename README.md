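# igxe — integrative gene-environment interaction selection

`igxe` is a Python implementation of a two-stage penalized variable-selection
model for gene-environment (G×E) interaction studies with multi-omics
regulators. It is aimed at statistical genetics / cancer genomics analysts
who have, for the same subjects, a continuous outcome Y, a few environmental
factors E, gene expressions G, and the expressions' upstream regulators
(DNA methylation and copy-number alteration, stacked as R) — and who want to
select outcome-relevant genes, G×E interactions, and regulators while
*using* the regulatory flow CNA/methylation → expression → outcome instead
of pooling all features as exchangeable predictors.

## The model

**Stage 1** learns the sparse regulatory relationship. Each expression is
regressed on all regulators with the LASSO,

    (1/2n)‖g_j − a_j − Rθ_j‖² + λ|θ_j|₁ ,

giving the transition matrix Θ̂ = (θ̂₁, …, θ̂_{p_g}), which is then split
into L rank-1 *linear regulatory models* (LRMs) by recursively deflated
sparse SVD: each triplet (d_l, u_l, v_l) minimizes

    (1/2n)‖Θ̂ − d·u·vᵀ‖²_F + λ_svd|d·u|₁ + λ_svd|d·v|₁ ,  ‖u‖₂ = ‖v‖₂ = 1,

so a sparse set of regulators (u_l) drives a sparse set of genes (v_l).

**Stage 2** regresses the outcome on the decomposed design

    Y = Eα + Σ_l X1_l b1_l + Σ_j X2_j b2_j + R̃γ + ε ,

where X1_l = (GV_l, GV_l·E₁, …, GV_l·E_q) are the regulated-expression
scores with their environment interactions, X2_j the same blocks for the
perpendicular-projection residual expressions G̃_j, and R̃ the residual
regulators. Environmental main effects are unpenalized (weak hierarchy);
each block carries a sparse group LASSO penalty λ(‖b‖₂ + |b|₁) — bi-level
selection of whole LRMs/genes and of individual main/interaction slots —
and γ a plain LASSO penalty, all driven by one tied λ. The solver
alternates a closed-form update of α with cyclic blockwise proximal
updates, descending a 100-value penalty grid with warm starts.

The package also ships the matching synthetic-data generator (AR-1 or
banded regulator correlation, rank-L sparse transition matrix, weak/strong
signal regimes), the S-LASSO and J-LASSO baselines, and ROC / partial-AUC
(PAUC) evaluation of selection accuracy over the penalty path. See
`docs/methods.md` for assumptions, tuning defaults, and limitations.

## Worked example

```python
import numpy as np, igxe

config = igxe.SimulationConfig(n=300, p_g=60, p_r=60, q=4, L_true=6,
                               support_size=5, n_causal_genes=10,
                               effects_per_gene=4, n_causal_regulators=10,
                               signal="strong", seed=1)
dataset, truth = igxe.simulate_dataset(config)

stage1 = igxe.fit_stage1(dataset.G, dataset.R, L=6, rng=1)
print("components extracted:", stage1.L)
print("singular values:", np.round(stage1.d, 1))
print("gene-loading support sizes:", np.count_nonzero(stage1.V, axis=0))

design = igxe.decompose(dataset.G, dataset.R, dataset.E, stage1)
path = igxe.fit_path(design, dataset.Y, dataset.E)

for fam in ("gene_gxe", "regulators"):
    roc = igxe.roc_from_path(path, truth, fam, stage1)
    print(f"IGE PAUC [{fam}]: {roc.pauc:.3f}")

jl = igxe.j_lasso_path(dataset)
for fam in ("gene_gxe", "regulators"):
    roc = igxe.roc_from_path(jl, truth, fam)
    print(f"J-LASSO PAUC [{fam}]: {roc.pauc:.3f}")
```

Output:

```
components extracted: 6
singular values: [53.1 51.2 46.  45.7 44.7 41.8]
gene-loading support sizes: [5 5 5 5 5 5]
IGE PAUC [gene_gxe]: 0.788
IGE PAUC [regulators]: 0.725
J-LASSO PAUC [gene_gxe]: 0.490
J-LASSO PAUC [regulators]: 0.860
```

All six generating regulatory components are recovered with exactly
5-sparse gene loadings (their true support size), and the integrative
model ranks true gene/G×E effects far better along its penalty path
(PAUC 0.79) than a joint LASSO that pools expressions, interactions and
regulators into one flat design (0.49). PAUC here is the trapezoidal area
under the selection ROC over the false-positive range the path actually
achieves — no extrapolation — so 1.0 means perfect ranking across the
whole sweep and values depend on how far the path can reach.

## Command line

```bash
igxe simulate --config config.json --seed 1 --out data/
igxe fit-stage1 --data data/ --L 20 --lambda-svd auto --out s1/
igxe fit --data data/ --stage1 s1/ --method ige --lambda auto --grid 0:3:100 --out fit/
igxe evaluate --config config.json --replicates 10 --methods ige,j_lasso,s_lasso --out eval/
```

Every command writes a `manifest.json` (config + seed + version) beside its
outputs, sufficient to re-run bit-identically.

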