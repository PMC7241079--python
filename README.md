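# smccnet

Phenotype-supervised sparse multiple canonical correlation networks for
integrating two omics blocks — a proteomic and a metabolomic matrix — with a
continuous clinical phenotype.

## The problem

Single-omics biomarker screens rank features one at a time and miss features
whose relevance comes from their *connections*: a protein that is only weakly
correlated with lung function may still belong to a tightly coupled
protein–metabolite module that tracks disease. This package builds such
modules directly. It is written for analysts working with paired blood
proteomics/metabolomics and a quantitative phenotype (the motivating setting
is COPD cohorts with FEV₁% predicted and CT percent emphysema), and it ships
a synthetic-data generator with planted signal so the entire pipeline is
testable without access to any cohort.

## The model

Let X₁ (n × p₁) and X₂ (n × p₂) be column-standardized omics blocks and y a
standardized phenotype. Sparse multiple CCA finds weight vectors w₁, w₂
maximizing

    J(w₁, w₂) = w₁ᵀ Σ₁₂ w₂ + s·(w₁ᵀ σ₁y + w₂ᵀ σ₂y),
    subject to ‖w_k‖₂ ≤ 1,  ‖w_k‖₁ ≤ l_k·√p_k,

where Σ₁₂ = X₁ᵀX₂/(n−1) and σ_ky = X_kᵀy/(n−1) are Pearson correlation
matrices, s ≥ 0 is the *scaling constant* that prioritizes omics–phenotype
over omics–omics correlation, and l_k ∈ (0, 1] are sparsity fractions chosen
by repeated 5-fold cross-validation over the 6×6 grid
(0.05, 0.15, …, 0.55)². The solver is block coordinate ascent; each half-step
is an exact soft-threshold projection onto the L1/L2 constraint set, so J is
monotone.

Networks come from consensus: |w̃w̃ᵀ| is averaged over feature subsamples,
max-normalized into a similarity matrix, clustered (average linkage on
1 − similarity), and trimmed at an edge threshold τ. Each trimmed network is
summarized by the first principal component of its feature submatrix and the
Pearson correlation ρ of that PC1 with the phenotype. The (s, τ) grid is
swept and a network is selected by diagnostics (|ρ| ≥ 0.20, both feature
kinds present, balanced protein:metabolite ratio, stability under adjacent
hyperparameters). Downstream evaluation covers blood-cell covariate
residualization sensitivity (Fisher's exact node overlap), per-feature
significance (|r| > 0.15 and BH-FDR p < 0.001), GOLD/PRISm spirometry
grading, emphysema severity bins, and subgroup PC1 ANOVA with Tukey's HSD.

## Worked example

`examples/03_network_discovery.py` generates a 300-subject cohort with 8
planted signal features per block, builds the consensus similarity at two
scaling constants, sweeps the edge-threshold grid and summarizes the
selected network:

```
  s  tau  abs_rho  n_nodes  n_edges
5.0 0.00 0.634406       35      595
5.0 0.05 0.665774       27      164
5.0 0.10 0.710544       21      109
...
selected scaling constant s=5.0, edge threshold tau=0.3
network: 6 proteins + 5 metabolites, 30 edges
PC1-phenotype correlation rho=0.759 (p=5.08e-57, n=298); PC1 explains 33% of network variance
top hubs: [('MET_014', 10), ('PROT_019', 10), ('MET_024', 9)]
planted features recovered: 9/16
```

Reading the numbers: each diagnostics row is one (s, τ) cell — trimming
raises |ρ| while shrinking the network; the selected 11-node network is a
protein–metabolite module whose single PC1 score per subject correlates at
0.76 with the phenotype, and its hubs are planted signal features. The other
examples cover preprocessing (`01`), the sparse CCA fit itself (`02`) and the
full adjusted-vs-unadjusted sensitivity pipeline with subgroup ANOVA (`04`).

A thin CLI mirrors the library for shell use:

```bash
smccnet simulate --seed 7 --out data/
smccnet run-all --config run.yaml --seed 7 --out results/
```

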