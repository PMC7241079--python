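"""Generate a synthetic protein-metabolite cohort and preprocess it.

Builds a 300-subject dataset with 8 planted signal features per block, then
runs the metabolite chain (run-day median normalization, outlier-subject
removal, >20% missingness filter, feature-neighbor KNN imputation, log +
standardize) and the proteomic log + standardize step.
"""

import smccnet as sm

config = sm.SyntheticConfig(
    n_subjects=300,
    p_proteins=40,
    p_metabolites=40,
    n_signal_1=8,
    n_signal_2=8,
    noise_sd=0.8,
    missing_rate=0.08,
    seed=11,
)
dataset = sm.generate_multiomics(config)
print(f"proteins: {dataset.proteins.data.shape}, "
      f"metabolites: {dataset.metabolites.data.shape}")
print(f"metabolite missing fraction: "
      f"{dataset.metabolites.data.isna().mean().mean():.3f}")

metabolites, report = sm.preprocess_metabolites(dataset.metabolites)
proteins, _ = sm.preprocess_proteins(dataset.proteins)
print(f"outlier subjects removed: {len(report['removed_subjects'])}")
print(f"features dropped for missingness: {len(report['dropped_features'])}")
print(f"cells imputed: {report['imputed_cells']}")
print(f"standardized metabolite block: {metabolites.data.shape}; "
      f"column means ~ {metabolites.data.mean().abs().max():.1e}, "
      f"SDs ~ {metabolites.data.std(ddof=1).mean():.3f}")
# The counts show how many subjects/features each filter touched; the final
# block has mean-0 / SD-1 columns ready for the canonical-correlation stage.
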