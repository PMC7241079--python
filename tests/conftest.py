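"""Shared fixtures: small generated datasets and one full recovery run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import smccnet as sm

# The planted-signal study conditions used for the pipeline-level recovery
# checks: unit latent loadings on 10 features per block, unit phenotype
# loading, noise SD 0.5, 500 subjects.
RECOVERY_CONFIG = dict(
    n_subjects=500,
    p_proteins=60,
    p_metabolites=60,
    n_signal_1=10,
    n_signal_2=10,
    latent_loading_range=(1.0, 1.0),
    phenotype_loading=1.0,
    noise_sd=0.5,
    missing_rate=0.05,
    seed=42,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Light dataset for unit-level checks."""
    config = sm.SyntheticConfig(
        n_subjects=200, p_proteins=30, p_metabolites=30, seed=7
    )
    return config, sm.generate_multiomics(config)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full pipeline run under the planted-signal recovery conditions.

    Session-scoped: the run feeds both the pipeline unit tests and the
    end-to-end recovery assertions.
    """
    outdir = tmp_path_factory.mktemp("recovery_run")
    config = sm.RunConfig(
        seed=42,
        output_dir=str(outdir),
        synthetic=sm.SyntheticConfig(**RECOVERY_CONFIG),
        adjustment="both",
        scaling_grid=(5.0, 10.0),
        subsample=sm.SubsampleScheme(n_subsamples=50, seed=0),
    )
    manifest = sm.run_pipeline(config)
    dataset = sm.generate_multiomics(config.synthetic)
    return config, dataset, manifest


@pytest.fixture(scope="session")
def standardized_recovery():
    """Preprocessed standardized matrices under the recovery conditions."""
    config = sm.SyntheticConfig(**RECOVERY_CONFIG)
    ds = sm.generate_multiomics(config)
    prot, _ = sm.preprocess_proteins(ds.proteins)
    met, _ = sm.preprocess_metabolites(ds.metabolites)
    shared = prot.subject_ids.intersection(met.subject_ids)
    X1 = prot.data.loc[shared]
    X2 = met.data.loc[shared]
    y = sm.standardize_phenotype(ds.phenotype.loc[shared])
    return ds, X1, X2, y


@pytest.fixture()
def standardized_small(small_dataset):
    """Preprocessed, subject-aligned standardized matrices + phenotype."""
    config, ds = small_dataset
    prot, _ = sm.preprocess_proteins(ds.proteins)
    met, _ = sm.preprocess_metabolites(ds.metabolites)
    shared = prot.subject_ids.intersection(met.subject_ids)
    X1 = prot.data.loc[shared]
    X2 = met.data.loc[shared]
    y = sm.standardize_phenotype(ds.phenotype.loc[shared])
    return ds, X1, X2, y
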