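"""Synthetic multi-omics data with planted phenotype-associated signal.

Generates a proteomic block and a metabolomic block tied to a single latent
factor, emulating the statistical structure the downstream analysis assumes:
log-normal raw intensities, linear blood-cell covariate effects on the log
scale, per-day multiplicative run-day batch factors on the metabolite block,
missing-completely-at-random metabolite values, and a continuous phenotype
driven by the same latent factor. Ground-truth signal indices are carried
along so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .containers import ConfigurationError, OmicsBlock


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream derived from a single pipeline seed.

    Stage names are hashed (CRC32) into the seed sequence so each stage
    draws from an independent, reproducible stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults mirror a desk-scale version of a blood multi-omics cohort:
    a few hundred subjects, tens of features per block with a planted
    subset loading on one latent factor, six blood-cell covariates with
    linear effects on log-intensities, multiplicative run-day batches and
    a modest MCAR missingness rate on the metabolite block.
    """

    n_subjects: int = 500
    p_proteins: int = 60
    p_metabolites: int = 60
    n_signal_1: int = 10
    n_signal_2: int = 10
    latent_loading_range: Tuple[float, float] = (0.5, 1.0)
    phenotype_loading: float = 1.0
    noise_sd: float = 1.0
    n_covariates: int = 6
    covariate_effect_sd: float = 0.3
    n_run_days: int = 5
    run_day_scale_sd: float = 0.2
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_1 > self.p_proteins:
            raise ConfigurationError(
                f"n_signal_1 ({self.n_signal_1}) exceeds p_proteins ({self.p_proteins})"
            )
        if self.n_signal_2 > self.p_metabolites:
            raise ConfigurationError(
                f"n_signal_2 ({self.n_signal_2}) exceeds p_metabolites "
                f"({self.p_metabolites})"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be at least 3")
        if self.n_run_days < 1:
            raise ConfigurationError("n_run_days must be at least 1")
        lo, hi = self.latent_loading_range
        if lo > hi:
            raise ConfigurationError("latent_loading_range must be (low, high)")


@dataclass
class SyntheticDataset:
    """Generated blocks plus ground truth."""

    proteins: OmicsBlock
    metabolites: OmicsBlock
    phenotype: pd.Series
    fev1_fvc: pd.Series
    covariates: pd.DataFrame
    signal_idx_1: np.ndarray
    signal_idx_2: np.ndarray
    latent: np.ndarray
    loadings_1: np.ndarray = field(default=None)
    loadings_2: np.ndarray = field(default=None)

    @property
    def signal_ids_1(self) -> list:
        return [self.proteins.feature_ids[i] for i in self.signal_idx_1]

    @property
    def signal_ids_2(self) -> list:
        return [self.metabolites.feature_ids[i] for i in self.signal_idx_2]


def _block_log_intensities(
    rng: np.random.Generator,
    n: int,
    p: int,
    signal_idx: np.ndarray,
    z: np.ndarray,
    covariates: np.ndarray,
    config: SyntheticConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Log-scale intensities: baseline + latent loading (signal only) +
    covariate effects + iid Gaussian noise. Returns (log_matrix, loadings)."""
    lo, hi = config.latent_loading_range
    loadings = np.zeros(p)
    mag = rng.uniform(lo, hi, size=signal_idx.size)
    sign = rng.choice([-1.0, 1.0], size=signal_idx.size)
    loadings[signal_idx] = mag * sign

    baseline = rng.normal(np.log(1000.0), 0.5, size=p)
    cov_eff = rng.normal(0.0, config.covariate_effect_sd, size=(config.n_covariates, p))
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))
    logm = baseline[None, :] + np.outer(z, loadings) + covariates @ cov_eff + noise
    return logm, loadings


def generate_multiomics(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model.

    The latent factor z is standard normal per subject; planted signal
    features load on z on the log scale, all features receive covariate
    effects and noise, intensities are exponentiated, the metabolite block
    is scaled by a per-run-day factor and masked MCAR, and the phenotype is
    gamma*z plus covariate contributions and noise. Identical configs
    (including seed) give bitwise-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    z = rng.standard_normal(n)
    covariates = rng.standard_normal((n, config.n_covariates))

    signal_1 = np.sort(rng.choice(config.p_proteins, config.n_signal_1, replace=False))
    signal_2 = np.sort(
        rng.choice(config.p_metabolites, config.n_signal_2, replace=False)
    )

    log_prot, load_1 = _block_log_intensities(
        rng, n, config.p_proteins, signal_1, z, covariates, config
    )
    log_met, load_2 = _block_log_intensities(
        rng, n, config.p_metabolites, signal_2, z, covariates, config
    )

    subjects = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    prot_ids = [f"PROT_{j:03d}" for j in range(config.p_proteins)]
    met_ids = [f"MET_{j:03d}" for j in range(config.p_metabolites)]

    proteins = pd.DataFrame(np.exp(log_prot), index=subjects, columns=prot_ids)

    # per-day multiplicative batch factor on the raw scale; run-day median
    # normalization is then exactly the right correction
    day_labels = rng.integers(0, config.n_run_days, size=n)
    day_scale = np.exp(rng.normal(0.0, config.run_day_scale_sd, size=config.n_run_days))
    met_raw = np.exp(log_met) * day_scale[day_labels][:, None]

    mask = rng.random((n, config.p_metabolites)) < config.missing_rate
    met_raw = np.where(mask, np.nan, met_raw)
    metabolites = pd.DataFrame(met_raw, index=subjects, columns=met_ids)
    run_day = pd.Series(
        [f"day{d}" for d in day_labels], index=subjects, name="run_day"
    )

    # phenotype: latent effect + covariate contribution + noise
    pheno_cov = rng.normal(0.0, config.covariate_effect_sd, size=config.n_covariates)
    phenotype = (
        config.phenotype_loading * z
        + covariates @ pheno_cov
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    # FEV1/FVC in (0, 1.2): squashed around 0.7; obstruction lowers the
    # ratio together with lung function, so it increases with z
    ratio_raw = 0.7 + 0.12 * z + rng.normal(0.0, 0.05, size=n)
    fev1_fvc = 1.2 / (1.0 + np.exp(-(ratio_raw - 0.6) / 0.25))

    return SyntheticDataset(
        proteins=OmicsBlock(proteins, "protein"),
        metabolites=OmicsBlock(metabolites, "metabolite", run_day),
        phenotype=pd.Series(phenotype, index=subjects, name="phenotype"),
        fev1_fvc=pd.Series(fev1_fvc, index=subjects, name="fev1_fvc"),
        covariates=pd.DataFrame(
            covariates,
            index=subjects,
            columns=[f"cov_{k}" for k in range(config.n_covariates)],
        ),
        signal_idx_1=signal_1,
        signal_idx_2=signal_2,
        latent=z,
        loadings_1=load_1,
        loadings_2=load_2,
    )


def generate_clinical_labels(
    dataset: SyntheticDataset,
    config: SyntheticConfig,
    indicator_effect: float = 1.0,
) -> pd.DataFrame:
    """Per-subject clinical table for grading and subgroup analyses.

    FEV1% is a monotone (rank-preserving) map of the continuous phenotype
    onto a 20-120 range; percent emphysema is a softplus of the latent
    factor (always >= 0); heart-disease and exacerbation indicators are
    Bernoulli with log-odds ``indicator_effect * z``, so setting
    ``indicator_effect=0`` severs them from the latent factor.
    """
    rng = substream(config.seed, "clinical_labels")
    z = dataset.latent
    pheno = dataset.phenotype.to_numpy()

    lo, hi = pheno.min(), pheno.max()
    span = hi - lo if hi > lo else 1.0
    fev1_pct = 20.0 + 100.0 * (pheno - lo) / span

    emph_raw = -0.5 + 1.2 * (-z) + rng.normal(0.0, 0.8, size=z.size)
    pct_emphysema = 8.0 * np.log1p(np.exp(emph_raw))  # softplus, >= 0

    def _indicator(name: str) -> np.ndarray:
        r = substream(config.seed, name)
        logit = -1.0 + indicator_effect * (-z)
        return (r.random(z.size) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    return pd.DataFrame(
        {
            "fev1_pct": fev1_pct,
            "fev1_fvc": dataset.fev1_fvc.to_numpy(),
            "pct_emphysema": pct_emphysema,
            "heart_disease": _indicator("heart_disease"),
            "exacerbations": _indicator("exacerbations"),
        },
        index=dataset.phenotype.index,
    )


def write_dataset(dataset: SyntheticDataset, config: SyntheticConfig, outdir) -> dict:
    """Persist blocks, clinical table and ground truth as delimited text/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.proteins.data.to_csv(outdir / "proteins.csv")
    met = dataset.metabolites.data.copy()
    met.to_csv(outdir / "metabolites.csv")
    clinical = generate_clinical_labels(dataset, config)
    clinical.insert(0, "phenotype", dataset.phenotype)
    clinical["run_day"] = dataset.metabolites.run_day
    clinical.to_csv(outdir / "clinical.csv")
    dataset.covariates.to_csv(outdir / "covariates.csv")
    truth = {
        "seed": config.seed,
        "signal_proteins": dataset.signal_ids_1,
        "signal_metabolites": dataset.signal_ids_2,
        "loadings_proteins": dataset.loadings_1.tolist(),
        "loadings_metabolites": dataset.loadings_2.tolist(),
        "phenotype_loading": config.phenotype_loading,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "proteins": str(outdir / "proteins.csv"),
        "metabolites": str(outdir / "metabolites.csv"),
        "clinical": str(outdir / "clinical.csv"),
        "covariates": str(outdir / "covariates.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
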