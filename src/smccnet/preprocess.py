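"""Data processing for the two omics blocks and the phenotype.

The metabolite chain is fixed in this order: run-day median normalization,
aggregate-z outlier subject removal, missingness filtering, KNN imputation
across features, then natural log + per-feature standardization. Proteomic
inputs are assumed vendor-normalized upstream and only receive the final
log + standardization. Covariate residualization (blood-cell adjustment) is
optional and applied after standardization, with residuals re-standardized
so the adjusted and unadjusted branches feed identically scaled matrices to
the canonical-correlation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, DataError, OmicsBlock


@dataclass
class PreprocessConfig:
    outlier_z_cutoff: float = 3.5
    max_missing_fraction: float = 0.20
    knn_k: int = 10
    standardize_phenotype: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.max_missing_fraction < 1.0):
            raise ConfigurationError(
                f"max_missing_fraction must be in (0, 1), got "
                f"{self.max_missing_fraction}"
            )
        if self.knn_k < 1:
            raise ConfigurationError(f"knn_k must be >= 1, got {self.knn_k}")


def runday_normalize(block: OmicsBlock) -> OmicsBlock:
    """Divide each observed value by its feature's run-day median and multiply
    by the feature's overall median (medians over observed values only).

    With a single run day the operation is the identity; missing entries stay
    missing and never enter a median.
    """
    if block.run_day is None:
        raise DataError("run-day normalization requires run_day labels")
    data = block.data
    if (data <= 0).any().any():
        raise DataError("run-day normalization requires positive intensities")

    out = data.copy()
    overall = data.median(axis=0, skipna=True)
    for day, idx in data.groupby(block.run_day).groups.items():
        sub = data.loc[idx]
        day_med = sub.median(axis=0, skipna=True)
        bad = day_med.index[day_med.isna() | (day_med == 0)]
        if len(bad) > 0:
            raise DataError(
                f"feature(s) {bad.tolist()} have no usable values on run day "
                f"{day!r} (all missing or zero median)"
            )
        out.loc[idx] = sub / day_med * overall
    return block.with_data(out)


def remove_outlier_subjects(
    block: OmicsBlock, config: PreprocessConfig | None = None
) -> tuple[OmicsBlock, list]:
    """Drop subjects whose aggregate feature z-score median is extreme.

    Features are z-scored across subjects (observed values, ddof=1;
    zero-variance features contribute z=0); each subject's aggregate is the
    median of its feature z-scores; subjects whose aggregate lies more than
    ``outlier_z_cutoff`` SDs from the cohort mean of aggregates are removed.
    """
    config = config or PreprocessConfig()
    if block.n_subjects < 3:
        raise DataError("outlier removal requires at least 3 subjects")
    data = block.data
    mu = data.mean(axis=0, skipna=True)
    sd = data.std(axis=0, ddof=1, skipna=True)
    z = (data - mu).div(sd.mask(sd == 0.0), axis=1)
    zero_var = sd.index[sd == 0.0]
    z[zero_var] = 0.0  # zero-variance feature -> z = 0
    z = z.mask(data.isna())  # keep genuinely missing cells out of medians
    agg = z.median(axis=1, skipna=True)

    center = agg.mean()
    spread = agg.std(ddof=1)
    if spread == 0 or np.isnan(spread):
        flagged = pd.Series(False, index=agg.index)
    else:
        flagged = (agg - center).abs() > config.outlier_z_cutoff * spread
    if flagged.all():
        raise DataError("all subjects flagged as outliers; data degenerate")
    removed = agg.index[flagged].tolist()
    kept = block.with_data(data.loc[~flagged])
    return kept, removed


def filter_missingness(
    block: OmicsBlock, config: PreprocessConfig | None = None
) -> tuple[OmicsBlock, list]:
    """Drop features whose missing fraction strictly exceeds the cutoff.

    The inequality is strict: a feature missing in exactly 20% of subjects
    survives the default 0.20 cutoff. Survivor order is preserved.
    """
    config = config or PreprocessConfig()
    frac = block.data.isna().mean(axis=0)
    drop = frac.index[frac > config.max_missing_fraction]
    if len(drop) == block.n_features:
        raise DataError("all features exceed the missingness cutoff")
    kept = block.with_data(block.data.drop(columns=drop))
    return kept, drop.tolist()


def knn_impute(block: OmicsBlock, config: PreprocessConfig | None = None) -> OmicsBlock:
    """Impute each missing cell from the k nearest *features*.

    The distance between two features is the Euclidean distance between
    their columns over the subjects where both are observed; candidates for
    cell (i, j) are features observed at subject i with at least one subject
    co-observed with feature j. The imputed value is the unweighted mean of
    the k nearest candidates' values at subject i (all of them if fewer than
    k qualify; the feature's observed mean if none do). Ties in distance
    break by column index.
    """
    config = config or PreprocessConfig()
    X = block.values
    n, p = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        bad = [block.feature_ids[j] for j in np.where(~obs.any(axis=0))[0]]
        raise DataError(f"feature(s) with zero observed values: {bad}")
    if obs.all():
        return block.copy()

    out = X.copy()
    col_means = np.nanmean(X, axis=0)
    missing_cols = np.where(~obs.all(axis=0))[0]
    for j in missing_cols:
        # distances from feature j to all others over co-observed subjects
        dists = np.full(p, np.inf)
        for l in range(p):
            if l == j:
                continue
            shared = obs[:, j] & obs[:, l]
            if not shared.any():
                continue
            diff = X[shared, j] - X[shared, l]
            dists[l] = np.sqrt(np.sum(diff * diff))
        for i in np.where(~obs[:, j])[0]:
            candidates = np.where(obs[i, :] & np.isfinite(dists))[0]
            if candidates.size == 0:
                out[i, j] = col_means[j]
                continue
            order = candidates[np.lexsort((candidates, dists[candidates]))]
            chosen = order[: config.knn_k]
            out[i, j] = X[i, chosen].mean()
    return block.with_data(
        pd.DataFrame(out, index=block.subject_ids, columns=block.feature_ids)
    )


def log_standardize(block: OmicsBlock) -> OmicsBlock:
    """Natural log, then center and scale each feature to unit SD (ddof=1)."""
    data = block.data
    if data.isna().any().any():
        raise DataError("log_standardize requires a complete matrix (impute first)")
    nonpos = data <= 0
    if nonpos.any().any():
        j = nonpos.any(axis=0).idxmax()
        i = nonpos[j].idxmax()
        raise DataError(f"nonpositive value at subject {i!r}, feature {j!r}")
    logged = np.log(data)
    sd = logged.std(axis=0, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero) > 0:
        raise DataError(f"zero-variance feature(s) after log: {zero.tolist()}")
    standardized = (logged - logged.mean(axis=0)) / sd
    return block.with_data(standardized)


def standardize_phenotype(values: pd.Series) -> pd.Series:
    """Center/scale non-missing entries (ddof=1); missing entries stay missing."""
    obs = values.dropna()
    if obs.size < 2 or obs.std(ddof=1) == 0:
        raise DataError("phenotype needs >= 2 non-missing values with variance")
    return (values - obs.mean()) / obs.std(ddof=1)


def residualize_covariates(
    block: OmicsBlock, covariates: pd.DataFrame, restandardize: bool = True
) -> OmicsBlock:
    """Replace each feature by its OLS residual on (intercept + covariates).

    Residual columns are re-standardized by default so adjusted and
    unadjusted branches are on the same scale. A feature fully explained by
    the covariates leaves a zero-variance residual, which is an error.
    """
    if covariates.isna().any().any():
        raise DataError("covariate table contains missing values")
    cov = covariates.reindex(block.subject_ids)
    if cov.isna().any().any():
        missing = cov.index[cov.isna().any(axis=1)].tolist()
        raise DataError(f"covariates missing for subjects: {missing}")
    C = np.column_stack([np.ones(block.n_subjects), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify collinear columns via pivoted correlations with earlier ones
        names = ["intercept"] + list(cov.columns)
        collinear = []
        for k in range(1, C.shape[1]):
            if np.linalg.matrix_rank(C[:, : k + 1]) == np.linalg.matrix_rank(C[:, :k]):
                collinear.append(names[k])
        raise DataError(f"rank-deficient covariate design; collinear: {collinear}")

    Y = block.values
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta
    if restandardize:
        sd = resid.std(axis=0, ddof=1)
        zero = np.where(sd < 1e-12)[0]
        if zero.size > 0:
            ids = [block.feature_ids[j] for j in zero]
            raise DataError(
                f"zero-variance residual (feature fully explained by covariates): {ids}"
            )
        resid = (resid - resid.mean(axis=0)) / sd
    return block.with_data(
        pd.DataFrame(resid, index=block.subject_ids, columns=block.feature_ids)
    )


def preprocess_metabolites(
    block: OmicsBlock, config: PreprocessConfig | None = None
) -> tuple[OmicsBlock, dict]:
    """Full metabolite chain: normalize -> outliers -> filter -> impute ->
    log+standardize. Returns the processed block and a report dict."""
    config = config or PreprocessConfig()
    normalized = runday_normalize(block) if block.run_day is not None else block
    no_outliers, removed = remove_outlier_subjects(normalized, config)
    filtered, dropped = filter_missingness(no_outliers, config)
    n_imputed = int(filtered.data.isna().sum().sum())
    imputed = knn_impute(filtered, config)
    final = log_standardize(imputed)
    report = {
        "removed_subjects": removed,
        "dropped_features": dropped,
        "imputed_cells": n_imputed,
        "n_subjects": final.n_subjects,
        "n_features": final.n_features,
    }
    return final, report


def preprocess_proteins(block: OmicsBlock) -> tuple[OmicsBlock, dict]:
    """Proteomic chain: vendor normalization assumed done; log+standardize."""
    final = log_standardize(block)
    return final, {"n_subjects": final.n_subjects, "n_features": final.n_features}
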