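"""Config-driven end-to-end runs.

One call executes the whole analysis for a dataset (synthetic or loaded
from delimited files): preprocess both blocks, select sparsity penalties by
cross-validation, sweep scaling constants and edge thresholds, trim and
summarize the selected network, export files, and — when both covariate
branches run — compare adjusted vs unadjusted node sets with Fisher's exact
test and run the subgroup PC1 analyses. Every stage draws randomness from a
named substream of the single run seed, and a JSON manifest records
configs, seeds and per-stage shapes so each reported number is recomputable
from the persisted intermediates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import ConfigurationError, OmicsBlock
from .evaluate import (
    classify_emphysema_severity,
    classify_gold_series,
    compare_networks,
    feature_significance,
    subgroup_pc1_analysis,
)
from .io import read_omics_table, write_network, write_omics_table
from .network import (
    SweepResult,
    hub_report,
    hyperparameter_sweep,
    node_correlations,
    summarize_network,
    trim_edges,
)
from .preprocess import (
    PreprocessConfig,
    preprocess_metabolites,
    preprocess_proteins,
    residualize_covariates,
    standardize_phenotype,
)
from .simulate import (
    SyntheticConfig,
    generate_clinical_labels,
    generate_multiomics,
    substream,
)
from .smcca import (
    PenaltyPair,
    ScalingScheme,
    SubsampleScheme,
    correlation_range_report,
    cv_select_penalties,
)

logger = logging.getLogger("smccnet")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; see docs/methods.md for units."""

    seed: int = 0
    output_dir: str = "smccnet_run"
    # input: either a synthetic config or paths to delimited files
    synthetic: Optional[SyntheticConfig] = None
    protein_path: Optional[str] = None
    metabolite_path: Optional[str] = None
    clinical_path: Optional[str] = None
    covariate_path: Optional[str] = None
    phenotype_column: str = "phenotype"
    run_day_column: str = "run_day"
    covariate_columns: Optional[Sequence[str]] = None
    adjustment: str = "adjusted"  # adjusted | unadjusted | both
    # analysis grids
    scaling_grid: Sequence[float] = (5.0, 10.0, 15.0, 20.0)
    penalty_grid: Sequence[float] = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55)
    tau_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 0.7001, 0.05), 2))
    cv_scaling: float = 10.0
    cv_repeats: int = 10
    subsample: SubsampleScheme = field(default_factory=SubsampleScheme)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cut_height: float = 0.999
    min_abs_rho: float = 0.20
    ratio_band: Sequence[float] = (0.25, 4.0)

    def __post_init__(self) -> None:
        if self.adjustment not in ("adjusted", "unadjusted", "both"):
            raise ConfigurationError(
                f"adjustment must be adjusted|unadjusted|both, got {self.adjustment}"
            )
        for name in ("scaling_grid", "penalty_grid", "tau_grid"):
            if len(list(getattr(self, name))) == 0:
                raise ConfigurationError(f"{name} must be nonempty")
        if self.synthetic is None and not (
            self.protein_path and self.metabolite_path and self.clinical_path
        ):
            raise ConfigurationError(
                "either a synthetic config or protein/metabolite/clinical paths "
                "are required"
            )


def load_config(path) -> RunConfig:
    """RunConfig from a YAML or JSON file (keys mirror the dataclass)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "subsample" in raw and isinstance(raw["subsample"], dict):
        raw["subsample"] = SubsampleScheme(**raw["subsample"])
    if "preprocess" in raw and isinstance(raw["preprocess"], dict):
        raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
    return RunConfig(**raw)


def _load_inputs(config: RunConfig):
    """Returns (proteins, metabolites, clinical, covariates) aligned later."""
    if config.synthetic is not None:
        dataset = generate_multiomics(config.synthetic)
        clinical = generate_clinical_labels(dataset, config.synthetic)
        clinical.insert(0, "phenotype", dataset.phenotype)
        return dataset.proteins, dataset.metabolites, clinical, dataset.covariates
    clinical = pd.read_csv(config.clinical_path, index_col=0)
    run_day = (
        clinical[config.run_day_column]
        if config.run_day_column in clinical.columns
        else None
    )
    proteins = read_omics_table(config.protein_path, "protein")
    metabolites = read_omics_table(config.metabolite_path, "metabolite", run_day)
    covariates = None
    if config.covariate_path:
        covariates = pd.read_csv(config.covariate_path, index_col=0)
    elif config.covariate_columns:
        covariates = clinical[list(config.covariate_columns)]
    return proteins, metabolites, clinical, covariates


def _analyze_branch(
    X1: pd.DataFrame,
    X2: pd.DataFrame,
    y: pd.Series,
    config: RunConfig,
    branch: str,
    outdir: Path,
) -> dict:
    """CV penalty selection, (s, tau) sweep, selected-network outputs."""
    y_arr = y.to_numpy(dtype=float)
    keep = ~np.isnan(y_arr)
    corr_report = correlation_range_report(
        X1.to_numpy(dtype=float), X2.to_numpy(dtype=float), y_arr
    )

    cv_seed = substream(config.seed, f"cv-{branch}").integers(2**31)
    cv = cv_select_penalties(
        X1.to_numpy(dtype=float)[keep],
        X2.to_numpy(dtype=float)[keep],
        ((y_arr[keep] - y_arr[keep].mean()) / y_arr[keep].std(ddof=1)),
        ScalingScheme(config.cv_scaling),
        grid_values=config.penalty_grid,
        seed=int(cv_seed),
        n_repeats=config.cv_repeats,
    )
    logger.info(
        "[%s] CV chose penalties l1=%.2f l2=%.2f", branch, cv.chosen.l1, cv.chosen.l2
    )

    sub_seed = substream(config.seed, f"subsample-{branch}").integers(2**31)
    subsampling = SubsampleScheme(
        config.subsample.fraction_1,
        config.subsample.fraction_2,
        config.subsample.n_subsamples,
        int(sub_seed),
    )
    sweep = hyperparameter_sweep(
        X1,
        X2,
        y,
        config.scaling_grid,
        config.tau_grid,
        cv.chosen,
        subsampling,
        cut_height=config.cut_height,
        min_abs_rho=config.min_abs_rho,
        ratio_band=tuple(config.ratio_band),
    )
    sweep.table.to_csv(outdir / f"diagnostics_{branch}.csv", index=False)

    result = {
        "correlation_ranges": corr_report,
        "penalties": {"l1": cv.chosen.l1, "l2": cv.chosen.l2},
        "selected": None,
        "network_nodes": [],
    }
    if sweep.selected is None:
        return result

    s_sel, tau_sel = sweep.selected
    sim = sweep.similarity_by_s[s_sel]
    module = sweep.module_by_s[s_sel]
    net = trim_edges(module, sim, tau_sel)
    combined = pd.concat([X1, X2], axis=1)
    summary = summarize_network(net, combined, y)
    nodes = node_correlations(net, combined, y)
    hubs = hub_report(net)
    complement = sweep.complement_by_s[s_sel]
    comp_summary = None
    if len(complement) >= 2:
        comp_ids = [sim.feature_ids[i] for i in complement]
        comp_summary = summarize_network(comp_ids, combined, y)

    files = write_network(
        net, outdir, basename=f"network_{branch}",
        node_r=dict(zip(nodes["feature_id"], nodes["r"])),
    )
    files = {k: Path(v).name for k, v in files.items()}  # manifest stays
    # reproducible across output directories
    nodes.to_csv(outdir / f"node_correlations_{branch}.csv", index=False)
    pd.Series(summary.pc1_scores, index=combined.index, name="pc1").to_csv(
        outdir / f"pc1_{branch}.csv"
    )

    sig = feature_significance(
        nodes["r"].to_numpy(), summary.n_used, nodes["feature_id"].tolist()
    )
    sig.to_csv(outdir / f"node_significance_{branch}.csv", index=False)

    result.update(
        {
            "selected": {"s": s_sel, "tau": tau_sel},
            "rho": summary.rho,
            "p_value": summary.p_value,
            "n_used": summary.n_used,
            "variance_explained": summary.variance_explained,
            "complement_rho": None if comp_summary is None else comp_summary.rho,
            "network_nodes": net.node_ids,
            "n_proteins": net.n_proteins,
            "n_metabolites": net.n_metabolites,
            "n_edges": len(net.edges),
            "hubs": hubs["ranked_nodes"][:5],
            "strongest_edge": hubs["strongest_edge"],
            "files": files,
            "pc1_scores": pd.Series(summary.pc1_scores, index=combined.index),
        }
    )
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for each adjustment branch; returns the manifest."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    proteins, metabolites, clinical, covariates = _load_inputs(config)
    if covariates is not None and covariates.shape[1] == 0:
        covariates = None

    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "branches": {},
    }

    # --- preprocessing ------------------------------------------------------
    prot_std, prot_report = preprocess_proteins(proteins)
    met_std, met_report = preprocess_metabolites(metabolites, config.preprocess)
    manifest["stages"]["preprocess"] = {
        "proteins": prot_report,
        "metabolites": met_report,
    }

    # subjects present in both assays only (others dropped, with a count)
    shared = prot_std.subject_ids.intersection(met_std.subject_ids)
    n_dropped = (
        len(prot_std.subject_ids) + len(met_std.subject_ids) - 2 * len(shared)
    )
    manifest["stages"]["align"] = {
        "shared_subjects": len(shared),
        "dropped_subjects": n_dropped,
    }
    prot_std = prot_std.subset_subjects(shared)
    met_std = met_std.subset_subjects(shared)
    clinical = clinical.loc[shared]
    if covariates is not None:
        covariates = covariates.loc[shared]

    phenotype = clinical[config.phenotype_column]
    if config.preprocess.standardize_phenotype:
        phenotype = standardize_phenotype(phenotype)

    branches = (
        ["adjusted", "unadjusted"] if config.adjustment == "both"
        else [config.adjustment]
    )
    universe = set(prot_std.feature_ids) | set(met_std.feature_ids)
    pc1_by_branch = {}
    for branch in branches:
        if branch == "adjusted":
            if covariates is None:
                raise ConfigurationError(
                    "adjusted branch requested but no covariates supplied"
                )
            X1 = residualize_covariates(prot_std, covariates).data
            X2 = residualize_covariates(met_std, covariates).data
        else:
            X1, X2 = prot_std.data, met_std.data
        res = _analyze_branch(X1, X2, phenotype, config, branch, outdir)
        pc1 = res.pop("pc1_scores", None)
        if pc1 is not None:
            pc1_by_branch[branch] = pc1
        manifest["branches"][branch] = res

    # --- sensitivity comparison --------------------------------------------
    if len(branches) == 2:
        adj = set(manifest["branches"]["adjusted"]["network_nodes"])
        unadj = set(manifest["branches"]["unadjusted"]["network_nodes"])
        if adj and unadj:
            overlap = compare_networks(adj, unadj, universe)
            manifest["overlap"] = {
                "in_both": overlap.in_both,
                "adjusted_only": overlap.adjusted_only,
                "unadjusted_only": overlap.unadjusted_only,
                "neither": overlap.neither,
                "odds_ratio": overlap.odds_ratio,
                "p_value": overlap.p_value,
            }

    # --- subgroup analyses --------------------------------------------------
    branch0 = branches[0]
    if branch0 in pc1_by_branch and {"fev1_pct", "fev1_fvc"} <= set(clinical.columns):
        pc1 = pc1_by_branch[branch0]
        gold = classify_gold_series(clinical["fev1_pct"], clinical["fev1_fvc"])
        copd_group = gold.map(
            {
                "GOLD0": "control",
                "GOLD1": "moderate",
                "GOLD2": "moderate",
                "GOLD3": "severe",
                "GOLD4": "severe",
            }
        )
        subgroups = {}
        usable = copd_group.notna() & pc1.notna()
        counts = copd_group[usable].value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            res = subgroup_pc1_analysis(pc1[usable], copd_group[usable])
            subgroups["copd_severity"] = {
                "sizes": res.group_sizes,
                "F": res.f_statistic,
                "p": res.p_value,
                "pairwise": res.pairwise.to_dict(orient="records"),
            }
        if "pct_emphysema" in clinical.columns:
            emph = clinical["pct_emphysema"].map(classify_emphysema_severity)
            counts = emph.value_counts()
            if len(counts) >= 2 and (counts >= 2).all():
                res = subgroup_pc1_analysis(pc1, emph)
                subgroups["emphysema_severity"] = {
                    "sizes": res.group_sizes,
                    "F": res.f_statistic,
                    "p": res.p_value,
                    "pairwise": res.pairwise.to_dict(orient="records"),
                }
        manifest["subgroups"] = subgroups
        # tidy long-format export for boxplots
        tidy = pd.DataFrame(
            {"pc1": pc1, "gold": gold, "copd_group": copd_group}
        )
        tidy.to_csv(outdir / "subgroup_pc1_long.csv")

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    # persist standardized inputs for recomputability
    write_omics_table(prot_std, outdir / "proteins_standardized.csv")
    write_omics_table(met_std, outdir / "metabolites_standardized.csv")
    return manifest
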