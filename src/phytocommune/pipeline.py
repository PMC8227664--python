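"""End-to-end orchestration: data -> QC -> annotation -> diversity ->
network -> path models, driven by one config mapping and one seed."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diversity as dv
from . import network as net
from . import pathmodel as pm
from . import qc as qcmod
from . import synthetic as syn
from .feature_table import FeatureTable

DEFAULT_CONFIG = {
    "seed": 0,
    "qc": {"rt_window": 5.0, "corr_min": 0.7, "adduct_tol": 0.005,
           "batch_alpha": 0.10},
    "annotation": {"k_max": 12},
    "network": {"power": 8, "min_module_size": 5, "merge_height": 0.25,
                "cut_height": None, "cut_quantile": None},
    "dispersion": {"alpha": 0.05, "permutations": 9999},
    "sem": {"alpha": 0.05, "prune": True},
}


class PipelineConfigError(ValueError):
    pass


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_inputs(paths: dict):
    table = FeatureTable.from_csv(paths["feature_table"])
    metadata = pd.read_csv(paths["metadata"], index_col="sample_id")
    counts = pd.read_csv(paths["herbivore_counts"])
    outcomes = pd.read_csv(paths["rearing_outcomes"])
    plots = pd.read_csv(paths["plot_covariates"], index_col="plot")
    community = syn.HerbivoreTable(counts=counts, outcomes=outcomes, plots=plots)
    return table, metadata, community, None


def cross_tabulate_modules_classes(module_labels: pd.Series,
                                   class_labels: pd.Series,
                                   include_grey: bool = False) -> pd.DataFrame:
    """Counts of features by (module color x phytochemical class)."""
    shared = module_labels.index.intersection(class_labels.index)
    ml = module_labels.loc[shared]
    cl = class_labels.loc[shared]
    if not include_grey:
        keep = ml != net.GREY
        ml, cl = ml[keep], cl[keep]
    return pd.crosstab(ml, cl)


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute every stage in order and return the run report dict.

    Honors the dispersion gate: PERMANOVA only runs for a comparison when
    group dispersions do not differ at the configured alpha.
    """
    t0 = time.time()
    cfg = _merge_config(config)
    seed = int(cfg.get("seed", 0))
    has_inputs = bool(cfg.get("inputs"))
    has_synth = "synthetic" in cfg and cfg["synthetic"] is not None
    if has_inputs == has_synth:
        raise PipelineConfigError(
            "config must contain exactly one of 'inputs' and 'synthetic'")

    report: dict = {"seed": seed, "parameters": cfg,
                    "software_version": __import__("phytocommune").__version__}

    # -- stage 0: data ------------------------------------------------------
    truth = None
    if has_synth:
        sblock = dict(cfg["synthetic"] or {})
        hier = syn.HierarchyConfig(seed=seed, **sblock.get("hierarchy", {}))
        dataset = syn.make_dataset(config=hier, seed=seed,
                                   n_modules=sblock.get("n_modules", 4))
        table, metadata, community = dataset.table, dataset.metadata, dataset.community
        truth = dataset.truth
    else:
        table, metadata, community, truth = load_inputs(cfg["inputs"])
    report["data"] = {"n_features_raw": table.n_features,
                      "n_samples": table.n_samples,
                      "synthetic": bool(has_synth)}

    # -- stage 1: QC --------------------------------------------------------
    q = cfg["qc"]
    table_qc, qc_log = qcmod.run_qc(table, metadata, rt_window=q["rt_window"],
                                    corr_min=q["corr_min"],
                                    mass_tol=q["adduct_tol"],
                                    alpha=q["batch_alpha"])
    report["qc"] = {"n_in": qc_log["n_input"], "n_groups": qc_log["n_groups"],
                    "n_after_representatives": qc_log["n_after_representatives"],
                    "n_adducts_removed": len(qc_log["adducts_removed"]),
                    "n_batch_removed": len(qc_log["batch_removed"]["feature_id"]),
                    "n_out": qc_log["n_output"], "params": qc_log["params"]}

    # -- stage 2: annotation + normalization --------------------------------
    k_max = cfg["annotation"]["k_max"]
    analytes = table_qc.features.index[~table_qc.features["is_standard"]]
    assignment, cluster_models, parity_log = ann.annotate_features(
        table_qc.features.loc[analytes], k_range=range(1, k_max + 1), seed=seed)
    standards = ann.default_standards()
    normalized = ann.normalize_abundances(table_qc, assignment, standards, metadata)
    normalized = normalized.subset(list(analytes))  # standards served their purpose
    class_counts = assignment.table["class_label"].value_counts().to_dict()
    report["annotation"] = {
        "parity": {k: v for k, v in parity_log.items() if k != "parity_ambiguous"},
        "n_parity_ambiguous": len(parity_log["parity_ambiguous"]),
        "clusters": {m.partition: {"k": m.k, "covariance": m.covariance_type}
                     for m in cluster_models},
        "class_counts": class_counts,
    }

    # -- stage 3: diversity / dispersion / composition ----------------------
    alpha = cfg["dispersion"]["alpha"]
    n_perm = cfg["dispersion"]["permutations"]
    div_report = {}
    for level in ("site", "subsite", "plot"):
        d = dv.diversity_by_level(normalized.abundance, metadata, level)
        div_report[level] = {
            "mean_effective": {k: float(v) for k, v in d.groups["mean"].items()},
            "F": d.anova_F, "df": d.anova_df, "p": d.anova_p, "skipped": d.skipped}
    report["chemical_diversity"] = div_report

    chem_dist = dv.manhattan_distances(normalized.abundance)
    disp_report = {}
    for level in ("site", "subsite"):
        groups = metadata.loc[normalized.abundance.index, level]
        res = dv.dispersion(chem_dist, groups)
        entry = {"F": res.F, "df": res.df, "p": res.p,
                 "gate_passed": dv.dispersion_gate(res.p, alpha)}
        if entry["gate_passed"]:
            per = dv.permanova(chem_dist, groups, n_perm=n_perm, seed=seed + 101)
            entry["permanova"] = {"pseudo_F": per.pseudo_F, "R2": per.R2,
                                  "p": per.p, "n_permutations": per.n_permutations,
                                  "complete_enumeration": per.complete_enumeration}
        else:
            entry["permanova"] = None  # gate blocked composition testing
        disp_report[level] = entry
    report["chemical_dispersion"] = disp_report

    # herbivores: plot-level counts aggregated over collections
    morph_cols = community.morphotype_columns()
    herb_by_plot = community.counts.groupby("plot")[morph_cols].sum()
    herb_dist = dv.jaccard_distances(herb_by_plot)
    herb_report = {}
    plot_meta = community.plots
    for level in ("site", "subsite"):
        groups = plot_meta.loc[herb_by_plot.index, level]
        res = dv.dispersion(herb_dist, groups)
        entry = {"F": res.F, "df": res.df, "p": res.p,
                 "gate_passed": dv.dispersion_gate(res.p, alpha)}
        if entry["gate_passed"]:
            per = dv.permanova(herb_dist, groups, n_perm=n_perm, seed=seed + 103)
            entry["permanova"] = {"pseudo_F": per.pseudo_F, "R2": per.R2,
                                  "p": per.p, "n_permutations": per.n_permutations,
                                  "complete_enumeration": per.complete_enumeration}
        else:
            entry["permanova"] = None
        herb_report[level] = entry
    report["herbivore_dispersion"] = herb_report

    # -- stage 4: covariance network ----------------------------------------
    ncfg = cfg["network"]
    Xlog = np.log(normalized.abundance)
    Xc = Xlog - Xlog.mean(axis=0)
    tom = net.tom_from_correlation(Xc, power=ncfg["power"])
    labels = net.detect_modules(tom, min_size=ncfg["min_module_size"],
                                cut_height=ncfg.get("cut_height"),
                                cut_quantile=ncfg.get("cut_quantile"))
    modules = net.module_eigenvalues(Xc, labels)
    modules = net.merge_close_modules(Xc, modules,
                                      merge_height=ncfg["merge_height"])
    mod_disp = net.module_dispersion(normalized.abundance, modules, metadata)
    confusion = cross_tabulate_modules_classes(modules.labels,
                                               assignment.table["class_label"])
    report["network"] = {
        "module_sizes": {k: int(v) for k, v in modules.sizes().items()},
        "explained_variance": {k: float(v) for k, v in modules.explained.items()},
        "merge_history": modules.merge_history,
        "module_dispersion_ranking": mod_disp.to_dict(orient="records"),
        "module_class_confusion": {str(k): {str(c): int(n) for c, n in row.items()}
                                   for k, row in confusion.iterrows()},
    }

    # -- stage 5: path models ------------------------------------------------
    scfg = cfg["sem"]
    sem_df, model, tagged, protected = build_plot_frame_and_model(
        normalized, metadata, community, modules)
    report["sem"] = {"n_plots": len(sem_df), "variables": model.variables}
    try:
        full_fit = pm.fit_path_model(model, sem_df)
        sem_entry = {"full": _fit_summary(full_fit)}
        if scfg.get("prune", True):
            pruned_fit, prune_log = pm.prune_paths(
                model, sem_df, tagged=tagged, alpha=scfg["alpha"],
                protected=protected)
            sem_entry["pruned"] = _fit_summary(pruned_fit)
            sem_entry["pruning_log"] = [
                {"edge": list(e["edge"]), "p": e["p"], "action": e["action"]}
                for e in prune_log]
            sem_entry["aic_decreased"] = bool(
                pruned_fit.aic_deviance <= full_fit.aic_deviance + 1e-9)
        report["sem"].update(sem_entry)
    except (ValueError, np.linalg.LinAlgError) as exc:
        # tiny designs can yield singular plot-level covariance matrices
        report["sem"]["error"] = str(exc)

    report["wall_time_s"] = round(time.time() - t0, 3)
    if truth is not None:
        report["truth_reference"] = "truth.json"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        normalized.to_csv(out / "normalized_features.csv")
        assignment.table.to_csv(out / "class_assignment.csv")
        modules.labels.rename("module").to_csv(out / "feature_modules.csv")
        modules.eigenvalues.to_csv(out / "module_eigenvalues.csv")
        confusion.to_csv(out / "module_class_confusion.csv")
        chem_dist.to_frame().to_csv(out / "chemical_manhattan.csv")
        sem_df.to_csv(out / "sem_plot_frame.csv")
        if truth is not None:
            truth.to_json(out / "truth.json")
            metadata.to_csv(out / "metadata.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
    return report


def build_plot_frame_and_model(normalized: FeatureTable, metadata: pd.DataFrame,
                               community: syn.HerbivoreTable,
                               modules: net.ModuleSet):
    """Plot-level SEM frame plus the chemistry-augmented model.

    Backbone (protected): elevation -> leaves -> herbivore abundance ->
    diversity, elevation/leaves -> parasitoid success, with a residual
    covariance between parasitoid success and herbivore diversity.
    Chemistry (tagged, prunable): every module eigensignal to every
    community response, and elevation/leaves to every module.
    """
    morph_cols = community.morphotype_columns()
    herb_by_plot = community.counts.groupby("plot")[morph_cols].sum()
    abund = herb_by_plot.sum(axis=1)
    diver = herb_by_plot.apply(
        lambda r: dv.shannon_effective(r.to_numpy()) if r.sum() > 0 else np.nan,
        axis=1)
    psucc = dv.parasitoid_success(community.outcomes)
    plot_meta = community.plots

    eig_plot = modules.eigenvalues.join(metadata["plot"]).groupby("plot").mean()
    frame = pd.DataFrame({
        "elevation": plot_meta["elevation_m"],
        "leaves": np.log(plot_meta["leaves_per_plant"]),
        "herb_abundance": np.log1p(abund),
        "herb_diversity": diver,
        "parasitoid": psucc,
    })
    mod_vars = []
    for mod in modules.module_names:
        name = f"mod_{mod}"
        frame[name] = eig_plot[mod]
        mod_vars.append(name)
    frame = frame.dropna()

    lines = [
        "leaves ~ elevation",
        "herb_abundance ~ leaves",
        "herb_diversity ~ elevation + leaves + herb_abundance",
        "parasitoid ~ elevation + leaves",
        "parasitoid ~~ herb_diversity",
    ]
    protected = {("elevation", "leaves"), ("leaves", "herb_abundance"),
                 ("elevation", "herb_diversity"), ("leaves", "herb_diversity"),
                 ("herb_abundance", "herb_diversity"),
                 ("elevation", "parasitoid"), ("leaves", "parasitoid")}
    tagged = set()
    for name in mod_vars:
        lines.append(f"herb_abundance ~ {name}")
        lines.append(f"herb_diversity ~ {name}")
        lines.append(f"parasitoid ~ {name}")
        lines.append(f"{name} ~ elevation + leaves")
        tagged |= {(name, "herb_abundance"), (name, "herb_diversity"),
                   (name, "parasitoid"), ("elevation", name), ("leaves", name)}
    model = pm.parse_model("\n".join(lines))
    return frame, model, tagged, protected


def _fit_summary(fit: pm.PathFit) -> dict:
    paths = fit.params[fit.params["kind"] == "path"]
    return {
        "chi2": fit.chi2, "df": fit.df, "p": fit.p_value, "aic": fit.aic,
        "aic_deviance": fit.aic_deviance, "converged": fit.converged,
        "paths": {row["name"]: {"estimate": float(row["estimate"]),
                                "p": None if np.isnan(row["p"]) else float(row["p"])}
                  for _, row in paths.iterrows()},
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)
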