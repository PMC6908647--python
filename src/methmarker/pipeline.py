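"""End-to-end marker-discovery pipeline.

Stage order: QC -> differential methylation -> differential expression ->
CIMP consensus clustering -> methylation-expression integration -> candidate
construction -> cross-cancer specificity screen -> information-gain filter ->
SBFS -> cross-validated evaluation.  One table is written per stage plus a
JSON summary; the log records every threshold used.

Differential methylation compares the target cancer's tumors against the
pooled normals of every simulated cancer type (the multi-project normal
reference design); expression, clustering and classification use the target
type's own samples.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as mcluster
from . import deg as mdeg
from . import dmc as mdmc
from . import integrate as mintegrate
from . import io as mio
from . import markers as mmarkers
from . import preprocess as mpre
from . import evaluate as meval
from .simulate import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger("methmarker")

DEFAULTS: dict = {
    "seed": 0,
    "target_type": None,          # default: first cancer_type in the sample sheet
    "qc": {"max_missing": 0.10},
    "dmc": {"delta_threshold": 0.2, "fdr_threshold": 0.05},
    "deg": {"lfc_threshold": 1.5, "fdr_threshold": 0.05},
    "cluster": {"k": 3, "n_reps": 200, "subsample_frac": 0.8, "n_init": 10,
                "sd_min": 0.2, "normal_mean_max": 0.05},
    "integration": {"r_threshold": 0.3, "fdr_threshold": 0.05,
                    "distant": False},
    "markers": {"ig_threshold": 0.3, "n_bins": 10, "sbfs_cv": 5},
    "evaluation": {"folds": 10},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(config_path=None, overrides: dict | None = None) -> dict:
    config = _deep_merge({}, DEFAULTS)
    if config_path is not None:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _deep_merge(config, _unflatten(user))
    if overrides:
        config = _deep_merge(config, _unflatten(overrides))
    return config


def _unflatten(d: dict) -> dict:
    """Accept both nested mappings and flat ``stage.parameter`` keys."""
    out: dict = {}
    for key, value in d.items():
        if isinstance(key, str) and "." in key:
            stage, param = key.split(".", 1)
            out.setdefault(stage, {})[param] = value
        elif isinstance(value, dict):
            out[key] = _unflatten(value)
        else:
            out[key] = value
    return out


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        elif isinstance(v, dict):
            out[k] = _deep_merge({}, v)
        else:
            out[k] = v
    return out


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def load_inputs(config: dict):
    inputs = config.get("inputs", {})
    if "simulate" in config:
        sim = {k: v for k, v in config["simulate"].items()}
        sim.setdefault("seed", config.get("seed", 0))
        cfg = CohortConfig(**sim)
        return generate_cohort(cfg)[:4] + (None,)
    beta = mio.read_beta_matrix(inputs["beta"])
    ann = mio.read_manifest(inputs["manifest"])
    counts = mio.read_counts(inputs["counts"])
    sheet = mio.read_sample_sheet(inputs["samples"])
    return beta, ann, counts, sheet, None


def run_pipeline(config_path=None, config: dict | None = None,
                 outdir=None) -> dict:
    """Run every stage; returns (and writes) the summary dict."""
    if config is None:
        config = load_config(config_path)
    outdir = Path(outdir or config.get("outdir", "methmarker_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": seed, "status": "ok", "thresholds": {
        k: config[k] for k in ("qc", "dmc", "deg", "cluster", "integration",
                               "markers", "evaluation")}}
    logger.info("thresholds: %s", summary["thresholds"])

    try:
        beta, ann, counts, sheet, _truth = _stage("inputs")(load_inputs)(config)
        target = config.get("target_type") or sheet["cancer_type"].iloc[0]
        summary["target_type"] = str(target)
        is_target = sheet["cancer_type"] == target
        cond = sheet["condition"]

        # ---- QC ----------------------------------------------------------
        qc_cfg = config["qc"]
        filtered, report = _stage("qc")(mpre.filter_probes)(
            beta, ann, max_missing=qc_cfg["max_missing"])
        imputed = _stage("qc")(mpre.impute_missing)(filtered, sheet)
        mio.write_json(report.to_dict(), outdir / "qc_report.json")
        summary["qc"] = report.to_dict()

        # ---- differential methylation: target tumors vs pooled normals ---
        dmc_cfg = config["dmc"]
        target_tumors = sheet.index[is_target & (cond == "tumor")]
        all_normals = sheet.index[cond == "normal"]
        meth_samples = target_tumors.union(all_normals, sort=False)
        stats = _stage("dmc")(mdmc.dmc_stats)(
            imputed[meth_samples], cond.loc[meth_samples])
        dmcs = mdmc.call_dmcs(stats, dmc_cfg["delta_threshold"],
                              dmc_cfg["fdr_threshold"])
        dmcs.to_csv(outdir / "dmc.tsv", sep="\t", index_label="probe_id")
        summary["dmc"] = {
            "n_dmcs": int(len(dmcs)),
            "n_hyper": int((dmcs["direction"] == "hyper").sum()),
            "n_hypo": int((dmcs["direction"] == "hypo").sum()),
        }
        context = mdmc.context_summary(dmcs, ann)
        mio.write_json(context, outdir / "dmc_context.json")
        if len(dmcs) == 0:
            return _finish(summary, outdir, "no candidates: empty DMC set")
        dmg = _stage("dmc")(mdmc.map_dmcs_to_genes)(dmcs, ann)

        # ---- differential expression: target type only -------------------
        deg_cfg = config["deg"]
        expr_samples = sheet.index[is_target][
            sheet.loc[is_target].index.isin(counts.columns)]
        counts_t = counts[expr_samples]
        factors = _stage("deg")(mdeg.tmm_factors)(counts_t)
        factors.to_csv(outdir / "tmm_factors.tsv", sep="\t",
                       index_label="sample_id")
        deg_stats = _stage("deg")(mdeg.nb_test)(
            counts_t, factors, cond.loc[expr_samples])
        deg_stats.to_csv(outdir / "deg.tsv", sep="\t", index_label="gene_id")
        up, down = mdeg.call_degs(deg_stats, deg_cfg["lfc_threshold"],
                                  deg_cfg["fdr_threshold"])
        summary["deg"] = {"n_up": len(up), "n_down": len(down),
                          "dispersion": deg_stats.attrs["dispersion"]}

        # ---- consensus clustering on target tumors ----------------------
        cl_cfg = config["cluster"]
        variable = _stage("cluster")(mcluster.select_variable_probes)(
            imputed[target_tumors], imputed[all_normals], ann,
            sd_min=cl_cfg["sd_min"], normal_mean_max=cl_cfg["normal_mean_max"])
        summary["cluster"] = {"n_variable_probes": len(variable)}
        if len(variable) >= 2 and len(target_tumors) >= cl_cfg["k"]:
            result = _stage("cluster")(mcluster.consensus_cluster)(
                imputed.loc[variable, target_tumors], k=cl_cfg["k"],
                n_reps=cl_cfg["n_reps"],
                subsample_frac=cl_cfg["subsample_frac"],
                n_init=cl_cfg["n_init"], seed=seed)
            result.labels.to_csv(outdir / "cluster_labels.tsv", sep="\t")
            result.consensus_matrix.to_csv(outdir / "consensus_matrix.tsv",
                                           sep="\t")
            summary["cluster"]["shares"] = mcluster.label_shares(result.labels)
            assoc_rows = []
            for feature in ("histology", "hpv_status", "hpv_clade"):
                if feature in sheet.columns:
                    values = sheet.loc[target_tumors, feature]
                    if values.notna().sum() >= 4 and values.dropna().nunique() >= 2:
                        res = mcluster.cluster_association(
                            result.labels, values, seed=seed)
                        assoc_rows.append((feature, res.p_value, res.method))
            pd.DataFrame(assoc_rows, columns=["feature", "p", "method"]).to_csv(
                outdir / "cluster_associations.tsv", sep="\t", index=False)
            f_stat, p_anova = mcluster.cluster_methylation_anova(
                result.labels, imputed.loc[variable, target_tumors].mean(axis=0))
            summary["cluster"]["anova"] = {"F": f_stat, "p": p_anova}

        # ---- integration -------------------------------------------------
        int_cfg = config["integration"]
        expr = mintegrate.log_cpm(counts_t, factors)
        quadrants = mintegrate.quadrant_classify(dmg, up, down)
        summary["integration"] = {
            "hyper_up": len(quadrants.hyper_up),
            "hyper_down": len(quadrants.hyper_down),
            "hypo_up": len(quadrants.hypo_up),
            "hypo_down": len(quadrants.hypo_down),
        }
        local = _stage("integration")(mintegrate.local_correlation)(
            imputed[expr_samples], expr, ann,
            r_threshold=int_cfg["r_threshold"],
            fdr_threshold=int_cfg["fdr_threshold"])
        local.records.to_csv(outdir / "local_correlation.tsv", sep="\t",
                             index=False)
        class_counts = pd.Series(local.gene_classes).value_counts().to_dict()
        summary["integration"]["local_gene_classes"] = class_counts

        # ---- candidate construction + specificity screen -----------------
        if not quadrants.hyper_down:
            return _finish(summary, outdir,
                           "no candidates: no hyper-down genes")
        candidates = _stage("candidates")(mmarkers.build_candidates)(
            dmcs, quadrants.hyper_down, ann)
        if not candidates.probes("initial"):
            return _finish(summary, outdir,
                           "no candidates: empty initial candidate set")
        other_tables: dict[str, pd.DataFrame] = {}
        for other in sheet["cancer_type"].unique():
            if other == target:
                continue
            o_mask = sheet["cancer_type"] == other
            o_samples = sheet.index[o_mask]
            o_stats = _stage("screen")(mdmc.dmc_stats)(
                imputed[o_samples], cond.loc[o_samples])
            other_tables[str(other)] = mdmc.call_dmcs(
                o_stats, dmc_cfg["delta_threshold"], dmc_cfg["fdr_threshold"])
        candidates = mmarkers.specificity_filter(candidates, other_tables)
        if not candidates.probes("specificity_filtered"):
            return _finish(summary, outdir,
                           "no candidates: all removed by specificity screen")

        # ---- IG filter + SBFS on target-type samples ---------------------
        mk_cfg = config["markers"]
        clf_samples = sheet.index[is_target]
        labels = cond.loc[clf_samples].to_numpy()
        beta_clf = imputed[clf_samples]
        candidates, gains = _stage("select")(mmarkers.ig_filter)(
            candidates, beta_clf, labels,
            threshold=mk_cfg["ig_threshold"], n_bins=mk_cfg["n_bins"])
        if not candidates.probes("ig_filtered"):
            return _finish(summary, outdir,
                           "no candidates: none pass the IG filter")
        panel = _stage("select")(mmarkers.sbfs)(
            candidates, beta_clf, labels, seed=seed, cv=mk_cfg["sbfs_cv"],
            gains=gains)
        stage_table = pd.DataFrame(
            [(s, ";".join(p)) for s, p in candidates.stages.items()],
            columns=["stage", "probes"])
        stage_table.to_csv(outdir / "candidate_stages.tsv", sep="\t",
                           index=False)
        mio.write_json(panel.to_dict(), outdir / "marker_panel.json")
        summary["markers"] = {
            "stage_sizes": {s: len(p) for s, p in candidates.stages.items()},
            "panel": list(panel.probe_ids),
            "ig": {p: gains[p] for p in candidates.probes("ig_filtered")},
        }

        # ---- cross-validated evaluation ----------------------------------
        ev_cfg = config["evaluation"]
        X = beta_clf.loc[panel.probe_ids].to_numpy(dtype=float).T
        report = _stage("evaluate")(meval.cross_validate)(
            X, labels, folds=ev_cfg["folds"], seed=seed)
        report.to_table().to_csv(outdir / "evaluation.tsv", sep="\t",
                                 index=False)
        summary["evaluation"] = {
            "auc": report.auc,
            "accuracy": report.accuracy,
            "weighted": report.weighted,
            "folds": report.folds,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
    return _finish(summary, outdir, None)


def _finish(summary: dict, outdir: Path, status: str | None) -> dict:
    if status:
        summary["status"] = status
        logger.info("pipeline stopped: %s", status)
    mio.write_json(summary, outdir / "summary.json")
    return summary


def simulate_to_dir(outdir, **kwargs) -> dict:
    """Generate a cohort and write the pipeline input files."""
    cfg = CohortConfig(**kwargs)
    beta, ann, counts, sheet, truth = generate_cohort(cfg)
    write_cohort(outdir, beta, ann, counts, sheet, truth)
    return {"outdir": str(outdir), "n_probes": cfg.n_probes,
            "n_samples": int(beta.shape[1])}
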