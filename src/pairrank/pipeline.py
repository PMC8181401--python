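"""End-to-end orchestration: config-driven runs with reproducible manifests.

A run executes the stages in the analysis order — ingest or simulate,
binarize (gene-list restriction, MAD filter, pairing, prevalence filter),
train (resampled selection + final fit), score, evaluate (cutoff, KM,
log-rank, Cox), and optionally the immune-fraction association — writing
every artifact as TSV/JSON under one output directory and a manifest
(config snapshot, input digests, seed, per-stage timings, outputs) last.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, data_io, immune_assoc, pair_engine, signature_selection
from . import survival_eval, synthetic
from .errors import ValidationError

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "filters": {"mad_threshold": 0.5, "mad_log2": False, "prevalence_min": 0.20},
    "selection": {
        "n_iterations": 1000,
        "subsample_frac": 0.8,
        "min_frequency": 0.5,
        "top_k": None,
    },
    "evaluation": {"cutoff_horizon": 36.0, "validation_horizon": 60.0},
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(config: dict) -> dict:
    """Schema check; collects every violation into one error message."""
    problems: list[str] = []
    merged = json.loads(json.dumps(_DEFAULTS))
    for key, value in config.items():
        if isinstance(value, dict) and key in merged:
            merged[key].update(value)
        else:
            merged[key] = value
    if "output_dir" not in merged:
        problems.append("output_dir: required field missing")
    has_sim = "simulate" in merged
    has_inputs = "inputs" in merged
    if has_sim == has_inputs:
        problems.append("exactly one of 'simulate' or 'inputs' must be given")
    if has_inputs:
        inputs = merged["inputs"]
        for fld in ("expression", "clinical"):
            if fld not in inputs:
                problems.append(f"inputs.{fld}: required field missing")
    filters = merged["filters"]
    if not 0 < filters["prevalence_min"] < 0.5:
        problems.append("filters.prevalence_min: must lie in (0, 0.5)")
    if filters["mad_threshold"] < 0:
        problems.append("filters.mad_threshold: must be non-negative")
    sel = merged["selection"]
    if sel["n_iterations"] < 1:
        problems.append("selection.n_iterations: must be >= 1")
    if not 0 < sel["subsample_frac"] <= 1:
        problems.append("selection.subsample_frac: must lie in (0, 1]")
    for fld in ("cutoff_horizon", "validation_horizon"):
        if merged["evaluation"][fld] <= 0:
            problems.append(f"evaluation.{fld}: must be positive")
    if problems:
        raise ValidationError("invalid config: " + "; ".join(problems))
    return merged


def run_pipeline(config_path: str | Path) -> dict:
    """Execute the full pipeline from a YAML config; returns the manifest."""
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text())
    config = validate_config(raw)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": {"config": _digest(config_path)},
        "stages": [],
        "outputs": {},
    }

    def _stage(name):
        start = _time.perf_counter()

        def _done():
            manifest["stages"].append(
                {"name": name, "seconds": round(_time.perf_counter() - start, 3)}
            )

        return _done

    # stage 1: ingest or simulate ------------------------------------------
    done = _stage("ingest")
    gene_list = None
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        sim_cfg.setdefault("seed", seed)
        spec = synthetic.CohortSpec(**sim_cfg)
        expr, surv, truth = synthetic.simulate_cohort(spec)
        data_io.write_expression(expr, outdir / "expr.tsv")
        data_io.write_survival(surv, outdir / "clin.tsv")
        truth_json = {
            "informative_pairs": truth["informative_pairs"],
            "coefficients": truth["coefficients"].tolist(),
            "censoring_rate_achieved": truth["censoring_rate_achieved"],
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2))
        manifest["outputs"]["truth"] = str(outdir / "truth.json")
    else:
        inputs = config["inputs"]
        expr_path = Path(inputs["expression"])
        clin_path = Path(inputs["clinical"])
        manifest["input_digests"]["expression"] = _digest(expr_path)
        manifest["input_digests"]["clinical"] = _digest(clin_path)
        expr = data_io.read_expression(expr_path)
        surv = data_io.read_survival(clin_path, inputs.get("time_unit", "months"))
        if inputs.get("gene_list"):
            gl_path = Path(inputs["gene_list"])
            manifest["input_digests"]["gene_list"] = _digest(gl_path)
            gene_list = data_io.read_gene_list(gl_path)
    done()

    # stage 2: binarize ----------------------------------------------------
    done = _stage("binarize")
    filters = config["filters"]
    if gene_list is not None:
        expr = pair_engine.restrict_to_genes(expr, gene_list)
    expr = pair_engine.mad_filter(
        expr, filters["mad_threshold"], log2_transform=filters["mad_log2"]
    )
    indicators = pair_engine.binarize_pairs(expr)
    indicators = pair_engine.prevalence_filter(indicators, filters["prevalence_min"])
    indicators.to_csv(outdir / "pairs.tsv", sep="\t")
    manifest["outputs"]["pairs"] = str(outdir / "pairs.tsv")
    done()

    # stage 3: train -------------------------------------------------------
    done = _stage("train")
    sel_cfg = config["selection"]
    result = signature_selection.resampled_lasso(
        indicators,
        surv,
        n_iter=int(sel_cfg["n_iterations"]),
        subsample_frac=float(sel_cfg["subsample_frac"]),
        seed=seed,
    )
    result.pair_frequencies.sort_values(ascending=False).to_csv(
        outdir / "pair_frequencies.tsv", sep="\t"
    )
    if sel_cfg.get("top_k"):
        selected = signature_selection.select_top(result, top_k=int(sel_cfg["top_k"]))
    else:
        selected = signature_selection.select_top(
            result, min_frequency=float(sel_cfg["min_frequency"])
        )
    signature = signature_selection.fit_final(indicators, surv, selected, seed=seed)
    done()

    # stage 4: score -------------------------------------------------------
    done = _stage("score")
    scores = pair_engine.risk_score(indicators, signature)
    done()

    # stage 5: evaluate ----------------------------------------------------
    done = _stage("evaluate")
    ev = config["evaluation"]
    roc = survival_eval.td_roc(scores, surv, ev["cutoff_horizon"])
    signature.cutoff = roc.optimal_cutoff
    data_io.write_signature(signature, outdir / "signature.json")
    manifest["outputs"]["signature"] = str(outdir / "signature.json")
    scores.to_frame().to_csv(outdir / "scores.tsv", sep="\t", index_label="sample_id")
    manifest["outputs"]["scores"] = str(outdir / "scores.tsv")
    groups = pair_engine.assign_groups(scores, roc.optimal_cutoff)
    groups.to_frame().to_csv(outdir / "groups.tsv", sep="\t", index_label="sample_id")
    roc.to_frame().to_csv(outdir / "roc_grid.tsv", sep="\t", index=False)
    statistic, p_value = survival_eval.logrank_test(surv, groups)
    curves = survival_eval.km_curve(surv, groups)
    km_frames = [frame.assign(group=g) for g, frame in curves.items()]
    pd.concat(km_frames).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    cox_input = surv.copy()
    cox_input["risk_group"] = groups
    cox = survival_eval.cox_models(cox_input)
    cox.to_csv(outdir / "cox_report.tsv", sep="\t", index=False)
    summary = {
        "n_samples": int(len(surv)),
        "n_events": int(surv["status"].sum()),
        "n_genes_after_filters": int(len(expr)),
        "n_pairs_after_prevalence": int(len(indicators)),
        "n_selected_pairs": len(signature.pairs),
        "cutoff": roc.optimal_cutoff,
        "cutoff_horizon_months": ev["cutoff_horizon"],
        "cutoff_auc": roc.auc,
        "cutoff_sensitivity": roc.optimal_sens,
        "cutoff_specificity": roc.optimal_spec,
        "logrank_statistic": statistic,
        "logrank_p": p_value,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest["outputs"]["summary"] = str(outdir / "summary.json")
    done()

    # stage 6: immune association (optional) -------------------------------
    done = _stage("immune")
    if "immune" in config:
        imm_cfg = dict(config["immune"])
        imm_cfg.setdefault("seed", seed + 1)
        imm_spec = synthetic.ImmuneSpec(**imm_cfg)
        mixture, _, basis = synthetic.simulate_immune(imm_spec, scores)
        fractions = immune_assoc.deconvolve(mixture, basis)
        fractions.to_csv(outdir / "fractions.tsv", sep="\t", index_label="sample_id")
        immune_assoc.compare_groups(fractions, groups).to_csv(
            outdir / "immune_group_diffs.tsv", sep="\t"
        )
        immune_assoc.correlate_with_score(fractions, scores).to_csv(
            outdir / "immune_correlations.tsv", sep="\t"
        )
        manifest["outputs"]["fractions"] = str(outdir / "fractions.tsv")
    done()

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
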