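"""End-to-end orchestration: one command reproduces the full analysis.

Stages: load-or-simulate → validate → inclusion filter → feature matrix →
entropy profiles and genotype tests → per-genotype Markov models → sPLS-DA
of two-call transition probabilities → Lasso paths (four behavioral
responses, gaussian; genotype, binomial) → random-forest genotype
classification → genotype-stratified univariate prediction of the selected
features → path-summary edge tables.

Every stage writes plain CSV into the run directory and the run closes with
a JSON manifest (parameters, seeds, row counts, SHA-256 of every output),
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .call_dataset import (
    AGES,
    BEHAVIOR_NAMES,
    GENOTYPE_CODE,
    GENOTYPES,
    CallSequence,
    derive_dependents,
    filter_pups,
    read_behavior_table,
    read_call_table,
    write_behavior_table,
    write_call_table,
)
from .predictive_models import (
    build_path_summary,
    evaluate_rf,
    fit_lasso_path,
    predict_behaviors,
    write_path_summary,
)
from .sequence_features import build_matrix, extract_features, trans_prob_name
from .sequence_structure import (
    entropy_group_tests,
    entropy_profile,
    entropy_table,
    fit_markov,
    fit_splsda,
)
from .synthetic_data import SimConfig, config_from_dict, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: Path
    sim: SimConfig | None = None
    calls_path: Path | None = None
    behavior_path: Path | None = None
    feature_age: str = "P8"
    min_calls: int = 11
    odorant: str = "Ur1"
    cutoff: float = 0.25
    top_k: int = 8
    min_count: int = 5
    keep_x: int | None = None
    n_components: int = 2
    n_trees: int = 1000
    rf_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload, outdir=outdir)

    @classmethod
    def from_dict(cls, payload: Mapping, outdir: str | Path | None = None) -> "RunConfig":
        cfg = cls(outdir=Path(outdir or payload.get("outdir", "usvsyntax_run")))
        if "simulate" in payload:
            cfg.sim = config_from_dict(payload["simulate"] or {})
        if "calls" in payload:
            cfg.calls_path = Path(payload["calls"])
        if "behavior" in payload:
            cfg.behavior_path = Path(payload["behavior"])
        for key in ("feature_age", "min_calls", "odorant", "cutoff", "top_k",
                    "min_count", "keep_x", "n_components", "n_trees", "rf_seed"):
            if key in payload and payload[key] is not None:
                setattr(cfg, key, payload[key])
        if cfg.sim is None and cfg.calls_path is None:
            raise ValueError("config must provide either a 'simulate' block or a 'calls' path")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- data -------------------------------------------------------------
    if cfg.sim is not None:
        seqs, behaviors = simulate_dataset(cfg.sim)
        write_call_table(seqs, out / "calls.csv")
        write_behavior_table(behaviors, out / "behavior.csv")
    else:
        seqs = read_call_table(cfg.calls_path)
        behaviors = read_behavior_table(cfg.behavior_path) if cfg.behavior_path else []
    for s in seqs:
        s.validate()
    counts["sequences"] = len(seqs)
    counts["behavior_records"] = len(behaviors)

    # -- inclusion filter + features --------------------------------------
    kept = filter_pups(seqs, min_calls=cfg.min_calls, age=cfg.feature_age)
    counts["pups_included"] = len(kept)
    features = [extract_features(s) for s in kept]
    dependents = {b.mouse_id: derive_dependents(b, odorant=cfg.odorant) for b in behaviors}
    X, Y = build_matrix(features, dependents)
    counts["matrix_rows"] = len(X)
    X.to_csv(out / "features.csv")
    Y.to_csv(out / "dependents.csv")

    # -- entropy ----------------------------------------------------------
    profiles = [entropy_profile(s) for s in seqs]
    entropy_table(profiles).to_csv(out / "entropy.csv", index=False)
    try:
        entropy_group_tests(profiles).to_csv(out / "entropy_tests.csv", index=False)
    except ValueError as exc:
        logger.warning("entropy group tests skipped: %s", exc)

    # -- markov models ----------------------------------------------------
    markov = {}
    for geno in GENOTYPES:
        group_seqs = [s for s in kept if s.genotype == geno]
        if not group_seqs:
            continue
        model = fit_markov(group_seqs, group=(geno, cfg.feature_age),
                           top_k=cfg.top_k, min_count=cfg.min_count)
        markov[geno] = model
        model.counts.to_csv(out / f"markov_{geno}_counts.csv")
        model.probs.to_csv(out / f"markov_{geno}_probs.csv")
        pd.DataFrame(model.frequent_edges, columns=["from_call", "to_call", "prob"]).to_csv(
            out / f"markov_{geno}_edges.csv", index=False)

    # -- sPLS-DA on transition probabilities, pooled over ages -------------
    all_features = [extract_features(s) for s in seqs if len(s.calls) >= cfg.min_calls]
    from .sequence_features import features_frame
    from .call_dataset import CALL_TYPES
    pooled_ids = [f"{fv.pup_id}:{fv.age}" for fv in all_features]
    prob_cols = [trans_prob_name(i, j) for i in CALL_TYPES for j in CALL_TYPES]
    pooled = features_frame(
        [_with_id(fv, pid) for fv, pid in zip(all_features, pooled_ids)]
    )[prob_cols]
    labels = [fv.genotype for fv in all_features]
    splsda = fit_splsda(pooled, labels, keep_x=cfg.keep_x, n_components=cfg.n_components)
    splsda.scores.assign(genotype=list(labels),
                         age=[fv.age for fv in all_features]).to_csv(out / "splsda_scores.csv")
    splsda.loadings.to_csv(out / "splsda_loadings.csv")

    # -- lasso models ------------------------------------------------------
    selected_union: list[str] = []
    lasso_summary = []
    predictors = X.drop(columns=["genotype"])
    for response in BEHAVIOR_NAMES:
        y = Y[response]
        ok = y.notna()
        path = fit_lasso_path(X[ok.to_numpy()], y[ok], family="gaussian",
                              cutoff=cfg.cutoff, response_name=response)
        _write_lasso(path, out)
        lasso_summary.append((response, path))
        selected_union += [f for f, _ in path.selected if f != "genotype"]
    path2 = fit_lasso_path(predictors, X["genotype"], family="binomial",
                           cutoff=cfg.cutoff, response_name="genotype")
    _write_lasso(path2, out)
    lasso_summary.append(("genotype", path2))
    selected_union += [f for f, _ in path2.selected]
    selected_union = list(dict.fromkeys(selected_union))  # dedupe, keep order
    counts["selected_features"] = len(selected_union)

    # -- random forest -----------------------------------------------------
    rf = evaluate_rf(predictors, X["genotype"], n_trees=cfg.n_trees, seed=cfg.rf_seed)
    pd.DataFrame(rf.confusion, index=["true_WT", "true_DEL"],
                 columns=["pred_WT", "pred_DEL"]).to_csv(out / "rf_confusion.csv")
    pd.Series({
        "sensitivity": rf.sensitivity, "specificity": rf.specificity,
        "accuracy": rf.accuracy, "accuracy_p": rf.accuracy_p,
        "no_information_rate": rf.no_information_rate,
        "mcnemar_b": rf.mcnemar_b, "mcnemar_c": rf.mcnemar_c,
        "mcnemar_chi2": rf.mcnemar_chi2, "mcnemar_p": rf.mcnemar_p,
    }, name="value").to_csv(out / "rf_metrics.csv")
    rf.feature_importances.sort_values(ascending=False).to_csv(out / "rf_importances.csv")

    # -- stratified prediction + path summary ------------------------------
    preds = predict_behaviors(X, Y, selected_union)
    preds.to_csv(out / "regressions.csv", index=False)
    summary = build_path_summary(markov, preds)
    write_path_summary(summary, out)

    manifest = {
        "package": "usvsyntax",
        "version": __version__,
        "config": _config_payload(cfg),
        "counts": counts,
        "selected_features": selected_union,
        "outputs": {},
    }
    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, ensure_ascii=False)
    return manifest


def _with_id(fv, new_id: str):
    from dataclasses import replace
    return replace(fv, pup_id=new_id)


def _write_lasso(path_obj, out: Path) -> None:
    df = path_obj.coef_path.T
    df.insert(0, "lambda", path_obj.lambdas)
    df.insert(1, "frac_dev", path_obj.frac_dev)
    df.to_csv(out / f"lasso_{path_obj.response_name}_path.csv", index=False)
    pd.DataFrame(path_obj.selected, columns=["feature", "entry_frac_dev"]).to_csv(
        out / f"lasso_{path_obj.response_name}_selected.csv", index=False)


def _config_payload(cfg: RunConfig) -> dict:
    payload: dict = {
        "feature_age": cfg.feature_age, "min_calls": cfg.min_calls,
        "odorant": cfg.odorant, "cutoff": cfg.cutoff, "top_k": cfg.top_k,
        "min_count": cfg.min_count, "keep_x": cfg.keep_x,
        "n_components": cfg.n_components, "n_trees": cfg.n_trees,
        "rf_seed": cfg.rf_seed,
    }
    if cfg.sim is not None:
        payload["simulate"] = {
            "seed": cfg.sim.seed,
            "n_pups": dict(cfg.sim.n_pups),
            "length_mean": cfg.sim.length_mean,
            "length_dispersion": cfg.sim.length_dispersion,
            "effects": [
                {"feature": e.feature, "behavior": e.behavior,
                 "genotype": e.genotype, "beta": e.beta}
                for e in cfg.sim.effect_spec
            ],
        }
    if cfg.calls_path is not None:
        payload["calls"] = str(cfg.calls_path)
    if cfg.behavior_path is not None:
        payload["behavior"] = str(cfg.behavior_path)
    return payload
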