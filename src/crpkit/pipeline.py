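"""End-to-end authentication pipeline.

simulate (or load) -> align (COW) -> preprocess (SNV + calibration-fitted
mean centering) -> Kennard-Stone split -> explore (PCA scores, T²/Q,
Ward dendrogram) -> train the requested classifiers -> evaluate
(venetian-blinds CV on calibration, confusion metrics on validation).

Driven by a plain-dict config (typically loaded from YAML); unknown keys
are rejected before any computation, all randomness flows from the single
``seed``, and identical config + seed give bit-identical metric reports.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import classify, evaluate, preprocess, simulate, unsupervised
from .io import FingerprintMatrix, read_matrix_csv, write_matrix_csv

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger("crpkit.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "simulate": {
        "n_per_class": [38, 49],
        "n_points": 30935,
        "intensity_noise_cv": 0.1,
        "additive_noise_sd": 0.02,
        "baseline_level": 0.05,
        "global_shift_sd": 1.0,
        "local_warp_sd": 0.5,
        "n_replicates": 3,
    },
    "matrix_csv": None,  # alternative input: a pre-assembled matrix
    "align": {
        "enabled": True,
        "segment": 150,
        "slack": 5,
        "reference": "auto",
        "optimize": False,
        "segment_grid": [100, 150, 200],
        "slack_grid": [3, 5, 10],
    },
    "preprocess": {"steps": ["snv", "mean_center"]},
    "split": {"fraction": 0.6, "per_class": True},
    "explore": {"n_components": 3, "confidence": 0.95},
    "models": ["knn", "plsda", "svmda", "cart", "simca"],
    "model_params": {
        "knn": {"k": 3},
        "plsda": {"n_latent": 2},
        "simca": {"n_pcs": 5, "alpha": 0.05},
        "svmda": {"kernel": "linear", "C": 1.0},
        "cart": {},
    },
    "evaluate": {"positive_class": "RA", "cv_blocks": 10},
    "save_models": False,
    "write_matrices": True,
}


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in ref:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(ref[key], dict) and isinstance(val, dict) and key != "model_params":
            _check_keys(val, ref[key], path + key + ".")


def validate_config(config: dict | None) -> dict:
    """Merge a partial config over the defaults; unknown keys are an error."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        _check_keys(config, DEFAULT_CONFIG)
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
    bad_models = [m for m in merged["models"] if m not in classify._KINDS]
    if bad_models:
        raise ValueError(f"unknown model kind(s) {bad_models}")
    return merged


def _build_input(cfg: dict) -> FingerprintMatrix:
    if cfg["matrix_csv"]:
        log.info("loading matrix from %s", cfg["matrix_csv"])
        return read_matrix_csv(cfg["matrix_csv"])
    s = cfg["simulate"]
    log.info("simulating dataset: n_per_class=%s n_points=%s seed=%s",
             s["n_per_class"], s["n_points"], cfg["seed"])
    rh, ra = simulate.default_templates(n_points=int(s["n_points"]))
    params = simulate.SimulationParams(
        intensity_noise_cv=s["intensity_noise_cv"],
        additive_noise_sd=s["additive_noise_sd"],
        baseline_level=s["baseline_level"],
        global_shift_sd=s["global_shift_sd"],
        local_warp_sd=s["local_warp_sd"],
        n_replicates=int(s["n_replicates"]),
        seed=int(cfg["seed"]),
    )
    return simulate.simulate_dataset(rh, ra, tuple(int(n) for n in s["n_per_class"]), params)


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Run the full workflow; writes artifacts under ``out_dir`` and returns
    the metrics report (also written as metrics.json)."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    m = _build_input(cfg)

    # --- alignment -------------------------------------------------------
    a = cfg["align"]
    if a["enabled"]:
        ref = preprocess.choose_reference(m) if a["reference"] == "auto" else int(a["reference"])
        if a["optimize"]:
            params = preprocess.optimize_cow(m, a["segment_grid"], a["slack_grid"],
                                             reference_index=ref)
            log.info("optimized COW params: segment=%d slack=%d",
                     params.segment_length, params.slack)
        else:
            params = preprocess.CowParams(segment_length=int(a["segment"]),
                                          slack=int(a["slack"]), reference_index=ref)
        log.info("COW alignment to reference row %d (segment=%d slack=%d)",
                 params.reference_index, params.segment_length, params.slack)
        m = preprocess.cow_align_matrix(m, params)
        if cfg["write_matrices"]:
            write_matrix_csv(m, out / "aligned.csv")

    # --- split, then preprocessing fitted on calibration only ------------
    sp = cfg["split"]
    split = classify.kennard_stone_split(m, fraction=float(sp["fraction"]),
                                         per_class=bool(sp["per_class"]))
    log.info("Kennard-Stone split: %d calibration / %d validation (%s)",
             split.calibration.size, split.validation.size, split.per_class)
    np.savetxt(out / "split_calibration.txt", split.calibration, fmt="%d")
    np.savetxt(out / "split_validation.txt", split.validation, fmt="%d")

    def subset(mat: FingerprintMatrix, idx: np.ndarray) -> FingerprintMatrix:
        return FingerprintMatrix(mat.X[idx], mat.axis.copy(),
                                 [mat.sample_ids[i] for i in idx],
                                 [mat.class_labels[i] for i in idx],
                                 class_set=mat.class_set)

    cal_raw = subset(m, split.calibration)
    val_raw = subset(m, split.validation)
    recipe = preprocess.PreprocessRecipe(cfg["preprocess"]["steps"])
    cal = recipe.fit_transform(cal_raw)
    val = recipe.transform(val_raw)
    full = recipe.transform(m)
    if cfg["write_matrices"]:
        write_matrix_csv(full, out / "preprocessed.csv")

    # --- unsupervised exploration ----------------------------------------
    e = cfg["explore"]
    pca = unsupervised.fit_pca(full, int(e["n_components"]))
    report = unsupervised.t2_q_outliers(pca, full, confidence=float(e["confidence"]))
    with open(out / "scores.csv", "w") as fh:
        fh.write("sample_id,class_label," +
                 ",".join(f"PC{i+1}" for i in range(pca.n_components)) + "\n")
        for i, sid in enumerate(full.sample_ids):
            lab = full.class_labels[i] if full.class_labels else ""
            fh.write(f"{sid},{lab}," + ",".join(f"{v:.8g}" for v in pca.scores[i]) + "\n")
    with open(out / "t2q.csv", "w") as fh:
        fh.write(f"# t2_limit={report.t2_limit:.8g} q_limit={report.q_limit:.8g} "
                 f"confidence={report.confidence}\n")
        fh.write("sample_id,t2,q,flagged\n")
        for sid, t2, q in zip(report.sample_ids, report.t2, report.q):
            fh.write(f"{sid},{t2:.8g},{q:.8g},{int(sid in report.flagged)}\n")
    dend = unsupervised.hca_ward(full)
    (out / "dendrogram.nwk").write_text(unsupervised.dendrogram_to_newick(dend) + "\n")
    log.info("explore: %d components, %d sample(s) flagged as outliers",
             pca.n_components, len(report.flagged))

    # --- supervised models ------------------------------------------------
    y_cal = cal.labels_array()
    y_val = val.labels_array()
    pos = cfg["evaluate"]["positive_class"]
    if pos not in (m.class_set or ()):
        pos = sorted(set(y_cal))[-1]
    n_blocks = min(int(cfg["evaluate"]["cv_blocks"]), cal.n_samples)
    metrics: dict = {"config": cfg, "n_calibration": int(split.calibration.size),
                     "n_validation": int(split.validation.size),
                     "outliers_flagged": report.flagged, "models": {}}
    for kind in cfg["models"]:
        params = cfg["model_params"].get(kind, {})
        model = classify.make_classifier(kind, **params)
        model.fit(cal.X, y_cal)
        # venetian-blinds CV on the calibration set
        cv_correct, cv_total = 0, 0
        for train, test in evaluate.venetian_blinds(cal.n_samples, n_blocks):
            fold = classify.make_classifier(kind, **params)
            fold.fit(cal.X[train], y_cal[train])
            pred = fold.predict(cal.X[test])
            cv_correct += int(np.sum(pred == y_cal[test]))
            cv_total += test.size
        y_pred = model.predict(val.X)
        summary = evaluate.confusion_summary(y_val, y_pred, positive_class=pos,
                                             class_set=m.class_set)
        val_acc = 100.0 * float(np.mean(y_pred == y_val))
        entry = {
            "cv_accuracy_pct": round(100.0 * cv_correct / cv_total, 2),
            "validation_accuracy_pct": round(val_acc, 2),
            "n_unassigned": summary.n_unassigned,
            "sensitivity": round(summary.sensitivity, 2),
            "specificity": round(summary.specificity, 2),
            "ner": round(summary.ner, 2),
            "er": round(summary.er, 2),
            "counts": summary.counts,
        }
        metrics["models"][kind] = entry
        log.info("%s: CV %.2f%%, validation %.2f%% (%d unassigned)", kind,
                 entry["cv_accuracy_pct"], entry["validation_accuracy_pct"],
                 entry["n_unassigned"])
        if cfg["save_models"]:
            (out / f"model_{kind}.json").write_text(json.dumps(model.to_dict()))

    # runtimes stay out of the report files so identical config + seed give
    # bit-identical outputs
    log.info("pipeline finished in %.1f s", time.time() - t0)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _write_text_report(metrics, out / "metrics.txt")
    return metrics


def _write_text_report(metrics: dict, path: Path) -> None:
    lines = [
        f"samples: {metrics['n_calibration']} calibration / "
        f"{metrics['n_validation']} validation",
        f"outliers flagged: {', '.join(metrics['outliers_flagged']) or 'none'}",
        "",
        f"{'model':8s} {'CV%':>8s} {'Pred%':>8s} {'ER':>6s} {'NER':>6s} "
        f"{'Spec':>6s} {'Sens':>6s} {'NA':>4s}",
    ]
    for kind, e in metrics["models"].items():
        lines.append(
            f"{kind:8s} {e['cv_accuracy_pct']:8.2f} {e['validation_accuracy_pct']:8.2f} "
            f"{e['er']:6.2f} {e['ner']:6.2f} {e['specificity']:6.2f} "
            f"{e['sensitivity']:6.2f} {e['n_unassigned']:4d}"
        )
    path.write_text("\n".join(lines) + "\n")
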