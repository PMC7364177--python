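"""Execute a resolved run configuration and write the result bundle.

The bundle always contains the resolved configuration (defaults
materialised) and a log with every seed, so any run is replayable
bit-identically.  ROI runs write metrics, per-fold results, pooled
predictions, ROC points and weight maps; searchlight runs write the
statistic and sphere-size maps; permutation statistics add the null
distribution (per-permutation maxima for searchlight) and p-maps.

A config whose feature-selection step lists several amounts fans out into
independent sub-runs; the shared report lists every accuracy with the
Bonferroni-adjusted alpha = 0.05 / m, never only the best one.
"""

from __future__ import annotations

import csv
import datetime
from pathlib import Path

import numpy as np

from . import __version__, config as cfg, crossval, data_io, fusion as fus
from . import permstats, searchlight as sl
from .data_io import DataError, FeatureMatrix, LabelVector, VolumeSpace

__all__ = ["run"]


def _load_inputs(c: dict) -> tuple[FeatureMatrix, LabelVector,
                                   data_io.FoldAssignment]:
    inp = c["input"]
    if inp["samples"]:
        paths = cfg.expand_samples(inp["samples"])
        if inp["mask"] is None:
            raise DataError("input.mask is required for volume samples")
        data = data_io.load_samples(paths, inp["mask"])
    else:
        data = data_io.load_table(inp["samples_table"], "features")
    kind = "labels" if c["task"] == "classify" else "scores"
    labels = data_io.load_table(inp["labels"], kind)
    if inp["folds"]:
        folds = data_io.load_table(inp["folds"], "folds")
    else:
        folds = crossval.random_folds(data.n_samples, int(inp["k"]), labels,
                                      seed=c["seed"])
    return data, labels, folds


def _load_blocks(c: dict) -> list[fus.FeatureBlock]:
    blocks = []
    for b in c["fusion"]["blocks"]:
        if b["samples"]:
            matrix = data_io.load_samples(cfg.expand_samples(b["samples"]),
                                          b["mask"])
        else:
            matrix = data_io.load_table(b["samples_table"], "features")
        blocks.append(fus.FeatureBlock(b["name"] or f"block{len(blocks)}",
                                       matrix, b["normalize"]))
    return blocks


def _write_csv(path: Path, header: list[str], rows) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _fmt(x):
    return "" if x is None else f"{x:.6g}"


def _write_cv_outputs(result: crossval.CVResult, out: Path, c: dict,
                      space) -> None:
    agg = result.aggregate
    if result.task == "classify":
        rows = [["pooled", _fmt(agg["accuracy"]), _fmt(agg["sensitivity"]),
                 _fmt(agg["specificity"])]]
        header = ["scope", "accuracy", "sensitivity", "specificity"]
        rows.append(["mean_over_folds", _fmt(agg["accuracy_mean_over_folds"]),
                     "", ""])
    else:
        header = ["scope", "prediction_precision_r"]
        rows = [["pooled", _fmt(agg["r"])]]
    _write_csv(out / "metrics.csv", header, rows)
    if c["outputs"]["per_fold"] and result.per_fold:
        rows = []
        for f in result.per_fold:
            if result.task == "classify":
                rows.append([f.fold, _fmt(f.metrics["accuracy"]),
                             _fmt(f.metrics["sensitivity"]),
                             _fmt(f.metrics["specificity"]),
                             f.counts.TP, f.counts.TN, f.counts.FP,
                             f.counts.FN])
            else:
                rows.append([f.fold, len(f.test_indices)])
        header = (["fold", "accuracy", "sensitivity", "specificity",
                   "TP", "TN", "FP", "FN"] if result.task == "classify"
                  else ["fold", "n_test"])
        _write_csv(out / "per_fold.csv", header, rows)
    if c["outputs"]["predictions"]:
        _write_csv(out / "predictions.csv",
                   ["sample", "actual", "predicted", "decision_value"],
                   [[i, _fmt(a), _fmt(p), _fmt(d)] for i, (a, p, d) in
                    enumerate(zip(result.actual, result.predicted,
                                  result.decision_values))])
    if c["outputs"]["roc"] and result.task == "classify":
        fpr, tpr, auc = result.roc()
        _write_csv(out / "roc.csv", ["fpr", "tpr"],
                   [[_fmt(x), _fmt(y)] for x, y in zip(fpr, tpr)])
        (out / "auc.txt").write_text(f"{auc:.6g}\n")
    if (c["outputs"]["weight_maps"] and result.mean_weights is not None
            and isinstance(space, VolumeSpace)):
        data_io.write_map(result.mean_weights, space,
                          out / "mean_weight_map.nii.gz")
        for f in result.per_fold:
            if f.weights is not None:
                data_io.write_map(f.weights[0], space,
                                  out / f"weight_map_fold{f.fold:02d}.nii.gz")


def _run_roi(data, labels, folds, pipeline, c, out: Path) -> dict:
    result = crossval.run_cv(data, labels, folds, pipeline, seed=c["seed"])
    _write_cv_outputs(result, out, c, data.space)
    summary = {"statistic": result.statistic}
    n_perm = c["statistics"]["permutations"]
    if n_perm > 0:
        perm = permstats.permutation_test(data, labels, folds, pipeline,
                                          n_perm, seed=c["seed"])
        _write_csv(out / "null_distribution.csv", ["permutation", "statistic"],
                   [[i, _fmt(v)] for i, v in enumerate(perm.null_samples)])
        (out / "pvalue.txt").write_text(str(perm.p) + "\n")
        summary["p"] = perm.p
    return summary


def _run_searchlight(data, labels, folds, pipeline, c, out: Path) -> dict:
    mode, stats = c["mode"], c["statistics"]
    n_perm = stats["permutations"]
    if n_perm > 0:
        res = permstats.permutation_test_searchlight(
            data, labels, folds, mode["radius"], pipeline, n_perm,
            seed=c["seed"], units=mode["units"])
        observed = res.observed_map
        data_io.write_map(np.nan_to_num(res.uncorrected_p, nan=1.0),
                          data.space, out / "p_uncorrected.nii.gz")
        data_io.write_map(np.nan_to_num(res.corrected_p, nan=1.0), data.space,
                          out / "p_fwe_corrected.nii.gz")
        _write_csv(out / "null_maxima.csv", ["permutation", "max_statistic"],
                   [[i, _fmt(v)] for i, v in enumerate(res.fwe.max_null)])
    else:
        index = sl.build_spheres(data.space, mode["radius"], mode["units"])
        slr = sl.run_searchlight(data, labels, folds, mode["radius"],
                                 pipeline, seed=c["seed"],
                                 units=mode["units"], sphere_index=index)
        observed = slr.statistic_map
        data_io.write_map(slr.n_voxels_map.astype(float), data.space,
                          out / "sphere_size_map.nii.gz")
    data_io.write_map(np.nan_to_num(observed, nan=0.0), data.space,
                      out / "statistic_map.nii.gz")
    return {"statistic": float(np.nanmean(observed))}


def run(config: cfg.RunConfig, base_dir: str | Path | None = None) -> Path:
    """Validate and execute a configuration; returns the output directory."""
    problems = cfg.validate(config)
    if problems:
        raise cfg.ConfigError("invalid configuration:\n  - " +
                              "\n  - ".join(problems))
    c = config.data
    out = Path(base_dir) if base_dir else Path(c["outputs"]["directory"])
    out.mkdir(parents=True, exist_ok=True)
    cfg.save_config(config, out / "resolved_config.yaml")

    log_lines = [f"mvpkit {__version__}",
                 f"seed: {c['seed']}",
                 f"started: {datetime.datetime.now().isoformat()}"]

    amounts = cfg.selection_amounts(config)
    summaries = []
    if c.get("fusion"):
        blocks = _load_blocks(c)
        labels_kind = "labels" if c["task"] == "classify" else "scores"
        labels = data_io.load_table(c["input"]["labels"], labels_kind)
        if c["input"]["folds"]:
            folds = data_io.load_table(c["input"]["folds"], "folds")
        else:
            folds = crossval.random_folds(blocks[0].matrix.n_samples,
                                          int(c["input"]["k"]), labels,
                                          seed=c["seed"])
        pipeline = cfg.build_pipeline(config)
        result = fus.run_fusion(blocks, labels, folds, pipeline,
                                strategy=c["fusion"]["strategy"],
                                seed=c["seed"])
        _write_cv_outputs(result, out, c, blocks[0].matrix.space)
        summaries.append(("fusion", {"statistic": result.statistic}))
    else:
        data, labels, folds = _load_inputs(c)
        run_one = (_run_searchlight if c["mode"]["type"] == "searchlight"
                   else _run_roi)
        if amounts is None:
            pipeline = cfg.build_pipeline(config)
            summaries.append(("run", run_one(data, labels, folds, pipeline,
                                             c, out)))
        else:
            # several selection amounts: independent analyses, all reported
            for amount in amounts:
                pipeline = cfg.build_pipeline(config, amount_override=amount)
                sub = out / f"amount_{amount:g}"
                sub.mkdir(parents=True, exist_ok=True)
                summaries.append(
                    (f"amount={amount:g}",
                     run_one(data, labels, folds, pipeline, c, sub)))

    rows = []
    m = len(summaries)
    for name, summary in summaries:
        p = summary.get("p")
        rows.append([name, _fmt(summary["statistic"]),
                     "" if p is None else str(p)])
    header = ["analysis", "statistic", "p"]
    if amounts is not None and m > 1:
        header += [f"bonferroni_alpha=0.05/{m}={0.05 / m:g}"]
    _write_csv(out / "summary.csv", header, rows)
    log_lines.append(f"analyses: {m}")
    log_lines.append(f"finished: {datetime.datetime.now().isoformat()}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
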