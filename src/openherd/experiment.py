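"""Experiment orchestration: data -> splits -> train -> evaluate -> aggregate.

A run directory is fully regenerable from the resolved configuration copy it
contains: data generation, per-trial splits, training and evaluation all
derive their randomness from the single global seed, expanded per trial by a
counter.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from openherd.config import RunConfig, save_config
from openherd.evaluation import (MetricReport, OpennessConfig, aggregate,
                                 closed_set_report, evaluate_table, openness,
                                 score_test_set)
from openherd.synthetic import DatasetManifest, generate_dataset, load_manifest, make_identities
from openherd.training import SplitSpec, TrainedModel, make_openness_ladder, make_splits, train

__all__ = ["trial_seed", "prepare_data", "run_trial", "run_experiment", "run_openness_sweep",
           "reaggregate"]


def trial_seed(global_seed: int, trial: int) -> int:
    """Per-trial seed derived from the global seed by a counter."""
    return int(np.random.SeedSequence([int(global_seed), 0xEE, trial]).generate_state(1)[0]
               % (2**31))


def prepare_data(config: RunConfig, out_dir: str | Path) -> DatasetManifest:
    """Generate (or reuse) the synthetic herd described by the config."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        return load_manifest(manifest_path)
    syn = config.synthetic
    ids = make_identities(syn.n_ids, syn.sigma_id, seed=config.seed)
    return generate_dataset(
        ids, per_id_per_session=syn.per_id_per_session, sessions=tuple(syn.sessions),
        nuisance=syn.nuisance(), out_dir=out_dir, seed=config.seed,
        size=syn.image_size, days=tuple(syn.days), rgb=syn.rgb,
        session_illumination=syn.session_illumination,
    )


def run_trial(config: RunConfig, manifest: DatasetManifest, split: SplitSpec,
              trial_dir: str | Path) -> dict:
    """Train and evaluate one split; writes checkpoint, scores and metrics."""
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    tc = config.train_config(trial_seed(config.seed, split.trial_index))
    model = train(manifest, split, backbone_spec=config.backbone.spec(), config=tc)
    model.save(trial_dir / "checkpoint.npz")
    (trial_dir / "split.json").write_text(json.dumps({
        "trial_index": split.trial_index,
        "known_ids": list(split.known_ids),
        "unknown_ids": list(split.unknown_ids),
        "seed": split.seed,
    }, indent=2))

    table = score_test_set(model, manifest, split, day=config.eval.test_day)
    table.to_csv(trial_dir / "scores.csv", index=False)
    metrics = evaluate_table(table)
    if config.eval.export_curves:
        _export_curves(table, trial_dir)
    (trial_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics


def _export_curves(table: pd.DataFrame, trial_dir: Path) -> None:
    from sklearn import metrics as skm
    scores = table["known_score"].to_numpy()
    fpr, tpr, thr = skm.roc_curve(table["is_known"].to_numpy(), scores)
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        trial_dir / "curve_roc.csv", index=False)
    correct = table["predicted_label"].to_numpy() == table["true_label"].to_numpy()
    rows = []
    for s in np.unique(scores)[::-1]:
        passing = scores >= s
        k = table["is_known"].to_numpy()
        rows.append({
            "threshold": s,
            "ccr": float(np.mean(passing & k & correct) * len(table) / max(k.sum(), 1)),
            "fpr": float(np.mean(passing & ~k) * len(table) / max((~k).sum(), 1)),
        })
    pd.DataFrame(rows).to_csv(trial_dir / "curve_oscr.csv", index=False)


def run_experiment(config: RunConfig, out_dir: str | Path) -> MetricReport:
    """The full multi-trial protocol; returns the aggregated MetricReport.

    Layout of ``out_dir``: ``config.yaml`` (resolved copy), ``data/`` with
    images and manifest, ``trial_<t>/`` with checkpoint, split, scores and
    metrics, and ``summary.json`` with mean +/- sd over trials.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    manifest = prepare_data(config, out_dir / "data")

    all_ids = sorted(manifest.per_individual)
    splits = make_splits(all_ids, config.protocol.n_known, config.protocol.n_trials,
                         seed=config.seed)
    results = []
    for split in splits:
        metrics = run_trial(config, manifest, split, out_dir / f"trial_{split.trial_index}")
        results.append(metrics)

    report = aggregate(results, sd_convention=config.eval.sd_convention)
    (out_dir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    return report


def run_closed_set(config: RunConfig, out_dir: str | Path) -> dict:
    """All individuals known: train one model and report Acc / macro-F1 /
    confusion matrices on the test day."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    manifest = prepare_data(config, out_dir / "data")
    all_ids = sorted(manifest.per_individual)
    # every individual is known; the placeholder unknown id matches no
    # manifest row, so the evaluated table is all-known
    split = SplitSpec(trial_index=0, known_ids=tuple(all_ids),
                      unknown_ids=("__none__",), seed=config.seed)
    tc = config.train_config(trial_seed(config.seed, 0))
    model = train(manifest, split, backbone_spec=config.backbone.spec(), config=tc)
    table = score_test_set(model, manifest, split, day=config.eval.test_day)
    known_table = table[table["is_known"]].reset_index(drop=True)
    rep = closed_set_report(known_table)
    counts = pd.DataFrame(rep["confusion_counts"], index=rep["classes"], columns=rep["classes"])
    counts.to_csv(out_dir / "confusion.csv")
    (out_dir / "metrics.json").write_text(json.dumps({"acc": rep["acc"], "f1": rep["f1"]},
                                                     indent=2))
    return rep


def run_openness_sweep(config: RunConfig, known_counts: list[int], n_unknown: int,
                       n_trials: int, out_dir: str | Path) -> pd.DataFrame:
    """Train/evaluate every ladder rung; returns and writes the ladder summary.

    Output columns: known count, openness under both variants, CSA, AUROC
    and OSCR averaged over trials (mirroring the openness-performance curve).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    manifest = prepare_data(config, out_dir / "data")
    all_ids = sorted(manifest.per_individual)
    rungs = make_openness_ladder(all_ids, n_unknown, known_counts, n_trials, seed=config.seed)

    rows = []
    for split in rungs:
        c = len(split.known_ids)
        rung_dir = out_dir / f"trial_{split.trial_index}_known_{c}"
        metrics = run_trial(config, manifest, split, rung_dir)
        k_test = c + len(split.unknown_ids)
        rows.append({
            "trial": split.trial_index,
            "n_known": c,
            "openness_ratio": openness(OpennessConfig(k_train=c, k_test=k_test,
                                                      variant="ratio")),
            "openness_sqrt": openness(OpennessConfig(k_train=c, k_test=k_test,
                                                     variant="sqrt")),
            **metrics,
        })
    frame = pd.DataFrame(rows)
    summary = frame.groupby("n_known", as_index=False).mean().drop(columns="trial")
    summary = summary.sort_values("n_known", ascending=False)
    summary.to_csv(out_dir / "ladder_summary.csv", index=False)
    frame.to_csv(out_dir / "ladder_trials.csv", index=False)
    return summary


def reaggregate(run_dir: str | Path, sd_convention: str = "sample") -> MetricReport:
    """Rebuild the aggregate summary from the per-trial metrics files."""
    run_dir = Path(run_dir)
    metric_files = sorted(run_dir.glob("trial_*/metrics.json"))
    if not metric_files:
        raise FileNotFoundError(f"no trial_*/metrics.json under {run_dir}")
    results = [json.loads(p.read_text()) for p in metric_files]
    report = aggregate(results, sd_convention=sd_convention)
    (run_dir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    return report
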