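"""Experiment drivers: paired model comparison, feature ablation,
robustness sweeps and training-curve rendering.

All designs are paired: every arm of a comparison re-uses the identical
stratified split for each seed (verified by split-hash equality), and
per-condition results are summarized as medians over the seed set.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import bench
from .features import CHANNEL_COLUMNS, FEATURE_COLUMNS
from .model import DeepPsy, DeepPsySpec, make_dataset, train

log = logging.getLogger(__name__)

#: the four nested feature subsets of the ablation design
ABLATION_DATASETS = {
    1: ("network", "performance", "consumption"),
    2: ("performance", "consumption"),
    3: ("network", "performance"),
    4: ("performance",),
}


def ablation_columns(channels) -> list:
    cols = [c for ch in channels for c in CHANNEL_COLUMNS[ch]]
    return [c for c in FEATURE_COLUMNS if c in cols]


def _subset(data: dict, idx) -> dict:
    return {
        "grids": data["grids"][idx],
        "features": data["features"][idx],
        "labels": data["labels"][idx],
    }


def run_deeppsy_once(
    cohort,
    n_days: int,
    seed: int,
    spec: DeepPsySpec = None,
    channels=None,
):
    """One end-to-end fusion-model run on a fresh stratified split.

    ``channels`` restricts the feature channels (ablation); the
    trajectory branch is active only when the network channel is present.
    Returns (test EvalReport, TrainLog, split_hash).
    """
    use_traj = channels is None or "network" in channels
    cols = None if channels is None else ablation_columns(channels)
    base = spec or DeepPsySpec()
    spec = dataclasses.replace(base, seed=seed, use_trajectory=use_traj)
    data = make_dataset(cohort, n_days, seed=seed, feature_columns=cols)
    splits = bench.split_data(len(data["labels"]), data["labels"], seed=seed)
    tr, val, test = splits
    model = DeepPsy(
        spec,
        grid_shape=data["grids"].shape[2:],
        n_features=data["features"].shape[1],
    )
    model, tlog = train(model, _subset(data, tr), _subset(data, val), spec)
    probs = model.predict_proba(data["grids"][test], data["features"][test])
    rep = bench.compute_metrics(
        data["labels"][test],
        probs.argmax(axis=1),
        probs[:, 1],
        model="DeepPsy",
        seed=seed,
    )
    return rep, tlog, bench.split_hash(*splits)


def run_baseline_once(cohort, n_days: int, seed: int):
    """Best tabular classifier of the five-algorithm bench on the same split."""
    data = make_dataset(cohort, n_days, seed=seed)
    splits = bench.split_data(len(data["labels"]), data["labels"], seed=seed)
    reports = bench.run_bench(data["features"], data["labels"], splits, seed=seed)
    name = bench.select_classifier(reports)
    winner = next(r for r in reports if r.model == name)
    return winner, bench.split_hash(*splits)


def run_comparison(cohort, n_days: int, seeds, spec: DeepPsySpec = None) -> dict:
    """Paired baseline-vs-fusion comparison over a seed set.

    Per seed, the selected tabular classifier and the fusion model are
    evaluated on the identical held-out split. Returns a dict with the
    per-seed table, median paired differences and a sign-test p-value on
    the recall differences.
    """
    rows = []
    for seed in seeds:
        base_rep, h1 = run_baseline_once(cohort, n_days, seed)
        dp_rep, _, h2 = run_deeppsy_once(cohort, n_days, seed, spec=spec)
        assert h1 == h2, "comparison arms must share the split"
        rows.append(
            {
                "seed": seed,
                "baseline_model": base_rep.model,
                "baseline_recall": base_rep.recall,
                "baseline_f1": base_rep.f1,
                "baseline_accuracy": base_rep.accuracy,
                "deeppsy_recall": dp_rep.recall,
                "deeppsy_f1": dp_rep.f1,
                "deeppsy_accuracy": dp_rep.accuracy,
                "split_hash": h1,
            }
        )
    table = pd.DataFrame(rows)
    diffs = table["deeppsy_recall"] - table["baseline_recall"]
    nonzero = diffs[diffs != 0]
    p = (
        binomtest(int((nonzero > 0).sum()), len(nonzero)).pvalue
        if len(nonzero)
        else 1.0
    )
    return {
        "table": table,
        "median_recall_diff": float(diffs.median()),
        "median_f1_diff": float((table["deeppsy_f1"] - table["baseline_f1"]).median()),
        "sign_test_p": float(p),
    }


def run_ablation(
    cohort, n_days: int, seeds, datasets=None, spec: DeepPsySpec = None
) -> dict:
    """Retrain the fusion model per nested feature subset, paired seeds."""
    datasets = datasets or ABLATION_DATASETS
    rows = []
    for ds_id, channels in datasets.items():
        for seed in seeds:
            rep, _, h = run_deeppsy_once(
                cohort, n_days, seed, spec=spec, channels=channels
            )
            rows.append(
                {
                    "dataset": ds_id,
                    "channels": "+".join(channels),
                    "seed": seed,
                    "recall": rep.recall,
                    "f1": rep.f1,
                    "accuracy": rep.accuracy,
                    "split_hash": h,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("dataset")[["recall", "f1", "accuracy"]]
        .median()
        .reset_index()
    )
    return {"table": table, "summary": summary}


def run_sweep(
    cohort,
    n_days: int,
    param: str,
    values,
    seeds,
    spec: DeepPsySpec = None,
) -> dict:
    """Robustness sweep of one hyperparameter over paired seeds.

    ``param`` is a DeepPsySpec field (e.g. ``conv1_kernels`` or
    ``batch_size``). Returns the per-run table and a per-value summary
    with the median and the fluctuation (max - min of per-value medians
    is the headline range).
    """
    values = list(values)
    if not values:
        raise ValueError("sweep needs at least one value")
    base = spec or DeepPsySpec()
    rows = []
    for v in values:
        swept = dataclasses.replace(base, **{param: v})
        for seed in seeds:
            rep, _, h = run_deeppsy_once(cohort, n_days, seed, spec=swept)
            rows.append(
                {
                    "param": param,
                    "value": v,
                    "seed": seed,
                    "accuracy": rep.accuracy,
                    "recall": rep.recall,
                    "f1": rep.f1,
                    "split_hash": h,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("value")[["accuracy", "recall", "f1"]].median().reset_index()
    )
    fluctuation = {
        m: float(summary[m].max() - summary[m].min())
        for m in ("accuracy", "recall", "f1")
    }
    return {"table": table, "summary": summary, "fluctuation": fluctuation}


# ---------------------------------------------------------------------------
# training curves


def stabilization_epoch(losses) -> int:
    """First epoch after which the loss varies by < 1% of its range."""
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty training log")
    full_range = losses.max() - losses.min()
    if full_range == 0:
        return 1
    for e in range(len(losses)):
        tail = losses[e:]
        if tail.max() - tail.min() < 0.01 * full_range:
            return e + 1
    return len(losses)


def plot_training(trainlog, outdir) -> dict:
    """Write accuracy and loss curves; annotate the stabilization epoch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = trainlog.to_frame()
    if frame.empty:
        raise ValueError("empty training log")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stab = stabilization_epoch(frame["train_loss"].to_numpy())
    paths = {}
    for metric, cols in (
        ("loss", [c for c in ("train_loss", "val_loss") if c in frame]),
        ("accuracy", [c for c in ("train_acc", "val_acc") if c in frame]),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for c in cols:
            ax.plot(frame["epoch"], frame[c], label=c)
        ax.axvline(stab, color="gray", ls="--", lw=0.8)
        ax.annotate(f"stable @ {stab}", (stab, ax.get_ylim()[1]), fontsize=8)
        ax.set_xlabel("epoch")
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"training_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths[metric] = path
    return {"stabilization_epoch": stab, "figures": paths}
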