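"""Repeated random-split evaluation of the classifier with averaged ROC.

The cohort is repeatedly partitioned into training / validation / test
subsets (default 70/15/15, stratified by class, largest-remainder rounding),
a freshly initialized network is trained per trial, and the test-set scores
give a per-trial ROC and AUC.  The 30-trial default summary reports the mean
AUC with a 95% percentile interval over trials, the vertically averaged ROC
curve, and sensitivity/specificity at the curve's upper-left operating point
(maximum Youden's J = TPR - FPR).

Feature selection is performed once on the full table before the trials by
default, mirroring a selection-then-split workflow; this leaks test
information into the selection, so ``selection_inside_trial=True`` re-runs
the selection on each trial's training subset for comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable
from .network import (encode_targets, init_network, score_and_classify,
                      train_levenberg_marquardt)
from .selection import normalize_table, select_features


@dataclass
class SplitConfig:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_trials: int = 30
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios) or abs(sum(self.ratios) - 1) > 1e-9:
            raise ValueError("ratios must be positive and sum to 1")


@dataclass
class ROCSummary:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    trial_aucs: np.ndarray
    auc_mean: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    confusion: np.ndarray          # rows true class (neg, pos), cols predicted

    def to_dict(self) -> dict:
        return {
            "auc_mean": float(self.auc_mean),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "trial_aucs": [float(a) for a in self.trial_aucs],
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "fpr_grid": [float(v) for v in self.fpr_grid],
            "mean_tpr": [float(v) for v in self.mean_tpr],
        }


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Integer subset sizes summing to n; remainders win in ratio order."""
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(v)) for v in raw]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def random_split(n: int, labels: np.ndarray, config: SplitConfig, trial: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets for one trial.

    The per-trial seed is base_seed + trial.  With stratification (default)
    the largest-remainder rounding is applied within each class, so no class
    can vanish from the training subset.
    """
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(config.base_seed + trial)
    parts: list[list[np.ndarray]] = [[], [], []]
    if config.stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            sizes = _largest_remainder(len(idx), config.ratios)
            pos = 0
            for part, size in zip(parts, sizes):
                part.append(idx[pos: pos + size])
                pos += size
    else:
        for attempt in range(100):
            idx = rng.permutation(n)
            sizes = _largest_remainder(n, config.ratios)
            cand = [idx[:sizes[0]], idx[sizes[0]:sizes[0] + sizes[1]],
                    idx[sizes[0] + sizes[1]:]]
            if len(np.unique(labels[cand[0]])) == len(np.unique(labels)):
                parts = [[c] for c in cand]
                break
            warnings.warn(f"trial {trial}: redrew split missing a train class")
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a class-complete split")
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return train, val, test


def roc_and_auc(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoid AUC.

    Returns (fpr, tpr, auc).  The trapezoid AUC equals the rank-sum
    concordance statistic with ties counted 1/2.
    """
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def average_roc(trials: list[tuple[np.ndarray, np.ndarray]],
                grid_step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Vertical averaging: step-interpolate each trial's TPR onto a common
    FPR grid and take the pointwise mean."""
    if not trials:
        raise ValueError("need at least one trial curve")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    stack = []
    for fpr, tpr in trials:
        pos = np.searchsorted(fpr, grid, side="right") - 1
        stack.append(tpr[np.clip(pos, 0, len(tpr) - 1)])
    return grid, np.mean(stack, axis=0)


def summarize_trials(trial_aucs: np.ndarray, fpr_grid: np.ndarray,
                     mean_tpr: np.ndarray, confusion: np.ndarray) -> ROCSummary:
    """Mean AUC with 95% percentile CI and the Youden-J operating point."""
    trial_aucs = np.asarray(trial_aucs, float)
    if trial_aucs.size < 2:
        raise ValueError("need at least 2 trials for a confidence interval")
    lo, hi = np.percentile(trial_aucs, [2.5, 97.5])
    j = mean_tpr - fpr_grid
    at = int(np.argmax(j))
    return ROCSummary(
        fpr_grid=fpr_grid, mean_tpr=mean_tpr, trial_aucs=trial_aucs,
        auc_mean=float(trial_aucs.mean()), auc_ci=(float(lo), float(hi)),
        sensitivity=float(mean_tpr[at]), specificity=float(1.0 - fpr_grid[at]),
        confusion=confusion,
    )


@dataclass
class PipelineResult:
    summary: ROCSummary
    selection: "object"                      # SelectionResult
    trials: pd.DataFrame                     # per-trial AUC + confusion
    config: dict = field(default_factory=dict)


def run_pipeline(table: FeatureTable, config: SplitConfig | None = None,
                 k: int = 20, prune_threshold: float = 0.85, bins: int = 4,
                 selection_inside_trial: bool = False,
                 goal: float = 1e-3, max_epochs: int = 1000,
                 hidden: tuple[int, ...] = (10, 7, 5),
                 out_dir=None) -> PipelineResult:
    """End-to-end evaluation: select features, then repeated split/train/test.

    ``table`` is an assembled (un-normalized) FeatureTable.  Selection runs
    once on the full table unless ``selection_inside_trial``.  Per-trial the
    network seed is base_seed + 10000 + trial, the split seed base_seed +
    trial, so the whole summary is reproducible bit for bit from base_seed.
    """
    config = config or SplitConfig()
    n = table.n_subjects
    labels = table.labels
    reduced, sel_result = select_features(table, k=k, threshold=prune_threshold,
                                          bins=bins)
    curves, aucs, rows = [], [], []
    confusion = np.zeros((2, 2), dtype=int)
    for trial in range(config.n_trials):
        tr, va, te = random_split(n, labels, config, trial)
        if selection_inside_trial:
            sub = table.copy()
            sub.data = table.data.iloc[tr]
            sub.labels = labels[tr]
            sub.meta = None
            trial_reduced, _ = select_features(sub, k=k,
                                               threshold=prune_threshold,
                                               bins=bins)
            cols = list(trial_reduced.data.columns)
            norm_full = normalize_table(table)
            X_all = norm_full.data[cols].to_numpy(float)
        else:
            X_all = reduced.data.to_numpy(float)
        T_all = encode_targets(labels)
        net = init_network(config.base_seed + 10_000 + trial,
                           (X_all.shape[1],) + tuple(hidden) + (2,))
        net, rec = train_levenberg_marquardt(
            net, (X_all[tr], T_all[tr]), (X_all[va], T_all[va]),
            goal=goal, max_epochs=max_epochs)
        scores, pred = score_and_classify(net, X_all[te])
        fpr, tpr, auc = roc_and_auc(scores, labels[te])
        curves.append((fpr, tpr))
        aucs.append(auc)
        for yt, yp in zip(labels[te], pred):
            confusion[yt, yp] += 1
        rows.append({"trial": trial, "auc": auc, "epochs": rec.epochs_run,
                     "stop_reason": rec.stop_reason,
                     "test_correct": int((pred == labels[te]).sum()),
                     "test_n": len(te)})
    grid, mean_tpr = average_roc(curves)
    summary = summarize_trials(np.array(aucs), grid, mean_tpr, confusion)
    trials_df = pd.DataFrame(rows)
    cfg = {"ratios": list(config.ratios), "n_trials": config.n_trials,
           "stratified": config.stratified, "base_seed": config.base_seed,
           "k": k, "prune_threshold": prune_threshold, "bins": bins,
           "selection_inside_trial": selection_inside_trial,
           "hidden": list(hidden), "goal": goal, "max_epochs": max_epochs}
    result = PipelineResult(summary=summary, selection=sel_result,
                            trials=trials_df, config=cfg)
    if out_dir is not None:
        persist_result(result, out_dir)
    return result


def persist_result(result: PipelineResult, out_dir) -> None:
    """Write summary.json, trials.csv, roc_mean.csv and the selection report."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    payload = {"summary": result.summary.to_dict(), "config": result.config}
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    result.trials.to_csv(os.path.join(out_dir, "trials.csv"), index=False)
    pd.DataFrame({"fpr": result.summary.fpr_grid,
                  "tpr": result.summary.mean_tpr}).to_csv(
        os.path.join(out_dir, "roc_mean.csv"), index=False)
    with open(os.path.join(out_dir, "selection.json"), "w") as fh:
        json.dump(result.selection.to_dict(), fh, indent=2, sort_keys=True)
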