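"""Model-object interface to the radiomic classification pipeline.

`RadiomicClassifier` wraps the full workflow — feature normalization,
correlation pruning, mRMR selection and the repeated-split evaluation of the
Levenberg-Marquardt-trained tanh network — behind a familiar model/results
pair: build the model from a feature table (or cohort), call ``fit()``, and
read estimates and diagnostics off the returned results object.

Example
-------
>>> from radiotexnet import synthetic, features, RadiomicClassifier
>>> cohort = synthetic.generate_cohort(10, 10, seed=7)
>>> table = features.assemble_feature_table(cohort, ng_list=(16, 32))
>>> res = RadiomicClassifier(table).fit(n_trials=10, base_seed=7)
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import PipelineResult, ROCSummary, SplitConfig, run_pipeline
from .features import FeatureTable


class RadiomicClassifier:
    """Two-class radiomic classifier evaluated by repeated random splits.

    Parameters
    ----------
    table:
        Assembled (un-normalized) cohort feature table with binary labels.
    n_selected:
        Number of features retained by the mRMR stage (default 20).
    prune_threshold:
        |Pearson| threshold above which one member of a feature pair is
        pruned before mRMR (default 0.85).
    mi_bins:
        Equal-frequency bins for the plug-in mutual-information estimates.
    hidden:
        Hidden-layer widths of the tanh network (default (10, 7, 5)).
    """

    def __init__(self, table: FeatureTable, n_selected: int = 20,
                 prune_threshold: float = 0.85, mi_bins: int = 4,
                 hidden: tuple[int, ...] = (10, 7, 5)):
        self.table = table
        self.n_selected = n_selected
        self.prune_threshold = prune_threshold
        self.mi_bins = mi_bins
        self.hidden = tuple(hidden)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, labels, **kwargs
                       ) -> "RadiomicClassifier":
        """Build directly from a subjects x features DataFrame and 0/1 labels."""
        return cls(FeatureTable(data, np.asarray(labels, int)), **kwargs)

    @classmethod
    def from_subjects(cls, subjects, ng_list=(16, 32, 64, 96), kernel="db1",
                      include_clinical: bool = True, **kwargs
                      ) -> "RadiomicClassifier":
        """Extract features from (volume, mask, clinical, label) subjects."""
        from .features import assemble_feature_table

        table = assemble_feature_table(subjects, ng_list=ng_list, kernel=kernel,
                                       include_clinical=include_clinical)
        return cls(table, **kwargs)

    def fit(self, n_trials: int = 30, ratios=(0.70, 0.15, 0.15),
            base_seed: int = 0, stratified: bool = True,
            selection_inside_trial: bool = False, goal: float = 1e-3,
            max_epochs: int = 1000, out_dir=None
            ) -> "RadiomicClassifierResults":
        """Run the repeated split/train/test evaluation and summarize it."""
        config = SplitConfig(ratios=tuple(ratios), n_trials=n_trials,
                             stratified=stratified, base_seed=base_seed)
        result = run_pipeline(
            self.table, config, k=self.n_selected,
            prune_threshold=self.prune_threshold, bins=self.mi_bins,
            selection_inside_trial=selection_inside_trial, goal=goal,
            max_epochs=max_epochs, hidden=self.hidden, out_dir=out_dir)
        return RadiomicClassifierResults(self, result)


@dataclass
class RadiomicClassifierResults:
    """Fit results: trial AUCs, averaged ROC, operating point and selection."""

    model: RadiomicClassifier
    pipeline: PipelineResult

    @property
    def roc(self) -> ROCSummary:
        return self.pipeline.summary

    @property
    def auc_mean(self) -> float:
        return self.pipeline.summary.auc_mean

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self.pipeline.summary.auc_ci

    @property
    def sensitivity(self) -> float:
        return self.pipeline.summary.sensitivity

    @property
    def specificity(self) -> float:
        return self.pipeline.summary.specificity

    @property
    def trial_aucs(self) -> np.ndarray:
        return self.pipeline.summary.trial_aucs

    @property
    def confusion(self) -> np.ndarray:
        return self.pipeline.summary.confusion

    @property
    def selected_features(self) -> list[str]:
        return list(self.pipeline.selection.selected)

    def summary(self) -> str:
        """Human-readable fit summary in the style of a model results table."""
        s = self.pipeline.summary
        cfg = self.pipeline.config
        lines = [
            "Radiomic two-class classifier - repeated-split evaluation",
            "=" * 60,
            f"subjects: {self.model.table.n_subjects}   "
            f"features: {self.model.table.n_features}   "
            f"selected: {len(self.selected_features)}",
            f"trials: {cfg['n_trials']}   split: "
            f"{'/'.join(f'{r:.0%}' for r in cfg['ratios'])}   "
            f"base_seed: {cfg['base_seed']}",
            "-" * 60,
            f"mean test AUC: {s.auc_mean:.3f}   "
            f"95% CI: [{s.auc_ci[0]:.3f}, {s.auc_ci[1]:.3f}]",
            f"operating point (max Youden J): sensitivity {s.sensitivity:.3f}, "
            f"specificity {s.specificity:.3f}",
            f"pooled test confusion [[TN, FP], [FN, TP]]: "
            f"{s.confusion.tolist()}",
            "-" * 60,
            "top selected features (by |corr| with target):",
        ]
        rel = self.pipeline.selection.relevance
        for name in self.selected_features[:10]:
            lines.append(f"  {rel[name]:+.3f}  {name}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Averaged ROC curve with the operating point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.pipeline.summary
        ax.plot(s.fpr_grid, s.mean_tpr,
                label=f"mean ROC (AUC={s.auc_mean:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(1 - s.specificity, s.sensitivity, "ro",
                label="operating point")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    def save(self, out_dir) -> None:
        from .evaluation import persist_result

        persist_result(self.pipeline, out_dir)
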