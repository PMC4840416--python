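"""Protocol sweep: all (top-k residues, component combo, pose strategy)
model-construction protocols on one dataset, plus the docking-score baseline
comparison.

For each protocol the sweep ranks residues on the training inhibitors,
builds the feature matrix, half-splits it, grid-searches (c, gamma), refits
at the best cell and evaluates the held-out half (confusion metrics, ROC
AUC, TPR at 1% FPR).  With the default three k values, five component
combinations and two pose strategies this produces the 30-model report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResidueEnergyTable
from .miec import (
    K_VALUES,
    POSE_STRATEGIES,
    COMBOS,
    build_matrix,
    enumerate_protocols,
    rank_residues,
    select_top_k,
)
from .modeling import (
    GridConfig,
    TrainConfig,
    MIECSVMClassifier,
    inflection_point,
    metrics_from_predictions,
    roc_from_scores,
    stratified_half_split,
)

__all__ = ["ProtocolSweepReport", "run_protocol_sweep", "compare_to_baseline"]


@dataclass
class ProtocolSweepReport:
    """Per-protocol selection results and test metrics."""

    rows: pd.DataFrame
    grids: dict[tuple[int, str, str], pd.DataFrame]

    def __len__(self) -> int:
        return len(self.rows)


def run_protocol_sweep(
    tables_by_strategy: dict[str, list[ResidueEnergyTable]],
    labels,
    train_cfg: TrainConfig,
    grid_cfg: GridConfig | None = None,
    k_values: tuple[int, ...] = K_VALUES,
    combos: tuple[str, ...] = tuple(COMBOS),
) -> ProtocolSweepReport:
    """Evaluate every protocol on per-strategy energy tables.

    ``tables_by_strategy`` maps each pose strategy name to one energy table
    per sample (same sample order as ``labels``).  Residue rankings are
    recomputed per strategy from that strategy's inhibitor tables.
    """
    labels = np.asarray(labels, dtype=int)
    if grid_cfg is None:
        grid_cfg = GridConfig()
    strategies = tuple(tables_by_strategy)
    protocols = enumerate_protocols(k_values, combos, strategies)

    rankings = {
        strat: rank_residues(
            [t for t, lab in zip(tables, labels) if lab == 1]
        )
        for strat, tables in tables_by_strategy.items()
    }

    rows = []
    grids: dict[tuple[int, str, str], pd.DataFrame] = {}
    for k, combo, strategy in protocols:
        residue_ids = select_top_k(rankings[strategy], k)
        matrix = build_matrix(
            tables_by_strategy[strategy], labels, residue_ids, combo
        )
        train, test = stratified_half_split(matrix, train_cfg)
        clf = MIECSVMClassifier(
            grid=grid_cfg,
            cv_folds=train_cfg.cv_folds,
            positive_class_weight=train_cfg.positive_class_weight,
            random_state=train_cfg.seed,
        )
        clf.fit(train.features, train.labels)

        proba = clf.inhibitor_probability(test.features)
        roc = roc_from_scores(proba, test.labels)
        n_neg = int(np.sum(test.labels == -1))
        metrics = metrics_from_predictions(test.labels, clf.predict(test.features))
        rows.append(
            {
                "k": k,
                "combo": combo,
                "pose_strategy": strategy,
                "n_features": matrix.features.shape[1],
                "best_c_exp": clf.best_c_exp_,
                "best_gamma_exp": clf.best_gamma_exp_,
                "cv_mcc": clf.best_mcc_,
                "test_TP": metrics.TP,
                "test_FP": metrics.FP,
                "test_TN": metrics.TN,
                "test_FN": metrics.FN,
                "test_SE": metrics.SE,
                "test_SP": metrics.SP,
                "test_MCC": metrics.MCC,
                "test_AUC": roc.auc,
                "inflection_TPR": inflection_point(roc, n_neg),
            }
        )
        grids[(k, combo, strategy)] = clf.grid_result_.to_frame()

    return ProtocolSweepReport(rows=pd.DataFrame(rows), grids=grids)


def compare_to_baseline(
    probabilities, docking_scores, labels
) -> pd.DataFrame:
    """AUC and 1%-FPR inflection: SVM probabilities vs docking-score ranking.

    Docking scores rank lower-is-better, so they enter the ROC negated.
    """
    labels = np.asarray(labels, dtype=int)
    n_neg = int(np.sum(labels == -1))
    rows = []
    for name, scores in (
        ("miec_svm", np.asarray(probabilities, dtype=float)),
        ("docking", -np.asarray(docking_scores, dtype=float)),
    ):
        roc = roc_from_scores(scores, labels)
        rows.append(
            {
                "method": name,
                "AUC": roc.auc,
                "inflection_TPR": inflection_point(roc, n_neg),
            }
        )
    return pd.DataFrame(rows)
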