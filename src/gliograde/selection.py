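"""Random-forest importance ranking with backward feature elimination.

The default battery reduction mirrors the study design: sub-visual features
are eliminated in two sequential stages (171 -> 50 -> 15), visual features in
one stage (24 -> 11), and the Ki-67 proliferative index is exempt from
elimination — it is a fixed IHC characteristic that always enters the model
table, giving 11 + 15 + 1 = 27 model features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from gliograde.features import (
    KI67_FEATURE_NAME,
    SUBVISUAL_FEATURE_NAMES,
    VISUAL_FEATURE_NAMES,
)

logger = logging.getLogger(__name__)

DEFAULT_FOREST_SIZE = 500
DEFAULT_DROP_FRACTION = 0.2
#: default battery targets: sub-visual two-stage 171 -> 50 -> 15; visual 24 -> 11
SUBVISUAL_STAGE_TARGETS = (50, 15)
VISUAL_TARGET = 11


@dataclass
class ImportanceRanking:
    scores: pd.Series          # feature name -> normalized importance, sums to 1
    forest_size: int
    seed: int

    def ordered(self) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index)


@dataclass
class SelectionResult:
    selected: list[str]
    elimination_trace: list[dict] = field(default_factory=list)
    target_count: int = 0


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; importance ranking needs >= 2 classes")


def rank_importance(table: pd.DataFrame, columns: list[str] | None = None,
                    seed: int = 0, forest_size: int = DEFAULT_FOREST_SIZE,
                    label_column: str = "grade",
                    max_features="sqrt") -> ImportanceRanking:
    """Mean-impurity-decrease importances from a random forest, normalized to sum 1.

    ``max_features`` follows the forest's split-candidate subsampling;
    ``None`` considers every feature at every split, which makes importance
    split cleanly between duplicated columns (useful for audits).
    """
    columns = list(columns) if columns is not None else [
        c for c in table.columns if c not in ("case_id", label_column)
    ]
    X, y = table[columns], table[label_column].to_numpy()
    _check_xy(X, y)
    rf = RandomForestClassifier(n_estimators=forest_size, random_state=seed,
                                max_features=max_features, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return ImportanceRanking(pd.Series(imp, index=columns), forest_size, seed)


def backward_eliminate(table: pd.DataFrame, columns: list[str],
                       target_count: int, drop_fraction: float = DEFAULT_DROP_FRACTION,
                       cv_folds: int = 5, seed: int = 0,
                       forest_size: int = DEFAULT_FOREST_SIZE,
                       label_column: str = "grade") -> SelectionResult:
    """Iteratively drop the least-important features until ``target_count`` remain.

    Each round re-ranks the surviving features with a fresh forest and drops
    the lowest ``ceil(drop_fraction * current)`` of them, capped so the count
    never undershoots the target; the stratified CV accuracy of the surviving
    set is recorded in the trace (set ``cv_folds=0`` to skip scoring).
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    columns = list(columns)
    if target_count >= len(columns):
        if target_count > len(columns):
            logger.warning("target_count %d exceeds the %d available features; "
                           "keeping all", target_count, len(columns))
        return SelectionResult(columns, [], target_count)

    y = table[label_column].to_numpy()
    current = columns
    trace: list[dict] = []
    round_no = 0
    ranking = None
    while len(current) > target_count:
        round_no += 1
        ranking = rank_importance(table, current, seed=seed + round_no,
                                  forest_size=forest_size, label_column=label_column)
        ordered = ranking.ordered()
        n_drop = min(math.ceil(drop_fraction * len(current)),
                     len(current) - target_count)
        dropped = ordered[len(ordered) - n_drop:]
        current = [c for c in current if c not in dropped]
        entry = {"round": round_no, "dropped": dropped, "n_remaining": len(current)}
        if cv_folds:
            # folds cannot exceed the smallest class on small cohorts
            folds = max(2, min(cv_folds, int(np.unique(y, return_counts=True)[1].min())))
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
            entry["cv_accuracy"] = float(
                cross_val_score(rf, table[current], y, cv=cv).mean()
            )
        trace.append(entry)
    # final trim by last-round importance ranking (no-op when counts already match)
    if len(current) > target_count:
        ranking = rank_importance(table, current, seed=seed + round_no + 1,
                                  forest_size=forest_size, label_column=label_column)
        keep = set(ranking.ordered()[:target_count])
        current = [c for c in current if c in keep]
    return SelectionResult(current, trace, target_count)


def select_paper_battery(table: pd.DataFrame, seed: int = 0,
                         subvisual_stage_targets=SUBVISUAL_STAGE_TARGETS,
                         visual_target: int = VISUAL_TARGET,
                         forest_size: int = DEFAULT_FOREST_SIZE,
                         cv_folds: int = 5,
                         label_column: str = "grade") -> dict:
    """Run the default battery reduction on a full 196-feature table.

    Returns a dict with the selected visual (11) and sub-visual (15) feature
    names, the elimination traces, and the 27-feature model table (selected
    columns + Ki-67 + label).
    """
    sub_cols = list(SUBVISUAL_FEATURE_NAMES)
    sub_trace = []
    for stage, target in enumerate(subvisual_stage_targets):
        res = backward_eliminate(table, sub_cols, target_count=target,
                                 seed=seed + 1000 * stage, forest_size=forest_size,
                                 cv_folds=cv_folds, label_column=label_column)
        sub_cols = res.selected
        sub_trace.extend({**e, "stage": stage + 1} for e in res.elimination_trace)

    vis_res = backward_eliminate(table, list(VISUAL_FEATURE_NAMES),
                                 target_count=visual_target, seed=seed + 5000,
                                 forest_size=forest_size, cv_folds=cv_folds,
                                 label_column=label_column)

    model_columns = vis_res.selected + sub_cols + [KI67_FEATURE_NAME]
    keep = [c for c in ("case_id", label_column) if c in table.columns]
    model_table = table[keep + model_columns].copy()
    return {
        "visual_selected": vis_res.selected,
        "subvisual_selected": sub_cols,
        "visual_trace": vis_res.elimination_trace,
        "subvisual_trace": sub_trace,
        "model_columns": model_columns,
        "model_table": model_table,
    }
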