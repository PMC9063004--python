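"""Random-forest Gini-importance ranking of delta features.

A 500-tree classification forest (bootstrap per tree, Gini split
criterion) is trained to predict responder status from the delta table;
features are ranked by mean decrease in Gini impurity and the top two are
carried into internal validation. Rows are sorted by patient id before
fitting, so the ranking depends on the data, not on storage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .delta import DeltaFeatureTable

log = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
POSITIVE_LABEL = "RS"


@dataclass
class ImportanceRanking:
    """Per-feature mean decrease in Gini, sorted descending."""

    importances: pd.Series  # index: feature name, sorted
    n_trees: int
    seed: int
    oob_score: float | None = None

    @property
    def ranked_features(self) -> List[str]:
        return list(self.importances.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.importances.index,
                "mean_decrease_gini": self.importances.values,
                "rank": np.arange(1, len(self.importances) + 1),
            }
        )


def rank_by_gini(
    table: DeltaFeatureTable,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_features: int | None = None,
) -> ImportanceRanking:
    """Rank delta features by random-forest Gini importance.

    Conventional forest defaults: ``floor(sqrt(p))`` candidate features per
    split, unlimited depth, minimum node size 1, out-of-bag error recorded.
    Ties in importance break lexicographically by feature name.
    """
    clean = table.dropna()
    y = (clean.labels == POSITIVE_LABEL).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both response classes are required")
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need >= 2 patients per class")
    X = clean.data.sort_index()
    y = (clean.labels.loc[X.index] == POSITIVE_LABEL).to_numpy().astype(int)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need >= 2 features")
    if max_features is None:
        max_features = int(np.floor(np.sqrt(p)))
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=max_features,
        min_samples_leaf=1,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X.to_numpy(), y)
    imp = pd.Series(rf.feature_importances_, index=X.columns)
    order = sorted(imp.index, key=lambda name: (-imp[name], name))
    return ImportanceRanking(
        importances=imp.loc[order],
        n_trees=n_trees,
        seed=seed,
        oob_score=float(rf.oob_score_),
    )


def select_top_k(ranking: ImportanceRanking, k: int = 2) -> List[str]:
    """First ``k`` feature names in rank order (ties already resolved)."""
    names = ranking.ranked_features
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} ranked features")
    imp = ranking.importances
    if len(names) > k and imp.iloc[k - 1] == imp.iloc[k]:
        log.info(
            "importance tie at the top-%d boundary; lexicographic tie-break", k
        )
    return names[:k]
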