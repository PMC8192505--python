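"""Random-forest feature fusion: concatenate, rank, select.

AG and BT feature matrices are concatenated column-wise, ranked by
random-forest importance against the training labels, and the top-k
(default 512) feature names form the fused AGBT fingerprint.  The
selector is fitted on training rows only and applied unchanged to
validation/test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor


@dataclass
class FeatureMatrix:
    """Named feature matrix with per-column provenance tag (AG or BT)."""

    data: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("feature names must be unique")
        missing = set(self.data.columns) - set(self.provenance)
        if missing:
            raise ValueError(f"columns without provenance: {sorted(missing)[:5]}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tag: str | None = None) -> "FeatureMatrix":
        """Wrap a DataFrame; provenance from ``tag`` or the ``AG::``/``BT::`` prefix."""
        if tag is not None:
            prov = {c: tag for c in df.columns}
        else:
            prov = {c: ("AG" if str(c).startswith("AG::") else "BT") for c in df.columns}
        return cls(df, prov)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def rows(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(ids)], dict(self.provenance))


@dataclass
class ImportanceRanking:
    """Features ordered by non-increasing normalized importance."""

    ranking: list[tuple[str, float]]
    rf_seed: int
    n_trees: int

    def __post_init__(self) -> None:
        scores = np.array([s for _, s in self.ranking])
        if np.any(scores < 0):
            raise ValueError("importance scores must be non-negative")
        if scores.size and not np.isclose(scores.sum(), 1.0):
            raise ValueError("importance scores must sum to 1")
        if np.any(np.diff(scores) > 1e-12):
            raise ValueError("ranking must be non-increasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ranking]


@dataclass
class FusedSelector:
    """Ordered list of selected feature names with AG/BT provenance counts."""

    selected: list[str]
    provenance_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("selector must keep at least one feature")

    @property
    def k(self) -> int:
        return len(self.selected)


def concat_features(ag: FeatureMatrix, bt: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation over an identical molecule-id set.

    Row order follows ``ag``; provenance tags are preserved.
    """
    ag_ids, bt_ids = set(ag.ids), set(bt.ids)
    if ag_ids != bt_ids:
        diff = sorted(ag_ids.symmetric_difference(bt_ids))
        raise ValueError(f"molecule id mismatch between AG and BT matrices: {diff}")
    overlap = set(ag.names) & set(bt.names)
    if overlap:
        raise ValueError(f"duplicate feature names: {sorted(overlap)[:5]}")
    joined = pd.concat([ag.data, bt.data.loc[ag.data.index]], axis=1)
    return FeatureMatrix(joined, {**ag.provenance, **bt.provenance})


def _infer_task(y: np.ndarray) -> str:
    return "classification" if set(np.unique(y)) <= {0.0, 1.0} else "regression"


def rank_importance(X: FeatureMatrix, y, n_trees: int = 500, rf_seed: int = 0,
                    importance: str = "impurity") -> ImportanceRanking:
    """Random-forest importance ranking of all features against ``y``.

    Mean-impurity-decrease by default; ``importance='permutation'`` uses
    permutation importance (clipped at zero).  Ties break
    lexicographically by feature name; deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != X.data.shape[0]:
        raise ValueError("label length does not match feature rows")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; importance is undefined")
    cls = RandomForestClassifier if _infer_task(y) == "classification" else RandomForestRegressor
    forest = cls(n_estimators=n_trees, random_state=rf_seed, n_jobs=1)
    forest.fit(X.data.to_numpy(), y)
    if importance == "impurity":
        scores = forest.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        result = permutation_importance(forest, X.data.to_numpy(), y,
                                        n_repeats=5, random_state=rf_seed, n_jobs=1)
        scores = np.clip(result.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance type {importance!r}")
    total = scores.sum()
    scores = scores / total if total > 0 else np.full_like(scores, 1.0 / len(scores))
    order = sorted(zip(X.names, scores), key=lambda kv: (-kv[1], kv[0]))
    return ImportanceRanking(order, rf_seed, n_trees)


def select_top_k(ranking: ImportanceRanking, k: int = 512,
                 provenance: dict[str, str] | None = None) -> FusedSelector:
    """First k names of the ranking (clamped to the number of features)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    selected = ranking.names[:min(k, len(ranking.ranking))]
    counts: dict[str, int] = {"AG": 0, "BT": 0}
    for name in selected:
        tag = (provenance or {}).get(name) or ("AG" if name.startswith("AG::") else "BT")
        counts[tag] = counts.get(tag, 0) + 1
    return FusedSelector(selected, counts)


def apply_selector(selector: FusedSelector, X: FeatureMatrix) -> FeatureMatrix:
    """Column subset in selector order; identical on train and test matrices."""
    missing = [n for n in selector.selected if n not in X.data.columns]
    if missing:
        raise ValueError(f"selected feature missing from matrix: {missing[0]!r}")
    sub = X.data[selector.selected]
    return FeatureMatrix(sub, {n: X.provenance[n] for n in selector.selected})


def fuse_fingerprints(ag: FeatureMatrix, bt: FeatureMatrix, y, k: int = 512,
                      n_trees: int = 500, rf_seed: int = 0) -> tuple[FusedSelector, FeatureMatrix]:
    """Convenience pipeline: concat -> rank -> select -> apply."""
    combined = concat_features(ag, bt)
    ranking = rank_importance(combined, y, n_trees=n_trees, rf_seed=rf_seed)
    selector = select_top_k(ranking, k, combined.provenance)
    return selector, apply_selector(selector, combined)
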