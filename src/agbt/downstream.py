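"""Splitting, model training, consensus ensembles, and evaluation.

Models: gradient-boosted trees and random forests (scikit-learn), and
single-task / multitask feed-forward networks.  Predictions are averaged
over an ensemble of seed-varied models (20 by default) to suppress
seed-to-seed variance.  Regression is scored by squared-Pearson R²,
RMSE and MAE; classification by accuracy and AUC-ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import roc_auc_score

from .nn import MLPConfig, MultiTaskMLP

CONSENSUS_SEEDS: tuple[int, ...] = tuple(range(20))


# ---------------------------------------------------------------------------
# Splits

@dataclass
class SplitPlan:
    train: list[str]
    validation: list[str]
    test: list[str]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split partitions overlap")


def split_random(ids: Sequence[str], seed: int) -> SplitPlan:
    """Uniform 8:1:1 shuffle split; 10 plans from seeds 0-9 form the repeat protocol."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("random 8:1:1 split needs at least 10 molecules")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(len(ids) * 0.8)
    n_val = int(len(ids) * 0.1)
    shuffled = [ids[i] for i in order]
    return SplitPlan(shuffled[:n_train], shuffled[n_train:n_train + n_val],
                     shuffled[n_train + n_val:], "random_811", seed)


def split_scaffold(ids: Sequence[str], smiles: Sequence[str]) -> SplitPlan:
    """Deterministic Bemis–Murcko scaffold split at 8:1:1.

    Molecules sharing a scaffold always land in the same partition:
    scaffold groups (largest first, ties by scaffold string) fill train
    to >=80%, then validation to >=10%, remainder test.
    """
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    groups: dict[str, list[str]] = {}
    for mol_id, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {mol_id!r}: {smi!r}")
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
        groups.setdefault(scaffold, []).append(mol_id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(ids)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for _, members in ordered:
        if len(train) < 0.8 * n:
            train += members
        elif len(val) < 0.1 * n:
            val += members
        else:
            test += members
    if not val or not test:
        raise ValueError("scaffold split degenerate: too few scaffold groups")
    return SplitPlan(train, val, test, "scaffold_811")


# ---------------------------------------------------------------------------
# Models

@dataclass
class ModelSpec:
    """Kind, hyperparameters, tasks and seed of one downstream model."""

    kind: str
    tasks: list[str] = field(default_factory=lambda: ["y"])
    task_types: dict[str, str] = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gbdt", "rf", "stdnn", "mtdnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "mtdnn" and len(self.tasks) < 2:
            raise ValueError("mtdnn requires at least 2 tasks")
        if self.kind != "mtdnn" and len(self.tasks) != 1:
            raise ValueError(f"{self.kind} takes exactly 1 task")

    def task_type(self, task: str) -> str:
        return self.task_types.get(task, "regression")

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.kind, list(self.tasks), dict(self.task_types),
                         dict(self.hyperparameters), seed)


class FittedModel:
    """A trained downstream model exposing per-task ``predict``."""

    def __init__(self, spec: ModelSpec, impl) -> None:
        self.spec = spec
        self.impl = impl

    def predict(self, X) -> dict[str, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("NaN in feature matrix")
        if isinstance(self.impl, MultiTaskMLP):
            out = self.impl.predict(X)
            return {t: out[:, j] for j, t in enumerate(self.spec.tasks)}
        task = self.spec.tasks[0]
        if self.spec.task_type(task) == "classification":
            return {task: self.impl.predict_proba(X)[:, 1]}
        return {task: self.impl.predict(X)}


def train_model(spec: ModelSpec, X, y_per_task: Mapping[str, np.ndarray],
                label_masks: Mapping[str, np.ndarray] | None = None,
                X_val=None, y_val_per_task: Mapping[str, np.ndarray] | None = None) -> FittedModel:
    """Fit one model; deterministic for a fixed spec seed.

    ``y_per_task`` maps task name to a label vector aligned with rows of
    ``X``; ``label_masks`` flags observed labels for multitask training.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    hp = spec.hyperparameters
    if spec.kind in ("gbdt", "rf"):
        task = spec.tasks[0]
        y = np.asarray(y_per_task[task], dtype=float)
        is_clf = spec.task_type(task) == "classification"
        n_estimators = hp.get("n_estimators", 500)
        if spec.kind == "gbdt":
            cls = GradientBoostingClassifier if is_clf else GradientBoostingRegressor
            impl = cls(n_estimators=n_estimators, random_state=spec.seed,
                       **{k: v for k, v in hp.items() if k != "n_estimators"})
        else:
            cls = RandomForestClassifier if is_clf else RandomForestRegressor
            impl = cls(n_estimators=n_estimators, random_state=spec.seed, n_jobs=1,
                       **{k: v for k, v in hp.items() if k != "n_estimators"})
        impl.fit(X, y.astype(int) if is_clf else y)
        return FittedModel(spec, impl)

    # stdnn / mtdnn
    cfg = MLPConfig(seed=spec.seed, **{k: v for k, v in hp.items()
                                       if k in MLPConfig.__dataclass_fields__ and k != "seed"})
    Y = np.column_stack([np.asarray(y_per_task[t], dtype=float) for t in spec.tasks])
    mask = None
    if label_masks is not None:
        mask = np.column_stack([np.asarray(label_masks[t], dtype=bool) for t in spec.tasks])
    Y_val = None
    if X_val is not None and y_val_per_task is not None:
        Y_val = np.column_stack([np.asarray(y_val_per_task[t], dtype=float)
                                 for t in spec.tasks])
    mlp = MultiTaskMLP(X.shape[1], [spec.task_type(t) for t in spec.tasks], cfg)
    mlp.fit(X, Y, label_mask=mask, X_val=X_val, Y_val=Y_val)
    return FittedModel(spec, mlp)


# ---------------------------------------------------------------------------
# Consensus

@dataclass
class ConsensusEnsemble:
    """Seed-varied copies of one model spec; prediction = arithmetic mean."""

    members: list[FittedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble has no members")
        kinds = {m.spec.kind for m in self.members}
        if len(kinds) != 1:
            raise ValueError("ensemble members must share a model spec")


def train_consensus(spec: ModelSpec, X, y_per_task, seeds: Sequence[int] = CONSENSUS_SEEDS,
                    **kwargs) -> ConsensusEnsemble:
    """Fit one model per seed (20 by default, seeds 0-19)."""
    return ConsensusEnsemble([train_model(spec.with_seed(s), X, y_per_task, **kwargs)
                              for s in seeds])


def consensus_predict(ensemble: ConsensusEnsemble, X) -> dict[str, np.ndarray]:
    """Mean of member predictions per task (probabilities for classification)."""
    per_member = [m.predict(X) for m in ensemble.members]
    return {task: np.mean([p[task] for p in per_member], axis=0)
            for task in per_member[0]}


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class MetricReport:
    """Evaluation bundle for one split.

    Regression: ``r_squared`` is the squared Pearson correlation (the
    shift/scale-invariant R² used throughout), with the coefficient of
    determination in ``extras``; plus RMSE and MAE.  Classification:
    accuracy at 0.5 and AUC-ROC.
    """

    task_type: str
    n: int
    r_squared: float | None = None
    rmse: float | None = None
    mae: float | None = None
    accuracy: float | None = None
    auc_roc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"task_type": self.task_type, "n": self.n, **self.extras}
        for key in ("r_squared", "rmse", "mae", "accuracy", "auc_roc"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out


def evaluate(pred, truth, task_type: str) -> MetricReport:
    """Score predictions against ground truth for one split."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-d arrays")
    if len(pred) < 2:
        raise ValueError("need at least 2 observations")
    if task_type == "regression":
        if np.std(truth) == 0 or np.std(pred) == 0:
            raise ValueError("zero-variance input: squared-Pearson R² undefined")
        r, _ = stats.pearsonr(pred, truth)
        rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        mae = float(np.mean(np.abs(pred - truth)))
        ss_res = float(np.sum((truth - pred) ** 2))
        ss_tot = float(np.sum((truth - truth.mean()) ** 2))
        return MetricReport("regression", len(pred), r_squared=float(r ** 2),
                            rmse=rmse, mae=mae,
                            extras={"coefficient_of_determination": 1.0 - ss_res / ss_tot})
    if task_type == "classification":
        labels = truth.astype(int)
        if len(np.unique(labels)) < 2:
            raise ValueError("single-class truth: AUC undefined")
        accuracy = float(np.mean((pred >= 0.5).astype(int) == labels))
        return MetricReport("classification", len(pred), accuracy=accuracy,
                            auc_roc=float(roc_auc_score(labels, pred)))
    raise ValueError(f"unknown task type {task_type!r}")
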