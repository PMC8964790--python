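"""Fatigue-state classification: random forest, Gini selection, GA tuning.

Two binary tasks are supported: non-fatigue (L1) vs. fatigue (L2+L3),
and moderate (L2) vs. severe (L3) fatigue. The estimator is a random
forest. Inside each outer cross-validation fold, features are ranked by
mean Gini impurity decrease on the training split, the top k are kept,
and the forest hyperparameters are tuned by a small genetic algorithm
(tournament selection, uniform crossover, per-gene mutation, elitism)
whose fitness is inner 3-fold cross-validated accuracy — outer test rows
never inform selection or tuning. Reported metrics are pooled over the
outer folds: accuracy, recall and F1 of the positive class (fatigue,
respectively severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "ClassifierConfig",
    "CvReport",
    "gini_rank_features",
    "ga_optimize",
    "crossvalidate",
]

#: hyperparameter search space: name -> tuple of allowed values
DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "n_estimators": (50, 100, 200),
    "max_depth": (2, 4, 8, None),
    "min_samples_leaf": (1, 2, 4),
    "max_features": (0.1, 0.3, "sqrt"),
}


@dataclass
class ClassifierConfig:
    """Settings for one classification task."""

    positive_class: str = "fatigue"
    n_features: int = 100
    search_space: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    population: int = 8
    generations: int = 5
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    cv_folds: int = 5
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for name, choices in self.search_space.items():
            if len(choices) < 1:
                raise ValueError(f"empty search space for {name!r}")


@dataclass
class CvReport:
    """Pooled cross-validation metrics and per-fold diagnostics."""

    accuracy: float
    recall: float
    f1: float
    fold_accuracies: tuple[float, ...]
    confusion: np.ndarray  # rows true, cols predicted, order (negative, positive)
    selected_features: tuple[tuple[str, ...], ...]  # per fold
    best_params: tuple[dict, ...]  # per fold
    seed: int


def gini_rank_features(X, y, names, seed: int = 0) -> tuple[str, ...]:
    """Feature names ordered by decreasing mean Gini impurity importance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 sessions per class")
    forest = RandomForestClassifier(n_estimators=200, random_state=seed)
    forest.fit(X, y)
    order = np.argsort(-forest.feature_importances_, kind="stable")
    return tuple(names[i] for i in order)


def _genome_fitness(genome: dict, X, y, config: ClassifierConfig, seed: int) -> float:
    model = RandomForestClassifier(random_state=seed, **genome)
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    return float(cross_val_score(model, X, y, cv=inner, scoring="accuracy").mean())


def ga_optimize(
    config: ClassifierConfig, X, y, seed: int | None = None
) -> tuple[dict, list[float]]:
    """Genetic search over the forest hyperparameter grid.

    Fitness is inner-CV accuracy on (X, y) — callers pass the training
    split only. Returns the best genome and the best-so-far fitness trace
    (non-decreasing by elitism).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    space = config.search_space
    keys = list(space)

    def random_genome() -> dict:
        return {k: space[k][rng.integers(len(space[k]))] for k in keys}

    cache: dict[tuple, float] = {}

    def fitness(genome: dict) -> float:
        key = tuple(genome[k] for k in keys)
        if key not in cache:
            cache[key] = _genome_fitness(genome, X, y, config, seed)
        return cache[key]

    population = [random_genome() for _ in range(config.population)]
    scores = [fitness(g) for g in population]
    best_idx = int(np.argmax(scores))
    best, best_score = dict(population[best_idx]), scores[best_idx]
    trace = [best_score]

    for _ in range(config.generations):
        new_pop = [dict(best)]  # elitism
        while len(new_pop) < config.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                a, b = rng.integers(len(population), size=2)
                parents.append(population[a] if scores[a] >= scores[b] else population[b])
            child = dict(parents[0])
            if rng.random() < config.crossover_rate:
                for k in keys:
                    if rng.random() < 0.5:
                        child[k] = parents[1][k]
            for k in keys:
                if rng.random() < config.mutation_rate:
                    child[k] = space[k][rng.integers(len(space[k]))]
            new_pop.append(child)
        population = new_pop
        scores = [fitness(g) for g in population]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best, best_score = dict(population[gen_best]), scores[gen_best]
        trace.append(best_score)
    return best, trace


def crossvalidate(X, y, names, config: ClassifierConfig) -> CvReport:
    """Stratified outer CV with in-fold Gini selection and GA tuning."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("crossvalidate expects a binary task")
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} sessions < {config.cv_folds} folds; "
            "reduce cv_folds"
        )
    if config.positive_class not in classes:
        raise ValueError(f"positive class {config.positive_class!r} absent from labels")
    name_idx = {n: i for i, n in enumerate(names)}
    outer = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    y_true_all, y_pred_all, fold_acc = [], [], []
    selected_all, params_all = [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        fold_seed = (config.seed * 1009 + fold) % (2**31)
        ranked = gini_rank_features(X[tr], y[tr], names, seed=fold_seed)
        keep = ranked[: config.n_features]
        cols = np.array([name_idx[n] for n in keep])
        best, _trace = ga_optimize(config, X[np.ix_(tr, cols)], y[tr], seed=fold_seed)
        model = RandomForestClassifier(random_state=fold_seed, **best)
        model.fit(X[np.ix_(tr, cols)], y[tr])
        pred = model.predict(X[np.ix_(te, cols)])
        y_true_all.extend(y[te])
        y_pred_all.extend(pred)
        fold_acc.append(float(np.mean(pred == y[te])))
        selected_all.append(tuple(keep))
        params_all.append(best)
    y_true_all = np.asarray(y_true_all)
    y_pred_all = np.asarray(y_pred_all)
    pos = config.positive_class
    neg = [c for c in classes if c != pos][0]
    cm = confusion_matrix(y_true_all, y_pred_all, labels=[neg, pos])
    tp = cm[1, 1]
    recall = tp / cm[1].sum() if cm[1].sum() else 0.0
    precision = tp / cm[:, 1].sum() if cm[:, 1].sum() else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return CvReport(
        accuracy=float(np.mean(y_true_all == y_pred_all)),
        recall=float(recall),
        f1=float(f1),
        fold_accuracies=tuple(fold_acc),
        confusion=cm,
        selected_features=tuple(selected_all),
        best_params=tuple(params_all),
        seed=config.seed,
    )
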