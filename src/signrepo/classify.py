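"""Per-disease classifier training, cross-validation, and candidate ranking.

A disease's training set labels its known drugs TRUE and a 3× larger random
sample of the remaining scoreable drugs FALSE.  Disease-gene columns that
are zero for every drug in the training set carry no association and are
dropped.  Random-forest and single-hidden-layer neural-network models are
tuned by an inner grid search and evaluated by 10-fold cross-validation
(AUC of the pooled out-of-fold probabilities); the whole procedure is
repeated with fresh negative samples, the best-AUC classifier(s) kept, and
unknown drugs ranked by their mean TRUE-probability over the tied-best
classifiers that predicted them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "ClassifierResult",
    "RepeatResult",
    "PredictionRecord",
    "MODEL_KINDS",
    "filter_eligible_diseases",
    "build_training_set",
    "cross_validate",
    "repeat_and_select",
    "predict_candidates",
    "read_known_associations",
    "write_predictions",
]

MODEL_KINDS = ("random_forest", "neural_network")

#: Hyperparameter grids emulating a self-tuning training harness:
#: random forest — 500 trees, features-per-split in {√p, p/3, p/2}, tuned by
#: out-of-bag AUC (the forest's built-in generalisation estimate, so tuning
#: costs one fit per grid point); neural network — one hidden layer, size in
#: {1, 3, 5}, weight decay in {0, 1e-4, 1e-1}, at most 500 iterations, tuned
#: by inner 5-fold AUC.
RF_GRID = ["sqrt", 1.0 / 3.0, 0.5]
NN_GRID = {"hidden_layer_sizes": [(1,), (3,), (5,)], "alpha": [0.0, 1e-4, 1e-1]}


class OOBTunedRandomForest:
    """500-tree random forest with max_features chosen by out-of-bag AUC.

    Ties break toward the first grid value.  Exposes the minimal estimator
    surface the cross-validation loop needs (fit / predict_proba).
    """

    def __init__(self, seed: int, grid=tuple(RF_GRID)):
        self.seed = seed
        self.grid = grid
        self.best_ = None
        self.best_max_features_ = None
        self.oob_aucs_ = {}

    def fit(self, X, y):
        best_auc = -np.inf
        for mf in self.grid:
            forest = RandomForestClassifier(
                n_estimators=500, max_features=mf,
                oob_score=True, random_state=self.seed,
            )
            _fit(forest, X, y)
            oob = forest.oob_decision_function_[:, 1]
            oob = np.nan_to_num(oob, nan=0.5)  # rows never out-of-bag
            auc = roc_auc_score(y, oob)
            self.oob_aucs_[mf] = float(auc)
            if auc > best_auc:
                best_auc, self.best_, self.best_max_features_ = auc, forest, mf
        return self

    def predict_proba(self, X):
        return self.best_.predict_proba(X)


@dataclass
class TrainingSet:
    """Labelled DV matrix for one disease (features × TRUE/FALSE labels)."""

    disease: str
    features: pd.DataFrame  # rows: drugs; columns: retained disease genes
    labels: np.ndarray      # bool, aligned with features rows
    seed: int


@dataclass
class ClassifierResult:
    """One repetition's cross-validated classifier."""

    model_kind: str
    auc: float
    repetition_index: int
    training_set: TrainingSet
    seed: int
    model_: object = field(default=None, repr=False)  # fitted handle, set on refit


@dataclass
class RepeatResult:
    disease: str
    model_kind: str
    mean_auc: float
    sd_auc: float
    best: list[ClassifierResult]
    aucs: list[float]


@dataclass(frozen=True)
class PredictionRecord:
    drug: str
    disease: str
    probability: float
    n_classifiers: int


def filter_eligible_diseases(
    associations: dict[str, set[str]],
    min_known: int = 10,
    scoreable_drugs: set[str] | None = None,
) -> list[str]:
    """Diseases with strictly more than ``min_known`` known drugs.

    Counts are restricted to scoreable drugs when a set is given.  Order is
    lexicographic for determinism.
    """
    out = []
    for disease in sorted(associations):
        known = associations[disease]
        if scoreable_drugs is not None:
            known = known & scoreable_drugs
        if len(known) > min_known:
            out.append(disease)
    return out


def build_training_set(
    matrix: pd.DataFrame,
    known_drugs: set[str],
    disease: str = "",
    *,
    ratio: int = 3,
    seed: int = 0,
) -> TrainingSet:
    """Label known drugs TRUE, sample ``ratio × |TRUE|`` negatives, and drop
    disease-gene columns that are all-zero over the sampled rows."""
    positives = sorted(set(matrix.index) & known_drugs)
    if not positives:
        raise ValueError(f"disease {disease!r}: no known drug is scoreable")
    pool = sorted(set(matrix.index) - known_drugs)
    n_neg = ratio * len(positives)
    rng = np.random.default_rng(seed)
    if len(pool) < n_neg:
        logger.warning(
            "disease %s: negative pool (%d) smaller than %dx positives (%d); "
            "using the whole pool", disease, len(pool), ratio, n_neg,
        )
        negatives = pool
    else:
        negatives = sorted(rng.choice(pool, size=n_neg, replace=False))
    rows = positives + list(negatives)
    features = matrix.loc[rows]
    nonzero = features.columns[(features != 0).any(axis=0)]
    features = features[nonzero]
    if features.shape[1] == 0:
        raise ValueError(
            f"disease {disease!r}: every disease-gene column is zero over "
            "the training rows; no feature remains"
        )
    labels = np.array([True] * len(positives) + [False] * len(negatives))
    return TrainingSet(disease=disease, features=features, labels=labels, seed=seed)


def _make_search(model_kind: str, seed: int, tune: bool):
    """Build the (possibly grid-searched) estimator for one fit."""
    if model_kind == "random_forest":
        if not tune:
            return RandomForestClassifier(n_estimators=500, random_state=seed)
        return OOBTunedRandomForest(seed)
    if model_kind == "neural_network":
        base = MLPClassifier(max_iter=500, solver="lbfgs", random_state=seed)
        if not tune:
            return base
        inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        return GridSearchCV(base, NN_GRID, scoring="roc_auc", cv=inner, n_jobs=1)
    raise ValueError(f"unknown model kind: {model_kind!r}")


def _fit(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny folds trigger convergence chatter
        est.fit(X, y)
    return est


def cross_validate(
    ts: TrainingSet,
    model_kind: str,
    *,
    folds: int = 10,
    seed: int = 0,
    repetition_index: int = 0,
    tune: bool = True,
) -> ClassifierResult:
    """Stratified k-fold cross-validation of one model on one training set.

    Each outer fold fits a (tuned) model on the remaining folds and scores
    the held-out drugs; the AUC is computed once from the pooled held-out
    TRUE-probabilities, which is stable under the 1:3 class imbalance.
    """
    y = ts.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    X = ts.features.to_numpy(dtype=float)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.empty(len(y), dtype=float)
    for train_idx, test_idx in outer.split(X, y):
        est = _make_search(model_kind, seed, tune)
        _fit(est, X[train_idx], y[train_idx])
        proba[test_idx] = est.predict_proba(X[test_idx])[:, 1]
    auc = float(roc_auc_score(y, proba))
    return ClassifierResult(
        model_kind=model_kind, auc=auc, repetition_index=repetition_index,
        training_set=ts, seed=seed,
    )


def repeat_and_select(
    matrix: pd.DataFrame,
    known_drugs: set[str],
    model_kind: str,
    *,
    disease: str = "",
    repetitions: int = 100,
    base_seed: int = 0,
    folds: int = 10,
    ratio: int = 3,
    tune: bool = True,
) -> RepeatResult:
    """Repeat negative sampling + cross-validation; keep ALL tied-best
    classifiers and the mean AUC over repetitions."""
    results = []
    for rep in range(repetitions):
        seed = base_seed + rep
        ts = build_training_set(matrix, known_drugs, disease,
                                ratio=ratio, seed=seed)
        results.append(
            cross_validate(ts, model_kind, folds=folds, seed=seed,
                           repetition_index=rep, tune=tune)
        )
    aucs = [r.auc for r in results]
    top = max(aucs)
    best = [r for r in results if r.auc == top]
    return RepeatResult(
        disease=disease, model_kind=model_kind,
        mean_auc=float(np.mean(aucs)), sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        best=best, aucs=aucs,
    )


def refit_best(result: ClassifierResult, *, tune: bool = True) -> ClassifierResult:
    """Refit the repetition's model on its full training set for prediction."""
    ts = result.training_set
    est = _make_search(result.model_kind, result.seed, tune)
    _fit(est, ts.features.to_numpy(dtype=float), ts.labels)
    result.model_ = est
    return result


def predict_candidates(
    best: list[ClassifierResult],
    matrix: pd.DataFrame,
    known_drugs: set[str],
    disease: str = "",
    *,
    threshold: float = 0.5,
    mean_over: str = "exceeding",
    tune: bool = True,
) -> list[PredictionRecord]:
    """Score every unknown drug with each tied-best classifier.

    A drug becomes a candidate if at least one best classifier gives it
    TRUE-probability above the threshold; its reported probability is the
    mean over the best classifiers that predicted it (``mean_over ==
    "exceeding"``) or over all best classifiers (``"all"``).  Records are
    sorted by descending probability, then drug id.
    """
    if mean_over not in ("exceeding", "all"):
        raise ValueError("mean_over must be 'exceeding' or 'all'")
    unknown = sorted(set(matrix.index) - known_drugs)
    if not unknown:
        return []
    probs: dict[str, list[float]] = {d: [] for d in unknown}
    for res in best:
        if res.model_ is None:
            refit_best(res, tune=tune)
        cols = res.training_set.features.columns
        X = matrix.loc[unknown, cols].to_numpy(dtype=float)
        p = res.model_.predict_proba(X)[:, 1]
        for drug, pi in zip(unknown, p):
            probs[drug].append(float(pi))
    records = []
    for drug in unknown:
        p = probs[drug]
        exceeding = [x for x in p if x > threshold]
        if not exceeding:
            continue
        chosen = exceeding if mean_over == "exceeding" else p
        records.append(
            PredictionRecord(
                drug=drug, disease=disease,
                probability=float(np.mean(chosen)),
                n_classifiers=len(chosen),
            )
        )
    records.sort(key=lambda r: (-r.probability, r.drug))
    return records


# -- table I/O --------------------------------------------------------


def read_known_associations(path) -> dict[str, set[str]]:
    """Read ``drug_id  disease_id`` TSV into disease → known-drug sets."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["drug", "disease"], dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.disease, set()).add(r.drug)
    return out


def write_predictions(records: list[PredictionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tdisease_id\tprobability\tn_classifiers\n")
        for r in records:
            fh.write(f"{r.drug}\t{r.disease}\t{r.probability:.6f}\t{r.n_classifiers}\n")
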