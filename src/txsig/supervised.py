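"""Supervised engine: pairwise task construction, stratified splitting, RFE-CV
feature selection, fold-internal oversampling, the classifier grid, and
repeated / nested cross-validated evaluation with seven metrics.

Leakage discipline: scalers and oversamplers are fit inside each training fold
only; every fold's train/test index sets are recorded in an audit trail that
tests can verify mechanically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import (
    DEFAULT_CLASSIFIERS,
    DEFAULT_OVERSAMPLERS,
    METRIC_ORDER,
    ExpressionMatrix,
    GroupAnnotation,
    RunConfig,
    ValidationError,
)
from .oversample import oversample_training_fold

__all__ = [
    "BinaryTask",
    "ModelConfig",
    "EvaluationResult",
    "RfeSelection",
    "build_pairwise_tasks",
    "stratified_partition",
    "rfecv_select",
    "evaluate_model_grid",
    "nested_cv_evaluate",
    "default_model_configs",
    "load_default_grids",
    "assert_no_leakage",
]

#: Classifiers standardized (train-fold-fit z-scaling) before fitting.
SCALED_CLASSIFIERS = frozenset({"LR", "SVM", "KNN", "GP"})

#: RFE core estimators evaluated per the pipeline definition.
RFE_CORES = ("LR", "LDA", "SVM")


def make_classifier(classifier_id: str, seed: int, params: dict | None = None):
    """Instantiate a roster classifier by its Table-2 abbreviation."""
    params = dict(params or {})
    factories = {
        "LR": lambda: LogisticRegression(max_iter=2000, random_state=seed, **params),
        "LDA": lambda: LinearDiscriminantAnalysis(**params),
        "GNB": lambda: GaussianNB(**params),
        "SVM": lambda: SVC(random_state=seed, **params),
        "KNN": lambda: KNeighborsClassifier(**params),
        "DTC": lambda: DecisionTreeClassifier(random_state=seed, **params),
        "GP": lambda: GaussianProcessClassifier(random_state=seed, **params),
        "RF": lambda: RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 100), random_state=seed, **params),
        "BC": lambda: BaggingClassifier(random_state=seed, **params),
        "ETC": lambda: ExtraTreesClassifier(
            n_estimators=params.pop("n_estimators", 100), random_state=seed, **params),
        "GBC": lambda: GradientBoostingClassifier(random_state=seed, **params),
        "Dummy": lambda: DummyClassifier(strategy="stratified", random_state=seed),
    }
    if classifier_id not in factories:
        raise ValidationError(f"unknown classifier id {classifier_id!r}")
    return factories[classifier_id]()


def load_default_grids() -> dict[str, dict]:
    from importlib import resources

    with resources.files("txsig").joinpath("data/default_grids.yaml").open() as fh:
        return yaml.safe_load(fh) or {}


@dataclass(frozen=True)
class BinaryTask:
    """One one-vs-one comparison: 'A_vs_B' with A the positive (disease) class."""

    name: str
    positive: str
    negative: str
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    X: np.ndarray   # samples x genes
    y: np.ndarray   # labels in {positive, negative}

    def __post_init__(self) -> None:
        labels = set(np.unique(self.y))
        if labels != {self.positive, self.negative}:
            raise ValidationError(
                f"task {self.name}: labels {labels} do not match "
                f"{{{self.positive}, {self.negative}}}"
            )
        for lbl in (self.positive, self.negative):
            if (self.y == lbl).sum() == 0:
                raise ValidationError(f"task {self.name}: class {lbl!r} is empty")

    def subset_features(self, genes) -> "BinaryTask":
        genes = tuple(genes)
        idx = [self.gene_ids.index(g) for g in genes]
        return BinaryTask(self.name, self.positive, self.negative, genes,
                          self.sample_ids, self.X[:, idx], self.y)


@dataclass(frozen=True)
class ModelConfig:
    classifier: str
    oversampler: str
    grid: dict = field(default_factory=dict)

    @property
    def model_id(self) -> str:
        return f"{self.classifier}+{self.oversampler}"


@dataclass
class EvaluationResult:
    task: str
    config: ModelConfig
    scheme: str                     # repeated_kfold | nested_cv
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    selected_features: tuple[str, ...] = ()
    mlcps: float | None = None
    rank: int | None = None

    def row(self) -> dict:
        out = {"task": self.task, "model": self.config.model_id,
               "classifier": self.config.classifier,
               "oversampler": self.config.oversampler, "scheme": self.scheme}
        for m in METRIC_ORDER:
            out[f"{m}_mean"] = self.metrics_mean[m]
            out[f"{m}_sd"] = self.metrics_sd[m]
        out["mlcps"] = self.mlcps
        out["rank"] = self.rank
        out["selected_features"] = ",".join(self.selected_features)
        return out


@dataclass(frozen=True)
class RfeSelection:
    genes: tuple[str, ...]
    core: str
    cv_scores: dict[int, float]     # feature count -> mean CV F1
    low_score: bool


def default_model_configs(config: RunConfig | None = None) -> list[ModelConfig]:
    """Full roster cross: (11 named algorithms + Dummy) x 3 oversamplers = 36."""
    config = config or RunConfig()
    grids = dict(load_default_grids())
    grids.update(config.param_grids or {})
    out = []
    for clf in config.classifiers or DEFAULT_CLASSIFIERS:
        for ovs in config.oversamplers or DEFAULT_OVERSAMPLERS:
            out.append(ModelConfig(clf, ovs, grids.get(clf, {})))
    return out


def build_pairwise_tasks(x: ExpressionMatrix, annotation: GroupAnnotation,
                         task_order: tuple[str, ...] | None = None,
                         cv_folds: int | None = None) -> list[BinaryTask]:
    """One binary task per unordered class pair (one-vs-one decomposition).

    The positive class of each task is the earlier label in ``task_order``.
    The default order keeps the annotation's first-appearance order but moves
    ``Control`` last, so the canonical Control/BPS/DO annotation yields
    BPS_vs_Control, DO_vs_Control and BPS_vs_DO with the disease group positive.
    """
    labels = annotation.labels_for(x.sample_ids)
    groups = [g for g in annotation.groups() if (labels == g).sum() > 0]
    if len(groups) < 2:
        raise ValidationError("need >= 2 annotated groups for pairwise tasks")
    if cv_folds is not None:
        bad = [g for g in groups if (labels == g).sum() < 2 * cv_folds]
        if bad:
            raise ValidationError(
                f"group(s) too small to stratify {cv_folds} folds: {', '.join(bad)}"
            )
    if task_order is None:
        task_order = tuple(g for g in groups if g != "Control")
        if "Control" in groups:
            task_order += ("Control",)
    # earlier in task_order = positive (disease-of-interest) class
    priority = {g: i for i, g in enumerate(task_order)}
    tasks = []
    for a, b in itertools.combinations(groups, 2):
        pos, neg = (a, b) if priority.get(a, np.inf) <= priority.get(b, np.inf) else (b, a)
        mask = np.isin(labels, [a, b])
        sample_ids = tuple(s for s, m in zip(x.sample_ids, mask) if m)
        tasks.append(BinaryTask(
            f"{pos}_vs_{neg}", pos, neg, x.gene_ids, sample_ids,
            x.values[:, mask].T, labels[mask],
        ))
    return tasks


def stratified_partition(task: BinaryTask, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold test-index sets; deterministic given seed."""
    for lbl in (task.positive, task.negative):
        if (task.y == lbl).sum() < k:
            raise ValidationError(
                f"class {lbl!r} has fewer than k={k} samples; cannot stratify"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(task.X, task.y)]


# ---------------------------------------------------------------------------
# fold-level machinery


def _fit_and_score(classifier_id: str, params: dict, task_pos: str,
                   X_tr, y_tr, X_te, y_te, oversampler: str, seed: int,
                   average: str = "positive") -> dict[str, float]:
    """Train one fold (scale -> oversample -> fit) and score the seven metrics."""
    if classifier_id in SCALED_CLASSIFIERS:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    if oversampler != "none":
        X_tr, y_tr = oversample_training_fold(X_tr, y_tr, oversampler, seed)
    clf = make_classifier(classifier_id, seed, params)
    clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)

    pos = task_pos
    y_true_bin = (y_te == pos).astype(int)
    if hasattr(clf, "predict_proba"):
        pos_col = list(clf.classes_).index(pos)
        y_score = clf.predict_proba(X_te)[:, pos_col]
    elif hasattr(clf, "decision_function"):
        y_score = clf.decision_function(X_te)
        if list(clf.classes_).index(pos) == 0:
            y_score = -y_score
    else:
        raise ValidationError(
            f"classifier {classifier_id!r} exposes neither probabilities nor "
            "decision scores; ROC-AUC/Average Precision cannot be computed"
        )

    avg = "binary" if average == "positive" else average
    kw = {"pos_label": pos} if avg == "binary" else {}
    metrics = {
        "F1": f1_score(y_te, y_pred, average=avg, zero_division=0, **kw),
        "Accuracy": accuracy_score(y_te, y_pred),
        "Balanced Accuracy": balanced_accuracy_score(y_te, y_pred),
        "Precision": precision_score(y_te, y_pred, average=avg, zero_division=0, **kw),
        "Recall": recall_score(y_te, y_pred, average=avg, zero_division=0, **kw),
        "Average Precision": average_precision_score(y_true_bin, y_score),
        "ROC-AUC": (roc_auc_score(y_true_bin, y_score)
                    if len(np.unique(y_true_bin)) > 1 else np.nan),
    }
    # sklearn's average_precision_score can exceed 1.0 by float epsilon
    return {k: (float(v) if np.isnan(v) else float(np.clip(v, 0.0, 1.0)))
            for k, v in metrics.items()}


def _feature_importance(estimator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_)).ravel()
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_)
    raise ValidationError("RFE core estimator exposes no coefficients")


def rfecv_select(task: BinaryTask, config: RunConfig, seed: int,
                 low_score_threshold: float | None = None) -> RfeSelection:
    """Recursive feature elimination with CV-chosen feature count.

    Each of the core estimators (LR, LDA, linear SVM) eliminates one feature
    at a time from the full panel, scoring every feature count by stratified
    k-fold CV F1; the core with the highest peak score wins and its optimal
    feature set (never smaller than ``min_features``) is returned. If the best
    achievable CV score is below ``low_score_threshold`` the selection is
    flagged ``low_score`` and the floor-sized set is returned. The default
    threshold is the F1 of the trivial always-positive predictor plus 0.1
    (capped at 0.95), so the flag marks "no better than baseline" regardless
    of the class balance.
    """
    if task.X.shape[1] < config.min_features:
        raise ValidationError("panel smaller than min_features")
    if np.any(task.X.std(axis=0) == 0):
        raise ValidationError("all-constant feature in task matrix")
    if low_score_threshold is None:
        prevalence = float((task.y == task.positive).mean())
        all_positive_f1 = 2 * prevalence / (1 + prevalence)
        low_score_threshold = min(0.95, all_positive_f1 + 0.1)

    per_core = rfecv_select_per_core(task, config, seed)
    best = max(per_core.values(), key=lambda s: max(s.cv_scores.values()))
    peak = max(best.cv_scores.values())
    if peak < low_score_threshold:
        # floor behaviour: no informative signal, return the minimal set
        core_params = {"LR": {}, "LDA": {}, "SVM": {"kernel": "linear"}}
        floor_genes = best.genes if len(best.genes) == config.min_features else \
            _rfe_floor_genes(task, config, seed, best.core,
                             core_params[best.core])
        return RfeSelection(floor_genes, best.core, best.cv_scores, True)
    return best


def rfecv_select_per_core(task: BinaryTask, config: RunConfig,
                          seed: int) -> dict[str, RfeSelection]:
    """One RFE-CV selection per core estimator (LR, LDA, linear SVM)."""
    core_params = {"LR": {}, "LDA": {}, "SVM": {"kernel": "linear"}}
    return {core: _rfe_one_core(task, config, seed, core, core_params[core])
            for core in RFE_CORES}


def rfecv_select_per_fold(task: BinaryTask, config: RunConfig,
                          seed: int) -> list[RfeSelection]:
    """RFE-CV run inside each training fold of a stratified k-fold split."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    out = []
    for tr, _ in skf.split(task.X, task.y):
        sub = BinaryTask(task.name, task.positive, task.negative, task.gene_ids,
                         tuple(task.sample_ids[i] for i in tr),
                         task.X[tr], task.y[tr])
        out.append(rfecv_select(sub, config, seed))
    return out


#: CV repeats used inside RFE to stabilize both scores and elimination order.
RFE_CV_REPEATS = 3


def _rfe_step(task: BinaryTask, feats: list[int], core: str, params: dict,
              k: int, seed: int) -> tuple[float, np.ndarray]:
    """Score one feature set by repeated k-fold CV F1 and return the mean
    per-feature importance across the fold fits (|coef| on scaled data)."""
    rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=RFE_CV_REPEATS,
                                   random_state=seed)
    scores, importances = [], []
    for tr, te in rskf.split(task.X, task.y):
        X_tr, X_te = task.X[np.ix_(tr, feats)], task.X[np.ix_(te, feats)]
        scaler = StandardScaler().fit(X_tr)
        clf = make_classifier(core, seed, params)
        clf.fit(scaler.transform(X_tr), task.y[tr])
        pred = clf.predict(scaler.transform(X_te))
        scores.append(f1_score(task.y[te], pred, pos_label=task.positive,
                               zero_division=0))
        importances.append(_feature_importance(clf))
    return float(np.mean(scores)), np.mean(importances, axis=0)


def _rfe_one_core(task: BinaryTask, config: RunConfig, seed: int, core: str,
                  params: dict) -> RfeSelection:
    """Recursive elimination (step 1) for one core estimator.

    At each feature count the set is scored by repeated stratified CV and the
    feature with the lowest mean |coefficient| across fold fits is dropped
    (ties -> lowest index). The returned set maximizes mean CV F1, smaller
    sets winning ties, and never shrinks below min_features.
    """
    feats = list(range(task.X.shape[1]))
    cv_scores: dict[int, float] = {}
    sets: dict[int, list[int]] = {}
    while True:
        score, importance = _rfe_step(task, feats, core, params,
                                      config.cv_folds, seed)
        cv_scores[len(feats)] = score
        sets[len(feats)] = feats.copy()
        if len(feats) <= config.min_features:
            break
        drop = int(np.argmin(importance))
        feats = [f for i, f in enumerate(feats) if i != drop]
    best_count = min(
        (count for count in cv_scores
         if cv_scores[count] == max(cv_scores.values())),
    )
    genes = tuple(task.gene_ids[i] for i in sets[best_count])
    return RfeSelection(genes, core, cv_scores, False)


def _rfe_floor_genes(task: BinaryTask, config: RunConfig, seed: int, core: str,
                     params: dict) -> tuple[str, ...]:
    """The min_features-sized set at the end of the elimination path."""
    feats = list(range(task.X.shape[1]))
    while len(feats) > config.min_features:
        _, importance = _rfe_step(task, feats, core, params,
                                  config.cv_folds, seed)
        drop = int(np.argmin(importance))
        feats = [f for i, f in enumerate(feats) if i != drop]
    return tuple(task.gene_ids[i] for i in feats)


# ---------------------------------------------------------------------------
# evaluation schemes


def _aggregate(task: BinaryTask, cfg: ModelConfig, scheme: str,
               fold_metrics: list[dict[str, float]]) -> EvaluationResult:
    mean, sd = {}, {}
    for m in METRIC_ORDER:
        vals = np.array([fm[m] for fm in fold_metrics], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean[m] = float(vals.mean()) if vals.size else 0.0
        sd[m] = float(vals.std()) if vals.size else 0.0
    return EvaluationResult(task.name, cfg, scheme, mean, sd)


def evaluate_model_grid(task: BinaryTask, configs: list[ModelConfig],
                        config: RunConfig, seed: int,
                        audit: list | None = None) -> list[EvaluationResult]:
    """Repeated stratified k-fold evaluation of every model configuration.

    Per fold: scaler and oversampler fit on the training portion only, the
    classifier trained, and all seven metrics scored on the untouched test
    fold. Results aggregate mean +/- sd over n_repeats x k folds.
    """
    if not configs:
        raise ValidationError("no model configurations supplied")
    ss = np.random.SeedSequence([seed, 0x5EED])
    child_seeds = ss.generate_state(len(configs) * 2)
    results = []
    for ci, cfg in enumerate(configs):
        cv_seed = int(child_seeds[2 * ci] % (2 ** 31))
        fold_seed0 = int(child_seeds[2 * ci + 1] % (2 ** 31))
        rskf = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                       n_repeats=config.cv_repeats,
                                       random_state=cv_seed)
        fold_metrics = []
        for fi, (tr, te) in enumerate(rskf.split(task.X, task.y)):
            fm = _fit_and_score(cfg.classifier, {}, task.positive,
                                task.X[tr], task.y[tr], task.X[te], task.y[te],
                                cfg.oversampler, fold_seed0 + fi,
                                config.metric_average)
            fold_metrics.append(fm)
            if audit is not None:
                audit.append({"scheme": "repeated_kfold", "model": cfg.model_id,
                              "fold": fi, "train": sorted(map(int, tr)),
                              "test": sorted(map(int, te))})
        results.append(_aggregate(task, cfg, "repeated_kfold", fold_metrics))
    return results


def _grid_points(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def nested_cv_evaluate(task: BinaryTask, configs: list[ModelConfig],
                       config: RunConfig, seed: int,
                       audit: list | None = None) -> list[EvaluationResult]:
    """Two-layer CV: inner k-fold grid search by F1 on each outer-training
    portion only; outer test folds are never touched by tuning, oversampling,
    or scaling fits."""
    if not configs:
        raise ValidationError("no model configurations supplied")
    ss = np.random.SeedSequence([seed, 0x4E57])
    child_seeds = ss.generate_state(len(configs) * 3)
    results = []
    for ci, cfg in enumerate(configs):
        outer_seed = int(child_seeds[3 * ci] % (2 ** 31))
        inner_seed = int(child_seeds[3 * ci + 1] % (2 ** 31))
        fold_seed0 = int(child_seeds[3 * ci + 2] % (2 ** 31))
        rskf = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                       n_repeats=config.cv_repeats,
                                       random_state=outer_seed)
        points = _grid_points(cfg.grid)
        fold_metrics = []
        for fi, (tr, te) in enumerate(rskf.split(task.X, task.y)):
            best_params, best_score = points[0], -np.inf
            if len(points) > 1:
                inner = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                                        random_state=inner_seed)
                inner_splits = list(inner.split(task.X[tr], task.y[tr]))
                if audit is not None:
                    for itr, ite in inner_splits:
                        audit.append({
                            "scheme": "nested_cv", "model": cfg.model_id,
                            "outer_fold": fi,
                            "outer_test": sorted(map(int, te)),
                            "inner_train": sorted(int(tr[i]) for i in itr),
                            "inner_test": sorted(int(tr[i]) for i in ite)})
                for params in points:
                    scores = []
                    for itr, ite in inner_splits:
                        fm = _fit_and_score(
                            cfg.classifier, params, task.positive,
                            task.X[tr][itr], task.y[tr][itr],
                            task.X[tr][ite], task.y[tr][ite],
                            cfg.oversampler, fold_seed0 + fi,
                            config.metric_average)
                        scores.append(fm["F1"])
                    score = float(np.mean(scores))
                    if score > best_score:
                        best_params, best_score = params, score
            fm = _fit_and_score(cfg.classifier, best_params, task.positive,
                                task.X[tr], task.y[tr], task.X[te], task.y[te],
                                cfg.oversampler, fold_seed0 + fi,
                                config.metric_average)
            fold_metrics.append(fm)
            if audit is not None:
                audit.append({"scheme": "nested_cv", "model": cfg.model_id,
                              "outer_fold": fi, "train": sorted(map(int, tr)),
                              "test": sorted(map(int, te)),
                              "best_params": {k: str(v) for k, v in best_params.items()}})
        results.append(_aggregate(task, cfg, "nested_cv", fold_metrics))
    return results


def assert_no_leakage(audit: list) -> None:
    """Machine check of the no-leakage invariant over an audit trail."""
    for entry in audit:
        if "train" in entry and "test" in entry:
            if set(entry["train"]) & set(entry["test"]):
                raise AssertionError(f"train/test overlap in {entry['model']}")
        if "inner_train" in entry:
            outer_test = set(entry["outer_test"])
            if outer_test & set(entry["inner_train"]) or outer_test & set(entry["inner_test"]):
                raise AssertionError(
                    f"outer-test index inside inner CV for {entry['model']}"
                )


def results_table(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])
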