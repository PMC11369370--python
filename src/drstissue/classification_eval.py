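"""Patient-wise splitting, linear-SVM training and repeated evaluation.

Measurements from one patient are correlated (shared physiology, shared
probe session), so splitting at the measurement level would leak patient
identity into the test set and inflate performance.  All splitting here is
patient-wise: patients are partitioned 70/30 and every measurement inherits
its patient's side.

Each evaluation iteration re-derives the whole analysis from its own
training split — class profiles, feature spec, ReliefF ranking, top-k
selection, classifier fit — so nothing about the test patients can inform
the model.  Tumor is the positive class throughout (sensitivity = tumor
detection rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_extraction import (
    DEFAULT_MIN_PAIR_SEPARATION_NM,
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_SMOOTH_WINDOW_NM,
    FeatureTable,
    build_feature_spec,
    compute_features,
)
from .feature_selection import DEFAULT_TOP_K, relieff_rank, select_top_k
from .preprocessing import class_profiles, snv_normalize_set
from .spectra_io import SpectraSet

__all__ = [
    "SplitError",
    "TrainingError",
    "EvaluationError",
    "SplitPlan",
    "LinearModel",
    "IterationResult",
    "EvaluationReport",
    "patient_split",
    "train_classifier",
    "evaluate",
    "run_iteration",
    "run_repeated",
]

DEFAULT_TRAIN_RATIO = 0.70
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_FOLDS = 10
DEFAULT_N_ITER = 10
_SPLIT_RETRIES = 100


class SplitError(ValueError):
    pass


class TrainingError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test patient-id sets."""

    train_patients: frozenset
    test_patients: frozenset
    ratio: float
    seed: int | None

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise SplitError("train and test patient sets overlap")


@dataclass(frozen=True)
class LinearModel:
    """A fitted linear max-margin classifier with its standardization.

    decision(x) = w . standardize(x) + b; standardization statistics come
    from the training set only.
    """

    feature_names: tuple
    weights: np.ndarray
    bias: float
    C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cv_accuracy: dict  # C -> mean CV accuracy

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Z @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 = tumor where the decision value exceeds the native threshold 0."""
        return (self.decision(X) > 0).astype(int)


@dataclass(frozen=True)
class IterationResult:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    cutoff: float  # decision-value threshold maximizing Youden J
    roc: tuple  # ((fpr, tpr), ...) monotone nondecreasing
    confusion: dict  # TP / FP / TN / FN

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "confusion": dict(self.confusion),
            "roc": [list(pt) for pt in self.roc],
        }


@dataclass(frozen=True)
class EvaluationReport:
    iterations: tuple  # of IterationResult
    config_echo: dict = field(default_factory=dict)

    _METRICS = ("sensitivity", "specificity", "accuracy", "auc")

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(it, metric) for it in self.iterations]))

    def sd(self, metric: str) -> float:
        vals = [getattr(it, metric) for it in self.iterations]
        if len(vals) < 2:
            return 0.0  # SD undefined for one iteration; report 0 by convention
        return float(np.std(vals, ddof=1))

    def to_dict(self) -> dict:
        return {
            "n_iterations": len(self.iterations),
            "aggregate": {
                m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self._METRICS
            },
            "iterations": [it.to_dict() for it in self.iterations],
            "config": dict(self.config_echo),
        }


def patient_split(
    spectra: SpectraSet,
    ratio: float = DEFAULT_TRAIN_RATIO,
    seed: int | None = None,
) -> SplitPlan:
    """Partition patients (not measurements) into train/test sets.

    |train| = round(ratio * n_patients).  If either side ends up missing a
    class entirely the split is redrawn with a fresh seed, up to a retry
    limit, then raises :class:`SplitError`.
    """
    patients = list(spectra.patients())
    if len(patients) < 2:
        raise SplitError("need at least two patients to split")
    n_train = int(np.floor(ratio * len(patients) + 0.5))
    if n_train < 1 or n_train >= len(patients):
        raise SplitError(f"ratio {ratio} leaves an empty side for {len(patients)} patients")

    labels_by_patient = {}
    for m in spectra:
        if m.label != "unlabeled":
            labels_by_patient.setdefault(m.patient_id, set()).add(m.label)
    all_labels = set().union(*labels_by_patient.values()) if labels_by_patient else set()

    rng = np.random.default_rng(seed)
    for _ in range(_SPLIT_RETRIES):
        perm = rng.permutation(len(patients))
        train = frozenset(patients[i] for i in perm[:n_train])
        test = frozenset(patients[i] for i in perm[n_train:])
        covered = all(
            all_labels
            <= set().union(
                *(labels_by_patient.get(p, set()) for p in side), set()
            )
            for side in (train, test)
        )
        if covered or not all_labels:
            return SplitPlan(train, test, ratio, seed)
    raise SplitError(
        f"could not produce a split with both classes on both sides in "
        f"{_SPLIT_RETRIES} attempts"
    )


def train_classifier(
    table: FeatureTable,
    C_grid=DEFAULT_C_GRID,
    folds: int = DEFAULT_FOLDS,
    seed: int | None = None,
) -> LinearModel:
    """Fit a linear SVM with C chosen by stratified k-fold CV accuracy.

    Features are standardized with training-set statistics (stored in the
    model).  The winning C (ties -> smallest C) is refit on the full
    training table.
    """
    X, y = table.X, table.y
    if np.unique(y).size < 2:
        raise TrainingError("training data contains a single class")
    if np.all(X.std(axis=0) == 0):
        raise TrainingError("all features are constant; nothing to fit")
    min_class = int(np.bincount(y).min())
    eff_folds = min(folds, min_class)
    if eff_folds < folds:
        warnings.warn(
            f"folds={folds} exceeds smallest class size {min_class}; using {eff_folds}",
            stacklevel=2,
        )
    if eff_folds < 2:
        raise TrainingError("smallest class too small for cross-validation")

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)

    cv_acc = {}
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    fold_ix = list(skf.split(Z, y))
    for C in C_grid:
        accs = []
        for tr, va in fold_ix:
            clf = SVC(kernel="linear", C=C)
            clf.fit(Z[tr], y[tr])
            accs.append(float(np.mean(clf.predict(Z[va]) == y[va])))
        cv_acc[float(C)] = float(np.mean(accs))
    best_C = min((C for C in cv_acc), key=lambda C: (-cv_acc[C], C))

    final = SVC(kernel="linear", C=best_C).fit(Z, y)
    return LinearModel(
        feature_names=tuple(table.feature_names),
        weights=final.coef_.ravel().copy(),
        bias=float(final.intercept_[0]),
        C=best_C,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        cv_accuracy=cv_acc,
    )


def evaluate(model: LinearModel, table: FeatureTable) -> IterationResult:
    """Score a test table: confusion at decision threshold 0, ROC/AUC threshold-free.

    The ROC is built by sweeping the decision value over all test scores
    (trapezoidal AUC); the reported cutoff is the decision value maximizing
    Youden J = sensitivity + specificity - 1.  Headline sensitivity,
    specificity and accuracy use the classifier's native threshold 0.
    """
    if tuple(table.feature_names) != model.feature_names:
        raise EvaluationError("test table features do not match the model")
    y = table.y
    if np.unique(y).size < 2:
        raise EvaluationError("test set contains a single class; sensitivity/specificity undefined")
    scores = model.decision(table.X)

    pred = (scores > 0).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    fpr, tpr, thresholds = _roc_curve(y, scores)
    area = float(_trapezoid_auc(fpr, tpr))
    youden = tpr - fpr
    # roc_curve's first threshold is +inf (the empty-positive corner)
    best = int(np.argmax(youden))
    cutoff = float(thresholds[best]) if np.isfinite(thresholds[best]) else float(scores.max())

    return IterationResult(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        auc=area,
        cutoff=cutoff,
        roc=tuple((float(f), float(t)) for f, t in zip(fpr, tpr)),
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
    )


def run_iteration(
    spectra: SpectraSet,
    seed: int,
    ratio: float = DEFAULT_TRAIN_RATIO,
    top_k: int = DEFAULT_TOP_K,
    k_neighbors: int = 10,
    smooth_window_nm: float = DEFAULT_SMOOTH_WINDOW_NM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_nm: float = DEFAULT_MIN_PAIR_SEPARATION_NM,
    max_pairs: int | None = None,
    C_grid=DEFAULT_C_GRID,
    folds: int = DEFAULT_FOLDS,
    return_artifacts: bool = False,
):
    """One full split -> features -> selection -> train -> evaluate pass.

    The feature spec and ReliefF ranking are derived from the training
    patients only; the test split is touched exactly once, for scoring.
    """
    labeled = spectra.labeled()
    plan = patient_split(labeled, ratio=ratio, seed=seed)
    train_set = snv_normalize_set(labeled.subset_patients(plan.train_patients))
    test_set = snv_normalize_set(labeled.subset_patients(plan.test_patients))

    profiles = class_profiles(train_set)
    spec = build_feature_spec(
        profiles,
        smooth_window_nm=smooth_window_nm,
        min_prominence=min_prominence,
        min_separation_nm=min_separation_nm,
        max_pairs=max_pairs,
    )
    train_table = compute_features(train_set, spec)
    ranked = relieff_rank(train_table, k_neighbors=k_neighbors)
    k = min(top_k, len(spec))
    selected = select_top_k(ranked, spec, k=k)

    train_sel = compute_features(train_set, selected)
    test_sel = compute_features(test_set, selected)
    model = train_classifier(train_sel, C_grid=C_grid, folds=folds, seed=seed)
    result = evaluate(model, test_sel)
    if return_artifacts:
        return result, {"plan": plan, "spec": spec, "ranked": ranked,
                        "selected": selected, "model": model}
    return result


def _iteration_seed(base_seed: int, i: int) -> int:
    # documented fan-out: one base seed -> per-iteration seeds, kept < 2^31
    return (int(base_seed) * 100_003 + 7919 * i) % (2**31)


def run_repeated(
    spectra: SpectraSet,
    n_iter: int = DEFAULT_N_ITER,
    base_seed: int = 0,
    **iteration_kwargs,
) -> EvaluationReport:
    """Repeat the full pipeline over ``n_iter`` independent patient splits.

    Reports per-iteration metrics plus mean and sample SD (ddof=1) across
    iterations.  Stage failures are re-raised annotated with the iteration
    index.
    """
    iterations = []
    for i in range(n_iter):
        seed = _iteration_seed(base_seed, i)
        try:
            iterations.append(run_iteration(spectra, seed=seed, **iteration_kwargs))
        except Exception as e:
            raise type(e)(f"iteration {i}: {e}") from e
    echo = {"n_iter": n_iter, "base_seed": base_seed, **iteration_kwargs}
    echo.pop("C_grid", None)
    return EvaluationReport(iterations=tuple(iterations), config_echo=echo)
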