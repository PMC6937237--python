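"""Patient-grouped nested cross-validation with a linear SVM.

Every split — outer and inner — partitions *patients*, never samples, so the
72 augmented views of one patient can never straddle a train/test boundary.
Inside each outer training fold, features are standardized, screened by
one-way ANOVA F-statistic (top ``m_select``, ties broken by feature index),
and a linear SVM cost parameter is tuned by an inner patient-grouped CV on
balanced accuracy.  Test folds are scored using only each sample's center
view (no shift, rotation or flip), with balanced accuracy and the area under
the precision-recall curve computed from signed distances to the separating
hyperplane (one-vs-rest averaged for the three-class task).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import GENOTYPES

DEFAULT_COST_GRID = tuple(10.0 ** np.arange(-3, 4))


@dataclass
class Sample:
    """One classification unit: a feature matrix of views for one patient VOI.

    ``matrix`` has one row per view (72 augmented rows for CNN features, a
    single row for age/radiomics); ``center_row`` indexes the view used for
    scoring.  ``patient_id`` is the grouping key for every split.
    """

    uid: str
    patient_id: str
    label: object
    matrix: np.ndarray
    center_row: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if not (0 <= self.center_row < self.matrix.shape[0]):
            raise ValueError("center_row out of range")


@dataclass
class FoldPlan:
    """Patient-grouped outer/inner fold structure, reusable across feature sets."""

    outer_folds: list[tuple[list[str], list[str]]]  # (train_pids, test_pids)
    inner_folds: list[list[tuple[list[str], list[str]]]]
    seed: int
    stratified: bool

    @property
    def k(self) -> int:
        return len(self.outer_folds)


@dataclass
class TaskSpec:
    """A genotype classification task: label map plus cohort filter."""

    name: str
    label_map: dict[str, object]

    def labels_for(self, genotypes: Sequence[str]) -> list[object]:
        return [self.label_map[g] for g in genotypes]

    def in_cohort(self, genotype: str) -> bool:
        return genotype in self.label_map


#: The three genotype decoding tasks: all three subtypes, IDH status over the
#: whole cohort, and pTERT status within IDH-mutant patients only.
TASKS = {
    "three_subtype": TaskSpec("three_subtype", {g: g for g in GENOTYPES}),
    "idh": TaskSpec(
        "idh",
        {"IDHwt": "IDHwt", "IDHmut_pTERTmut": "IDHmut", "IDHmut_pTERTwt": "IDHmut"},
    ),
    "ptert_in_idh_mut": TaskSpec(
        "ptert_in_idh_mut",
        {"IDHmut_pTERTmut": "pTERTmut", "IDHmut_pTERTwt": "pTERTwt"},
    ),
}


@dataclass
class FoldResult:
    balanced_accuracy: float
    auprc: float
    chosen_cost: float
    selected_feature_indices: np.ndarray
    coef: np.ndarray | None = None
    intercept: np.ndarray | None = None


@dataclass
class ClassificationResult:
    per_fold: list[FoldResult]
    mean_accuracy: float
    ci95_halfwidth: float

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.balanced_accuracy for f in self.per_fold])

    @property
    def fold_auprcs(self) -> np.ndarray:
        return np.array([f.auprc for f in self.per_fold])

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "ci95_halfwidth": self.ci95_halfwidth,
            "per_fold": [
                {
                    "balanced_accuracy": f.balanced_accuracy,
                    "auprc": f.auprc,
                    "chosen_cost": f.chosen_cost,
                    "n_selected_features": int(len(f.selected_feature_indices)),
                }
                for f in self.per_fold
            ],
        }


def _split_patients(pids, labels, k, seed, stratified):
    pids = np.asarray(pids)
    if stratified and labels is not None:
        y = np.asarray([str(l) for l in labels])
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            warnings.warn(
                f"a class has fewer than {k} patients; "
                "falling back to non-stratified folds"
            )
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            return [(list(pids[tr]), list(pids[te])) for tr, te in splitter.split(pids)]
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(list(pids[tr]), list(pids[te])) for tr, te in splitter.split(pids, y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(list(pids[tr]), list(pids[te])) for tr, te in splitter.split(pids)]


def make_folds(
    patient_ids: Sequence[str],
    labels: Optional[Sequence] = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    inner_k: int = 5,
) -> FoldPlan:
    """Stratified, patient-grouped outer folds with per-fold inner folds.

    Splits patient ids, so no patient can appear on both sides of any outer
    or inner division.  The same plan is reused across feature sets for a
    given task so their fold accuracies are paired.
    """
    pids = list(patient_ids)
    if len(set(pids)) != len(pids):
        raise ValueError("patient ids must be unique")
    if k > len(pids):
        raise ValueError("k exceeds the number of patients")
    label_of = None
    if labels is not None:
        label_of = dict(zip(pids, labels))
    outer = _split_patients(pids, labels, k, seed, stratified)
    inner: list[list[tuple[list[str], list[str]]]] = []
    for fold_i, (train_pids, _) in enumerate(outer):
        tr_labels = [label_of[p] for p in train_pids] if label_of else None
        ki = min(inner_k, len(train_pids))
        inner.append(
            _split_patients(train_pids, tr_labels, ki, seed + 1 + fold_i, stratified)
        )
    return FoldPlan(outer, inner, seed, stratified and labels is not None)


def f_statistic(train_features: np.ndarray, train_labels: Sequence) -> np.ndarray:
    """One-way ANOVA F per feature: (SSB/(g-1)) / (SSW/(n-g)).

    Features with zero between- and within-group variance get F = 0; features
    with spread between groups but none within get +inf (they rank first).
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    n = X.shape[0]
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        ssb += Xc.shape[0] * (mc - grand) ** 2
        ssw += ((Xc - mc) ** 2).sum(axis=0)
    dfb = classes.size - 1
    dfw = n - classes.size
    if dfw <= 0:
        raise ValueError("need more samples than classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F[np.isnan(F)] = 0.0  # 0/0: flat feature
    return F


def select_top_features(f_values: np.ndarray, m: int) -> np.ndarray:
    """Indices of the top-m F values; ties broken by ascending feature index."""
    f = np.asarray(f_values)
    if m >= f.size:
        return np.arange(f.size)
    order = np.argsort(-f, kind="stable")
    return np.sort(order[:m])


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall from a confusion matrix (rows = true classes)."""
    cm = np.asarray(confusion, dtype=np.float64)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class needs at least one test sample")
    return float((np.diag(cm) / row_sums).mean())


def balanced_accuracy_from_predictions(y_true, y_pred) -> float:
    """Mean recall over the true classes actually present in ``y_true``."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    lbls = sorted(set(y_true) | set(y_pred), key=str)
    cm = confusion_matrix(y_true, y_pred, labels=lbls)
    rows = cm.sum(axis=1)
    present = rows > 0
    return float((np.diag(cm)[present] / rows[present]).mean())


def auprc(scores: Sequence[float], positives: Sequence[bool]) -> float:
    """Area under the precision-recall curve, average-precision form.

    Sum over descending score thresholds of precision times the recall
    increment; tied scores enter together.
    """
    s = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positives, dtype=bool)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined without positive samples")
    if n_pos == pos.size:
        raise ValueError("AUPRC undefined without negative samples")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    while i < s_sorted.size:
        j = i
        while j < s_sorted.size and s_sorted[j] == s_sorted[i]:
            j += 1
        tp_new = tp + int(pos_sorted[i:j].sum())
        fp_new = fp + int((~pos_sorted[i:j]).sum())
        if tp_new > tp:
            precision = tp_new / (tp_new + fp_new)
            ap += precision * (tp_new - tp) / n_pos
        tp, fp = tp_new, fp_new
        i = j
    return float(ap)


def auprc_multiclass(distances: np.ndarray, labels: Sequence, classes: Sequence) -> float:
    """Mean one-vs-rest AUPRC over the classes present in a test fold.

    ``distances`` holds one signed hyperplane distance column per class in
    ``classes`` order.  Classes without both a positive and a negative sample
    in the fold are skipped.
    """
    D = np.atleast_2d(np.asarray(distances, dtype=np.float64))
    y = np.asarray(labels)
    vals = []
    for j, c in enumerate(classes):
        pos = y == c
        if 0 < pos.sum() < pos.size:
            vals.append(auprc(D[:, j], pos))
    if not vals:
        raise ValueError("no class with both positives and negatives in fold")
    return float(np.mean(vals))


def _fit_svm(X, y, cost, random_state=0):
    clf = LinearSVC(C=cost, random_state=random_state, tol=1e-4, max_iter=5000, dual="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        clf.fit(X, y)
    return clf


def _stack_rows(samples: list[Sample]):
    X = np.vstack([s.matrix for s in samples])
    y = np.concatenate([[s.label] * s.matrix.shape[0] for s in samples])
    return X, y


def _center_rows(samples: list[Sample]):
    X = np.vstack([s.matrix[s.center_row] for s in samples])
    y = np.asarray([s.label for s in samples])
    return X, y


def nested_cv(
    samples: list[Sample],
    plan: FoldPlan,
    m_select: int = 4000,
    cost_grid: Sequence[float] | None = None,
    standardize: bool = True,
    random_state: int = 0,
) -> ClassificationResult:
    """Run the grouped nested CV defined by ``plan`` over ``samples``.

    Per outer fold: standardization and F-screening are fit on the training
    patients only; the SVM cost is chosen by the plan's inner folds on
    balanced accuracy (ties to the smaller cost); the final SVM trains on all
    training rows (every augmented view) and is scored on the test samples'
    center views only.
    """
    from .stats import ci95

    cost_grid = tuple(cost_grid) if cost_grid is not None else DEFAULT_COST_GRID
    by_pid: dict[str, list[Sample]] = {}
    for s in samples:
        by_pid.setdefault(s.patient_id, []).append(s)
    all_labels = sorted({s.label for s in samples}, key=str)
    if len(all_labels) < 2:
        raise ValueError("need at least two classes")

    per_fold: list[FoldResult] = []
    for fold_i, (train_pids, test_pids) in enumerate(plan.outer_folds):
        train_s = [s for p in train_pids for s in by_pid.get(p, [])]
        test_s = [s for p in test_pids for s in by_pid.get(p, [])]
        if not train_s or not test_s:
            raise ValueError("empty fold after cohort filtering")
        X_tr, y_tr = _stack_rows(train_s)
        if np.unique(y_tr).size < 2:
            raise ValueError("single-class training fold")
        scaler = StandardScaler().fit(X_tr) if standardize else None
        if scaler is not None:
            X_tr = scaler.transform(X_tr)
        sel = select_top_features(f_statistic(X_tr, y_tr), m_select)
        X_tr = X_tr[:, sel]

        # inner CV over costs, scored on center views, grouped by patient
        best_cost, best_score = cost_grid[0], -np.inf
        inner = plan.inner_folds[fold_i]
        for cost in cost_grid:
            scores = []
            for in_tr, in_va in inner:
                tr = [s for p in in_tr for s in by_pid.get(p, [])]
                va = [s for p in in_va for s in by_pid.get(p, [])]
                if not tr or not va:
                    continue
                Xi, yi = _stack_rows(tr)
                Xv, yv = _center_rows(va)
                if scaler is not None:
                    Xi, Xv = scaler.transform(Xi), scaler.transform(Xv)
                Xi, Xv = Xi[:, sel], Xv[:, sel]
                if np.unique(yi).size < 2:
                    continue
                clf = _fit_svm(Xi, yi, cost, random_state)
                scores.append(balanced_accuracy_from_predictions(yv, clf.predict(Xv)))
            mean_score = float(np.mean(scores)) if scores else -np.inf
            if mean_score > best_score:
                best_cost, best_score = cost, mean_score

        clf = _fit_svm(X_tr, y_tr, best_cost, random_state)
        X_te, y_te = _center_rows(test_s)
        if scaler is not None:
            X_te = scaler.transform(X_te)
        X_te = X_te[:, sel]
        acc = balanced_accuracy_from_predictions(y_te, clf.predict(X_te))

        dist = clf.decision_function(X_te)
        if dist.ndim == 1:  # binary: signed distance to the single hyperplane
            pos_label = clf.classes_[1]
            fold_auprc = auprc(dist, y_te == pos_label)
        else:
            fold_auprc = auprc_multiclass(dist, y_te, clf.classes_)
        per_fold.append(
            FoldResult(
                balanced_accuracy=acc,
                auprc=fold_auprc,
                chosen_cost=float(best_cost),
                selected_feature_indices=sel,
                coef=np.array(clf.coef_, copy=True),
                intercept=np.array(clf.intercept_, copy=True),
            )
        )

    accs = [f.balanced_accuracy for f in per_fold]
    half = ci95(accs) if len(accs) > 1 else 0.0
    return ClassificationResult(per_fold, float(np.mean(accs)), half)


def chance_run(
    samples: list[Sample],
    n_repeats: int = 1,
    seed: int = 0,
    k: int = 10,
    inner_k: int = 5,
    m_select: int = 4000,
    cost_grid: Sequence[float] | None = None,
) -> np.ndarray:
    """Shuffled-label chance runs; returns fold accuracies, shape (repeats, k).

    Labels are permuted at the patient level, a fresh stratified grouped fold
    plan is built on the permuted labels, and the nested CV is re-run (by
    convention on the age feature alone, mirroring how the chance level of
    the genotype decoding is estimated).
    """
    rng = np.random.default_rng(seed)
    pids = [s.patient_id for s in samples]
    if len(set(pids)) != len(pids):
        raise ValueError("chance_run expects one sample per patient")
    labels = np.asarray([s.label for s in samples], dtype=object)
    out = np.empty((n_repeats, k))
    for rep in range(n_repeats):
        perm = labels[rng.permutation(len(labels))]
        shuffled = [
            Sample(s.uid, s.patient_id, lab, s.matrix, s.center_row)
            for s, lab in zip(samples, perm)
        ]
        plan = make_folds(
            pids, perm, k=k, seed=int(rng.integers(2**31)), inner_k=inner_k
        )
        res = nested_cv(shuffled, plan, m_select=m_select, cost_grid=cost_grid)
        out[rep] = res.fold_accuracies
    return out
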