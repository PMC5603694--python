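"""Multivoxel pattern classification engine.

Implements class-balanced rotation construction, inter-subject and
intra-subject leave-one-out cross-validation (LOOCV) with a linear
soft-margin SVM over configurable voxel masks, and group performance
statistics.

Class balancing
---------------
For a subject's binary label vector the larger class (size ``N_max``) is
the *rotate set* and the smaller (size ``N_min``) the *static set*.  For
each of ``N_max`` rotations, a circular window of ``N_min`` consecutive
rotate-set stimuli (ordered by stimulus id, shifted one position per
rotation) is combined with the full static set, producing a test pool
with exactly ``N_min`` stimuli per class; every majority-class stimulus
enters at least one window.  When the classes are already balanced the
scheme collapses to a single rotation containing all stimuli.

Because classifier fits vastly outnumber distinct data matrices, the
engine precomputes the linear Gram matrix of the masked features once per
cross-validation fold and hands sub-blocks to the SVM, which is exactly
equivalent to fitting on the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .datasets import BetaDataset
from .labels import label_vector
from .univariate import leave_one_out_gm_masks


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear soft-margin SVM configuration."""

    kind: str = "linear_svm"
    regularization: float = 1.0
    standardize: bool = False  # mean-center features using training data
    tol: float = 1e-2  # SMO stopping tolerance for the Gram-matrix engine

    def __post_init__(self) -> None:
        if self.kind != "linear_svm":
            raise ValueError("only linear_svm is supported")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass(frozen=True)
class BalancedRotation:
    """One class-balanced test-pool selection."""

    static_set: tuple[int, ...]  # minority-class indices
    rotate_window: tuple[int, ...]  # N_min consecutive majority indices
    rotation_index: int

    @property
    def pool(self) -> tuple[int, ...]:
        return self.static_set + self.rotate_window


def make_balanced_rotations(labels_pm1: np.ndarray) -> list[BalancedRotation]:
    """Build the N_max circular-window rotations for a +1/-1 label vector.

    Indices refer to positions in ``labels_pm1``, which is assumed already
    ordered by stimulus id.
    """
    y = np.asarray(labels_pm1)
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be nonempty")
    if len(pos) >= len(neg):
        rotate, static = pos, neg
    else:
        rotate, static = neg, pos
    n_max, n_min = len(rotate), len(static)
    if n_max == n_min:
        return [BalancedRotation(tuple(static), tuple(rotate), 0)]
    rotations = []
    for r in range(n_max):
        window = tuple(rotate[(r + j) % n_max] for j in range(n_min))
        rotations.append(BalancedRotation(tuple(static), window, r))
    return rotations


# ---------------------------------------------------------------------------
# linear SVM


def fit_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-3
) -> tuple[np.ndarray, float, "np.ufunc"]:
    """Fit a soft-margin linear SVM; return (w, b, decision function).

    ``decision(x) = w . x + b``; the signed hyperplane distance of an
    example is ``decision(x) / ||w||``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(X, y)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    return w, b, lambda x: np.asarray(x, dtype=float) @ w + b


class _GramSVM:
    """Linear SVM fitted from a precomputed Gram matrix block."""

    def __init__(self, G_train: np.ndarray, y_train: np.ndarray, C: float, tol: float = 1e-2):
        self.y = np.asarray(y_train, dtype=float)
        self.clf = SVC(kernel="precomputed", C=C, tol=tol)
        self.clf.fit(G_train, self.y)
        dual = self.clf.dual_coef_[0]
        sv = self.clf.support_
        self.w_norm = float(
            np.sqrt(max(dual @ G_train[np.ix_(sv, sv)] @ dual, 1e-300))
        )

    def distances(self, K_test_train: np.ndarray) -> np.ndarray:
        """Signed hyperplane distances for test examples given their
        kernel rows against the training set."""
        f = self.clf.decision_function(K_test_train)
        return f / self.w_norm

    def weight_vector(self, X_train: np.ndarray) -> np.ndarray:
        """Primal weights w = sum_i alpha_i y_i x_i (unnormalised)."""
        return self.clf.dual_coef_[0] @ X_train[self.clf.support_]


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class FoldResult:
    """One (held-out subject, rotation) evaluation."""

    subject_id: str
    rotation_index: int
    test_stim_ids: tuple[str, ...]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    hyperplane_distances: np.ndarray
    train_subject_ids: tuple[str, ...] = ()

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.true_labels == self.predicted_labels))

    @property
    def tpr(self) -> float:
        pos = self.true_labels > 0
        return float(np.mean(self.predicted_labels[pos] > 0)) if pos.any() else float("nan")

    @property
    def fpr(self) -> float:
        neg = self.true_labels < 0
        return float(np.mean(self.predicted_labels[neg] > 0)) if neg.any() else float("nan")


@dataclass(frozen=True)
class GroupPerformance:
    """Group summary of per-subject cross-validated accuracies."""

    per_subject_accuracy: np.ndarray
    mean_accuracy: float
    ci95: tuple[float, float]
    t_statistic: float
    p_value: float
    null_value: float
    mean_tpr: float
    mean_fpr: float
    degenerate: bool = False
    folds: tuple[FoldResult, ...] = field(default=(), repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_accuracy": [self.mean_accuracy],
                "ci_low": [self.ci95[0]],
                "ci_high": [self.ci95[1]],
                "mean_tpr": [self.mean_tpr],
                "mean_fpr": [self.mean_fpr],
                "t": [self.t_statistic],
                "p": [self.p_value],
            }
        )


def summarize_performance(
    per_subject_accuracies: np.ndarray,
    null_value: float = 0.5,
    fold_results: tuple[FoldResult, ...] = (),
) -> GroupPerformance:
    """Mean, t-based 95% CI, and a two-tailed one-sample t-test vs the
    chance level, plus TPR/FPR averaged over subjects (fold confusion
    counts pooled within subject first)."""
    acc = np.asarray(per_subject_accuracies, dtype=float)
    if len(acc) < 2:
        raise ValueError("need >= 2 per-subject accuracies")
    n = len(acc)
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    degenerate = sd == 0
    if degenerate:
        t_stat, p, ci = float("nan"), float("nan"), (mean, mean)
    else:
        se = sd / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean - tcrit * se, mean + tcrit * se)
        t_stat = (mean - null_value) / se
        p = 2.0 * stats.t.sf(abs(t_stat), n - 1)

    tprs, fprs = [], []
    by_subject: dict[str, list[FoldResult]] = {}
    for f in fold_results:
        by_subject.setdefault(f.subject_id, []).append(f)
    for subj_folds in by_subject.values():
        true = np.concatenate([f.true_labels for f in subj_folds])
        pred = np.concatenate([f.predicted_labels for f in subj_folds])
        pos, neg = true > 0, true < 0
        if pos.any():
            tprs.append(np.mean(pred[pos] > 0))
        if neg.any():
            fprs.append(np.mean(pred[neg] > 0))
    return GroupPerformance(
        per_subject_accuracy=acc,
        mean_accuracy=mean,
        ci95=ci,
        t_statistic=float(t_stat),
        p_value=float(p),
        null_value=null_value,
        mean_tpr=float(np.mean(tprs)) if tprs else float("nan"),
        mean_fpr=float(np.mean(fprs)) if fprs else float("nan"),
        degenerate=degenerate,
        folds=tuple(fold_results),
    )


def compare_accuracies(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test between accuracy lists."""
    a, b = np.asarray(group_a, dtype=float), np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 accuracies")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cross-validation engines


def _ordered_subject_labels(
    data: BetaDataset, labels: pd.DataFrame, target: str
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject stimulus orderings (by id) and +1/-1 label vectors."""
    orders, ys = [], []
    for s in range(data.n_subjects):
        order = np.argsort(np.asarray(data.stim_ids[s]))
        ids = [data.stim_ids[s][i] for i in order]
        orders.append(order)
        ys.append(label_vector(labels, target, ids))
    return orders, ys


def _predict_labels(distances: np.ndarray) -> np.ndarray:
    """Sign of the hyperplane distance; exact ties go to the positive class."""
    return np.where(distances >= 0, 1, -1)


def intersubject_loocv(
    data: BetaDataset,
    labels: pd.DataFrame,
    target: str = "valence",
    feature_mask: np.ndarray | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    gm_fraction: float = 0.5,
    null_value: float = 0.5,
) -> GroupPerformance:
    """Subject-wise leave-one-out cross-validation.

    For each held-out subject, its class-balanced rotations define the
    test pools; every training subject contributes its own class-balanced
    selection at the same rotation shift (its static set plus the circular
    window at ``r mod N_max`` of its majority class), so training sets are
    built from the corresponding stimuli whenever a training subject saw
    the same stimulus set and from class-matched counterparts otherwise.
    Rotation accuracies are averaged into one accuracy per subject.

    The per-fold feature mask is the leave-one-out group gray-matter mask
    of the training subjects, intersected with ``feature_mask`` (an ROI
    restriction) when given.
    """
    n_subj = data.n_subjects
    if n_subj < 3:
        raise ValueError("need >= 3 subjects")
    orders, ys = _ordered_subject_labels(data, labels, target)
    rotations = [make_balanced_rotations(y) for y in ys]
    loo_masks = leave_one_out_gm_masks(data.gm_masks, gm_fraction)

    # betas reordered by stimulus id once per subject
    B = [data.betas[s][orders[s]] for s in range(n_subj)]
    subj_slices = []
    start = 0
    for s in range(n_subj):
        subj_slices.append(slice(start, start + len(ys[s])))
        start += len(ys[s])
    stacked = np.vstack(B)

    per_subject_acc = np.empty(n_subj)
    folds: list[FoldResult] = []
    for t_subj in range(n_subj):
        mask = loo_masks[t_subj]
        if feature_mask is not None:
            mask = mask & np.asarray(feature_mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty feature mask for fold")
        Z = stacked[:, mask]
        if spec.standardize:
            Z = Z - Z.mean(axis=0, keepdims=True)
        G = Z @ Z.T

        train_subjects = [u for u in range(n_subj) if u != t_subj]
        test_rots = rotations[t_subj]
        accs = []
        sorted_ids_t = sorted(data.stim_ids[t_subj])
        for rot in test_rots:
            test_idx = np.array(rot.pool) + subj_slices[t_subj].start
            y_test = ys[t_subj][list(rot.pool)]
            train_idx, y_train = [], []
            for u in train_subjects:
                rots_u = rotations[u]
                rot_u = rots_u[rot.rotation_index % len(rots_u)]
                train_idx.extend(np.array(rot_u.pool) + subj_slices[u].start)
                y_train.extend(ys[u][list(rot_u.pool)])
            train_idx = np.asarray(train_idx)
            y_train = np.asarray(y_train)
            svm = _GramSVM(G[np.ix_(train_idx, train_idx)], y_train, spec.regularization, spec.tol)
            dist = svm.distances(G[np.ix_(test_idx, train_idx)])
            pred = _predict_labels(dist)
            fold = FoldResult(
                subject_id=data.subject_ids[t_subj],
                rotation_index=rot.rotation_index,
                test_stim_ids=tuple(sorted_ids_t[i] for i in rot.pool),
                true_labels=y_test,
                predicted_labels=pred,
                hyperplane_distances=dist,
                train_subject_ids=tuple(data.subject_ids[u] for u in train_subjects),
            )
            folds.append(fold)
            accs.append(fold.accuracy)
        per_subject_acc[t_subj] = float(np.mean(accs))

    return summarize_performance(per_subject_acc, null_value, tuple(folds))


def intrasubject_loocv(
    subject_betas: np.ndarray,
    labels_pm1: np.ndarray,
    feature_mask: np.ndarray | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
) -> float:
    """Stimulus-wise LOOCV within one subject, per balanced rotation.

    Within each rotation's pooled (balanced) set, each stimulus is left
    out in turn and predicted from the remaining pool; rotation accuracies
    are averaged into the subject accuracy.  Constant-feature degenerate
    pools score 0.5 by convention.
    """
    y = np.asarray(labels_pm1)
    if min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ValueError("each class needs >= 2 stimuli")
    X = np.asarray(subject_betas, dtype=float)
    if feature_mask is not None:
        X = X[:, np.asarray(feature_mask, dtype=bool)]
    G_full = X @ X.T
    accs = []
    for rot in make_balanced_rotations(y):
        pool = np.array(rot.pool)
        Xp = X[pool]
        if np.allclose(Xp, Xp[0]):
            accs.append(0.5)  # degenerate: no information in features
            continue
        Gp = G_full[np.ix_(pool, pool)]
        yp = y[pool]
        correct = []
        for i in range(len(pool)):
            keep = np.arange(len(pool)) != i
            svm = _GramSVM(Gp[np.ix_(keep, keep)], yp[keep], spec.regularization, spec.tol)
            d = svm.distances(Gp[np.ix_([i], keep)])
            correct.append(_predict_labels(d)[0] == yp[i])
        accs.append(float(np.mean(correct)))
    return float(np.mean(accs))


def fit_group_svm(
    data: BetaDataset,
    labels: pd.DataFrame,
    target: str = "valence",
    feature_mask: np.ndarray | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    gm_fraction: float = 0.5,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Fit one linear SVM on all subjects' (masked) brain states.

    Used to interpret the decoder: returns ``(w, b, X_train, mask)`` with
    ``w`` defined on the masked voxels.  The mask is the all-subject group
    gray-matter mask intersected with ``feature_mask``.
    """
    from .univariate import build_group_gm_mask

    mask = build_group_gm_mask(data.gm_masks, gm_fraction).include
    if feature_mask is not None:
        mask = mask & np.asarray(feature_mask, dtype=bool)
    orders, ys = _ordered_subject_labels(data, labels, target)
    X = np.vstack([data.betas[s][orders[s]][:, mask] for s in range(data.n_subjects)])
    y = np.concatenate(ys)
    w, b, _ = fit_linear_svm(X, y, C=spec.regularization)
    return w, b, X, mask
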