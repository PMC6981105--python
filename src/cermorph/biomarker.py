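"""Biomarker discovery: RFECV feature selection, bias-swept SVM ROC
validation, and mapping selected features back to atlas anatomy.

Selection is recursive feature elimination with stratified cross-validation
(RFECV): starting from all 490 (lobule, month) columns, a linear-kernel SVM
is fitted and the weakest feature (or features; smallest squared weight) is
removed each iteration, down to a single feature.  Each candidate subset
size visited is
scored by mean held-out accuracy across stratified folds, the optimal size
is the *smallest* size attaining the maximum mean score (parsimony), and
each feature's relevance is its mean elimination rank across folds.

Validation sweeps the SVM bias point ``B`` over the integers -50..50: for
each of ``n_reps`` random leave-5-out splits a linear SVM is fitted and its
decision values thresholded at ``tau(B)``, where B maps linearly onto
mean +/- 3 SD of the training decision values.  The mean true/false positive
rate per bias point traces a ROC curve whose area (trapezoidal, anchored at
(0,0) and (1,1)) summarizes discriminative ability.

No multiple-testing correction is applied anywhere in this module; the
bias-swept ROC validation is the only guard against selection optimism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y

from .atlas_io import LabeledAtlas
from .longitudinal import FeatureMatrix

log = logging.getLogger(__name__)


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Round-robin stratified folds: shuffled positives, then negatives.

    With 7 positives in 6 folds some folds receive one positive and some two;
    round-robin assignment keeps the imbalance as even as integer counts
    allow.  Returns a list of index arrays (the test set of each fold).
    """
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    slot = 0
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            folds[slot % n_folds].append(int(i))
            slot += 1
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _linear_svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C, class_weight="balanced")


class RFECVBiomarkerSelector(BaseEstimator):
    """Recursive feature elimination with cross-validated subset scoring.

    scikit-learn-style estimator: ``fit(X, y)`` then ``transform(X)`` keeps
    the selected columns.  Differs from :class:`sklearn.feature_selection.
    RFECV` in two spec'd ways: the per-feature relevance is the *mean
    elimination rank across folds* (and selection picks the best-ranked
    features), and the optimal subset size is the smallest size attaining
    the maximal mean CV score.

    Parameters
    ----------
    n_folds : int
        Stratified folds for subset-size scoring (default 6).
    C : float
        SVM regularization (linear kernel, balanced class weights).
    step : int or "auto"
        How many of the weakest features to drop per iteration.  1 removes a
        single feature every time; "auto" (default) drops 5% of the active
        set while more than ``exact_below`` features remain, then one at a
        time, so the score-vs-size curve is exact where subset sizes are
        decided and tractable for wide matrices.
    exact_below : int
        Subset size below which elimination is always one-at-a-time.
    random_state : int
        Seed for fold construction.

    Attributes
    ----------
    sizes_ : ndarray
        Candidate subset sizes visited, ascending.
    cv_scores_ : ndarray, aligned with ``sizes_``
        Mean held-out accuracy per candidate size.
    optimal_size_ : int
        Smallest visited size attaining the maximal mean score.
    mean_rank_ : ndarray
        Mean elimination rank per feature across folds (1 = eliminated last;
        features dropped in one batch share a rank).
    support_ : ndarray of bool
    selected_indices_ : ndarray of int
        The optimal-size best-ranked columns, in rank order.
    constant_columns_ : ndarray of int
        Columns with zero variance (retained but flagged).
    """

    def __init__(
        self,
        n_folds: int = 6,
        C: float = 1.0,
        step: int | str = "auto",
        exact_below: int = 50,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.C = C
        self.step = step
        self.exact_below = exact_below
        self.random_state = random_state

    def _n_remove(self, size: int) -> int:
        if size <= 1:
            return 0
        if self.step == "auto":
            n = 1 if size <= self.exact_below else int(np.ceil(0.05 * size))
        else:
            n = int(self.step)
        return min(max(n, 1), size - 1)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("y must contain both classes")
        n, p = X.shape
        self.constant_columns_ = np.flatnonzero(X.std(axis=0) == 0)
        if self.constant_columns_.size:
            log.warning("%d constant feature column(s) retained but "
                        "uninformative", self.constant_columns_.size)

        rng = np.random.default_rng(self.random_state)
        folds = stratified_folds(y, self.n_folds, rng)
        # the visited size sequence depends only on p: identical across folds
        sizes = []
        s = p
        while s >= 1:
            sizes.append(s)
            nr = self._n_remove(s)
            if nr == 0:
                break
            s -= nr
        size_pos = {s: i for i, s in enumerate(sizes)}

        scores = np.zeros((len(folds), len(sizes)))
        ranks = np.zeros((len(folds), p))
        for fi, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            Xtr, ytr = X[train_mask], y[train_mask]
            Xte, yte = X[test_idx], y[test_idx]
            active = np.arange(p)
            while True:
                size = active.size
                clf = _linear_svm(self.C).fit(Xtr[:, active], ytr)
                w = np.ravel(clf.coef_)
                # decision values by hand: cheaper than predict() here
                dec = Xte[:, active] @ w + float(clf.intercept_[0])
                pred = np.where(dec > 0, clf.classes_[1], clf.classes_[0])
                scores[fi, size_pos[size]] = float(np.mean(pred == yte))
                nr = self._n_remove(size)
                if nr == 0:
                    break
                # weakest = smallest squared weight; stable order on ties
                weakest = np.argsort(w**2, kind="stable")[:nr]
                ranks[fi, active[weakest]] = size  # eliminated at this size
                active = np.delete(active, weakest)
            ranks[fi, active] = 1  # the survivor of the elimination

        self.sizes_ = np.asarray(sizes[::-1])
        self.cv_scores_ = scores.mean(axis=0)[::-1]
        best = float(self.cv_scores_.max())
        self.optimal_size_ = int(self.sizes_[self.cv_scores_ == best][0])
        self.mean_rank_ = ranks.mean(axis=0)
        order = np.lexsort((np.arange(p), self.mean_rank_))
        self.selected_indices_ = order[: self.optimal_size_]
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_indices_] = True
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


@dataclass
class SelectionResult:
    """Outcome of RFECV on one feature family."""

    family: str
    sizes: np.ndarray  # candidate subset sizes visited (ascending)
    cv_scores: np.ndarray  # mean CV accuracy per visited size
    optimal_size: int
    selected_columns: list[int]
    decoded: list[dict]  # label / side / month per selected column
    mean_rank: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "family": self.family,
                    "optimal_size": self.optimal_size,
                    "selected_columns": [int(c) for c in self.selected_columns],
                    "decoded": self.decoded,
                    "sizes": self.sizes.tolist(),
                    "cv_scores": self.cv_scores.tolist(),
                    "mean_rank": self.mean_rank.tolist(),
                },
                indent=2,
            )
        )
        return path


def rfecv_select(
    fm: FeatureMatrix,
    atlas: LabeledAtlas,
    n_folds: int = 6,
    C: float = 1.0,
    seed: int = 0,
) -> SelectionResult:
    """Run RFECV on one feature family and decode the selected columns."""
    sel = RFECVBiomarkerSelector(n_folds=n_folds, C=C, random_state=seed)
    sel.fit(fm.X, fm.y)
    decoded = []
    for c in sel.selected_indices_:
        label, month = fm.decode(int(c))
        decoded.append(
            {
                "column": int(c),
                "label": int(label),
                "symmetric_label": atlas.symmetric_id_of(int(label)),
                "side": atlas.side_of(int(label)),
                "month": int(month),
            }
        )
    return SelectionResult(
        family=fm.family,
        sizes=sel.sizes_,
        cv_scores=sel.cv_scores_,
        optimal_size=sel.optimal_size_,
        selected_columns=[int(c) for c in sel.selected_indices_],
        decoded=decoded,
        mean_rank=sel.mean_rank_,
    )


# ---------------------------------------------------------------------------
# bias-swept leave-5-out ROC


@dataclass
class ROCResult:
    """Mean ROC curve over repeated leave-``n_test``-out splits."""

    descriptor: str
    biases: np.ndarray
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray
    auc: float
    n_reps: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "descriptor": self.descriptor,
                    "auc": self.auc,
                    "n_reps": self.n_reps,
                    "biases": self.biases.tolist(),
                    "mean_tpr": self.mean_tpr.tolist(),
                    "mean_fpr": self.mean_fpr.tolist(),
                },
                indent=2,
            )
        )
        return path


def _mean_curve_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal AUC of the mean curve, anchored at (0,0) and (1,1)."""
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((t, f))
    f, t = f[order], t[order]
    pooled = np.maximum.accumulate(t)
    if np.any(pooled != t):
        log.debug("ROC pooling adjusted %d non-monotone point(s)",
                  int(np.count_nonzero(pooled != t)))
    return float(np.trapezoid(pooled, f))


def svm_roc(
    X: np.ndarray,
    y: np.ndarray,
    n_test: int = 5,
    n_reps: int = 1000,
    bias_range: tuple[int, int] = (-50, 50),
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
    descriptor: str = "",
) -> ROCResult:
    """Bias-swept ROC over repeated random leave-``n_test``-out splits.

    For each repetition a uniformly random ``n_test``-subject test set is
    held out, a SVM is fitted on the remainder, and the decision values are
    thresholded at ``tau(B) = mu + 3 sigma * B / 50`` (``mu``, ``sigma`` the
    training decision-value statistics) for each integer bias point ``B``.
    Repetitions whose test draw has no positives contribute only to the FPR
    mean for that bias point (TPR undefined there), and vice versa.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    n = len(y)
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    if not 0 < n_test < n:
        raise ValueError("need 0 < n_test < n subjects")

    biases = np.arange(bias_range[0], bias_range[1] + 1)
    nb = biases.size
    tpr_sum = np.zeros(nb)
    tpr_cnt = np.zeros(nb)
    fpr_sum = np.zeros(nb)
    fpr_cnt = np.zeros(nb)
    rng = np.random.default_rng(seed)
    half = (bias_range[1] - bias_range[0]) / 2

    n_skipped = 0
    for _ in range(n_reps):
        test = rng.choice(n, size=n_test, replace=False)
        train = np.setdiff1d(np.arange(n), test)
        ytr = y[train]
        if np.unique(ytr).size < 2:
            n_skipped += 1
            continue
        clf = SVC(kernel=kernel, C=C, class_weight="balanced").fit(X[train], ytr)
        dec_tr = clf.decision_function(X[train])
        # anchor the sweep at the midpoint of the class-mean decision values:
        # unlike the plain training mean, this anchor does not shift with the
        # train/test class composition, which would otherwise bias the mean
        # TPR upward relative to the mean FPR at every bias point
        m1 = float(dec_tr[ytr == 1].mean())
        m0 = float(dec_tr[ytr == 0].mean())
        mu = 0.5 * (m1 + m0)
        sigma = max(0.5 * abs(m1 - m0), float(dec_tr.std()), 1e-12)
        dec_te = clf.decision_function(X[test])
        yte = y[test]
        npos = int((yte == 1).sum())
        nneg = n_test - npos
        taus = mu + 3.0 * sigma * (biases - (bias_range[0] + half)) / half
        pred = dec_te[None, :] >= taus[:, None]  # (nb, n_test)
        if npos:
            tpr_sum += (pred[:, yte == 1]).mean(axis=1)
            tpr_cnt += 1
        if nneg:
            fpr_sum += (pred[:, yte == 0]).mean(axis=1)
            fpr_cnt += 1
    if n_skipped:
        log.info("%d repetition(s) skipped: single-class training draw",
                 n_skipped)

    mean_tpr = tpr_sum / np.maximum(tpr_cnt, 1)
    mean_fpr = fpr_sum / np.maximum(fpr_cnt, 1)
    auc = _mean_curve_auc(mean_fpr, mean_tpr)
    return ROCResult(
        descriptor=descriptor,
        biases=biases,
        mean_tpr=mean_tpr,
        mean_fpr=mean_fpr,
        auc=auc,
        n_reps=n_reps,
    )


def evaluate_feature_sets(
    selection: SelectionResult,
    fm: FeatureMatrix,
    n_test: int = 5,
    n_reps: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> list[ROCResult]:
    """ROC-validate each selected feature alone, the subset, and the full set.

    Every evaluation reuses the same seed, hence an identical sequence of
    leave-``n_test``-out splits, so the AUC comparisons are paired.
    """
    results = []
    for c in selection.selected_columns:
        label, month = fm.decode(c)
        results.append(
            svm_roc(
                fm.X[:, [c]], fm.y, n_test, n_reps, seed=seed, C=C, kernel=kernel,
                descriptor=f"single:{label}_{month}",
            )
        )
    results.append(
        svm_roc(
            fm.X[:, selection.selected_columns], fm.y, n_test, n_reps, seed=seed,
            C=C, kernel=kernel, descriptor="subset",
        )
    )
    results.append(
        svm_roc(
            fm.X, fm.y, n_test, n_reps, seed=seed, C=C, kernel=kernel,
            descriptor="full",
        )
    )
    return results


# ---------------------------------------------------------------------------
# mapping selections back to anatomy


@dataclass
class BiomarkerMap:
    """A selected column resolved to its lobule mask and display slices."""

    column: int
    label_id: int
    symmetric_label: int
    side: str
    month: int
    mask: np.ndarray
    centroid_voxel: tuple[int, int, int]


def map_biomarker(
    column: int, fm: FeatureMatrix, atlas: LabeledAtlas
) -> BiomarkerMap:
    """Decode a feature column to (lobule, side, month) plus its atlas mask."""
    label, month = fm.decode(column)
    mask = atlas.lobule_mask(label)
    c = np.mean(np.argwhere(mask), axis=0)
    return BiomarkerMap(
        column=column,
        label_id=label,
        symmetric_label=atlas.symmetric_id_of(label),
        side=atlas.side_of(label),
        month=month,
        mask=mask,
        centroid_voxel=tuple(int(round(v)) for v in c),
    )


def render_biomarker(
    bm: BiomarkerMap, atlas: LabeledAtlas, path: str | Path
) -> Path:
    """Render coronal/sagittal/axial template slices through the lobule
    centroid with the lobule mask overlaid in red, neurological convention
    (anatomical left on the left of the image)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x0, y0, z0 = bm.centroid_voxel
    tpl, msk = atlas.template, bm.mask
    views = [
        (f"coronal y={y0}", tpl[:, y0, :].T, msk[:, y0, :].T),
        (f"sagittal x={x0}", tpl[x0, :, :].T, msk[x0, :, :].T),
        (f"axial z={z0}", tpl[:, :, z0].T, msk[:, :, z0].T),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, (title, img, m) in zip(axes, views):
        ax.imshow(img, origin="lower", cmap="gray")
        overlay = np.zeros(m.shape + (4,))
        overlay[m] = (1.0, 0.0, 0.0, 0.6)
        ax.imshow(overlay, origin="lower")
        ax.set_title(title, fontsize=8)
        ax.axis("off")
    fig.suptitle(
        f"{bm.side} lobule {bm.symmetric_label}, month {bm.month}", fontsize=10
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path
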