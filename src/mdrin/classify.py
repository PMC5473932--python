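"""Two-state discrimination from single structural features.

A feature V (an inter-domain distance, angle, torsion, or a residue-pair
distance d_ij) is measured per snapshot, each snapshot carries a state
label ("ox"/"red"), and the question is how well a single threshold V_sep
separates the two states.  An optimal single-threshold (linear)
discriminator is found by exhaustive scan over candidate thresholds, and
an RBF-kernel SVM with library-default hyperparameters provides the
non-linear comparison: on unimodal features the two agree, on bimodal
features the SVM wins because no single interval boundary can capture two
modes.

Snapshots are assigned independently to train/test with probability 1/2,
a single split (no cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "LinearDiscriminator",
    "split_train_test",
    "fit_linear_threshold",
    "evaluate_svm_rbf",
    "residue_discrimination_matrix",
]


def split_train_test(n: int, seed: int) -> np.ndarray:
    """Independent train/test assignment, P(train) = 1/2 per snapshot.

    Returns a boolean mask (True = train).  The two sets are disjoint,
    cover all snapshots, and are of almost equal size for large n.
    Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 snapshots")
    rng = np.random.default_rng(seed)
    return rng.random(n) < 0.5


@dataclass
class LinearDiscriminator:
    """Single-threshold classifier on one feature.

    Snapshots with value > ``threshold`` are predicted as ``high_label``,
    the rest as ``low_label``.  ``accuracy`` is the test-split accuracy
    (equals the training accuracy when no split was given).
    """

    feature_name: str
    threshold: float
    high_label: str
    low_label: str
    train_accuracy: float
    test_accuracy: float

    @property
    def accuracy(self) -> float:
        return self.test_accuracy

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return np.where(values > self.threshold, self.high_label, self.low_label)


def _scan_thresholds(v: np.ndarray, y: np.ndarray, classes) -> tuple[float, int]:
    """Best (threshold, direction) by exhaustive scan on training data.

    Candidates are the midpoints of consecutive sorted unique values plus
    one below the minimum and one above the maximum; both inequality
    directions are tried.  Ties are broken by the larger margin (distance
    from the threshold to the nearest training value; the two extreme
    candidates sit at distance 1), then by the direction that puts
    ``classes[0]`` above the threshold, then by the smaller threshold.

    Returns the threshold and direction (0: classes[0] above, 1: below).
    """
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    is0 = (y[order] == classes[0]).astype(np.int64)
    n = len(vs)
    n0 = int(is0.sum())
    uniq = np.unique(vs)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    margins = np.concatenate([[1.0], np.diff(uniq) / 2.0, [1.0]])
    # counts at or below each candidate
    k = np.searchsorted(vs, cands, side="right")
    cum0 = np.concatenate([[0], np.cumsum(is0)])
    n0_le = cum0[k]
    n1_le = k - n0_le
    acc_above = (n0 - n0_le + n1_le) / n  # classes[0] predicted above threshold
    acc_below = ((n - n0) - n1_le + n0_le) / n
    best = (-1.0, -1.0, 0, 0.0)  # acc, margin, direction pref, -threshold
    out_t, out_d = cands[0], 0
    for direction, accs in enumerate((acc_above, acc_below)):
        for i in range(len(cands)):
            key = (accs[i], margins[i], -direction, -cands[i])
            if key > best:
                best = key
                out_t, out_d = float(cands[i]), direction
    return out_t, out_d


def fit_linear_threshold(
    values,
    labels,
    split: np.ndarray | None = None,
    feature_name: str = "V",
) -> LinearDiscriminator:
    """Optimal single-threshold discriminator V_sep for one feature.

    Scans every candidate threshold (midpoints of consecutive sorted
    unique training values, plus one candidate below and one above the
    range) in both directions and keeps the training-accuracy maximiser;
    accuracy is then reported on the test split.  With ``split=None`` the
    whole sample is both train and test.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if split is None:
        train = np.ones(len(v), dtype=bool)
        test = train
    else:
        train = np.asarray(split, dtype=bool)
        test = ~train
    classes = np.unique(y[train])
    if len(classes) != 2:
        raise ValueError(f"training set must contain exactly 2 classes, got {classes}")
    thr, direction = _scan_thresholds(v[train], y[train], classes)
    high, low = (
        (classes[0], classes[1]) if direction == 0 else (classes[1], classes[0])
    )
    pred = np.where(v > thr, high, low)
    train_acc = float(np.mean(pred[train] == y[train]))
    test_acc = float(np.mean(pred[test] == y[test])) if test.any() else train_acc
    return LinearDiscriminator(
        feature_name=feature_name,
        threshold=thr,
        high_label=str(high),
        low_label=str(low),
        train_accuracy=train_acc,
        test_accuracy=test_acc,
    )


def evaluate_svm_rbf(
    features,
    labels,
    split: np.ndarray | None = None,
    C: float = 1.0,
) -> float:
    """Test accuracy of an RBF-kernel SVM on one or more feature columns.

    Hyperparameters follow the common library defaults: regularisation
    C = 1 and kernel width gamma = 1 / (p * Var(features)) for p feature
    columns.  Trains on the train split only and reports accuracy on the
    test split.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    if split is None:
        train = np.ones(len(y), dtype=bool)
        test = train
    else:
        train = np.asarray(split, dtype=bool)
        test = ~train
    if len(np.unique(y[train])) < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(C=C, kernel="rbf", gamma="scale")
    clf.fit(x[train], y[train])
    if not test.any():
        test = train
    return float(clf.score(x[test], y[test]))


def residue_discrimination_matrix(
    distances: np.ndarray,
    labels,
    split: np.ndarray | None = None,
) -> np.ndarray:
    """Classification accuracy of every residue-pair distance d_ij.

    ``distances`` is (n_snapshots, R, R) with per-frame symmetric Ca-Ca
    distance matrices pooled over both states, ``labels`` the per-snapshot
    state.  Entry (i, j) is the test accuracy of the optimal
    single-threshold classifier on d_ij, floored at 0.5 (an uninformative
    pair cannot beat a coin flip); the diagonal is fixed at 0.5 (d_ii = 0
    carries no information).
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels)
    if d.ndim != 3 or d.shape[1] != d.shape[2]:
        raise ValueError("distances must be (n_snapshots, R, R)")
    if len(y) != d.shape[0]:
        raise ValueError("labels length != number of snapshots")
    r = d.shape[1]
    acc = np.full((r, r), 0.5)
    for i in range(r):
        for j in range(i + 1, r):
            disc = fit_linear_threshold(d[:, i, j], y, split=split)
            acc[i, j] = acc[j, i] = max(0.5, disc.test_accuracy)
    return acc
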