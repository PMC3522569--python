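"""Feature ranking and subset selection: SVM-RFE, the prediction-risk
variant, mRMR and information gain.

All rankers return a :class:`Ranking` — a best-first permutation of
feature indices plus the per-feature criterion scores recorded at
selection/removal time.  Mutual information and entropies are measured in
bits (log base 2), on discretized features for mRMR and IG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class Ranking:
    """An ordered list of feature indices, best first."""

    order: tuple[int, ...]
    scores: tuple[float, ...]
    method: str

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ParameterError("ranking order must be a permutation of 0..p-1")

    def top(self, k: int) -> tuple[int, ...]:
        return self.order[:k]


# ---------------------------------------------------------------------------
# discretization (for the information-theoretic rankers)

@dataclass(frozen=True)
class Discretizer:
    """Per-feature quantile (or equal-width) binning, fit on training data only."""

    n_bins: int = 3
    strategy: str = "quantile"  # or "equal-width"
    cuts: tuple[np.ndarray, ...] = field(default=())

    def fit(self, X: np.ndarray) -> "Discretizer":
        X = np.asarray(X, dtype=np.float64)
        cuts = []
        for j in range(X.shape[1]):
            col = X[:, j]
            if self.strategy == "quantile":
                qs = np.quantile(col, np.linspace(0, 1, self.n_bins + 1)[1:-1])
            elif self.strategy == "equal-width":
                qs = np.linspace(col.min(), col.max(), self.n_bins + 1)[1:-1]
            else:
                raise ParameterError(f"unknown strategy {self.strategy!r}")
            qs = np.unique(qs)  # strictly increasing cut points
            cuts.append(qs)
        return Discretizer(self.n_bins, self.strategy, tuple(cuts))

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.cuts:
            raise ParameterError("discretizer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(X.shape, dtype=np.intp)
        for j, qs in enumerate(self.cuts):
            out[:, j] = np.searchsorted(qs, X[:, j], side="right")
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# entropies on integer-coded columns

def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI(a; b) in bits from the empirical joint distribution."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.bincount(ia * ub.size + ib, minlength=ua.size * ub.size).astype(np.float64)
    joint = joint.reshape(ua.size, ub.size) / a.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    indep = np.outer(px, py)
    return float((joint[nz] * np.log2(joint[nz] / indep[nz])).sum())


# ---------------------------------------------------------------------------
# rankers

def svm_rfe_rank(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> Ranking:
    """SVM recursive feature elimination with the weight-vector criterion.

    Removes one feature per iteration — the one with the smallest
    importance sum_machines w_j^2 over the one-vs-one linear SVMs — and
    retrains on the survivors.  The ranking is the reverse removal order;
    the recorded score is the importance at removal time.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    p = X.shape[1]
    if p < 1:
        raise ParameterError("need at least one feature")
    remaining = list(range(p))
    removal: list[tuple[int, float]] = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        importance = (clf.coef_**2).sum(axis=0)
        j = int(np.argmin(importance))  # ties: lowest index (argmin convention)
        removal.append((remaining[j], float(importance[j])))
        del remaining[j]
    removal.append((remaining[0], float("inf")))
    order = tuple(idx for idx, _ in reversed(removal))
    scores = tuple(s for _, s in reversed(removal))
    return Ranking(order=order, scores=scores, method="svm-rfe")


def prediction_risk_rank(X: np.ndarray, y: np.ndarray, model=None) -> Ranking:
    """Rank features by prediction risk: the increase in training error
    when a feature's column is replaced by its mean value.

    A constant column has zero risk (the replacement is the identity).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    clf = model if model is not None else SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    base_err = float(np.mean(clf.predict(X) != y))
    p = X.shape[1]
    risks = np.empty(p)
    for j in range(p):
        Xj = X.copy()
        Xj[:, j] = X[:, j].mean()
        risks[j] = float(np.mean(clf.predict(Xj) != y)) - base_err
    order = np.lexsort((np.arange(p), -risks))  # descending risk, ties by index
    return Ranking(
        order=tuple(int(i) for i in order),
        scores=tuple(float(risks[i]) for i in order),
        method="prediction-risk",
    )


def ig_rank(X_disc: np.ndarray, y: np.ndarray) -> Ranking:
    """Rank by information gain IG(f) = H(Y) - H(Y|F) on discretized data."""
    X_disc = np.asarray(X_disc)
    y = np.asarray(y)
    if _entropy_bits(y) == 0.0:
        raise DegenerateInputError("label vector has zero entropy")
    p = X_disc.shape[1]
    gains = np.array([mutual_information(X_disc[:, j], y) for j in range(p)])
    order = np.lexsort((np.arange(p), -gains))
    return Ranking(
        order=tuple(int(i) for i in order),
        scores=tuple(float(gains[i]) for i in order),
        method="ig",
    )


def mrmr_rank(X_disc: np.ndarray, y: np.ndarray) -> Ranking:
    """Greedy mRMR (MID form): maximize MI(f; y) - mean MI(f; selected)."""
    X_disc = np.asarray(X_disc)
    y = np.asarray(y)
    if _entropy_bits(y) == 0.0:
        raise DegenerateInputError("label vector has zero entropy")
    p = X_disc.shape[1]
    relevance = np.array([mutual_information(X_disc[:, j], y) for j in range(p)])
    redundancy = np.zeros(p)  # running sum of MI(f; selected)
    selected: list[int] = []
    scores: list[float] = []
    candidates = list(range(p))
    while candidates:
        crit = np.array(
            [
                relevance[j] - (redundancy[j] / len(selected) if selected else 0.0)
                for j in candidates
            ]
        )
        k = int(np.argmax(crit))  # ties: lowest candidate index
        j = candidates.pop(k)
        selected.append(j)
        scores.append(float(crit[k]))
        for c in candidates:
            redundancy[c] += mutual_information(X_disc[:, c], X_disc[:, j])
    return Ranking(order=tuple(selected), scores=tuple(scores), method="mrmr")


# ---------------------------------------------------------------------------
# subset-size choice

def choose_subset_size(
    rank: Ranking,
    X: np.ndarray,
    y: np.ndarray,
    classifier_factory=None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Evaluate nested prefixes of a ranking by cross-validated accuracy.

    Returns ``(selected_indices, curve)`` where ``curve[k-1]`` is the CV
    accuracy of the top-k prefix; the selected prefix is the smallest one
    whose accuracy is within one standard error of the best.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    factory = classifier_factory or (lambda: SVC(kernel="poly", degree=3, C=1.0, gamma="auto"))
    p = X.shape[1]
    n_folds = min(n_folds, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    curve = np.empty(p)
    fold_acc = np.empty((p, len(splits)))
    for k in range(1, p + 1):
        cols = list(rank.order[:k])
        for f, (tr, te) in enumerate(splits):
            clf = factory()
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            fold_acc[k - 1, f] = np.mean(clf.predict(X[np.ix_(te, cols)]) == y[te])
        curve[k - 1] = fold_acc[k - 1].mean()

    best = int(np.argmax(curve))
    se = fold_acc[best].std(ddof=1) / np.sqrt(len(splits)) if len(splits) > 1 else 0.0
    for k in range(p):
        if curve[k] >= curve[best] - se:
            return rank.order[: k + 1], curve
    return rank.order, curve
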