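"""The five compared classifiers: one-vs-one SVM with majority voting,
class-weighted SVM, kNN, Gaussian Naive Bayes, and MAPLSC.

Tie-breaking is deterministic everywhere: vote ties fall back to the
largest aggregate decision margin and then to the fixed (sorted) class
order; kNN distance ties are broken by training-sample index.

MAPLSC is a reconstruction of the multi-class asymmetric-PLS classifier:
each class pair gets a 2-component PLS projection whose 1-D latent score
is converted to a pairwise probability through class-conditional Gaussians
with *equal* priors (so the majority class cannot dominate the threshold),
and the pairwise probabilities are coupled into K posteriors by the
Hastie-Tibshirani iterative scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import ParameterError

#: Canonical lip color classes, in fixed tie-break order.
LIP_CLASSES = ("Deep-red", "Pale", "Purple", "Red")


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "poly"
    degree: int = 3
    C: float = 1.0
    gamma: str | float = "auto"  # 1 / n_features
    coef0: float = 0.0


def class_weights(class_sizes: dict) -> dict:
    """Per-class penalty multipliers at the inverse ratio of class sizes,
    normalized so the largest class has weight 1."""
    if any(s <= 0 for s in class_sizes.values()):
        raise ParameterError("class sizes must be positive")
    largest = max(class_sizes.values())
    return {c: largest / s for c, s in class_sizes.items()}


@dataclass
class OvoEnsemble:
    """One binary soft-margin SVM per unordered class pair, majority voting."""

    classes: tuple
    machines: dict = field(default_factory=dict)  # (ci, cj) -> fitted SVC
    config: SVMConfig = field(default_factory=SVMConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        k = len(self.classes)
        votes = np.zeros((X.shape[0], k))
        margins = np.zeros((X.shape[0], k))
        cls_index = {c: i for i, c in enumerate(self.classes)}
        for (ci, cj), clf in self.machines.items():
            # decision_function > 0 favors the alphabetically later class of
            # the pair under sklearn's internal ordering; map explicitly
            dec = clf.decision_function(X)
            pos = clf.classes_[1]
            neg = clf.classes_[0]
            wins_pos = dec > 0
            votes[:, cls_index[pos]] += wins_pos
            votes[:, cls_index[neg]] += ~wins_pos
            margins[:, cls_index[pos]] += dec
            margins[:, cls_index[neg]] -= dec
        out = np.empty(X.shape[0], dtype=object)
        for i in range(X.shape[0]):
            best = np.flatnonzero(votes[i] == votes[i].max())
            if best.size > 1:
                sub = best[margins[i, best] == margins[i, best].max()]
                best = sub  # still ties -> fixed class order (lowest index)
            out[i] = self.classes[int(best[0])]
        return out


def train_ovo_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    weights: dict | None = None,
) -> OvoEnsemble:
    """Train one binary SVM per class pair on that pair's samples only.

    ``weights`` maps class label -> penalty multiplier (the weighted-SVM
    variant); ``None`` gives the plain equal-penalty machine.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    config = config or SVMConfig()
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ParameterError("need at least two classes")
    ens = OvoEnsemble(classes=classes, config=config)
    for ci, cj in combinations(classes, 2):
        sel = (y == ci) | (y == cj)
        if min((y[sel] == ci).sum(), (y[sel] == cj).sum()) < 2:
            warnings.warn(f"pair ({ci}, {cj}) has a near-empty class", stacklevel=2)
        cw = {c: weights[c] for c in (ci, cj)} if weights else None
        clf = SVC(
            kernel=config.kernel,
            degree=config.degree,
            C=config.C,
            gamma=config.gamma,
            coef0=config.coef0,
            class_weight=cw,
        )
        clf.fit(X[sel], y[sel])
        ens.machines[(ci, cj)] = clf
    return ens


def train_wsvm(X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None) -> OvoEnsemble:
    """Weighted SVM: penalties at the inverse ratio of training class sizes."""
    y = np.asarray(y)
    sizes = {c: int((y == c).sum()) for c in np.unique(y)}
    return train_ovo_svm(X, y, config, weights=class_weights(sizes))


def predict_vote(ens: OvoEnsemble, x: np.ndarray):
    """Majority-vote prediction for a single feature vector."""
    return ens.predict(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# kNN

def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """k-nearest-neighbor prediction with Euclidean distance.

    Distance ties are broken by training-sample index; vote ties by the
    fixed sorted class order.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if k > X_train.shape[0]:
        raise ParameterError("k exceeds the number of training samples")
    Xq = np.atleast_2d(np.asarray(X_query, dtype=np.float64))
    classes = sorted(np.unique(y_train).tolist())
    cls_index = {c: i for i, c in enumerate(classes)}
    d = cdist(Xq, X_train)
    out = np.empty(Xq.shape[0], dtype=object)
    idx = np.arange(X_train.shape[0])
    for i in range(Xq.shape[0]):
        order = np.lexsort((idx, d[i]))[:k]
        counts = np.zeros(len(classes))
        for j in order:
            counts[cls_index[y_train[j]]] += 1
        out[i] = classes[int(np.argmax(counts))]
    return out


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes

def nb_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Gaussian Naive Bayes: labels, posteriors and the class order.

    Per-class per-feature Gaussians with variance flooring; posteriors are
    proportional to prior times the product of densities and sum to 1.
    """
    clf = GaussianNB()
    clf.fit(np.asarray(X_train, dtype=np.float64), np.asarray(y_train))
    Xq = np.atleast_2d(np.asarray(X_query, dtype=np.float64))
    post = clf.predict_proba(Xq)
    labels = clf.predict(Xq)
    return labels, post, tuple(clf.classes_.tolist())


# ---------------------------------------------------------------------------
# MAPLSC

def _pairwise_coupling(r: np.ndarray, n: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Hastie-Tibshirani coupling of pairwise probabilities into posteriors.

    ``r[i, j]`` estimates P(class i | class i or j); ``n[i, j]`` is the
    number of training samples behind that estimate.  Returns p with
    sum(p) == 1.
    """
    k = r.shape[0]
    p = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        mu = p[:, None] / (p[:, None] + p[None, :])
        np.fill_diagonal(mu, 0.5)
        new = p.copy()
        for i in range(k):
            num = sum(n[i, j] * r[i, j] for j in range(k) if j != i)
            den = sum(n[i, j] * mu[i, j] for j in range(k) if j != i)
            if den > 0:
                new[i] = p[i] * num / den
        new /= new.sum()
        if np.abs(new - p).max() < tol:
            p = new
            break
        p = new
    return p


class MAPLSC:
    """Multi-class asymmetric PLS classifier via pairwise coupling."""

    def __init__(self, n_components: int = 2, var_floor: float = 1e-9):
        self.n_components = n_components
        self.var_floor = var_floor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MAPLSC":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = tuple(sorted(np.unique(y).tolist()))
        if len(self.classes_) < 2:
            raise ParameterError("need at least two classes")
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.pair_models_: dict = {}
        self.pair_counts_: dict = {}
        for ci, cj in combinations(self.classes_, 2):
            sel = (y == ci) | (y == cj)
            Xp = X[sel]
            yp = (y[sel] == ci).astype(np.float64)  # 1 for the first class
            ncomp = min(self.n_components, Xp.shape[1], Xp.shape[0] - 1)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pls = PLSRegression(n_components=max(ncomp, 1), scale=False)
                    pls.fit(Xp, yp)
                    score = pls.predict(Xp).ravel()
                stats = {}
                for lab, cls in ((1.0, ci), (0.0, cj)):
                    s = score[yp == lab]
                    stats[cls] = (s.mean(), max(s.var(), self.var_floor))
                self.pair_models_[(ci, cj)] = (pls, stats)
            except Exception:
                warnings.warn(
                    f"PLS projection failed for pair ({ci}, {cj}); "
                    "falling back to priors",
                    stacklevel=2,
                )
                self.pair_models_[(ci, cj)] = None
            self.pair_counts_[(ci, cj)] = int(sel.sum())
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        k = len(self.classes_)
        idx = {c: i for i, c in enumerate(self.classes_)}
        out = np.empty((X.shape[0], k))
        r_all = np.full((X.shape[0], k, k), 0.5)
        n = np.zeros((k, k))
        for (ci, cj), model in self.pair_models_.items():
            i, j = idx[ci], idx[cj]
            n[i, j] = n[j, i] = self.pair_counts_[(ci, cj)]
            if model is None:
                pr = self.priors_[i] / (self.priors_[i] + self.priors_[j])
                r_all[:, i, j] = pr
                r_all[:, j, i] = 1.0 - pr
                continue
            pls, stats = model
            score = pls.predict(X).ravel()
            # equal-prior Gaussian posterior on the latent score
            mi, vi = stats[ci]
            mj, vj = stats[cj]
            li = np.exp(-0.5 * (score - mi) ** 2 / vi) / np.sqrt(vi)
            lj = np.exp(-0.5 * (score - mj) ** 2 / vj) / np.sqrt(vj)
            denom = li + lj
            rij = np.where(denom > 0, li / np.where(denom > 0, denom, 1.0), 0.5)
            rij = np.clip(rij, 1e-9, 1 - 1e-9)
            r_all[:, i, j] = rij
            r_all[:, j, i] = 1.0 - rij
        for q in range(X.shape[0]):
            out[q] = _pairwise_coupling(r_all[q], n)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array([self.classes_[int(i)] for i in proba.argmax(axis=1)], dtype=object)


def maplsc_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Convenience wrapper: fit MAPLSC and return labels, posteriors, classes."""
    model = MAPLSC().fit(X_train, y_train)
    Xq = np.atleast_2d(np.asarray(X_query, dtype=np.float64))
    proba = model.predict_proba(Xq)
    labels = np.array([model.classes_[int(i)] for i in proba.argmax(axis=1)], dtype=object)
    return labels, proba, model.classes_
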