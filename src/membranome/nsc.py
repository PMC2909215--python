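"""Nearest shrunken centroid classification.

The classifier standardizes each gene's class-centroid offset from the
overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

where s_i is the pooled within-class standard deviation and s0 a fudge
factor (default: median of the s_i).  Offsets are soft-thresholded by the
shrinkage parameter Delta,

    d'_ik = sign(d_ik) * (|d_ik| - Delta)_+ ,

which zeroes most genes and implicitly selects the classifier's gene list.
Samples are assigned to the class minimizing the discriminant

    delta_k(x) = sum_{i active} (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.

Ties break to the lexicographically smallest class label.  With no active
gene the discriminant reduces to the prior term and prediction falls back
to the prior argmax.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["ShrunkenCentroidClassifier"]


class ShrunkenCentroidClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style nearest shrunken centroid classifier.

    Parameters
    ----------
    shrinkage : float, default 0.0
        Soft-threshold Delta applied to the standardized offsets; at 0 all
        genes stay active.
    priors : 'proportional' or array-like
        Class prior probabilities; 'proportional' uses training frequencies.
    s0 : 'median' or float
        Fudge factor added to each gene's pooled scale; 'median' uses the
        median of the pooled scales.
    """

    def __init__(self, shrinkage: float = 0.0, priors="proportional", s0="median"):
        self.shrinkage = shrinkage
        self.priors = priors
        self.s0 = s0

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        K = len(self.classes_)
        counts = np.array([(y == c).sum() for c in self.classes_])
        if (counts < 2).any():
            small = [c for c, m in zip(self.classes_, counts) if m < 2]
            raise ValueError(f"classes with < 2 samples: {small}")

        centroids = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        overall = X.mean(axis=0)
        # pooled within-class variance with n - K degrees of freedom
        ss = np.zeros(p)
        for c, cent in zip(self.classes_, centroids):
            ss += ((X[y == c] - cent) ** 2).sum(axis=0)
        pooled = np.sqrt(ss / (n - K))
        s0 = float(np.median(pooled)) if self.s0 == "median" else float(self.s0)
        if s0 < 0:
            raise ValueError("s0 must be >= 0")

        m = np.sqrt(1.0 / counts - 1.0 / n)
        d = (centroids - overall) / (m[:, None] * (pooled + s0)[None, :])
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.shrinkage, 0.0)
        shrunken = overall + m[:, None] * (pooled + s0)[None, :] * d_shrunk

        if self.priors == "proportional":
            priors = counts / n
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (K,) or not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must be one probability per class")

        self.overall_centroid_ = overall
        self.class_centroids_ = centroids
        self.pooled_scale_ = pooled
        self.s0_ = s0
        self.class_factors_ = m
        self.offsets_ = d
        self.shrunken_offsets_ = d_shrunk
        self.shrunken_centroids_ = shrunken
        self.priors_ = priors
        self.class_counts_ = counts
        self.active_mask_ = (d_shrunk != 0).any(axis=0)
        self.n_features_in_ = p
        return self

    @property
    def n_active_genes_(self) -> int:
        check_is_fitted(self)
        return int(self.active_mask_.sum())

    def decision_function(self, X):
        """Per-class discriminant scores delta_k (lower is closer)."""
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from training data")
        active = self.active_mask_
        scale2 = (self.pooled_scale_ + self.s0_) ** 2
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff2 = (X[:, active] - self.shrunken_centroids_[k, active]) ** 2
            scores[:, k] = (diff2 / scale2[active]).sum(axis=1) - 2.0 * np.log(
                self.priors_[k]
            )
        return scores

    def predict(self, X):
        scores = self.decision_function(X)
        # argmin takes the first (lexicographically smallest) class on ties
        return self.classes_[np.argmin(scores, axis=1)]

    def predict_proba(self, X):
        scores = self.decision_function(X)
        logp = -0.5 * scores
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)
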