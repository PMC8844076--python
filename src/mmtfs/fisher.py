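"""Fisher-score filtering of a feature block.

The Fisher score of feature i is the ratio of between-class to
sample-weighted within-class divergence,

    F(x_i) = sum_k n_k (mu_ik - mu_i)^2
             ------------------------------------
             sum_k n_k sum_{j in k} (x_ij - mu_ik)^2  + eps,

where n_k is the size of class k, mu_ik the class mean and mu_i the
overall mean of the feature.  Larger scores mean stronger univariate
separation.  In the pipeline the filter is applied to the genotype block
only, reducing it to a width comparable to the imaging block before joint
selection; the inner within-class sum is multiplied by n_k, a weighting
that differs from the unweighted pooled sum and is used here deliberately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .preprocess import DEFAULT_EPS


@dataclass
class FisherScoreReport:
    """Scores, ranking and (after selection) the retained index set."""

    scores: np.ndarray                       # per-feature F >= 0
    ranking: np.ndarray                      # indices, descending score, ties by index
    class_counts: dict[str, int]
    class_means: np.ndarray                  # c x d per-class feature means
    overall_means: np.ndarray                # d
    eps: float
    retained: np.ndarray | None = None       # sorted top-m indices
    m: int | None = None

    def to_records(self, feature_names: list[str] | None = None) -> list[dict]:
        kept = set(self.retained.tolist()) if self.retained is not None else set()
        rank_of = np.empty(len(self.scores), dtype=int)
        rank_of[self.ranking] = np.arange(len(self.scores))
        return [
            {
                "feature": feature_names[i] if feature_names else str(i),
                "score": float(self.scores[i]),
                "rank": int(rank_of[i]),
                "retained": i in kept,
            }
            for i in range(len(self.scores))
        ]


def fisher_scores(X: np.ndarray, y: np.ndarray, eps: float = DEFAULT_EPS) -> FisherScoreReport:
    """Score every column of ``X`` (samples as rows) against labels ``y``.

    ``eps`` is added to the denominator so zero-within-variance features
    stay finite (and rank first when their class means differ).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ConfigurationError("X must be N x d with one label per row")
    if eps <= 0:
        raise ConfigurationError("epsilon must be positive")
    classes, inv = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ConfigurationError("between-class divergence undefined for a single class")
    n_k = np.bincount(inv).astype(float)              # (c,)
    overall = X.mean(axis=0)                          # (d,)
    # per-class means via index accumulation
    sums = np.zeros((len(classes), X.shape[1]))
    np.add.at(sums, inv, X)
    mu = sums / n_k[:, None]                          # (c, d)
    s_b = (n_k[:, None] * (mu - overall) ** 2).sum(axis=0)
    within = np.zeros((len(classes), X.shape[1]))
    np.add.at(within, inv, (X - mu[inv]) ** 2)        # per-class sum of squares
    denom = (n_k[:, None] * within).sum(axis=0) + eps
    scores = s_b / denom
    ranking = np.argsort(-scores, kind="stable")      # ties -> ascending index
    return FisherScoreReport(
        scores=scores,
        ranking=ranking,
        class_counts={str(c): int(n) for c, n in zip(classes, n_k)},
        class_means=mu,
        overall_means=overall,
        eps=eps,
    )


def select_top_m(
    report: FisherScoreReport, m: int, X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Retain the m top-scoring features; ties break toward lower index.

    Returns the retained indices **sorted ascending** (original feature
    order) and, when ``X`` is given, the reduced column subset.  Requesting
    more features than exist warns and keeps everything.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    d = len(report.scores)
    if m > d:
        warnings.warn(f"requested top {m} of {d} features; retaining all", stacklevel=2)
        m = d
    retained = np.sort(report.ranking[:m])
    report.retained = retained
    report.m = m
    reduced = None if X is None else np.asarray(X, dtype=float)[:, retained]
    return retained, reduced
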