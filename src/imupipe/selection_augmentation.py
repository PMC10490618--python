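"""Recursive feature elimination and genetic-crossover augmentation.

Each feature bank is pruned independently by recursive feature elimination
(RFE): an L2-regularized linear classifier is fit on the standardized
surviving features, the lowest-|coefficient| 5% are dropped, and the loop
repeats until ``n_keep`` remain.  The surviving training vectors are then
augmented by a crossover-only genetic scheme: every vector is crossed with
a freshly drawn same-class partner by swapping middle thirds, ten times,
multiplying the corpus by eleven.

Augmentation belongs on the training split only — crossing before the
train/test split would leak test information into training offspring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionResult",
    "AugmentedDataset",
    "rfe_select",
    "ga_crossover",
    "ga_augment",
    "RecursiveBankSelector",
    "GeneticAugmenter",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Surviving feature slots plus the order features were eliminated in."""

    kept_indices: np.ndarray
    ranking: list[int]                 # elimination order, first-dropped first
    estimator_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        if len(np.unique(self.kept_indices)) != len(self.kept_indices):
            raise ValueError("kept_indices must be unique")


@dataclass
class AugmentedDataset:
    """Originals followed by offspring, with per-offspring provenance."""

    vectors: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[int, int, int]]   # (parent, partner, generation)

    @property
    def n_original(self) -> int:
        return len(self.vectors) - len(self.provenance)


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------

class RecursiveBankSelector:
    """sklearn-style selector implementing the elimination loop.

    Parameters
    ----------
    n_keep : int or None
        Number of surviving features; ``None`` keeps ``keep_fraction``.
    keep_fraction : float
        Fraction retained when ``n_keep`` is None (default 0.5).
    step_fraction : float
        Fraction of remaining features dropped per iteration (ceil, >= 1).

    Importance is the L2 norm of a feature's logistic-regression
    coefficients across classes, computed on standardized features; exact
    ties are broken by dropping the higher index first.
    """

    def __init__(self, n_keep: int | None = None, keep_fraction: float = 0.5,
                 step_fraction: float = 0.05, C: float = 1.0,
                 max_iter: int = 200):
        self.n_keep = n_keep
        self.keep_fraction = keep_fraction
        self.step_fraction = step_fraction
        self.C = C
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_keep", "keep_fraction", "step_fraction", "C", "max_iter")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _ranker(self):
        # default penalty is L2; C controls its strength
        return LogisticRegression(C=self.C, max_iter=self.max_iter)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes for the RFE ranker")
        n_features = X.shape[1]
        n_keep = self.n_keep
        if n_keep is None:
            n_keep = max(1, int(round(self.keep_fraction * n_features)))
        if not 0 < n_keep <= n_features:
            raise ValueError(f"n_keep={n_keep} outside [1, {n_features}]")
        remaining = list(range(n_features))
        eliminated: list[int] = []
        while len(remaining) > n_keep:
            Xs = StandardScaler().fit_transform(X[:, remaining])
            clf = self._ranker().fit(Xs, y)
            importance = np.linalg.norm(clf.coef_, axis=0)
            n_drop = min(max(1, math.ceil(self.step_fraction * len(remaining))),
                         len(remaining) - n_keep)
            # ascending importance; equal importance drops the higher index
            order = sorted(range(len(remaining)),
                           key=lambda i: (importance[i], -remaining[i]))
            drop = sorted(order[:n_drop], reverse=True)
            for pos in drop:
                eliminated.append(remaining.pop(pos))
        self.result_ = SelectionResult(
            kept_indices=np.asarray(sorted(remaining), dtype=int),
            ranking=eliminated,
            estimator_config={"ranker": "logistic_l2", "C": self.C,
                              "step_fraction": self.step_fraction,
                              "n_keep": int(n_keep)},
        )
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[self.result_.kept_indices] = True
        self.n_features_in_ = n_features
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.result_.kept_indices]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_support(self, indices: bool = False):
        return self.result_.kept_indices if indices else self.support_


def rfe_select(X, y, n_keep: int, cfg: dict | None = None) -> SelectionResult:
    """Functional wrapper over :class:`RecursiveBankSelector`."""
    cfg = cfg or {}
    sel = RecursiveBankSelector(n_keep=n_keep, **cfg)
    return sel.fit(X, y).result_


# ---------------------------------------------------------------------------
# genetic augmentation
# ---------------------------------------------------------------------------

def ga_crossover(a, b) -> np.ndarray:
    """Middle-third swap: child = [a_first, b_middle, a_last].

    Both vectors are split at ``floor(L/3)`` and ``L - floor(L/3)`` (so for
    L=7 the segments have lengths 2, 3, 2) and the central parts swapped.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"parent shapes differ: {a.shape} vs {b.shape}")
    L = len(a)
    if L < 3:
        raise ValueError("vectors must have length >= 3")
    cut = L // 3
    child = a.copy()
    child[cut:L - cut] = b[cut:L - cut]
    return child


class GeneticAugmenter:
    """Crossover-only augmentation producing ``n_generations`` offspring
    per vector (imblearn-style ``fit_resample``).

    Each generation crosses the *original* vector with a freshly sampled
    partner (``chained=False``) or the previous offspring (``chained=True``).
    Note that under the pure middle-third swap the two modes produce
    identical offspring — the outer thirds persist through a chain and the
    middle is always the newest partner's — so the flag only documents
    which lineage the provenance records.
    Partners come from the same class by default: hybridizing across classes
    while inheriting the first parent's label would inject label noise.
    Offspring inherit the first parent's label.  Classes with a single
    vector are copied unchanged with a warning.
    """

    def __init__(self, n_generations: int = 10, same_class: bool = True,
                 chained: bool = False, random_state: int | None = None):
        self.n_generations = n_generations
        self.same_class = same_class
        self.chained = chained
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_generations", "same_class", "chained", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y) -> AugmentedDataset:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        offspring = []
        off_labels = []
        provenance = []
        for i in range(n):
            if self.same_class:
                pool = np.nonzero(y == y[i])[0]
            else:
                pool = np.arange(n)
            pool = pool[pool != i]
            if pool.size == 0:
                logger.warning("class %r has a single vector: copied without "
                               "crossover", y[i])
                for g in range(self.n_generations):
                    offspring.append(X[i].copy())
                    off_labels.append(y[i])
                    provenance.append((i, i, g))
                continue
            base = X[i]
            for g in range(self.n_generations):
                partner = int(rng.choice(pool))
                child = ga_crossover(base, X[partner])
                offspring.append(child)
                off_labels.append(y[i])
                provenance.append((i, partner, g))
                if self.chained:
                    base = child
        vectors = np.vstack([X] + [np.asarray(offspring)]) if offspring else X.copy()
        labels = np.concatenate([y, np.asarray(off_labels, dtype=y.dtype)]) \
            if off_labels else y.copy()
        return AugmentedDataset(vectors=vectors, labels=labels,
                                provenance=provenance)


def ga_augment(X, y, n_generations: int = 10,
               seed: int | None = None, same_class: bool = True,
               chained: bool = False) -> AugmentedDataset:
    """Functional wrapper over :class:`GeneticAugmenter`."""
    if len(np.asarray(X)) == 0:
        raise ValueError("cannot augment an empty dataset")
    aug = GeneticAugmenter(n_generations=n_generations, same_class=same_class,
                           chained=chained, random_state=seed)
    return aug.fit_resample(X, y)
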