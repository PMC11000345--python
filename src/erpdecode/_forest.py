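"""Seeded random forest: bootstrap-bagged CART trees with per-split feature
subsampling and soft voting.

A deliberately thin ensemble over :class:`sklearn.tree.DecisionTreeClassifier`
so that tens of thousands of tiny fits (permutation nulls at desk scale) stay
cheap on one CPU; predictions average per-tree class probabilities, as the
standard forest does.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier


class SeededRandomForest:
    """Random forest with fully seed-determined bootstrap and splits.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap-bagged trees.
    max_features : str or float
        Per-split candidate-feature rule: "sqrt", "log2", or a fraction
        in (0, 1].
    seed : int
        Fixes bootstrap resampling and every tree's split randomness.
    """

    def __init__(self, n_trees: int = 100, max_features: str | float = "sqrt", seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(max_features, float) and not 0 < max_features <= 1:
            raise ValueError("fractional max_features must be in (0, 1]")
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self._trees: list[DecisionTreeClassifier] = []
        self.n_classes_ = 0

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int | None = None) -> "SeededRandomForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.n_classes_ = int(n_classes if n_classes is not None else y.max() + 1)
        self._trees = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)  # bootstrap sample, with replacement
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y[idx], check_input=False)
            self._trees.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._trees:
            raise RuntimeError("fit before predict")
        X = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.zeros((X.shape[0], self.n_classes_))
        for tree in self._trees:
            proba = tree.predict_proba(X, check_input=False)
            # a bootstrap sample may miss a class; map through tree.classes_
            votes[:, tree.classes_.astype(int)] += proba
        return votes.argmax(axis=1)
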