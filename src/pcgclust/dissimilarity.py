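"""Unsupervised random-forest dissimilarity over binary PCG profiles.

The trick (due to Breiman & Cutler's "Addcl1" device) turns an unsupervised
problem into classification: a *synthetic reference* of the same size is
drawn by resampling each input column independently from its empirical
marginal, destroying between-variable dependence.  Random forests trained to
separate original from synthetic rows then carve the feature space along the
data's dependence structure, and the fraction of trees in which two points
share a terminal leaf (the *proximity*) becomes a similarity.  Ten forests
are trained and their proximity matrices averaged to damp forest-to-forest
randomness; the distance is ``1 - proximity / n_trees``.

The out-of-bag (OOB) misclassification error of the original-vs-synthetic
task doubles as a structure diagnostic: near 0.5 the forest cannot tell the
data from its independent-marginal shadow, i.e. there is little joint
structure to cluster.

Proximity matrices are dense over all points (original + synthetic); the
practical ceiling is ~10^4 points, which is why the method is run on a
subsample of large cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier

from .errors import StateError, ValidationError


@dataclass
class ReferenceSet:
    """Original rows stacked with their synthetic independent-marginal shadow.

    ``features`` has shape (2n, p): originals first, then n synthetic rows;
    ``is_original`` marks provenance per row.
    """

    features: np.ndarray
    is_original: np.ndarray

    @property
    def n_original(self) -> int:
        return int(self.is_original.sum())


@dataclass
class ForestConfig:
    """Hyperparameters of the forest ensemble.

    The ensemble size of 10 forests is part of the method; per-forest tree
    settings follow common RF classification defaults (sqrt(p) features per
    split, unbounded depth) except for a minimum leaf size of 5: proximity
    is resolved at leaf granularity, and fully grown trees on sparse binary
    profiles isolate points in near-singleton leaves, compressing all
    distances toward 1 and washing out the within-group contrast the
    embedding needs.  All settings are configurable.
    """

    n_forests: int = 10
    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_forests < 1 or self.n_trees < 1:
            raise ValidationError("n_forests and n_trees must be >= 1")


@dataclass
class DissimilarityResult:
    """Averaged proximities, derived distances and per-forest OOB errors."""

    proximity_mean: np.ndarray  # (2n, 2n), entries in [0, n_trees], diag n_trees
    distance: np.ndarray        # 1 - proximity_mean / n_trees, in [0, 1]
    oob_errors: np.ndarray      # one misclassification rate per forest
    n_trees: int
    n_forests: int

    @property
    def oob_mean(self) -> float:
        return float(self.oob_errors.mean())


def _as_feature_matrix(original) -> np.ndarray:
    if isinstance(original, pd.DataFrame):
        original = original.to_numpy()
    X = np.asarray(original, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("original table must be a nonempty 2-D array")
    return X


def make_reference(original, seed: int = 0) -> ReferenceSet:
    """Build the synthetic reference by column-wise marginal resampling.

    Each synthetic column is drawn with replacement from the corresponding
    original column, independently of the other columns, so synthetic rows
    follow the product of the empirical marginals.
    """
    X = _as_feature_matrix(original)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    synthetic = np.column_stack(
        [rng.choice(X[:, j], size=n, replace=True) for j in range(X.shape[1])]
    )
    features = np.vstack([X, synthetic])
    is_original = np.zeros(2 * n, dtype=bool)
    is_original[:n] = True
    return ReferenceSet(features=features, is_original=is_original)


def _forest_seeds(cfg: ForestConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    return rng.integers(0, 2**31 - 1, size=cfg.n_forests)


def train_forests(
    ref: ReferenceSet, cfg: ForestConfig
) -> tuple[list[RandomForestClassifier], np.ndarray]:
    """Fit ``cfg.n_forests`` original-vs-synthetic classifiers with OOB scoring."""
    n = ref.n_original
    if n < 2 or (len(ref.is_original) - n) < 2:
        raise ValidationError("need at least 2 points per class to train forests")
    y = ref.is_original.astype(int)
    forests: list[RandomForestClassifier] = []
    oob = np.empty(cfg.n_forests)
    for i, seed in enumerate(_forest_seeds(cfg)):
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            max_features=cfg.max_features,
            min_samples_leaf=cfg.min_samples_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=int(seed),
            n_jobs=1,
        )
        forest.fit(ref.features, y)
        oob[i] = 1.0 - forest.oob_score_
        forests.append(forest)
    return forests, oob


def proximity_matrix(forest: RandomForestClassifier, points) -> np.ndarray:
    """Co-leaf counts: entry (i, j) = number of trees placing i and j in one leaf."""
    X = _as_feature_matrix(points)
    try:
        leaves = forest.apply(X)  # (n, n_trees) terminal-leaf indices
    except Exception as exc:  # sklearn NotFittedError
        raise StateError("forest must be fitted before computing proximities") from exc
    n, n_trees = leaves.shape
    # one-hot over (tree, leaf) pairs; the Gram matrix counts shared leaves
    offsets = np.concatenate([[0], np.cumsum(leaves.max(axis=0) + 1)[:-1]])
    cols = (leaves + offsets).ravel()
    rows = np.repeat(np.arange(n), n_trees)
    onehot = sparse.csr_matrix(
        (np.ones(n * n_trees, dtype=np.int32), (rows, cols)),
        shape=(n, int(cols.max()) + 1),
    )
    return np.asarray((onehot @ onehot.T).todense(), dtype=np.int64)


def mean_dissimilarity(ref: ReferenceSet, cfg: ForestConfig) -> DissimilarityResult:
    """Average the per-forest proximities and derive the distance matrix."""
    forests, oob = train_forests(ref, cfg)
    acc = np.zeros((len(ref.is_original),) * 2)
    for forest in forests:
        acc += proximity_matrix(forest, ref.features)
    proximity_mean = acc / cfg.n_forests
    distance = 1.0 - proximity_mean / cfg.n_trees
    return DissimilarityResult(
        proximity_mean=proximity_mean,
        distance=distance,
        oob_errors=oob,
        n_trees=cfg.n_trees,
        n_forests=cfg.n_forests,
    )


def save_dissimilarity(result: DissimilarityResult, cfg: ForestConfig, path: str | Path) -> None:
    """Persist matrices as compressed npz plus a JSON sidecar of run metadata."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        proximity_mean=result.proximity_mean,
        distance=result.distance,
        oob_errors=result.oob_errors,
    )
    sidecar = {
        **dataclasses.asdict(cfg),
        "oob_errors": result.oob_errors.tolist(),
        "oob_mean": result.oob_mean,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_dissimilarity(path: str | Path) -> DissimilarityResult:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return DissimilarityResult(
        proximity_mean=arrays["proximity_mean"],
        distance=arrays["distance"],
        oob_errors=arrays["oob_errors"],
        n_trees=meta["n_trees"],
        n_forests=meta["n_forests"],
    )
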