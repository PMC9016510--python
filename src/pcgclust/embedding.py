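"""Two-dimensional multidimensional scaling of the RF distance matrix.

Metric MDS via stress majorization (SMACOF) with multiple starts; the first
candidate is initialised from classical (Torgerson) scaling, which recovers
exactly Euclidean inputs directly, and the remaining ``n_init - 1`` starts
are random.  Quality is reported as *normalized stress* (Kruskal's stress-1):

    stress = sqrt( sum_{i<j} (dhat_ij - d_ij)^2 / sum_{i<j} d_ij^2 )

where d are the input distances and dhat the Euclidean distances of the
embedded coordinates.  Stress 0 means perfect preservation; collapsing all
points onto one coordinate yields stress 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.manifold import smacof

from .errors import ValidationError


@dataclass
class Embedding:
    """2-D coordinates of every point plus the achieved normalized stress."""

    coords: np.ndarray  # (n, 2)
    stress: float
    n_init: int
    seed: int


def _validate_distance(distance: np.ndarray) -> np.ndarray:
    D = np.asarray(distance, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValidationError("distance matrix must be square with n >= 2")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValidationError("distance matrix entries must be nonnegative")
    return D


def stress_of(coords: np.ndarray, distance: np.ndarray) -> float:
    """Normalized stress (stress-1) of coordinates against a distance matrix."""
    D = _validate_distance(distance)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] != D.shape[0]:
        raise ValidationError(
            f"coords rows ({coords.shape}) must match distance dimension {D.shape[0]}"
        )
    iu = np.triu_indices(D.shape[0], k=1)
    d = D[iu]
    dhat = pdist(coords)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - d) ** 2) / denom))


def _classical_init(D: np.ndarray) -> np.ndarray:
    """Torgerson double-centering; exact for distances that are 2-D Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def mds_embed(
    distance: np.ndarray,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    eps: float = 1e-4,
) -> Embedding:
    """Embed a distance matrix in 2-D, returning the lowest-stress candidate.

    Candidates: one SMACOF run from the classical-scaling initialisation and
    ``n_init - 1`` runs from random starts seeded deterministically from
    ``seed`` (so candidate sets are nested as ``n_init`` grows).
    """
    D = _validate_distance(distance)
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best_coords: np.ndarray | None = None
    best_stress = np.inf
    inits: list[np.ndarray | None] = [_classical_init(D)]
    inits += [None] * (n_init - 1)
    for init in inits:
        run_seed = int(rng.integers(0, 2**31 - 1))
        coords, _ = smacof(
            D,
            metric=True,
            n_components=2,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=run_seed,
            normalized_stress=False,
        )
        s = stress_of(coords, D)
        if s < best_stress:
            best_stress, best_coords = s, coords
    assert best_coords is not None
    return Embedding(coords=best_coords, stress=best_stress, n_init=n_init, seed=seed)


def save_embedding(
    emb: Embedding, path: str | Path, point_ids=None, labels=None
) -> None:
    """Persist coordinates as CSV (point_id, x, y[, label]) + JSON sidecar."""
    path = Path(path)
    n = emb.coords.shape[0]
    df = pd.DataFrame(
        {
            "point_id": point_ids if point_ids is not None else np.arange(n),
            "x": emb.coords[:, 0],
            "y": emb.coords[:, 1],
        }
    )
    if labels is not None:
        df["label"] = np.asarray(labels)
    df.to_csv(path.with_suffix(".csv"), index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"stress": emb.stress, "n_init": emb.n_init, "seed": emb.seed}, indent=2)
    )


def plot_embedding(coords: np.ndarray, labels, path: str | Path) -> None:
    """Scatter of the 2-D projection colored by cluster label (-1 = outliers)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in np.unique(labels):
        mask = labels == lab
        ax.scatter(
            coords[mask, 0],
            coords[mask, 1],
            s=8,
            alpha=0.7,
            label=str(lab),
            color="0.6" if lab == -1 else None,
        )
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.legend(title="cluster", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
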