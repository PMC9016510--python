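"""Evaluation utilities against the generator's planted ground truth.

Only evaluation code may read the ``true_archetype`` column; the pipeline
itself never sees it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clustering import HDBSCANConfig, PipelineResult, run_full_pipeline
from .cohort import generate_cohort, planted_archetype_spec
from .dissimilarity import ForestConfig
from .errors import ValidationError


def archetype_recovery_ari(cohort: pd.DataFrame, result: PipelineResult) -> float:
    """Adjusted Rand index of detected clusters vs planted archetypes.

    Scored over clusterable points assigned to a cluster (label >= 0);
    outliers are excluded, as the planted labels say nothing about where a
    density-based method should draw its noise boundary.
    """
    if "true_archetype" not in cohort.columns:
        raise ValidationError("cohort carries no ground-truth archetype column")
    idx = result.partition.clusterable
    labels = result.assignment.labels
    mask = labels >= 0
    if mask.sum() < 2:
        return 0.0
    truth = cohort["true_archetype"].to_numpy()[idx][mask]
    return float(adjusted_rand_score(truth, labels[mask]))


def recovery_experiment(
    separations=(1.0, 0.6, 0.2),
    seeds=(0, 1, 2, 3, 4),
    n_patients: int = 1500,
    n_trees: int = 50,
    n_forests: int = 10,
    mds_n_init: int = 1,
    mds_max_iter: int = 120,
) -> pd.DataFrame:
    """Planted-archetype recovery across separation levels.

    Runs the full pipeline on cohorts from :func:`planted_archetype_spec`
    and returns one row per (separation, seed) with the recovery ARI and the
    pipeline diagnostics.  Forest/MDS sizes default to a desk-scale setting
    (10 forests of 50 trees, single classical-init MDS start).
    """
    rows = []
    for sep in separations:
        for seed in seeds:
            spec = planted_archetype_spec(
                n_patients=n_patients, separation=sep, seed=seed
            )
            cohort = generate_cohort(spec, mode="stochastic")
            result = run_full_pipeline(
                cohort,
                forest_cfg=ForestConfig(n_forests=n_forests, n_trees=n_trees, seed=seed),
                hdbscan_cfg=HDBSCANConfig(),
                seed=seed,
                mds_n_init=mds_n_init,
                mds_max_iter=mds_max_iter,
            )
            rows.append(
                {
                    "separation": sep,
                    "seed": seed,
                    "ari": archetype_recovery_ari(cohort, result),
                    "n_clusters": result.assignment.n_clusters,
                    "n_clusterable": int(result.partition.clusterable.size),
                    "oob_mean": result.dissimilarity.oob_mean
                    if result.dissimilarity
                    else np.nan,
                    "stress": result.embedding.stress if result.embedding else np.nan,
                }
            )
    return pd.DataFrame(rows)


def median_ari_by_separation(experiment: pd.DataFrame) -> pd.Series:
    """Median recovery ARI per separation level, sorted descending."""
    return (
        experiment.groupby("separation")["ari"].median().sort_index(ascending=False)
    )
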