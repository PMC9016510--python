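import numpy as np
import pandas as pd
import pytest

import pcgclust as pc
from pcgclust.clustering import (
    LABEL_HYPERTENSION_ONLY,
    LABEL_MENTAL_ONLY,
    LABEL_NO_PCG,
    LABEL_OTHER_SINGLE,
)


def _flag_row(taxonomy, *names):
    row = np.zeros(34, dtype=int)
    for name in names:
        row[taxonomy.index_of(name)] = 1
    return row


def test_partition_routes_crafted_patients(taxonomy, flags_cohort_factory):
    flags = np.stack(
        [
            _flag_row(taxonomy),                                   # 0: no PCG
            _flag_row(taxonomy, "hypertension"),                   # 1: hypertension only
            _flag_row(taxonomy, "depression"),                     # 2: mental only
            _flag_row(taxonomy, "depression", "psychosis"),        # 3: still one category
            _flag_row(taxonomy, "diabetes_type1", "diabetes_type2"),  # 4: other single cat
            _flag_row(taxonomy, "hypertension", "chronic_pain"),   # 5: clusterable
            _flag_row(taxonomy, "depression", "cancer", "gout"),   # 6: clusterable
        ]
    )
    cohort = flags_cohort_factory(flags)
    part = pc.partition_cohort(cohort, taxonomy)
    assert part.single_no_pcg.tolist() == [0]
    assert part.single_hypertension.tolist() == [1]
    assert part.single_mental.tolist() == [2, 3]
    assert part.other_single.tolist() == [4]
    assert part.clusterable.tolist() == [5, 6]
    assert part.sampled_out.size == 0  # below the subsample threshold


def test_partition_is_disjoint_and_complete(small_default_cohort):
    part = pc.partition_cohort(small_default_cohort)
    groups = [
        part.single_no_pcg,
        part.single_hypertension,
        part.single_mental,
        part.other_single,
        part.clusterable,
        part.sampled_out,
    ]
    combined = np.concatenate(groups)
    assert len(combined) == len(small_default_cohort)
    assert len(np.unique(combined)) == len(combined)


def test_partition_subsampling_applies_above_threshold(taxonomy, flags_cohort_factory):
    flags = np.tile(_flag_row(taxonomy, "hypertension", "chronic_pain"), (200, 1))
    cohort = flags_cohort_factory(flags)
    part = pc.partition_cohort(
        cohort, taxonomy, subsample_fraction=0.1, seed=0, subsample_threshold=100
    )
    assert part.clusterable.size == 20
    assert part.sampled_out.size == 180
    again = pc.partition_cohort(
        cohort, taxonomy, subsample_fraction=0.1, seed=0, subsample_threshold=100
    )
    assert np.array_equal(part.clusterable, again.clusterable)


def test_partition_validation(taxonomy, flags_cohort_factory):
    cohort = flags_cohort_factory(np.zeros((3, 34), dtype=int))
    with pytest.raises(pc.ValidationError):
        pc.partition_cohort(cohort.iloc[:0])
    with pytest.raises(pc.ValidationError):
        pc.partition_cohort(cohort, subsample_fraction=0.0)


def test_detect_clusters_wraps_density_clustering():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.2, (60, 2)), rng.normal(5, 0.2, (60, 2))])
    assignment = pc.detect_clusters(X, min_cluster_size=20)
    assert assignment.n_clusters == 2
    assert set(np.unique(assignment.labels)) <= {-1, 0, 1}
    assert set(assignment.persistence) == {0, 1}


def test_hdbscan_config_resolution():
    cfg = pc.HDBSCANConfig()
    assert cfg.resolved_min_cluster_size(100) == 15   # floor applies
    assert cfg.resolved_min_cluster_size(2000) == 40  # 2% of points
    assert pc.HDBSCANConfig(min_cluster_size=7).resolved_min_cluster_size(2000) == 7


def test_pipeline_recovers_planted_archetypes(planted_cohort):
    result = pc.run_full_pipeline(
        planted_cohort,
        forest_cfg=pc.ForestConfig(n_forests=4, n_trees=50, seed=0),
        seed=0,
        mds_n_init=1,
        mds_max_iter=120,
    )
    ari = pc.archetype_recovery_ari(planted_cohort, result)
    assert result.assignment.n_clusters >= 2
    assert ari > 0.5
    # whole-cohort labels cover every patient with a valid code
    labels = result.assignment.cohort_labels
    assert labels.notna().all() and len(labels) == len(planted_cohort)
    valid = set(range(result.assignment.n_clusters)) | set(pc.LABEL_NAMES)
    assert set(labels.unique()) <= valid


def test_pipeline_reserved_codes_match_partition(planted_cohort):
    result = pc.run_full_pipeline(
        planted_cohort,
        forest_cfg=pc.ForestConfig(n_forests=2, n_trees=25, seed=1),
        seed=1,
        mds_n_init=1,
        mds_max_iter=60,
    )
    labels = result.assignment.cohort_labels.to_numpy()
    part = result.partition
    assert (labels[part.single_no_pcg] == LABEL_NO_PCG).all()
    assert (labels[part.single_hypertension] == LABEL_HYPERTENSION_ONLY).all()
    assert (labels[part.single_mental] == LABEL_MENTAL_ONLY).all()
    assert (labels[part.other_single] == LABEL_OTHER_SINGLE).all()
    assert (labels[part.clusterable] >= -1).all()


def test_pipeline_short_circuits_without_clusterable_points(flags_cohort_factory):
    cohort = flags_cohort_factory(np.zeros((30, 34), dtype=int))
    result = pc.run_full_pipeline(cohort, seed=0)
    assert result.dissimilarity is None and result.embedding is None
    assert result.assignment.n_clusters == 0
    assert (result.assignment.cohort_labels == LABEL_NO_PCG).all()


def test_pipeline_deterministic(planted_cohort):
    kwargs = dict(
        forest_cfg=pc.ForestConfig(n_forests=2, n_trees=25, seed=2),
        seed=2,
        mds_n_init=1,
        mds_max_iter=60,
    )
    a = pc.run_full_pipeline(planted_cohort, **kwargs)
    b = pc.run_full_pipeline(planted_cohort, **kwargs)
    assert np.array_equal(a.assignment.labels, b.assignment.labels)
    assert np.array_equal(a.dissimilarity.distance, b.dissimilarity.distance)
    assert np.array_equal(a.embedding.coords, b.embedding.coords)
    assert a.assignment.persistence == b.assignment.persistence
    pd.testing.assert_frame_equal(a.assignment.condensed_tree, b.assignment.condensed_tree)
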