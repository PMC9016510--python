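"""Pre-clustering partition, HDBSCAN detection, and the full pipeline.

Before the expensive steps, three large "single" groups are peeled off the
cohort: patients with no PCGs, patients whose PCGs all belong to the
hypertension category, and patients whose PCGs all belong to the mental
category.  Patients confined to exactly one *other* disease category are
likewise removed from clustering (many identical points at one position
perturb a density-based detector) but kept in an audit group.  The remaining
patients — those spanning two or more disease categories — are the
clusterable set, optionally thinned to a 10% random subsample when large.

The pipeline then chains: synthetic-reference construction -> averaged
random-forest proximity -> distance matrix -> 2-D MDS (synthetic rows are
embedded too, then dropped) -> HDBSCAN on the original points' coordinates.

Whole-cohort labels use code -1 for HDBSCAN outliers, 0..k-1 for detected
clusters, and negative reserved codes for the pre-extracted groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hdbscan import DensityClustering, hdbscan_cluster
from .cohort import pcg_matrix
from .dissimilarity import (
    DissimilarityResult,
    ForestConfig,
    make_reference,
    mean_dissimilarity,
)
from .embedding import Embedding, mds_embed
from .errors import ValidationError
from .taxonomy import (
    HYPERTENSION_CATEGORY,
    MENTAL_CATEGORY,
    PCGTaxonomy,
    default_taxonomy,
)

# Reserved whole-cohort label codes for groups that never enter HDBSCAN.
LABEL_OUTLIER = -1
LABEL_NO_PCG = -2
LABEL_HYPERTENSION_ONLY = -3
LABEL_MENTAL_ONLY = -4
LABEL_OTHER_SINGLE = -5
LABEL_NOT_SAMPLED = -6

LABEL_NAMES = {
    LABEL_OUTLIER: "outliers",
    LABEL_NO_PCG: "no_pcg",
    LABEL_HYPERTENSION_ONLY: "hypertension_only",
    LABEL_MENTAL_ONLY: "mental_only",
    LABEL_OTHER_SINGLE: "other_single_type",
    LABEL_NOT_SAMPLED: "not_sampled",
}


@dataclass
class PartitionedCohort:
    """Disjoint patient-index sets produced by the pre-clustering filters.

    ``clusterable`` is the final (possibly subsampled) set entering the RF
    pipeline; ``sampled_out`` are clusterable patients thinned away by the
    subsample; ``other_single`` are single-category patients outside the
    hypertension/mental groups, excluded from clustering but reported.
    """

    single_no_pcg: np.ndarray
    single_hypertension: np.ndarray
    single_mental: np.ndarray
    other_single: np.ndarray
    clusterable: np.ndarray
    sampled_out: np.ndarray
    subsample_fraction: float
    seed: int


@dataclass
class ClusterAssignment:
    """HDBSCAN output on the clusterable points plus whole-cohort labels."""

    labels: np.ndarray              # per clusterable point: -1 or 0..k-1
    persistence: dict[int, float]
    condensed_tree: pd.DataFrame
    cohort_labels: pd.Series | None = None  # per patient, reserved codes included
    named_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.persistence)


@dataclass
class PipelineResult:
    partition: PartitionedCohort
    dissimilarity: DissimilarityResult | None
    embedding: Embedding | None
    assignment: ClusterAssignment


@dataclass
class HDBSCANConfig:
    """Detection settings; ``None`` sizes fall back to max(15, 2% of points)."""

    min_cluster_size: int | None = None
    min_samples: int | None = None

    def resolved_min_cluster_size(self, n_points: int) -> int:
        if self.min_cluster_size is not None:
            return self.min_cluster_size
        return max(15, round(0.02 * n_points))


def partition_cohort(
    cohort: pd.DataFrame,
    taxonomy: PCGTaxonomy | None = None,
    subsample_fraction: float = 0.10,
    seed: int = 0,
    subsample_threshold: int = 5000,
) -> PartitionedCohort:
    """Split a cohort into the three single groups, audit groups and the
    clusterable set.

    Subsampling (default 10%) only applies when the clusterable set exceeds
    ``subsample_threshold`` points, so small synthetic cohorts are not
    thinned away.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot partition an empty cohort")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValidationError("subsample_fraction must lie in (0, 1]")
    taxonomy = taxonomy or default_taxonomy()
    flags = pcg_matrix(cohort)
    cat_counts = flags @ taxonomy.membership  # (n, 15)
    n_cats = (cat_counts > 0).sum(axis=1)
    hyp = taxonomy.category_index(HYPERTENSION_CATEGORY)
    men = taxonomy.category_index(MENTAL_CATEGORY)

    idx = np.arange(len(cohort))
    no_pcg = idx[n_cats == 0]
    only_one = n_cats == 1
    hyp_only = idx[only_one & (cat_counts[:, hyp] > 0)]
    men_only = idx[only_one & (cat_counts[:, men] > 0)]
    other_single = idx[only_one & (cat_counts[:, hyp] == 0) & (cat_counts[:, men] == 0)]
    clusterable = idx[n_cats >= 2]

    sampled_out = np.array([], dtype=int)
    if subsample_fraction < 1.0 and clusterable.size > subsample_threshold:
        rng = np.random.default_rng(seed)
        keep_n = max(1, round(subsample_fraction * clusterable.size))
        keep = rng.choice(clusterable, size=keep_n, replace=False)
        keep.sort()
        sampled_out = np.setdiff1d(clusterable, keep)
        clusterable = keep

    return PartitionedCohort(
        single_no_pcg=no_pcg,
        single_hypertension=hyp_only,
        single_mental=men_only,
        other_single=other_single,
        clusterable=clusterable,
        sampled_out=sampled_out,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def detect_clusters(
    embedding_coords: np.ndarray,
    min_cluster_size: int,
    min_samples: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """HDBSCAN on 2-D coordinates of the original (non-synthetic) points.

    ``seed`` is accepted for interface symmetry with the stochastic stages;
    detection itself is deterministic.
    """
    del seed
    result: DensityClustering = hdbscan_cluster(
        embedding_coords, min_cluster_size=min_cluster_size, min_samples=min_samples
    )
    return ClusterAssignment(
        labels=result.labels,
        persistence=result.persistence,
        condensed_tree=result.condensed_tree,
    )


def _stage_seeds(seed: int, k: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(k)]


def run_full_pipeline(
    cohort: pd.DataFrame,
    taxonomy: PCGTaxonomy | None = None,
    forest_cfg: ForestConfig | None = None,
    hdbscan_cfg: HDBSCANConfig | None = None,
    seed: int = 0,
    subsample_fraction: float = 0.10,
    subsample_threshold: int = 5000,
    mds_n_init: int = 4,
    mds_max_iter: int = 300,
) -> PipelineResult:
    """Partition -> reference -> RF dissimilarity -> MDS -> HDBSCAN.

    Per-stage seeds are derived deterministically from ``seed``; fixed seeds
    give bit-identical results on reruns.
    """
    taxonomy = taxonomy or default_taxonomy()
    hdbscan_cfg = hdbscan_cfg or HDBSCANConfig()
    sub_seed, ref_seed, forest_seed, mds_seed = _stage_seeds(seed)
    if forest_cfg is None:
        forest_cfg = ForestConfig(seed=forest_seed)

    partition = partition_cohort(
        cohort,
        taxonomy,
        subsample_fraction=subsample_fraction,
        seed=sub_seed,
        subsample_threshold=subsample_threshold,
    )
    cohort_labels = pd.Series(
        np.full(len(cohort), LABEL_NOT_SAMPLED, dtype=np.int64),
        index=cohort.index,
        name="label",
    )
    pos = cohort.index.to_numpy()
    cohort_labels.loc[pos[partition.single_no_pcg]] = LABEL_NO_PCG
    cohort_labels.loc[pos[partition.single_hypertension]] = LABEL_HYPERTENSION_ONLY
    cohort_labels.loc[pos[partition.single_mental]] = LABEL_MENTAL_ONLY
    cohort_labels.loc[pos[partition.other_single]] = LABEL_OTHER_SINGLE

    n_clusterable = partition.clusterable.size
    if n_clusterable == 0:
        assignment = ClusterAssignment(
            labels=np.array([], dtype=np.int64),
            persistence={},
            condensed_tree=pd.DataFrame(),
            cohort_labels=cohort_labels,
        )
        return PipelineResult(partition, None, None, assignment)

    flags = pcg_matrix(cohort)[partition.clusterable]
    ref = make_reference(flags, seed=ref_seed)
    dissim = mean_dissimilarity(ref, forest_cfg)
    emb = mds_embed(dissim.distance, seed=mds_seed, n_init=mds_n_init, max_iter=mds_max_iter)
    original_coords = emb.coords[: n_clusterable]  # synthetic rows discarded

    mcs = hdbscan_cfg.resolved_min_cluster_size(n_clusterable)
    assignment = detect_clusters(
        original_coords, min_cluster_size=mcs, min_samples=hdbscan_cfg.min_samples
    )
    cohort_labels.loc[pos[partition.clusterable]] = assignment.labels
    assignment.cohort_labels = cohort_labels
    return PipelineResult(partition, dissim, emb, assignment)
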