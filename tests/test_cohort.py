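import numpy as np
import pandas as pd
import pytest

import pcgclust as pc
from pcgclust.cohort import (
    COST_FIELDS,
    cohort_spec_from_yaml,
    cohort_spec_to_yaml,
    pcg_columns,
)


def test_default_spec_is_consistent():
    spec = pc.default_cohort_spec()
    assert spec.n_patients == 18_732
    assert len(spec.archetypes) == 8
    assert abs(sum(a.proportion for a in spec.archetypes) - 1.0) < 1e-12
    by_label = {a.label: a for a in spec.archetypes}
    assert by_label["no_pcg"].mean_pcg_count == 0.0
    assert by_label["complex_high_cost"].mean_pcg_count == pytest.approx(2.1)
    assert by_label["hypertension_only"].pcg_pool == ("hypertension",)


def test_generate_schema_and_invariants(small_default_cohort):
    df = small_default_cohort
    assert len(df) == 600
    assert df["patient_id"].is_unique
    assert len(pcg_columns(df)) == 34
    assert (df["age"] >= 50.0).all()
    assert df["sex"].isin(["F", "M"]).all()
    assert df["gatekeeper"].isin([0, 1]).all()
    for f in COST_FIELDS:
        assert (df[f] >= 0).all()
    assert np.allclose(
        df["total_cost"], df[list(COST_FIELDS)].sum(axis=1)
    ), "total cost must equal the sum of its three components"
    assert (df["consultations_generalist"] <= df["consultations_total"]).all()


def test_generate_is_deterministic():
    spec = pc.default_cohort_spec(seed=42)
    spec.n_patients = 300
    a = pc.generate_cohort(spec, mode="stochastic")
    b = pc.generate_cohort(spec, mode="stochastic")
    pd.testing.assert_frame_equal(a, b)


def test_different_seeds_differ():
    spec_a = pc.default_cohort_spec(seed=1)
    spec_b = pc.default_cohort_spec(seed=2)
    spec_a.n_patients = spec_b.n_patients = 300
    a = pc.generate_cohort(spec_a, mode="stochastic")
    b = pc.generate_cohort(spec_b, mode="stochastic")
    assert not a.equals(b)


def test_stochastic_archetype_means_match_spec():
    """At n=6000 the per-archetype mean PCG count tracks the spec within 0.1."""
    spec = pc.default_cohort_spec(seed=5)
    spec.n_patients = 6000
    df = pc.generate_cohort(spec, mode="stochastic")
    flags = pc.pcg_matrix(df)
    counts = flags.sum(axis=1)
    for arch in spec.archetypes:
        mask = (df["true_archetype"] == arch.label).to_numpy()
        assert mask.sum() > 0
        assert counts[mask].mean() == pytest.approx(arch.mean_pcg_count, abs=0.1), arch.label


def test_exact_counts_sizes_and_shares():
    spec = pc.default_cohort_spec(seed=0)
    df = pc.generate_cohort(spec, mode="exact_counts")
    sizes = df["true_archetype"].value_counts()
    assert sizes.sum() == 18_732
    flags = pc.pcg_matrix(df)
    counts = flags.sum(axis=1)
    for arch in spec.archetypes:
        mask = (df["true_archetype"] == arch.label).to_numpy()
        assert mask.sum() == round(arch.proportion * 18_732)
        assert round(counts[mask].mean(), 1) == pytest.approx(arch.mean_pcg_count)
        assert round((counts[mask] >= 2).mean(), 1) == pytest.approx(arch.multimorbid_share)


def test_exact_counts_rejects_partial_separation():
    spec = pc.default_cohort_spec(seed=0)
    spec.separation = 0.5
    with pytest.raises(pc.ValidationError):
        pc.generate_cohort(spec, mode="exact_counts")


def test_unknown_mode_rejected():
    spec = pc.default_cohort_spec()
    spec.n_patients = 10
    with pytest.raises(pc.ValidationError):
        pc.generate_cohort(spec, mode="bogus")


def test_bad_proportions_rejected():
    spec = pc.default_cohort_spec()
    spec.archetypes[0].proportion += 0.5
    with pytest.raises(pc.ValidationError):
        pc.generate_cohort(spec)


def test_empty_pool_with_positive_mean_rejected():
    spec = pc.default_cohort_spec()
    spec.archetypes[1].pcg_pool = ()
    with pytest.raises(pc.ValidationError):
        pc.generate_cohort(spec)


def test_separation_leaks_flags_outside_pools():
    """Lower separation moves planted flags out of the archetype pools."""
    taxonomy = pc.default_taxonomy()
    pooled_share = {}
    for sep in (1.0, 0.2):
        spec = pc.planted_archetype_spec(n_patients=800, separation=sep, seed=3)
        df = pc.generate_cohort(spec, mode="stochastic")
        flags = pc.pcg_matrix(df)
        in_pool = 0
        total = 0
        for arch in spec.archetypes:
            mask = (df["true_archetype"] == arch.label).to_numpy()
            pool_idx = [taxonomy.index_of(p) for p in arch.pcg_pool]
            in_pool += flags[np.ix_(mask, pool_idx)].sum()
            total += flags[mask].sum()
        pooled_share[sep] = in_pool / total
    assert pooled_share[1.0] == 1.0
    assert pooled_share[0.2] < 0.6


def test_marginal_prevalences_against_recount(flags_cohort_factory):
    rng = np.random.default_rng(0)
    flags = (rng.random((50, 34)) < 0.2).astype(int)
    df = flags_cohort_factory(flags)
    prev = pc.marginal_prevalences(df)
    assert np.allclose(prev.to_numpy(), flags.mean(axis=0))


def test_cohort_csv_round_trip(small_default_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    pc.write_cohort_csv(small_default_cohort, path)
    loaded = pc.read_cohort_csv(path)
    assert np.array_equal(pc.pcg_matrix(loaded), pc.pcg_matrix(small_default_cohort))
    assert np.allclose(loaded["total_cost"], small_default_cohort["total_cost"])


def test_spec_yaml_round_trip(tmp_path):
    spec = pc.planted_archetype_spec(n_patients=100, separation=0.7, seed=9)
    path = tmp_path / "spec.yaml"
    cohort_spec_to_yaml(spec, path)
    loaded = cohort_spec_from_yaml(path)
    assert loaded == spec
    pd.testing.assert_frame_equal(
        pc.generate_cohort(loaded), pc.generate_cohort(spec)
    )
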