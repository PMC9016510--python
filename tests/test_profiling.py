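import numpy as np
import pandas as pd
import pytest

import pcgclust as pc
from pcgclust.profiling import label_names, profiles_to_csv


def _tiny_cohort(taxonomy):
    """Six patients with hand-set values for spreadsheet-style recounting."""
    flags = np.zeros((6, 34), dtype=int)
    flags[0, taxonomy.index_of("hypertension")] = 1
    flags[0, taxonomy.index_of("chronic_pain")] = 1
    flags[1, taxonomy.index_of("hypertension")] = 1
    flags[2, taxonomy.index_of("depression")] = 1
    flags[2, taxonomy.index_of("cancer")] = 1
    flags[2, taxonomy.index_of("gout")] = 1
    # patients 3-5 carry no PCGs
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "true_archetype": ["fixture"] * 6,
            "age": [60.0, 70.0, 80.0, 55.0, 65.0, 75.0],
            "sex": ["F", "M", "F", "M", "M", "F"],
            "deductible": [300.0, 500.0, 700.0, 900.0, 1100.0, 1300.0],
            "gatekeeper": [1, 0, 1, 0, 0, 1],
            "ambulatory_cost": [1000.0, 2000.0, 3000.0, 100.0, 200.0, 300.0],
            "inpatient_cost": [500.0, 0.0, 1500.0, 0.0, 0.0, 0.0],
            "medication_cost": [250.0, 750.0, 1250.0, 50.0, 50.0, 50.0],
            "hospital_days": [2, 0, 6, 0, 0, 0],
            "hospitalizations": [1, 0, 2, 0, 0, 0],
            "consultations_total": [10, 5, 20, 2, 3, 4],
            "consultations_generalist": [6, 3, 10, 2, 2, 3],
        }
    )
    for j, name in enumerate(taxonomy.names):
        df[f"pcg_{name}"] = flags[:, j]
    df["total_cost"] = df.ambulatory_cost + df.inpatient_cost + df.medication_cost
    return df


def test_profile_matches_hand_computed_values(taxonomy):
    cohort = _tiny_cohort(taxonomy)
    labels = [0, 0, 0, -2, -2, -2]  # one cluster of 3 + three no-PCG patients
    profiles = pc.profile_clusters(cohort, labels)
    assert set(profiles.index) == {-2, 0}

    row = profiles.loc[0]
    assert row["n"] == 3
    assert row["pct"] == pytest.approx(50.0)
    assert row["age_mean"] == pytest.approx((60 + 70 + 80) / 3)
    assert row["age_sd"] == pytest.approx(10.0)
    assert row["men_n"] == 1 and row["women_n"] == 2
    assert row["deductible_mean"] == pytest.approx(500.0)
    assert row["gatekeeper_share"] == pytest.approx(2 / 3)
    assert row["pcg_count_mean"] == pytest.approx((2 + 1 + 3) / 3)
    assert row["multimorbid_share"] == pytest.approx(2 / 3)
    assert row["ambulatory_cost_mean"] == pytest.approx(2000.0)
    assert row["inpatient_cost_mean"] == pytest.approx(2000.0 / 3)
    assert row["medication_cost_mean"] == pytest.approx(750.0)
    assert row["total_cost_mean"] == pytest.approx((1750 + 2750 + 5750) / 3)
    assert row["hospital_days_mean"] == pytest.approx(8 / 3)
    assert row["consultations_total_mean"] == pytest.approx(35 / 3)
    assert "hypertension" in row["top_pcgs"].split(";")

    base = profiles.loc[-2]
    assert base["n"] == 3
    assert base["pcg_count_mean"] == 0.0
    assert base["multimorbid_share"] == 0.0
    assert base["top_pcgs"] == ""


def test_profile_sizes_partition_the_cohort(small_default_cohort):
    rng = np.random.default_rng(0)
    labels = rng.integers(-2, 3, size=len(small_default_cohort))
    profiles = pc.profile_clusters(small_default_cohort, labels)
    assert profiles["n"].sum() == len(small_default_cohort)
    assert profiles["pct"].sum() == pytest.approx(100.0)
    assert (profiles["men_n"] + profiles["women_n"] == profiles["n"]).all()


def test_profile_label_validation(small_default_cohort):
    with pytest.raises(pc.ValidationError):
        pc.profile_clusters(small_default_cohort, [0, 1])  # wrong length
    bad = np.zeros(len(small_default_cohort), dtype=float)
    bad[0] = np.nan
    with pytest.raises(pc.ValidationError):
        pc.profile_clusters(small_default_cohort, bad)


def test_joint_distribution_hand_case(taxonomy):
    cohort = _tiny_cohort(taxonomy)
    labels = [0, 0, 0, -2, -2, -2]
    dist = pc.joint_pcg_distribution(cohort, labels, 0)
    hyp = taxonomy.index_of("hypertension")
    pain = taxonomy.index_of("chronic_pain")
    dep = taxonomy.index_of("depression")
    assert dist.matrix[hyp, hyp] == 2           # two patients carry hypertension
    assert dist.matrix[hyp, pain] == 1          # one carries both
    assert dist.matrix[hyp, dep] == 0           # never together here
    assert np.array_equal(dist.matrix, dist.matrix.T)
    assert dist.marginals[hyp] == pytest.approx(2 / 3)


def test_joint_distribution_matches_brute_force(flags_cohort_factory):
    rng = np.random.default_rng(1)
    flags = (rng.random((20, 34)) < 0.25).astype(int)
    cohort = flags_cohort_factory(flags)
    dist = pc.joint_pcg_distribution(cohort, np.zeros(20, dtype=int), 0)
    expected = np.zeros((34, 34), dtype=int)
    for i in range(34):
        for j in range(34):
            expected[i, j] = int(np.sum(flags[:, i] * flags[:, j]))
    assert np.array_equal(dist.matrix, expected)
    # off-diagonal co-occurrence can never exceed either marginal count
    diag = np.diag(dist.matrix)
    assert (dist.matrix <= np.minimum.outer(diag, diag)).all()


def test_joint_distribution_unknown_label(flags_cohort_factory):
    cohort = flags_cohort_factory(np.zeros((5, 34), dtype=int))
    with pytest.raises(pc.ValidationError):
        pc.joint_pcg_distribution(cohort, np.zeros(5, dtype=int), 3)


def _profile_row(**kw):
    base = dict(
        n=100, pct=10.0, age_mean=66.0, age_sd=10.0, men_n=40, women_n=60,
        deductible_mean=500.0, gatekeeper_share=0.4, pcg_count_mean=1.5,
        multimorbid_share=0.5, ambulatory_cost_mean=8000.0,
        inpatient_cost_mean=2000.0, medication_cost_mean=2500.0,
        total_cost_mean=12500.0, hospital_days_mean=4.0,
        hospitalizations_mean=0.3, consultations_total_mean=16.0,
        consultations_generalist_mean=10.0, top_pcgs="",
    )
    base.update(kw)
    return base


def test_name_clusters_on_published_style_profiles():
    """Four clusters with the published segments' descriptive statistics."""
    profiles = pd.DataFrame.from_dict(
        {
            0: _profile_row(pcg_count_mean=2.1, multimorbid_share=0.8,
                            age_mean=66.3, medication_cost_mean=4073.0,
                            inpatient_cost_mean=3109.0, hospital_days_mean=6.6,
                            total_cost_mean=18913.0),
            1: _profile_row(pcg_count_mean=1.7, multimorbid_share=0.6,
                            age_mean=67.8, medication_cost_mean=2221.0,
                            inpatient_cost_mean=1811.0, hospital_days_mean=3.6,
                            total_cost_mean=11509.0),
            2: _profile_row(pcg_count_mean=1.3, multimorbid_share=0.3,
                            age_mean=69.4, medication_cost_mean=3587.0,
                            inpatient_cost_mean=2749.0, hospital_days_mean=5.6,
                            total_cost_mean=16064.0),
            3: _profile_row(pcg_count_mean=1.1, multimorbid_share=0.1,
                            age_mean=68.1, medication_cost_mean=4450.0,
                            inpatient_cost_mean=1575.0, hospital_days_mean=3.4,
                            total_cost_mean=16387.0),
            -2: _profile_row(pcg_count_mean=0.0, multimorbid_share=0.0),
        },
        orient="index",
    )
    profiles.index.name = "label"
    names = pc.name_clusters(profiles)
    assert names == {
        0: "complex_high_cost",
        1: "slightly_complex",
        2: "oldest_high_risk",
        3: "one_costly_disease",
    }


def test_name_clusters_single_cluster_cases():
    one = pd.DataFrame.from_dict({0: _profile_row(pcg_count_mean=2.2)}, orient="index")
    assert pc.name_clusters(one) == {0: "complex_high_cost"}
    only_reserved = pd.DataFrame.from_dict({-2: _profile_row()}, orient="index")
    assert pc.name_clusters(only_reserved) == {}


def test_label_names_mixes_reserved_and_named():
    named = {0: "complex_high_cost"}
    out = label_names([-2, -1, 0, 1], named)
    assert out == ["no_pcg", "outliers", "complex_high_cost", "cluster_1"]


def test_profiles_to_csv_round_trip(taxonomy, tmp_path):
    cohort = _tiny_cohort(taxonomy)
    profiles = pc.profile_clusters(cohort, [0, 0, 0, -2, -2, -2])
    path = tmp_path / "profiles.csv"
    profiles_to_csv(profiles, path)
    loaded = pd.read_csv(path, index_col="label")
    assert loaded.loc[0, "n"] == 3
    assert loaded.loc[0, "pct"] == 50.0
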