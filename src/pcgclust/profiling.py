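"""Per-cluster descriptive statistics, joint PCG distributions, and naming.

The descriptive table mirrors the published cluster-profile layout: size and
share, age, sex split, deductible, gatekeeping share, mean PCG count,
multimorbid share, the four cost means (CHF), utilization means and the
PCGs most prevalent in the group.  Cluster names are attached by an advisory
rule set that mimics how the published clusters were labelled from their
descriptive statistics; naming never feeds back into the clustering itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import LABEL_NAMES
from .cohort import pcg_columns, pcg_matrix
from .errors import ValidationError
from .taxonomy import N_PCGS

PROFILE_COLUMNS = [
    "n", "pct", "age_mean", "age_sd", "men_n", "women_n", "deductible_mean",
    "gatekeeper_share", "pcg_count_mean", "multimorbid_share",
    "ambulatory_cost_mean", "inpatient_cost_mean", "medication_cost_mean",
    "total_cost_mean", "hospital_days_mean", "hospitalizations_mean",
    "consultations_total_mean", "consultations_generalist_mean", "top_pcgs",
]


@dataclass
class JointPCGDistribution:
    """34 x 34 co-occurrence counts within one cluster.

    ``matrix[i, j]`` counts the cluster's patients carrying both PCG i and
    PCG j; the diagonal holds per-PCG patient counts and ``marginals`` the
    per-PCG prevalence among cluster members.
    """

    label: int
    matrix: np.ndarray
    marginals: np.ndarray


def _check_labels(cohort: pd.DataFrame, labels) -> pd.Series:
    values = np.asarray(labels)
    if values.shape != (len(cohort),):
        raise ValidationError("labels must align one-to-one with the cohort")
    labels = pd.Series(values, index=cohort.index)
    if labels.isna().any():
        raise ValidationError("every patient must carry a label")
    return labels


def profile_clusters(cohort: pd.DataFrame, labels) -> pd.DataFrame:
    """One descriptive row per label (reserved codes included), indexed by label."""
    labels = _check_labels(cohort, labels)
    flags = pcg_matrix(cohort)
    counts = flags.sum(axis=1)
    n_total = len(cohort)
    rows = {}
    for lab in sorted(labels.unique(), key=lambda x: (isinstance(x, str), x)):
        mask = (labels == lab).to_numpy()
        sub = cohort.loc[mask]
        sub_counts = counts[mask]
        prevalence = flags[mask].mean(axis=0)
        top = [
            pcg_columns(cohort)[j].removeprefix("pcg_")
            for j in np.argsort(-prevalence)[:5]
            if prevalence[j] > 0
        ]
        rows[lab] = {
            "n": int(mask.sum()),
            "pct": 100.0 * mask.sum() / n_total,
            "age_mean": sub["age"].mean(),
            "age_sd": sub["age"].std(ddof=1),
            "men_n": int((sub["sex"] == "M").sum()),
            "women_n": int((sub["sex"] == "F").sum()),
            "deductible_mean": sub["deductible"].mean(),
            "gatekeeper_share": sub["gatekeeper"].mean(),
            "pcg_count_mean": sub_counts.mean(),
            "multimorbid_share": (sub_counts >= 2).mean(),
            "ambulatory_cost_mean": sub["ambulatory_cost"].mean(),
            "inpatient_cost_mean": sub["inpatient_cost"].mean(),
            "medication_cost_mean": sub["medication_cost"].mean(),
            "total_cost_mean": sub["total_cost"].mean(),
            "hospital_days_mean": sub["hospital_days"].mean(),
            "hospitalizations_mean": sub["hospitalizations"].mean(),
            "consultations_total_mean": sub["consultations_total"].mean(),
            "consultations_generalist_mean": sub["consultations_generalist"].mean(),
            "top_pcgs": ";".join(top),
        }
    profiles = pd.DataFrame.from_dict(rows, orient="index")[PROFILE_COLUMNS]
    profiles.index.name = "label"
    return profiles


def joint_pcg_distribution(cohort: pd.DataFrame, labels, label) -> JointPCGDistribution:
    """Symmetric PCG co-occurrence counts over one cluster's members."""
    labels = _check_labels(cohort, labels)
    mask = (labels == label).to_numpy()
    if not mask.any():
        raise ValidationError(f"no patients carry label {label!r}")
    F = pcg_matrix(cohort)[mask]
    matrix = F.T @ F  # (34, 34); diagonal = per-PCG patient counts
    return JointPCGDistribution(
        label=label, matrix=matrix, marginals=F.mean(axis=0)
    )


def name_clusters(profiles: pd.DataFrame) -> dict[int, str]:
    """Attach archetype names to detected clusters (labels >= 0) by rule.

    Rules, applied greedily: a near-single-PCG cluster holding the global
    maximum medication cost -> ``one_costly_disease``; the oldest remaining
    cluster with above-average hospital use -> ``oldest_high_risk``; the
    remaining cluster maximising both PCG count and total cost ->
    ``complex_high_cost``; remaining multimorbid clusters with below-average
    total cost -> ``slightly_complex``; anything left -> ``unlabelled_<k>``.
    """
    detected = profiles.loc[[lab for lab in profiles.index if isinstance(lab, (int, np.integer)) and lab >= 0]]
    names: dict[int, str] = {}
    if detected.empty:
        return names
    if len(detected) == 1:
        lab = detected.index[0]
        row = detected.iloc[0]
        if row["pcg_count_mean"] >= 1.8:
            return {int(lab): "complex_high_cost"}
        return {int(lab): "one_costly_disease" if row["pcg_count_mean"] < 1.35 else "slightly_complex"}

    remaining = set(detected.index)

    def _argbest(pool, key, reverse=True):
        ordered = sorted(
            pool,
            key=lambda l: (detected.loc[l, key], detected.loc[l, "total_cost_mean"]),
            reverse=reverse,
        )
        return ordered[0]

    # 1) one costly disease: ~1 PCG and the highest medication cost overall
    med_max = detected["medication_cost_mean"].max()
    costly = [
        l for l in remaining
        if detected.loc[l, "pcg_count_mean"] < 1.35
        and detected.loc[l, "medication_cost_mean"] >= med_max - 1e-9
    ]
    if costly:
        lab = _argbest(costly, "medication_cost_mean")
        names[int(lab)] = "one_costly_disease"
        remaining.discard(lab)
    # 2) oldest at high risk: strict age maximum plus high inpatient use
    if remaining:
        lab = _argbest(remaining, "age_mean")
        others = detected.loc[list(remaining)]
        high_hosp = (
            detected.loc[lab, "inpatient_cost_mean"] >= others["inpatient_cost_mean"].mean()
            or detected.loc[lab, "hospital_days_mean"] >= others["hospital_days_mean"].mean()
        )
        if detected.loc[lab, "age_mean"] >= others["age_mean"].max() and high_hosp:
            names[int(lab)] = "oldest_high_risk"
            remaining.discard(lab)
    # 3) complex high-cost: maximises both PCG count and total cost
    if remaining:
        by_pcg = _argbest(remaining, "pcg_count_mean")
        by_cost = _argbest(remaining, "total_cost_mean")
        if by_pcg == by_cost:
            names[int(by_pcg)] = "complex_high_cost"
            remaining.discard(by_pcg)
    # 4) slightly complex: multimorbid, below-average total cost
    mean_cost = detected["total_cost_mean"].mean()
    for lab in sorted(remaining, key=lambda l: -detected.loc[l, "total_cost_mean"]):
        row = detected.loc[lab]
        if row["multimorbid_share"] >= 0.5 and row["total_cost_mean"] <= mean_cost:
            names[int(lab)] = "slightly_complex"
            remaining.discard(lab)
            break
    for k, lab in enumerate(sorted(remaining)):
        names[int(lab)] = f"unlabelled_{k}"
    return names


def label_names(labels, named: dict[int, str] | None = None) -> list[str]:
    """Human-readable name per label code (reserved codes + archetype names)."""
    named = named or {}
    out = []
    for lab in np.asarray(labels):
        lab = int(lab)
        if lab in LABEL_NAMES:
            out.append(LABEL_NAMES[lab])
        else:
            out.append(named.get(lab, f"cluster_{lab}"))
    return out


def profiles_to_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    out = profiles.copy()
    out["pct"] = out["pct"].round(1)
    for col in ("gatekeeper_share", "multimorbid_share", "pcg_count_mean"):
        out[col] = out[col].round(1)
    out.to_csv(path)


def plot_joint_heatmap(dist: JointPCGDistribution, pcg_names, path: str | Path) -> None:
    """Heatmap of one cluster's joint PCG distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(dist.matrix, cmap="viridis")
    ax.set_xticks(range(N_PCGS), labels=pcg_names, rotation=90, fontsize=5)
    ax.set_yticks(range(N_PCGS), labels=pcg_names, fontsize=5)
    ax.set_title(f"Joint PCG distribution, cluster {dist.label}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
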