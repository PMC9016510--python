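"""Synthetic insured-population cohorts with a planted archetype structure.

The proprietary claims data behind the clustering method (one row per insured
person aged >= 50: 34 binary PCG indicators, demographics, annual deductible,
gatekeeping flag, cost and utilization fields) cannot be redistributed.  This
module generates cohorts whose *archetype* mixture mirrors the published
descriptive statistics of the eight population segments: an outlier fringe,
complex high-cost high-need patients, slightly complex patients with
inexpensive low-severity PCGs, the oldest patients at high hospitalization
risk, patients with one costly disease, the large no-PCG majority, and the
"only hypertension" / "only mental diseases" single groups.

Each archetype carries a PCG pool and a co-occurrence mode:

``joint``
    a patient-level latent severity makes pool PCGs positively correlated
    (diseases often appearing together);
``rare_joint``
    independent low-rate draws (diseases almost never appearing together);
``single``
    exactly one pool PCG (plus, rarely, a second), the "single costly
    disease" pattern.

Ground-truth archetype labels are recorded in a ``true_archetype`` column that
every pipeline stage must ignore except evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .taxonomy import (
    HYPERTENSION_CATEGORY,
    MENTAL_CATEGORY,
    N_PCGS,
    PCGTaxonomy,
    default_taxonomy,
)

COST_FIELDS = ("ambulatory_cost", "inpatient_cost", "medication_cost")
USE_FIELDS = (
    "hospital_days",
    "hospitalizations",
    "consultations_total",
    "consultations_generalist",
)

CooccurrenceMode = Literal["joint", "rare_joint", "single"]
GenerationMode = Literal["stochastic", "exact_counts"]

# Latent severity for the "joint" mode: Gamma with mean 1 and sd 0.5; larger
# spread would clip too many per-PCG probabilities at 1 for the densest pools.
_JOINT_GAMMA_SHAPE = 4.0
_JOINT_GAMMA_SCALE = 0.25


@dataclass
class ArchetypeSpec:
    """Mixture component of the synthetic cohort.

    Means are annual per-patient expectations: costs in CHF, utilization in
    visits/nights/stays per year.  ``multimorbid_share`` is the fraction of
    the archetype carrying two or more PCGs, hit exactly (to printed
    precision) in ``exact_counts`` generation.
    """

    label: str
    proportion: float
    mean_pcg_count: float
    pcg_pool: tuple[str, ...]
    cooccurrence: CooccurrenceMode
    multimorbid_share: float
    age_mean: float
    age_sd: float
    female_share: float
    deductible_mean: float
    gatekeeper_share: float
    cost_means: dict[str, float]
    use_means: dict[str, float]


@dataclass
class CohortSpec:
    """Full generator configuration.

    ``separation`` in [0, 1] controls archetype distinctness: each assigned
    PCG flag is relocated to a uniformly random PCG with probability
    ``1 - separation`` (1 = pure archetype pools, 0 = fully shared).
    """

    n_patients: int
    archetypes: list[ArchetypeSpec]
    seed: int = 0
    separation: float = 1.0
    cost_cv: float = 1.0
    use_dispersion: float = 1.0

    def proportions(self) -> np.ndarray:
        return np.array([a.proportion for a in self.archetypes], dtype=float)


# ---------------------------------------------------------------------------
# Default spec: the published eight-segment cohort of 18,732 insured persons
# ---------------------------------------------------------------------------

# Published per-segment counts; proportions are stored as exact fractions
# count/18,732 (the rounded percentages 1.7/4.4/... would not reproduce the
# printed segment sizes).
_DEFAULT_N = 18_732

_DEFAULT_ARCHETYPES: tuple[dict, ...] = (
    dict(
        label="outlier",
        count=321,
        mean_pcg_count=1.2,
        multimorbid_share=0.1,
        pcg_pool=("chronic_pain", "rheumatism", "gout", "osteoporosis"),
        cooccurrence="joint",
        age_mean=66.3, age_sd=10.8, female_share=0.60,
        deductible_mean=511, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=7967, inpatient_cost=2134, medication_cost=2683),
        use_means=dict(hospital_days=4.3, hospitalizations=0.4,
                       consultations_total=16.0, consultations_generalist=10.0),
    ),
    dict(
        label="complex_high_cost",
        count=817,
        mean_pcg_count=2.1,
        multimorbid_share=0.8,
        pcg_pool=("depression", "hypertension", "chronic_pain", "asthma_copd",
                  "psychosis", "bipolar_disorder", "rheumatism"),
        cooccurrence="joint",
        age_mean=66.3, age_sd=10.6, female_share=0.60,
        deductible_mean=448, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=11731, inpatient_cost=3109, medication_cost=4073),
        use_means=dict(hospital_days=6.6, hospitalizations=0.5,
                       consultations_total=20.2, consultations_generalist=11.6),
    ),
    dict(
        label="slightly_complex",
        count=709,
        mean_pcg_count=1.7,
        multimorbid_share=0.6,
        pcg_pool=("thyroid_disorder", "hypertension", "glaucoma",
                  "hyperlipidemia", "acid_related_disorder", "osteoporosis"),
        cooccurrence="joint",
        age_mean=67.8, age_sd=10.2, female_share=0.71,
        deductible_mean=535, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=7477, inpatient_cost=1811, medication_cost=2221),
        use_means=dict(hospital_days=3.6, hospitalizations=0.3,
                       consultations_total=17.0, consultations_generalist=9.8),
    ),
    dict(
        label="oldest_high_risk",
        count=531,
        mean_pcg_count=1.3,
        multimorbid_share=0.3,
        pcg_pool=("asthma_copd", "parkinson", "heart_failure", "arrhythmia",
                  "coronary_disease", "chronic_pain"),
        cooccurrence="rare_joint",
        age_mean=69.4, age_sd=10.9, female_share=0.47,
        deductible_mean=524, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=9728, inpatient_cost=2749, medication_cost=3587),
        use_means=dict(hospital_days=5.6, hospitalizations=0.4,
                       consultations_total=17.5, consultations_generalist=11.3),
    ),
    dict(
        label="one_costly_disease",
        count=1056,
        mean_pcg_count=1.1,
        multimorbid_share=0.1,
        pcg_pool=("cancer", "diabetes_type1", "diabetes_type2", "crohn_colitis",
                  "rheumatoid_arthritis", "transplant_immunosuppression",
                  "psychosis", "glaucoma", "hiv"),
        cooccurrence="single",
        age_mean=68.1, age_sd=11.2, female_share=0.49,
        deductible_mean=562, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=10362, inpatient_cost=1575, medication_cost=4450),
        use_means=dict(hospital_days=3.4, hospitalizations=0.3,
                       consultations_total=16.1, consultations_generalist=9.4),
    ),
    dict(
        label="no_pcg",
        count=12_720,
        mean_pcg_count=0.0,
        multimorbid_share=0.0,
        pcg_pool=(),
        cooccurrence="single",
        age_mean=64.0, age_sd=10.4, female_share=0.55,
        deductible_mean=908, gatekeeper_share=0.5,
        cost_means=dict(ambulatory_cost=4074, inpatient_cost=1199, medication_cost=965),
        use_means=dict(hospital_days=2.0, hospitalizations=0.2,
                       consultations_total=9.9, consultations_generalist=6.0),
    ),
    dict(
        label="hypertension_only",
        count=1813,
        mean_pcg_count=1.0,
        multimorbid_share=0.0,
        pcg_pool=("hypertension",),
        cooccurrence="single",
        age_mean=67.6, age_sd=9.7, female_share=0.36,
        deductible_mean=612, gatekeeper_share=0.5,
        cost_means=dict(ambulatory_cost=5462, inpatient_cost=1372, medication_cost=1732),
        use_means=dict(hospital_days=2.4, hospitalizations=0.3,
                       consultations_total=12.7, consultations_generalist=8.3),
    ),
    dict(
        label="mental_only",
        count=765,
        mean_pcg_count=1.0,
        multimorbid_share=0.0,
        pcg_pool=("depression", "psychosis", "bipolar_disorder"),
        cooccurrence="single",
        age_mean=63.2, age_sd=10.9, female_share=0.71,
        deductible_mean=558, gatekeeper_share=0.5,
        cost_means=dict(ambulatory_cost=7571, inpatient_cost=1585, medication_cost=1961),
        use_means=dict(hospital_days=3.5, hospitalizations=0.3,
                       consultations_total=18.5, consultations_generalist=9.5),
    ),
)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The published eight-archetype cohort (n = 18,732)."""
    archetypes = []
    for a in _DEFAULT_ARCHETYPES:
        a = dict(a)
        count = a.pop("count")
        archetypes.append(ArchetypeSpec(proportion=count / _DEFAULT_N, **a))
    return CohortSpec(n_patients=_DEFAULT_N, archetypes=archetypes, seed=seed)


def planted_archetype_spec(
    n_patients: int = 1500, separation: float = 1.0, seed: int = 0
) -> CohortSpec:
    """Four equally sized clusterable archetypes with disjoint PCG pools.

    A recovery benchmark: at ``separation=1.0`` the archetypes occupy disjoint
    blocks of PCG space and should be recoverable by the pipeline; lowering
    separation leaks flags across blocks.
    """
    common = dict(
        proportion=0.25,
        mean_pcg_count=2.5,
        multimorbid_share=0.65,
        cooccurrence="joint",
        age_mean=65.0, age_sd=10.0, female_share=0.5,
        deductible_mean=600, gatekeeper_share=0.4,
        cost_means=dict(ambulatory_cost=8000, inpatient_cost=2000, medication_cost=2500),
        use_means=dict(hospital_days=3.0, hospitalizations=0.3,
                       consultations_total=14.0, consultations_generalist=8.0),
    )
    # Eight-PCG pools keep within-archetype patterns diverse (few exact
    # duplicate points, which density-based detection is sensitive to).
    pools = {
        "planted_mental_pain": ("depression", "psychosis", "bipolar_disorder",
                                "chronic_pain", "rheumatism", "gout",
                                "addiction", "hypertension"),
        "planted_metabolic": ("thyroid_disorder", "glaucoma", "hyperlipidemia",
                              "osteoporosis", "acid_related_disorder",
                              "kidney_disease", "diabetes_type2", "other_chronic"),
        "planted_cardioresp": ("asthma_copd", "parkinson", "epilepsy",
                               "multiple_sclerosis", "alzheimer", "heart_failure",
                               "arrhythmia", "coronary_disease"),
        "planted_costly": ("cancer", "diabetes_type1", "crohn_colitis",
                           "psoriasis", "rheumatoid_arthritis",
                           "transplant_immunosuppression", "hiv", "hepatitis"),
    }
    archetypes = [
        ArchetypeSpec(label=label, pcg_pool=pool, **common)
        for label, pool in pools.items()
    ]
    return CohortSpec(
        n_patients=n_patients, archetypes=archetypes, seed=seed, separation=separation
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _validate_spec(spec: CohortSpec, taxonomy: PCGTaxonomy) -> None:
    if spec.n_patients <= 0:
        raise ValidationError("n_patients must be positive")
    props = spec.proportions()
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValidationError(f"archetype proportions sum to {props.sum()!r}, not 1")
    if not 0.0 <= spec.separation <= 1.0:
        raise ValidationError("separation must lie in [0, 1]")
    for a in spec.archetypes:
        if a.mean_pcg_count < 0:
            raise ValidationError(f"{a.label}: mean_pcg_count must be >= 0")
        if a.mean_pcg_count > 0 and not a.pcg_pool:
            raise ValidationError(f"{a.label}: empty PCG pool with mean_pcg_count > 0")
        for name in a.pcg_pool:
            taxonomy.index_of(name)  # raises on unknown names
        if a.cooccurrence == "single" and a.mean_pcg_count > 2:
            raise ValidationError(
                f"{a.label}: 'single' co-occurrence supports mean_pcg_count <= 2"
            )


def _largest_remainder_sizes(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer archetype sizes: floor(p*n) plus largest-remainder correction."""
    quota = proportions * n
    base = np.floor(quota + 1e-9).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _stochastic_flags(
    arch: ArchetypeSpec, n: int, taxonomy: PCGTaxonomy, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n, 34) flag matrix for one archetype, per its co-occurrence mode."""
    flags = np.zeros((n, N_PCGS), dtype=np.int64)
    if n == 0 or arch.mean_pcg_count == 0 or not arch.pcg_pool:
        return flags
    pool_idx = np.array([taxonomy.index_of(p) for p in arch.pcg_pool])
    p_base = arch.mean_pcg_count / len(pool_idx)
    if arch.cooccurrence == "joint":
        severity = rng.gamma(_JOINT_GAMMA_SHAPE, _JOINT_GAMMA_SCALE, size=n)
        p = np.clip(p_base * severity, 0.0, 1.0)
        draws = rng.random((n, len(pool_idx))) < p[:, None]
        flags[:, pool_idx] = draws.astype(np.int64)
    elif arch.cooccurrence == "rare_joint":
        draws = rng.random((n, len(pool_idx))) < min(p_base, 1.0)
        flags[:, pool_idx] = draws.astype(np.int64)
    elif arch.cooccurrence == "single":
        m = arch.mean_pcg_count
        if m <= 1.0:
            counts = (rng.random(n) < m).astype(int)
        else:
            counts = 1 + (rng.random(n) < (m - 1.0)).astype(int)
        counts = np.minimum(counts, len(pool_idx))
        for i in range(n):
            if counts[i]:
                chosen = rng.choice(pool_idx, size=counts[i], replace=False)
                flags[i, chosen] = 1
    else:
        raise ValidationError(f"unknown co-occurrence mode {arch.cooccurrence!r}")
    return flags


def _exact_flags(
    arch: ArchetypeSpec, n: int, taxonomy: PCGTaxonomy
) -> np.ndarray:
    """Deterministic flag allocation hitting mean PCG count and multimorbid share.

    round(share*n) patients receive >= 2 flags (a fixed two-category pair from
    the pool, so they remain clusterable), single-flag patients cycle over
    pool PCGs outside the hypertension/mental categories (falling back to the
    full pool when none exist, i.e. for the single-category archetypes), and
    leftover flags are spread round-robin as third/fourth PCGs.
    """
    flags = np.zeros((n, N_PCGS), dtype=np.int64)
    if n == 0 or arch.mean_pcg_count == 0:
        return flags
    pool = list(arch.pcg_pool)
    total = int(round(arch.mean_pcg_count * n))
    k2 = int(round(arch.multimorbid_share * n))
    if total < 2 * k2:
        raise ValidationError(
            f"{arch.label}: mean_pcg_count {arch.mean_pcg_count} too low for "
            f"multimorbid_share {arch.multimorbid_share}"
        )
    singles = min(n - k2, total - 2 * k2)
    excess = total - 2 * k2 - singles
    if k2 > 0:
        # first pool pair spanning two disease categories
        cat0 = taxonomy.category_of(pool[0])
        partner = next((p for p in pool[1:] if taxonomy.category_of(p) != cat0), None)
        if partner is None:
            raise ValidationError(
                f"{arch.label}: pool spans a single category, cannot build "
                "multimorbid (clusterable) patients in exact_counts mode"
            )
        base_pair = (pool[0], partner)
        extra_choices = [p for p in pool if p not in base_pair]
        if excess > 0 and not extra_choices:
            raise ValidationError(f"{arch.label}: pool too small for mean PCG count")
        for i in range(k2):
            for name in base_pair:
                flags[i, taxonomy.index_of(name)] = 1
        for e in range(excess):
            i = e % k2
            start = e // k2
            for step in range(len(extra_choices)):
                name = extra_choices[(i + start + step) % len(extra_choices)]
                j = taxonomy.index_of(name)
                if flags[i, j] == 0:
                    flags[i, j] = 1
                    break
            else:
                raise ValidationError(f"{arch.label}: pool exhausted allocating flags")
    safe = [
        p for p in pool
        if taxonomy.category_of(p) not in (HYPERTENSION_CATEGORY, MENTAL_CATEGORY)
    ] or pool
    for s in range(singles):
        flags[k2 + s, taxonomy.index_of(safe[s % len(safe)])] = 1
    return flags


def _lognormal(mean: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _neg_binomial(mean: float, dispersion: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(np.int64)


def generate_cohort(
    spec: CohortSpec,
    mode: GenerationMode = "stochastic",
    taxonomy: PCGTaxonomy | None = None,
) -> pd.DataFrame:
    """Generate a cohort table, one row per insured person.

    ``exact_counts`` mode fixes archetype sizes to round(proportion * n) with
    largest-remainder correction and allocates PCG flags deterministically so
    per-archetype mean PCG count and multimorbid share are hit by
    construction; ``stochastic`` mode draws everything.
    """
    taxonomy = taxonomy or default_taxonomy()
    _validate_spec(spec, taxonomy)
    if mode not in ("stochastic", "exact_counts"):
        raise ValidationError(f"unknown generation mode {mode!r}")
    if mode == "exact_counts" and spec.separation != 1.0:
        raise ValidationError(
            "exact_counts mode requires separation == 1.0 (marginal leakage "
            "would break the exact single-group counts)"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if mode == "exact_counts":
        sizes = _largest_remainder_sizes(spec.proportions(), n)
        assignment = np.repeat(np.arange(len(spec.archetypes)), sizes)
    else:
        assignment = rng.choice(len(spec.archetypes), size=n, p=spec.proportions())
        sizes = np.bincount(assignment, minlength=len(spec.archetypes))

    flags = np.zeros((n, N_PCGS), dtype=np.int64)
    columns: dict[str, np.ndarray] = {
        "age": np.zeros(n),
        "sex": np.empty(n, dtype=object),
        "deductible": np.zeros(n),
        "gatekeeper": np.zeros(n, dtype=np.int64),
        "ambulatory_cost": np.zeros(n),
        "inpatient_cost": np.zeros(n),
        "medication_cost": np.zeros(n),
        "hospital_days": np.zeros(n, dtype=np.int64),
        "hospitalizations": np.zeros(n, dtype=np.int64),
        "consultations_total": np.zeros(n, dtype=np.int64),
        "consultations_generalist": np.zeros(n, dtype=np.int64),
    }
    labels = np.empty(n, dtype=object)

    for k, arch in enumerate(spec.archetypes):
        rows = np.nonzero(assignment == k)[0]
        m = rows.size
        if m == 0:
            continue
        labels[rows] = arch.label
        if mode == "exact_counts":
            flags[rows] = _exact_flags(arch, m, taxonomy)
        else:
            flags[rows] = _stochastic_flags(arch, m, taxonomy, rng)
        columns["age"][rows] = np.clip(rng.normal(arch.age_mean, arch.age_sd, m), 50.0, None)
        columns["sex"][rows] = np.where(rng.random(m) < arch.female_share, "F", "M")
        columns["deductible"][rows] = _lognormal(arch.deductible_mean, spec.cost_cv, m, rng)
        columns["gatekeeper"][rows] = (rng.random(m) < arch.gatekeeper_share).astype(int)
        for f in COST_FIELDS:
            columns[f][rows] = _lognormal(arch.cost_means[f], spec.cost_cv, m, rng)
        columns["hospital_days"][rows] = _neg_binomial(
            arch.use_means["hospital_days"], spec.use_dispersion, m, rng
        )
        columns["hospitalizations"][rows] = _neg_binomial(
            arch.use_means["hospitalizations"], spec.use_dispersion, m, rng
        )
        total_mean = arch.use_means["consultations_total"]
        totals = _neg_binomial(total_mean, spec.use_dispersion, m, rng)
        ratio = 0.0 if total_mean <= 0 else min(
            1.0, arch.use_means["consultations_generalist"] / total_mean
        )
        columns["consultations_total"][rows] = totals
        columns["consultations_generalist"][rows] = rng.binomial(totals, ratio)

    if mode == "stochastic" and spec.separation < 1.0:
        # relocate each set flag with probability 1 - separation to a uniform PCG
        ones = np.argwhere(flags == 1)
        move = rng.random(len(ones)) < (1.0 - spec.separation)
        targets = rng.integers(0, N_PCGS, size=len(ones))
        for (i, j), mv, t in zip(ones, move, targets):
            if mv:
                flags[i, j] = 0
                flags[i, t] = 1

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "true_archetype": labels,
            **{k: v for k, v in columns.items()},
        }
    )
    for j, name in enumerate(taxonomy.names):
        df[f"pcg_{name}"] = flags[:, j]
    df["total_cost"] = sum(df[f] for f in COST_FIELDS)
    return df


# ---------------------------------------------------------------------------
# Cohort accessors and I/O
# ---------------------------------------------------------------------------

def pcg_columns(cohort: pd.DataFrame) -> list[str]:
    cols = [c for c in cohort.columns if c.startswith("pcg_")]
    if len(cols) != N_PCGS:
        raise ValidationError(f"cohort must carry {N_PCGS} pcg_* columns, found {len(cols)}")
    return cols


def pcg_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """The (n, 34) binary PCG indicator matrix of a cohort table."""
    mat = cohort[pcg_columns(cohort)].to_numpy(dtype=np.int64)
    if not np.isin(mat, (0, 1)).all():
        raise ValidationError("PCG indicator columns must be binary")
    return mat


def marginal_prevalences(cohort: pd.DataFrame) -> pd.Series:
    """Per-PCG fraction of patients carrying the flag."""
    if len(cohort) == 0:
        raise ValidationError("cannot compute prevalences of an empty cohort")
    cols = pcg_columns(cohort)
    return cohort[cols].mean()


def expected_prevalences(
    spec: CohortSpec, taxonomy: PCGTaxonomy | None = None
) -> np.ndarray:
    """Analytic per-PCG marginal prevalence implied by a cohort spec.

    Each archetype spreads its expected PCG count uniformly over its pool, so
    PCG j's prevalence is ``sum_a proportion_a * mean_pcg_count_a / |pool_a|``
    over the archetypes whose pool contains j.  Useful for building
    structure-free cohorts that share the spec's marginals (flags drawn
    independently per column carry no co-occurrence signal).
    """
    taxonomy = taxonomy or default_taxonomy()
    _validate_spec(spec, taxonomy)
    p = np.zeros(N_PCGS)
    for arch in spec.archetypes:
        if not arch.pcg_pool or arch.mean_pcg_count == 0:
            continue
        per_pcg = arch.mean_pcg_count / len(arch.pcg_pool)
        for name in arch.pcg_pool:
            p[taxonomy.index_of(name)] += arch.proportion * per_pcg
    return np.clip(p, 0.0, 1.0)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    pcg_columns(df)  # schema check
    return df


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    import yaml

    payload = dataclasses.asdict(spec)
    for arch in payload["archetypes"]:
        arch["pcg_pool"] = list(arch["pcg_pool"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    archetypes = [
        ArchetypeSpec(**{**a, "pcg_pool": tuple(a["pcg_pool"])})
        for a in payload.pop("archetypes")
    ]
    return CohortSpec(archetypes=archetypes, **payload)
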