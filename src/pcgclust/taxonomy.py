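"""Pharmacy-based cost groups (PCGs) and their disease-category taxonomy.

A PCG is a chronic-condition flag derived by Swiss insurers from a year of
prescribed-drug claims (active ingredient + quantity via ATC / defined daily
dose).  Thirty-four PCGs exist; for clustering they are grouped into fifteen
clinically meaningful disease categories.  A patient is *multimorbid* when two
or more PCGs are assigned in the year.

The official Swiss 34-PCG list and its 15-category grouping are not public in
a machine-readable form, so this module ships a synthetic stand-in taxonomy
whose names cover the disease groups discussed in the clustering literature
(hypertension, mental diseases, pain, asthma/COPD, thyroid, glaucoma,
diabetes, cancer, Parkinson, cardiac diseases, inflammatory diseases, immune
suppression, HIV, ...).  Users holding the official list can substitute it via
:func:`load_taxonomy`; none of the pipeline mathematics depends on the names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

N_PCGS = 34
N_CATEGORIES = 15

#: Categories that define the pre-extracted "single" clusters.
HYPERTENSION_CATEGORY = "hypertension"
MENTAL_CATEGORY = "mental"

# Synthetic stand-in for the official 34-PCG list: (pcg_name, category_name).
_DEFAULT_MAPPING: tuple[tuple[str, str], ...] = (
    ("hypertension", "hypertension"),
    ("depression", "mental"),
    ("psychosis", "mental"),
    ("bipolar_disorder", "mental"),
    ("chronic_pain", "pain"),
    ("rheumatism", "pain"),
    ("gout", "pain"),
    ("asthma_copd", "respiratory"),
    ("thyroid_disorder", "thyroid"),
    ("glaucoma", "glaucoma"),
    ("diabetes_type1", "diabetes"),
    ("diabetes_type2", "diabetes"),
    ("cancer", "cancer"),
    ("parkinson", "neurological"),
    ("epilepsy", "neurological"),
    ("multiple_sclerosis", "neurological"),
    ("alzheimer", "neurological"),
    ("heart_failure", "cardiac"),
    ("arrhythmia", "cardiac"),
    ("coronary_disease", "cardiac"),
    ("anticoagulation", "cardiac"),
    ("crohn_colitis", "inflammatory"),
    ("psoriasis", "inflammatory"),
    ("rheumatoid_arthritis", "inflammatory"),
    ("transplant_immunosuppression", "immune"),
    ("hiv", "hiv"),
    ("hyperlipidemia", "metabolic"),
    ("osteoporosis", "metabolic"),
    ("acid_related_disorder", "metabolic"),
    ("kidney_disease", "metabolic"),
    ("tuberculosis", "other"),
    ("hepatitis", "other"),
    ("addiction", "other"),
    ("other_chronic", "other"),
)


@dataclass(frozen=True)
class PCGCode:
    """One pharmacy-based cost group: positional id, name and disease category."""

    id: int
    name: str
    category: str


class PCGTaxonomy:
    """The 34 PCG codes and their grouping into 15 disease categories.

    Column order of every PCG vector/matrix in the package follows
    ``taxonomy.names``.
    """

    def __init__(self, codes: Sequence[PCGCode]):
        codes = tuple(codes)
        names = [c.name for c in codes]
        if len(codes) != N_PCGS:
            raise ConfigurationError(
                f"taxonomy must define exactly {N_PCGS} PCGs, got {len(codes)}"
            )
        if sorted(c.id for c in codes) != list(range(N_PCGS)):
            raise ConfigurationError("PCG ids must be a permutation of 0..33")
        if len(set(names)) != N_PCGS:
            raise ConfigurationError("PCG names must be unique")
        categories = sorted({c.category for c in codes})
        if len(categories) != N_CATEGORIES:
            raise ConfigurationError(
                f"taxonomy must use exactly {N_CATEGORIES} disease categories, "
                f"got {len(categories)}"
            )
        self.codes = tuple(sorted(codes, key=lambda c: c.id))
        self.names = tuple(c.name for c in self.codes)
        self.categories = tuple(categories)
        self._name_to_id = {c.name: c.id for c in self.codes}
        self._cat_to_idx = {cat: i for i, cat in enumerate(self.categories)}
        # 34 x 15 indicator: membership[p, k] = 1 iff PCG p belongs to category k
        self.membership = np.zeros((N_PCGS, N_CATEGORIES), dtype=np.int64)
        for c in self.codes:
            self.membership[c.id, self._cat_to_idx[c.category]] = 1

    def index_of(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise ConfigurationError(f"unknown PCG name {name!r}") from None

    def category_of(self, name: str) -> str:
        return self.codes[self.index_of(name)].category

    def category_index(self, category: str) -> int:
        try:
            return self._cat_to_idx[category]
        except KeyError:
            raise ConfigurationError(f"unknown disease category {category!r}") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PCGTaxonomy) and self.codes == other.codes

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PCGTaxonomy({N_PCGS} PCGs, {N_CATEGORIES} categories)"

    def to_csv(self, path: str | Path) -> None:
        """Write the mapping as two-column CSV (pcg_name, category_name)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pcg_name", "category_name"])
            for code in self.codes:
                writer.writerow([code.name, code.category])


def default_taxonomy() -> PCGTaxonomy:
    """The synthetic stand-in taxonomy shipped with the package."""
    return PCGTaxonomy(
        [PCGCode(i, name, cat) for i, (name, cat) in enumerate(_DEFAULT_MAPPING)]
    )


def load_taxonomy(path: str | Path) -> PCGTaxonomy:
    """Load a taxonomy from a two-column mapping file (CSV or YAML).

    CSV needs a ``pcg_name,category_name`` header; YAML is a flat
    ``pcg_name: category_name`` mapping.  PCG ids are assigned in file order.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if path.suffix.lower() in {".yml", ".yaml"}:
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError("YAML taxonomy must be a pcg->category mapping")
        pairs = [(str(k), str(v)) for k, v in data.items()]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "pcg_name",
                "category_name",
            } <= set(reader.fieldnames):
                raise ConfigurationError(
                    "CSV taxonomy needs columns pcg_name,category_name"
                )
            for row in reader:
                pairs.append((row["pcg_name"], row["category_name"]))
    return PCGTaxonomy([PCGCode(i, n, c) for i, (n, c) in enumerate(pairs)])


# ---------------------------------------------------------------------------
# PCG vector operations
# ---------------------------------------------------------------------------

def as_pcg_vector(flags: Iterable[int]) -> np.ndarray:
    """Validate and coerce a sequence of 34 binary indicators."""
    v = np.asarray(list(flags) if not isinstance(flags, np.ndarray) else flags)
    if v.ndim != 1 or v.shape[0] != N_PCGS:
        raise ValidationError(f"PCG vector must have length {N_PCGS}, got shape {v.shape}")
    if not np.isin(v, (0, 1)).all():
        raise ValidationError("PCG vector entries must be 0 or 1")
    return v.astype(np.int64)


def pcg_count(flags: Iterable[int]) -> int:
    """Number of PCGs assigned to a patient (sum of the 34 indicators)."""
    return int(as_pcg_vector(flags).sum())


def is_multimorbid(flags: Iterable[int]) -> bool:
    """True iff the patient carries two or more PCGs."""
    return pcg_count(flags) >= 2


def category_profile(flags: Iterable[int], taxonomy: PCGTaxonomy) -> np.ndarray:
    """Per-disease-category counts of assigned PCGs (length 15, sums to pcg_count)."""
    v = as_pcg_vector(flags)
    return v @ taxonomy.membership


def category_span(flags: Iterable[int], taxonomy: PCGTaxonomy) -> set[str]:
    """The set of disease categories touched by a PCG vector."""
    prof = category_profile(flags, taxonomy)
    return {taxonomy.categories[i] for i in np.nonzero(prof)[0]}
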