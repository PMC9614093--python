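"""Composition metrics: kin and adult classification, relationship intensity.

Kin is any relationship in the immediate or extended family (grandparents,
aunts, uncles, cousins, ...). Anyone under 13 years of age counts as a
child; 13 and over as an adult.

Relationship intensity is a cohort-level composite of three measures — the
number of activities the person does with the child, the parent-rated
emotional closeness, and the proportion of the child's waking hours spent
with the person. Each measure is z-scored over the pooled relationships,
the three z-scores are averaged per relationship, and a median split of the
average labels every relationship "high" or "low" intensity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import AlterRecord, EgoNetwork

__all__ = [
    "ADULT_AGE_YEARS",
    "DEFAULT_TAXONOMY",
    "UnknownRelationshipError",
    "load_taxonomy",
    "normalize_label",
    "classify_kin",
    "classify_adult",
    "IntensityScore",
    "score_intensity",
    "composition_proportions",
]

logger = logging.getLogger("csnq.composition")

#: Age boundary (in years) between "child" and "adult" relationships.
ADULT_AGE_YEARS = 13.0

_KIN_LABELS = {
    "mother", "mom", "mommy", "mama", "father", "dad", "daddy", "papa",
    "parent", "stepmother", "stepfather", "step-mother", "step-father",
    "sister", "brother", "sibling", "half-sister", "half-brother",
    "stepsister", "stepbrother", "twin", "baby sister", "baby brother",
    "grandmother", "grandma", "grandfather", "grandpa", "grandparent",
    "great-grandmother", "great-grandfather", "great aunt", "great uncle",
    "aunt", "uncle", "cousin", "second cousin", "niece", "nephew",
}

_NON_KIN_LABELS = {
    "friend", "family friend", "best friend", "classmate", "playmate", "peer",
    "neighbor", "neighbour", "teacher", "daycare teacher", "preschool teacher",
    "assistant teacher", "babysitter", "nanny", "au pair", "caregiver",
    "coach", "instructor", "swim instructor", "music teacher", "librarian",
    "pastor", "priest", "rabbi", "doctor", "pediatrician", "therapist",
    "daycare/preschool class", "daycare class", "preschool class", "class",
    "playgroup", "godmother", "godfather", "housekeeper", "tutor",
    "mother's friend", "father's friend", "parent's friend",
}

#: Shipped default relationship-label -> kin mapping.
DEFAULT_TAXONOMY: dict[str, bool] = {
    **{label: True for label in _KIN_LABELS},
    **{label: False for label in _NON_KIN_LABELS},
}


class UnknownRelationshipError(KeyError):
    """A relationship label absent from the taxonomy, under strict mode."""


def normalize_label(label: str) -> str:
    return " ".join(label.strip().lower().split())


def load_taxonomy(path: str | Path) -> dict[str, bool]:
    """Load a label->kin mapping from YAML ({label: bool}) or two-column CSV
    (label, kin)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: taxonomy YAML must map label -> bool")
        return {normalize_label(k): bool(v) for k, v in raw.items()}
    taxonomy: dict[str, bool] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in ("label", "relationship"):
                continue
            taxonomy[normalize_label(row[0])] = row[1].strip().lower() in (
                "1", "true", "yes", "kin",
            )
    return taxonomy


def classify_kin(
    label: str,
    taxonomy: Optional[Mapping[str, bool]] = None,
    strict: bool = False,
) -> bool:
    """Whether a relationship label denotes immediate or extended family.

    Labels are normalized (case, surrounding whitespace) before lookup.
    Unknown labels raise :class:`UnknownRelationshipError` under
    ``strict=True`` and are otherwise counted non-kin with a warning.
    """
    if not label or not label.strip():
        raise ValueError("relationship label must be nonempty")
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    key = normalize_label(label)
    if key in taxonomy:
        return taxonomy[key]
    if strict:
        raise UnknownRelationshipError(label)
    logger.warning("unknown relationship label %r treated as non-kin", label)
    return False


def classify_adult(age_years: Optional[float]) -> Optional[str]:
    """"adult" for age >= 13 years, "child" below, None when age is missing."""
    if age_years is None:
        return None
    return "child" if age_years < ADULT_AGE_YEARS else "adult"


@dataclass(frozen=True)
class IntensityScore:
    """Standardized intensity components and the median-split label."""

    z_activities: float
    z_closeness: float
    z_hours: float
    z_mean: float
    label: str  # "high" | "low"


def _zscores(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std()  # population (n) denominator; the split is unaffected
    if sd == 0:
        logger.warning("intensity measure %r has zero variance; z set to 0", name)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def score_intensity(
    pool: Sequence[AlterRecord],
) -> dict[tuple[str, str], IntensityScore]:
    """Composite intensity scoring over a pooled set of relationships.

    The pool is every relationship (across the cohort) with all three
    intensity measures reported; z-scores are computed over this pool, so
    the high/low labels are relative to the cohort, not to one child.
    Relationships whose average z-score exceeds the pool median are "high";
    scores at or below the median are "low" (ties go to "low", which keeps
    the rule deterministic; with distinct scores and an even pool the split
    is exactly half and half).
    """
    if len(pool) < 2:
        raise ValueError("intensity pool needs at least 2 relationships")
    for rec in pool:
        if not rec.has_intensity:
            raise ValueError(
                f"alter {rec.alter_id} (ego {rec.ego_id}) is missing an "
                "intensity measure"
            )
    acts = _zscores(
        np.array([r.intensity_activities for r in pool], dtype=float), "activities"
    )
    clos = _zscores(
        np.array([r.intensity_closeness for r in pool], dtype=float), "closeness"
    )
    hrs = _zscores(np.array([r.intensity_hours for r in pool], dtype=float), "hours")
    z_mean = (acts + clos + hrs) / 3.0
    median = float(np.median(z_mean))
    return {
        (r.ego_id, r.alter_id): IntensityScore(
            z_activities=float(acts[i]),
            z_closeness=float(clos[i]),
            z_hours=float(hrs[i]),
            z_mean=float(z_mean[i]),
            label="high" if z_mean[i] > median else "low",
        )
        for i, r in enumerate(pool)
    }


def composition_proportions(
    net: EgoNetwork,
    taxonomy: Optional[Mapping[str, bool]] = None,
    intensity_labels: Optional[Mapping[tuple[str, str], IntensityScore]] = None,
    strict: bool = False,
) -> dict:
    """Per-child composition proportions: kin, adult, high-intensity.

    Denominators count attribute-eligible alters: group nodes are excluded
    (their person-level attributes are undefined), and the adult and
    intensity proportions further restrict to alters with the relevant data
    reported. Proportions are None when no alter is eligible.
    """
    persons = [a for a in net.alters if not a.is_group]

    n_kin = sum(1 for a in persons if classify_kin(a.relationship, taxonomy, strict))
    prop_kin = n_kin / len(persons) if persons else None

    aged = [classify_adult(a.age_years) for a in persons]
    aged = [x for x in aged if x is not None]
    prop_adult = aged.count("adult") / len(aged) if aged else None

    n_high = n_low = None
    prop_high = None
    if intensity_labels is not None:
        labels = [
            intensity_labels[(a.ego_id, a.alter_id)].label
            for a in persons
            if (a.ego_id, a.alter_id) in intensity_labels
        ]
        if labels:
            n_high = labels.count("high")
            n_low = labels.count("low")
            prop_high = n_high / (n_high + n_low)

    return {
        "n_kin": n_kin,
        "prop_kin": prop_kin,
        "prop_adult": prop_adult,
        "n_high_intensity": n_high,
        "n_low_intensity": n_low,
        "prop_high_intensity": prop_high,
    }
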