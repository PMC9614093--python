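"""Diversity metrics: categorical entropy, EI homophily indices, typology.

Two complementary views of network diversity are computed over the alters
of an ego network:

* **Entropy** describes the representation of social categories among the
  alters, H(X) = -sum p * log2(p) over the category proportions p. 0 means
  every alter shares one category; a uniform split over k categories gives
  log2(k).
* **EI index** describes how different the network is *relative to the
  child*: (D - S) / (D + S) where D and S count alters coded different/same
  as the child on the attribute. -1 is a fully homophilous network, +1 a
  network entirely unlike the child.

Race coding: a multi-category individual collapses to "Mixed/Biracial" for
entropy, but EI sameness compares full category sets — an alter is
same-race if they share *either* race of a biracial child.

Language coding for entropy buckets each alter into English-monolingual,
English-bilingual, non-English-monolingual, other-multilingual, or
preverbal. EI sameness codes an alter different-speaker iff they speak a
language the child does not.

Component-level entropy supports a typology of how diversity is patterned:
*integrated* (every component mixed), *segregated* (overall entropy > 0 but
at least half the components homogeneous), or *no-diversity* (overall
entropy 0).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .records import AlterRecord, EgoNetwork, EgoRecord, MIXED_BIRACIAL, collapse_races

__all__ = [
    "INTEGRATED",
    "SEGREGATED",
    "NO_DIVERSITY",
    "LANGUAGE_CATEGORIES",
    "DiversityTypology",
    "shannon_entropy",
    "neighborhood_entropy",
    "racial_profile",
    "language_category",
    "language_profile",
    "ei_index",
    "code_racial_sameness",
    "code_linguistic_sameness",
    "attribute_ei",
    "component_entropy_profile",
    "classify_diversity_type",
]

logger = logging.getLogger("csnq.diversity")

INTEGRATED = "integrated"
SEGREGATED = "segregated"
NO_DIVERSITY = "no_diversity"

ENGLISH = "English"

LANGUAGE_CATEGORIES = (
    "English-monolingual",
    "English-bilingual",
    "non-English-monolingual",
    "other-multilingual",
    "preverbal",
)

_ENTROPY_TOL = 1e-12


def shannon_entropy(profile: Mapping[str, float]) -> float:
    """Base-2 Shannon entropy of a category->proportion profile.

    Proportions must be nonnegative and sum to 1 (tolerance 1e-9);
    zero-proportion categories contribute nothing (0*log 0 == 0).
    """
    if not profile:
        raise ValueError("empty category profile")
    total = 0.0
    h = 0.0
    for cat, p in profile.items():
        if p < 0:
            raise ValueError(f"negative proportion for {cat!r}")
        total += p
        if p > 0:
            h -= p * math.log2(p)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total!r}, expected 1")
    return 0.0 if h < _ENTROPY_TOL else h


def neighborhood_entropy(profile: Mapping[str, float]) -> float:
    """Entropy of a zip-level neighborhood category profile — the same
    computation as :func:`shannon_entropy`, applied to census-derived
    proportions supplied as input."""
    return shannon_entropy(profile)


def _counts_to_profile(counts: Mapping[str, int]) -> Optional[dict[str, float]]:
    total = sum(counts.values())
    if total == 0:
        return None
    return {cat: n / total for cat, n in sorted(counts.items())}


def racial_profile(alters: Sequence[AlterRecord]) -> Optional[dict[str, float]]:
    """Category proportions over alters with known race.

    Multi-race alters are coded "Mixed/Biracial"; alters with missing race
    (including attribute-less group nodes) are excluded and the proportions
    renormalized over the rest. None when no alter has a known race.
    """
    counts: dict[str, int] = {}
    for a in alters:
        if a.races is None:
            continue
        cat = collapse_races(a.races)
        counts[cat] = counts.get(cat, 0) + 1
    return _counts_to_profile(counts)


def language_category(alter: AlterRecord) -> Optional[str]:
    """Discrete language category of one alter, None when unreported."""
    spoken = alter.speaks()
    if spoken is None:
        return None
    if not spoken:
        return "preverbal"
    if spoken == {ENGLISH}:
        return "English-monolingual"
    if ENGLISH in spoken:
        return "English-bilingual"
    if len(spoken) == 1:
        return "non-English-monolingual"
    return "other-multilingual"


def language_profile(alters: Sequence[AlterRecord]) -> Optional[dict[str, float]]:
    """Proportions of discrete language categories among codable alters."""
    counts: dict[str, int] = {}
    for a in alters:
        cat = language_category(a)
        if cat is None:
            continue
        counts[cat] = counts.get(cat, 0) + 1
    return _counts_to_profile(counts)


def ei_index(n_same: int, n_different: int) -> float:
    """(different - same) / (different + same), in [-1, 1].

    The denominator counts coded alters; callers drop alters whose
    attribute cannot be compared to the child's.
    """
    if n_same < 0 or n_different < 0:
        raise ValueError("counts must be nonnegative")
    total = n_same + n_different
    if total == 0:
        raise ValueError("EI index needs at least one coded alter")
    return (n_different - n_same) / total


def code_racial_sameness(ego: EgoRecord, alter: AlterRecord) -> Optional[str]:
    """"same" iff the alter is of either race of the child.

    Category sets are intersected, so a Black/White biracial child matches
    any alter that is White or Black (or Black/White biracial). An
    individual labeled only "Mixed/Biracial" — component races unknown —
    cannot be compared to a party without that label and is coded missing
    rather than guessed.
    """
    if alter.races is None:
        return None
    if ego.races & alter.races:
        return "same"
    if alter.races == {MIXED_BIRACIAL} or ego.races == {MIXED_BIRACIAL}:
        return None
    return "different"


def code_linguistic_sameness(ego: EgoRecord, alter: AlterRecord) -> Optional[str]:
    """"different" iff the alter speaks a language the child does not.

    Preverbal infants speak nothing outside the child's set and are coded
    same; alters with unreported language are missing.
    """
    spoken = alter.speaks()
    if spoken is None:
        return None
    return "different" if spoken - ego.languages else "same"


def attribute_ei(
    ego: EgoRecord, alters: Sequence[AlterRecord], attribute: str
) -> Optional[float]:
    """EI index over coded alters for ``attribute`` in {"race", "language"};
    None when no alter could be coded."""
    coder = {"race": code_racial_sameness, "language": code_linguistic_sameness}[
        attribute
    ]
    codes = [coder(ego, a) for a in alters]
    n_same = codes.count("same")
    n_diff = codes.count("different")
    if n_same + n_diff == 0:
        return None
    return ei_index(n_same, n_diff)


def _component_profile(
    alters: Sequence[AlterRecord], attribute: str
) -> Optional[dict[str, float]]:
    if attribute == "race":
        return racial_profile(alters)
    if attribute == "language":
        return language_profile(alters)
    raise ValueError(f"unknown attribute {attribute!r}")


def component_entropy_profile(
    net: EgoNetwork, attribute: str = "race"
) -> tuple[list[Optional[float]], Optional[float]]:
    """Entropy of each component over its own members, plus the proportion
    of components with zero entropy.

    Returns one entropy per component (aligned with ``net.components``;
    None where no member has a codable attribute) and
    ``#zero-entropy components / #components with defined entropy``
    (None when no component has defined entropy).
    """
    entropies: list[Optional[float]] = []
    for comp in net.components:
        members = [a for a in net.alters if a.alter_id in comp]
        profile = _component_profile(members, attribute)
        entropies.append(None if profile is None else shannon_entropy(profile))
    defined = [h for h in entropies if h is not None]
    if not defined:
        return entropies, None
    zero_prop = sum(1 for h in defined if h <= _ENTROPY_TOL) / len(defined)
    return entropies, zero_prop


@dataclass(frozen=True)
class DiversityTypology:
    """How diversity is patterned across components."""

    label: str
    zero_entropy_component_prop: float


def classify_diversity_type(
    overall_entropy: Optional[float], zero_entropy_component_prop: Optional[float]
) -> Optional[DiversityTypology]:
    """Classify a network as integrated, segregated, or no-diversity.

    * overall entropy 0 -> no-diversity (every component is necessarily
      homogeneous too);
    * entropy > 0 with >= half the components homogeneous -> segregated;
    * entropy > 0 with fewer than half homogeneous -> integrated.

    The edge case of entropy > 0 with *every* component homogeneous (two
    disjoint single-race components of different races) falls under
    segregated, with a warning — it is patterned maximal segregation.
    Returns None when either ingredient is unavailable.
    """
    if overall_entropy is None or zero_entropy_component_prop is None:
        return None
    zp = zero_entropy_component_prop
    if not 0.0 <= zp <= 1.0:
        raise ValueError("zero-entropy component proportion must lie in [0, 1]")
    if overall_entropy <= _ENTROPY_TOL:
        return DiversityTypology(NO_DIVERSITY, zp)
    if zp >= 0.5:
        if zp >= 1.0:
            warnings.warn(
                "network with positive entropy but only homogeneous components; "
                "classified segregated",
                stacklevel=2,
            )
        return DiversityTypology(SEGREGATED, zp)
    return DiversityTypology(INTEGRATED, zp)
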