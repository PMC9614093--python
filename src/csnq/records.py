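"""Core record types for child egocentric-network rosters.

The focal child is the *ego*; the people (or multi-person groups such as a
"daycare/preschool class") the child sees on a weekly basis are the *alters*.
A roster pairs one :class:`EgoRecord` with that child's :class:`AlterRecord`
list; :class:`EgoNetwork` adds the inferred alter-alter tie set and its
connected-component partition, and :class:`MetricsRecord` holds the full set
of per-child network metrics (size, composition, structure, diversity).

Race categories follow a fixed controlled vocabulary. Parents may mark an
individual with more than one category; the raw category *set* is retained
here because homophily (EI) coding needs the component races, while entropy
coding collapses any multi-category individual to "Mixed/Biracial"
(see :func:`collapse_races`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "RACE_CATEGORIES",
    "MIXED_BIRACIAL",
    "URBAN",
    "SUBURBAN_RURAL",
    "PROTOCOL_LAB",
    "PROTOCOL_MUSEUM",
    "VocabularyError",
    "RosterError",
    "normalize_race",
    "collapse_races",
    "EgoRecord",
    "AlterRecord",
    "EgoNetwork",
    "MetricsRecord",
]

MIXED_BIRACIAL = "Mixed/Biracial"

#: Controlled vocabulary of racial categories.
RACE_CATEGORIES = (
    "African/Black-American",
    "Asian/Asian-American",
    "European/White-American",
    "Hispanic/Latino-American",
    "Native American",
    MIXED_BIRACIAL,
    "Other",
)

# Common survey spellings mapped onto the controlled vocabulary.
_RACE_ALIASES = {
    "african/black-american": "African/Black-American",
    "african or black-american": "African/Black-American",
    "african-american": "African/Black-American",
    "african american": "African/Black-American",
    "black": "African/Black-American",
    "asian/asian-american": "Asian/Asian-American",
    "asian or asian-american": "Asian/Asian-American",
    "asian-american": "Asian/Asian-American",
    "asian american": "Asian/Asian-American",
    "asian": "Asian/Asian-American",
    "european/white-american": "European/White-American",
    "european or white-american": "European/White-American",
    "white": "European/White-American",
    "european-american": "European/White-American",
    "european american": "European/White-American",
    "caucasian": "European/White-American",
    "hispanic/latino-american": "Hispanic/Latino-American",
    "hispanic or latino-american": "Hispanic/Latino-American",
    "hispanic or latino/a-american": "Hispanic/Latino-American",
    "hispanic": "Hispanic/Latino-American",
    "latino": "Hispanic/Latino-American",
    "latina": "Hispanic/Latino-American",
    "latino/a": "Hispanic/Latino-American",
    "native american": "Native American",
    "american indian": "Native American",
    "mixed/biracial": MIXED_BIRACIAL,
    "mixed or biracial": MIXED_BIRACIAL,
    "mixed": MIXED_BIRACIAL,
    "biracial": MIXED_BIRACIAL,
    "multiracial": MIXED_BIRACIAL,
    "other": "Other",
}

URBAN = "urban"
SUBURBAN_RURAL = "suburban_rural"

#: Study protocols. Context (hence density) data was collected under the
#: museum protocol; relationship-intensity measures under the lab protocol.
PROTOCOL_LAB = "lab"
PROTOCOL_MUSEUM = "museum"

_PROFILE_TOL = 1e-9


class VocabularyError(ValueError):
    """A categorical token is not in the controlled vocabulary."""


class RosterError(ValueError):
    """A roster row or record violates an invariant."""


def normalize_race(token: str) -> str:
    """Map a race string onto the controlled vocabulary.

    Raises :class:`VocabularyError` (listing the vocabulary) for unknown
    tokens.
    """
    key = " ".join(token.strip().lower().split())
    if not key:
        raise VocabularyError("empty race token")
    try:
        return _RACE_ALIASES[key]
    except KeyError:
        raise VocabularyError(
            f"unknown race category {token!r}; expected one of {RACE_CATEGORIES}"
        ) from None


def collapse_races(races: frozenset[str] | set[str]) -> str:
    """Collapse a race category set to the single category used for entropy.

    Any individual marked with more than one category is coded
    "Mixed/Biracial"; a singleton set maps to its sole member. The raw set
    is kept on the record because EI (homophily) coding compares full
    category sets.
    """
    if not races:
        raise ValueError("empty race set")
    if len(races) > 1:
        return MIXED_BIRACIAL
    return next(iter(races))


def _check_profile(profile: Mapping[str, float], name: str) -> None:
    total = 0.0
    for cat, p in profile.items():
        if p < 0:
            raise RosterError(f"{name}: negative proportion for {cat!r}")
        total += p
    if abs(total - 1.0) > _PROFILE_TOL:
        raise RosterError(f"{name}: proportions sum to {total!r}, expected 1")


@dataclass(frozen=True)
class EgoRecord:
    """One child: demographics plus optional neighborhood context.

    ``age_months`` is the child's age in months (positive). ``races`` is the
    child's own category set (nonempty); biracial children carry both
    component races when known. Neighborhood profiles are zip-level
    category->proportion maps supplied externally (census extracts);
    ``urbanicity`` labels the zip as urban or suburban/rural.
    ``protocol`` records which questionnaire variant the family completed;
    it governs which optional metrics (density, intensity) are defined.
    """

    ego_id: str
    age_months: float
    races: frozenset[str]
    languages: frozenset[str] = frozenset()
    childcare_out_of_home: Optional[bool] = None
    urbanicity: Optional[str] = None
    protocol: Optional[str] = None
    neighborhood_race_profile: Optional[Mapping[str, float]] = None
    neighborhood_language_profile: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not self.ego_id:
            raise RosterError("ego_id must be nonempty")
        if not (self.age_months > 0) or not math.isfinite(self.age_months):
            raise RosterError(f"ego {self.ego_id}: age_months must be positive")
        if not self.races:
            raise RosterError(f"ego {self.ego_id}: races must be nonempty")
        for r in self.races:
            if r not in RACE_CATEGORIES:
                raise VocabularyError(
                    f"ego {self.ego_id}: unknown race category {r!r}; "
                    f"expected one of {RACE_CATEGORIES}"
                )
        if self.urbanicity is not None and self.urbanicity not in (URBAN, SUBURBAN_RURAL):
            raise RosterError(
                f"ego {self.ego_id}: urbanicity must be {URBAN!r} or {SUBURBAN_RURAL!r}"
            )
        if self.protocol is not None and self.protocol not in (PROTOCOL_LAB, PROTOCOL_MUSEUM):
            raise RosterError(
                f"ego {self.ego_id}: protocol must be {PROTOCOL_LAB!r} or {PROTOCOL_MUSEUM!r}"
            )
        for name in ("neighborhood_race_profile", "neighborhood_language_profile"):
            profile = getattr(self, name)
            if profile is not None:
                _check_profile(profile, f"ego {self.ego_id} {name}")


@dataclass(frozen=True)
class AlterRecord:
    """One network member, a person or a multi-person group node.

    Group nodes (``is_group=True``, e.g. "daycare/preschool class") count
    toward network size and participate in context-based tie inference, but
    are excluded from attribute-based metrics unless the relevant attribute
    was actually reported (group demographics are normally undefined).

    ``contexts`` (nonempty) lists the settings in which the alter interacts
    with the child; shared contexts are the basis of tie inference.
    ``preverbal`` marks infants who do not yet speak; their empty language
    set is valid data, not missingness.
    """

    ego_id: str
    alter_id: str
    relationship: str
    contexts: frozenset[str]
    is_group: bool = False
    age_years: Optional[float] = None
    races: Optional[frozenset[str]] = None
    languages: Optional[frozenset[str]] = None
    preverbal: bool = False
    intensity_activities: Optional[float] = None
    intensity_closeness: Optional[float] = None
    intensity_hours: Optional[float] = None

    def __post_init__(self) -> None:
        where = f"alter {self.alter_id} (ego {self.ego_id})"
        if not self.ego_id or not self.alter_id:
            raise RosterError(f"{where}: ego_id and alter_id must be nonempty")
        if not self.contexts:
            raise RosterError(f"{where}: contexts must be nonempty")
        if self.age_years is not None and self.age_years < 0:
            raise RosterError(f"{where}: age_years must be nonnegative")
        if self.races is not None:
            if not self.races:
                raise RosterError(f"{where}: races must be nonempty or missing")
            for r in self.races:
                if r not in RACE_CATEGORIES:
                    raise VocabularyError(
                        f"{where}: unknown race category {r!r}; "
                        f"expected one of {RACE_CATEGORIES}"
                    )
        if self.intensity_hours is not None and not (0.0 <= self.intensity_hours <= 1.0):
            raise RosterError(f"{where}: intensity_hours must lie in [0, 1]")

    @property
    def has_intensity(self) -> bool:
        """True when all three intensity measures were reported."""
        return (
            self.intensity_activities is not None
            and self.intensity_closeness is not None
            and self.intensity_hours is not None
        )

    def speaks(self) -> Optional[frozenset[str]]:
        """Language set used for coding: empty set for preverbal infants,
        None when genuinely missing."""
        if self.languages is not None and self.languages:
            return self.languages
        if self.preverbal:
            return frozenset()
        return None


@dataclass
class EgoNetwork:
    """An assembled ego network.

    ``ties`` contains unordered alter-alter pairs only (the ego is excluded
    by the egocentric convention); ``components`` is the connected-component
    partition of the alter-alter graph, so every network has at least one
    component even when no ties exist.
    """

    ego: EgoRecord
    alters: list[AlterRecord]
    ties: frozenset[tuple[str, str]]
    components: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alters:
            raise RosterError(
                f"ego {self.ego.ego_id}: a network needs at least one alter"
            )
        ids = [a.alter_id for a in self.alters]
        id_set = set(ids)
        if len(id_set) != len(ids):
            raise RosterError(f"ego {self.ego.ego_id}: duplicate alter ids")
        for a, b in self.ties:
            if a == b:
                raise RosterError(f"ego {self.ego.ego_id}: self-tie {a!r}")
            if a not in id_set or b not in id_set:
                raise RosterError(
                    f"ego {self.ego.ego_id}: tie ({a!r}, {b!r}) references unknown alter"
                )
        if self.components:
            covered = set().union(*self.components)
            if covered != id_set or sum(len(c) for c in self.components) != len(id_set):
                raise RosterError(
                    f"ego {self.ego.ego_id}: components must partition the alter set"
                )

    @property
    def network_size(self) -> int:
        return len(self.alters)

    @property
    def n_ties(self) -> int:
        return len(self.ties)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def alter(self, alter_id: str) -> AlterRecord:
        for a in self.alters:
            if a.alter_id == alter_id:
                return a
        raise KeyError(alter_id)


@dataclass
class MetricsRecord:
    """All per-child network metrics (one row of the cohort metric table).

    Counts are nonnegative; proportions lie in [0, 1]; entropies are in bits
    (base-2, nonnegative); EI indices lie in [-1, 1]. Fields are ``None``
    when the underlying data was not collected for this child (e.g. density
    under the lab protocol, intensity under the museum protocol).
    """

    ego_id: str
    network_size: int
    n_components: int
    component_ratio: Optional[float]
    age_months: Optional[float] = None
    childcare_out_of_home: Optional[bool] = None
    urbanicity: Optional[str] = None
    n_high_intensity: Optional[int] = None
    n_low_intensity: Optional[int] = None
    prop_high_intensity: Optional[float] = None
    prop_kin: Optional[float] = None
    prop_adult: Optional[float] = None
    density: Optional[float] = None
    racial_entropy: Optional[float] = None
    language_entropy: Optional[float] = None
    racial_ei: Optional[float] = None
    linguistic_ei: Optional[float] = None
    neighborhood_racial_entropy: Optional[float] = None
    neighborhood_language_entropy: Optional[float] = None
    zero_entropy_component_prop: Optional[float] = None
    diversity_type: Optional[str] = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)
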