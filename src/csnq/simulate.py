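"""Synthetic cohort generator.

Emulates the statistical structure of a cross-sectional cohort of ~280
American children aged 6-60 months: network size growing with age
(overdispersed count, floor of 3), a family component plus an age-increasing
number of out-of-home activity contexts, roughly half kin relationships,
racial/linguistic category mixes tied to a synthetic neighborhood profile in
the urban stratum, and relationship-intensity measures (lab protocol only)
that are systematically higher for kin.

Everything is a pure function of ``(config, seed)``: two named substreams
(ego attributes, alter attributes) are spawned from one seed, so equal
seeds give byte-identical roster tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io import alter_frame, ego_frame
from .records import (
    AlterRecord,
    EgoRecord,
    MIXED_BIRACIAL,
    PROTOCOL_LAB,
    PROTOCOL_MUSEUM,
    SUBURBAN_RURAL,
    URBAN,
)

__all__ = ["GeneratorConfig", "default_config", "generate_cohort", "generate_records"]


class ConfigError(ValueError):
    """Infeasible generator configuration."""


_RACES = [
    "European/White-American",
    "African/Black-American",
    "Asian/Asian-American",
    "Hispanic/Latino-American",
    "Native American",
    "Other",
]

# Cohort-level probabilities of each (monoracial) ego race, matching a
# majority-White urban US sample.
_EGO_RACE_P = [0.62, 0.17, 0.08, 0.11, 0.005, 0.015]

_LANGS = ["Spanish", "Chinese", "Polish", "French", "Arabic"]
_LANG_P = [0.45, 0.2, 0.15, 0.1, 0.1]

# Neighborhood race mixes: the urban Dirichlet is diffuse (diverse zips),
# the suburban one concentrated on the majority category.
_URBAN_RACE_ALPHA = np.array([4.5, 2.2, 1.2, 1.6, 0.15, 0.35]) * 2.2
_SUBURBAN_RACE_ALPHA = np.array([0.80, 0.06, 0.04, 0.06, 0.01, 0.03]) * 60.0

_URBAN_LANG_ALPHA = np.array([6.0, 1.6, 0.7, 0.6, 0.4, 0.4]) * 2.5
_SUBURBAN_LANG_ALPHA = np.array([0.92, 0.03, 0.02, 0.01, 0.01, 0.01]) * 70.0
_NEIGH_LANGS = ["English"] + _LANGS

_EXTRA_CONTEXT_POOL = [
    "daycare",
    "school",
    "library storytime",
    "playgroup",
    "music class",
    "gym class",
    "church",
    "neighbors",
    "swim class",
    "art class",
]

_KIN_SEQUENCE = [
    ("mother", "parent"),
    ("father", "parent"),
    ("sister", "child"),
    ("grandmother", "grandparent"),
    ("grandfather", "grandparent"),
    ("brother", "child"),
    ("aunt", "adult"),
    ("uncle", "adult"),
    ("cousin", "child"),
    ("cousin", "child"),
    ("grandmother", "grandparent"),
    ("aunt", "adult"),
    ("uncle", "adult"),
    ("cousin", "child"),
]


@dataclass
class GeneratorConfig:
    """Synthetic-cohort parameters.

    Size parameters are calibrated toward a cohort mean network size of ~11
    (SD ~5, range 3-27) with a rank correlation with age of ~0.6; the kin
    count model targets a mean kin proportion of ~0.5 that falls with
    network size; the context model targets 1-7 components with a mean of
    ~2.5 rising with age.
    """

    n_egos: int = 280
    age_range_months: tuple[float, float] = (6.0, 60.0)

    # network size: truncated negative binomial, mean linear in age (and in
    # out-of-home childcare)
    size_intercept: float = 3.9
    size_age_slope: float = 0.20
    size_childcare_bump: float = 2.0
    size_dispersion: float = 22.0
    size_floor: int = 3
    size_ceiling: int = 40

    # kin count: floor + Poisson, weakly age-linked
    kin_count_base: int = 1
    kin_count_rate: float = 3.9
    kin_age_slope: float = 0.0

    # out-of-home contexts: 1 + Poisson(base + age_rate * age + size_rate * N);
    # the size term spreads big networks over more disjoint activities, which
    # is what drives their lower density
    extra_context_base: float = 0.05
    extra_context_age_rate: float = 0.008
    extra_context_size_rate: float = 0.070
    max_extra_contexts: int = 6

    # ego demographics
    urban_prob: float = 0.65
    biracial_prob: float = 0.19
    second_language_prob: float = 0.25
    childcare_base_prob: float = 0.05
    childcare_age_slope: float = 0.011
    museum_prob_over_36: float = 0.85

    # alter attributes
    kin_adult_prob: float = 0.85
    nonkin_adult_prob: float = 0.35
    kin_share_race_prob: float = 0.92

    # intensity model (lab protocol): kin relationships are closer, more
    # active, and occupy more waking hours
    kin_activity_mean: float = 5.0
    nonkin_activity_mean: float = 2.2
    kin_closeness_mean: float = 5.6
    nonkin_closeness_mean: float = 3.4
    closeness_sd: float = 1.0
    kin_hours_beta: tuple[float, float] = (2.2, 5.0)
    nonkin_hours_beta: tuple[float, float] = (1.3, 10.0)

    def validate(self) -> None:
        lo, hi = self.age_range_months
        if not (0 < lo < hi):
            raise ConfigError("age_range_months must be an increasing positive interval")
        if self.size_floor > self.size_ceiling:
            raise ConfigError("size_floor exceeds size_ceiling")
        if self.size_floor < 1 or self.n_egos < 1:
            raise ConfigError("n_egos and size_floor must be positive")
        if self.size_dispersion <= 0:
            raise ConfigError("size_dispersion must be positive")
        for name in ("urban_prob", "biracial_prob", "second_language_prob",
                     "museum_prob_over_36", "kin_adult_prob", "nonkin_adult_prob",
                     "kin_share_race_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB as gamma-Poisson mixture: variance = mean + mean^2 / dispersion
    lam = rng.gamma(shape=dispersion, scale=max(mean, 0.1) / dispersion)
    return int(rng.poisson(lam))


def _draw_category(rng: np.random.Generator, cats, probs) -> str:
    return cats[int(rng.choice(len(cats), p=np.asarray(probs) / np.sum(probs)))]


def _ego_races(rng: np.random.Generator, cfg: GeneratorConfig) -> frozenset[str]:
    first = _draw_category(rng, _RACES, _EGO_RACE_P)
    if rng.random() < cfg.biracial_prob:
        second = first
        while second == first:
            second = _draw_category(rng, _RACES, _EGO_RACE_P)
        return frozenset({first, second})
    return frozenset({first})


def _alter_race(rng: np.random.Generator, profile: np.ndarray) -> frozenset[str]:
    cat = _draw_category(rng, _RACES, profile)
    if rng.random() < 0.08:  # some alters are themselves biracial
        other = cat
        while other == cat:
            other = _draw_category(rng, _RACES, profile + 0.02)
        return frozenset({cat, other})
    return frozenset({cat})


def _alter_languages(
    rng: np.random.Generator, lang_profile: np.ndarray
) -> frozenset[str]:
    primary = _draw_category(rng, _NEIGH_LANGS, lang_profile)
    if primary == "English":
        if rng.random() < 0.12:
            return frozenset({"English", _draw_category(rng, _LANGS, _LANG_P)})
        return frozenset({"English"})
    if rng.random() < 0.75:
        return frozenset({"English", primary})
    return frozenset({primary})


def _make_ego(
    rng: np.random.Generator, cfg: GeneratorConfig, index: int
) -> tuple[EgoRecord, dict]:
    lo, hi = cfg.age_range_months
    age = round(float(rng.uniform(lo, hi)), 1)
    urban = rng.random() < cfg.urban_prob
    races = _ego_races(rng, cfg)
    languages = {"English"}
    if rng.random() < cfg.second_language_prob:
        languages.add(_draw_category(rng, _LANGS, _LANG_P))
    childcare = rng.random() < min(
        0.95, cfg.childcare_base_prob + cfg.childcare_age_slope * age
    )
    protocol = (
        PROTOCOL_MUSEUM
        if age >= 36.0 and rng.random() < cfg.museum_prob_over_36
        else PROTOCOL_LAB
    )
    race_alpha = _URBAN_RACE_ALPHA if urban else _SUBURBAN_RACE_ALPHA
    lang_alpha = _URBAN_LANG_ALPHA if urban else _SUBURBAN_LANG_ALPHA
    race_profile = rng.dirichlet(race_alpha)
    lang_profile = rng.dirichlet(lang_alpha)
    ego = EgoRecord(
        ego_id=f"ego{index:03d}",
        age_months=age,
        races=races,
        languages=frozenset(languages),
        childcare_out_of_home=childcare,
        urbanicity=URBAN if urban else SUBURBAN_RURAL,
        protocol=protocol,
        neighborhood_race_profile=dict(zip(_RACES, np.round(race_profile, 12))),
        neighborhood_language_profile=dict(zip(_NEIGH_LANGS, np.round(lang_profile, 12))),
    )
    aux = {"race_profile": race_profile, "lang_profile": lang_profile, "urban": urban}
    return ego, aux


def _kin_age(rng: np.random.Generator, role: str) -> float:
    if role == "parent":
        return round(float(rng.uniform(25, 42)), 1)
    if role == "grandparent":
        return round(float(rng.uniform(55, 78)), 1)
    if role == "adult":
        return round(float(rng.uniform(22, 55)), 1)
    return round(float(rng.uniform(0.5, 12.5)), 1)


def _intensity(
    rng: np.random.Generator, cfg: GeneratorConfig, kin: bool
) -> tuple[float, float, float]:
    acts = float(1 + rng.poisson(cfg.kin_activity_mean if kin else cfg.nonkin_activity_mean))
    clo = float(
        np.clip(
            rng.normal(
                cfg.kin_closeness_mean if kin else cfg.nonkin_closeness_mean,
                cfg.closeness_sd,
            ),
            1.0,
            7.0,
        )
    )
    a, b = cfg.kin_hours_beta if kin else cfg.nonkin_hours_beta
    hrs = float(np.clip(rng.beta(a, b), 0.0, 1.0))
    return acts, round(clo, 2), round(hrs, 4)


def _make_alters(
    rng: np.random.Generator, cfg: GeneratorConfig, ego: EgoRecord, aux: dict
) -> list[AlterRecord]:
    age = ego.age_months
    mean_size = (
        cfg.size_intercept
        + cfg.size_age_slope * age
        + (cfg.size_childcare_bump if ego.childcare_out_of_home else 0.0)
    )
    n = _neg_binomial(rng, mean_size, cfg.size_dispersion)
    n = int(np.clip(n, cfg.size_floor, cfg.size_ceiling))

    kin_mean = max(cfg.kin_count_rate + cfg.kin_age_slope * age, 0.0)
    n_kin = min(n, cfg.kin_count_base + int(rng.poisson(kin_mean)))
    n_kin = max(n_kin, 1)  # the family context is always present
    n_nonkin = n - n_kin

    lab = ego.protocol == PROTOCOL_LAB
    race_profile = aux["race_profile"] if aux["urban"] else _SUBURBAN_RACE_ALPHA
    lang_profile = aux["lang_profile"] if aux["urban"] else _SUBURBAN_LANG_ALPHA

    alters: list[AlterRecord] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"{ego.ego_id}_a{idx:02d}"

    # family component
    for k in range(n_kin):
        label, role = _KIN_SEQUENCE[k % len(_KIN_SEQUENCE)]
        a_age = _kin_age(rng, role)
        shares = rng.random() < cfg.kin_share_race_prob
        races = ego.races if shares else _alter_race(rng, race_profile)
        preverbal = a_age < 2.0
        langs = frozenset() if preverbal else ego.languages
        inten = _intensity(rng, cfg, kin=True) if lab else (None, None, None)
        alters.append(
            AlterRecord(
                ego_id=ego.ego_id,
                alter_id=next_id(),
                relationship=label,
                contexts=frozenset({"family"}),
                age_years=a_age,
                races=races,
                languages=langs or None,
                preverbal=preverbal,
                intensity_activities=inten[0],
                intensity_closeness=inten[1],
                intensity_hours=inten[2],
            )
        )

    if n_nonkin > 0:
        ctx_mean = (
            cfg.extra_context_base
            + cfg.extra_context_age_rate * age
            + cfg.extra_context_size_rate * n
        )
        n_ctx = 1 + int(rng.poisson(ctx_mean))
        n_ctx = int(min(n_ctx, n_nonkin, cfg.max_extra_contexts))
        pool = list(_EXTRA_CONTEXT_POOL)
        if ego.childcare_out_of_home:
            contexts = ["daycare"]
            pool.remove("daycare")
            contexts += list(rng.choice(pool, size=n_ctx - 1, replace=False))
        else:
            pool.remove("daycare")
            contexts = list(rng.choice(pool, size=n_ctx, replace=False))
        sizes = 1 + rng.multinomial(n_nonkin - n_ctx, np.full(n_ctx, 1.0 / n_ctx))

        for ctx, size in zip(contexts, sizes):
            group_here = ctx == "daycare" and bool(ego.childcare_out_of_home)
            for j in range(int(size)):
                if group_here and j == 0:
                    alters.append(
                        AlterRecord(
                            ego_id=ego.ego_id,
                            alter_id=next_id(),
                            relationship="daycare/preschool class",
                            contexts=frozenset({ctx}),
                            is_group=True,
                        )
                    )
                    continue
                teacher = ctx in ("daycare", "school") and j <= 1
                adult = teacher or rng.random() < cfg.nonkin_adult_prob
                a_age = (
                    round(float(rng.uniform(20, 60)), 1)
                    if adult
                    else round(float(rng.uniform(1.0, 12.5)), 1)
                )
                if teacher:
                    label = "teacher"
                elif ctx == "neighbors":
                    label = "neighbor"
                elif adult:
                    label = "family friend"
                else:
                    label = "friend"
                preverbal = a_age < 2.0
                langs = frozenset() if preverbal else _alter_languages(rng, lang_profile)
                inten = _intensity(rng, cfg, kin=False) if lab else (None, None, None)
                alters.append(
                    AlterRecord(
                        ego_id=ego.ego_id,
                        alter_id=next_id(),
                        relationship=label,
                        contexts=frozenset({ctx}),
                        age_years=a_age,
                        races=_alter_race(rng, race_profile),
                        languages=langs or None,
                        preverbal=preverbal,
                        intensity_activities=inten[0],
                        intensity_closeness=inten[1],
                        intensity_hours=inten[2],
                    )
                )
    return alters


def generate_records(
    config: Optional[GeneratorConfig] = None, seed: int = 0
) -> tuple[list[EgoRecord], list[AlterRecord]]:
    """Generate validated ego and alter records for one synthetic cohort."""
    cfg = config or default_config()
    cfg.validate()
    ego_seed, alter_seed = np.random.SeedSequence(seed).spawn(2)
    ego_rng = np.random.default_rng(ego_seed)
    alter_rng = np.random.default_rng(alter_seed)
    egos: list[EgoRecord] = []
    alters: list[AlterRecord] = []
    for i in range(cfg.n_egos):
        ego, aux = _make_ego(ego_rng, cfg, i)
        egos.append(ego)
        alters.extend(_make_alters(alter_rng, cfg, ego, aux))
    return egos, alters


def generate_cohort(
    config: Optional[GeneratorConfig] = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort as the (ego table, alter table) pair of
    roster frames, deterministic given ``(config, seed)``."""
    egos, alters = generate_records(config, seed)
    return ego_frame(egos), alter_frame(alters)
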