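"""Roster I/O: delimited ego/alter tables, network assembly, graph export.

The on-disk roster format is two delimited tables. The ego table has one
row per child; the alter table has one row per (ego, alter) pair.
Multi-valued cells (races, languages, contexts) use a configurable
separator, "|" by default. Neighborhood profiles are serialized inline as
"category:proportion" items joined by the same separator.

Validation is row-level: malformed cells raise :class:`RosterError` naming
the row and field; unknown race tokens list the controlled vocabulary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import (
    AlterRecord,
    EgoRecord,
    EgoNetwork,
    RosterError,
    VocabularyError,
    normalize_race,
)
from . import structure

__all__ = [
    "Dialect",
    "read_ego_table",
    "read_alter_table",
    "parse_ego_frame",
    "parse_alter_frame",
    "ego_frame",
    "alter_frame",
    "write_ego_table",
    "write_alter_table",
    "assemble_network",
    "export_graph",
    "read_edge_list",
]

logger = logging.getLogger("csnq.io")

EGO_COLUMNS = [
    "ego_id",
    "age_months",
    "races",
    "languages",
    "childcare_out_of_home",
    "urbanicity",
    "protocol",
    "neighborhood_race_profile",
    "neighborhood_language_profile",
]

ALTER_COLUMNS = [
    "ego_id",
    "alter_id",
    "relationship",
    "is_group",
    "age_years",
    "races",
    "languages",
    "preverbal",
    "contexts",
    "intensity_activities",
    "intensity_closeness",
    "intensity_hours",
]

_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


@dataclass(frozen=True)
class Dialect:
    """Table dialect: the cell delimiter, the separator for multi-valued
    cells, and the key:value separator inside profile cells."""

    delimiter: str = ","
    multi_value_sep: str = "|"
    profile_kv_sep: str = ":"


def _cell(row: Mapping[str, str], column: str) -> str:
    value = row.get(column)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def _parse_bool(text: str, where: str) -> Optional[bool]:
    if not text:
        return None
    low = text.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise RosterError(f"{where}: cannot parse boolean {text!r}")


def _parse_float(text: str, where: str) -> Optional[float]:
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise RosterError(f"{where}: cannot parse number {text!r}") from None


def _split_multi(text: str, dialect: Dialect) -> list[str]:
    if not text:
        return []
    return [t.strip() for t in text.split(dialect.multi_value_sep) if t.strip()]


def _parse_races(text: str, dialect: Dialect, where: str) -> Optional[frozenset[str]]:
    tokens = _split_multi(text, dialect)
    # tolerate ";" as a secondary separator inside a race multi-select cell
    if len(tokens) == 1 and ";" in tokens[0]:
        tokens = [t.strip() for t in tokens[0].split(";") if t.strip()]
    if not tokens:
        return None
    try:
        return frozenset(normalize_race(t) for t in tokens)
    except VocabularyError as err:
        raise VocabularyError(f"{where}: {err}") from None


def _parse_languages(text: str, dialect: Dialect) -> Optional[frozenset[str]]:
    tokens = _split_multi(text, dialect)
    if not tokens:
        return None
    return frozenset(t.title() for t in tokens)


def _parse_profile(
    text: str, dialect: Dialect, where: str
) -> Optional[dict[str, float]]:
    items = _split_multi(text, dialect)
    if not items:
        return None
    profile: dict[str, float] = {}
    for item in items:
        if dialect.profile_kv_sep not in item:
            raise RosterError(f"{where}: malformed profile item {item!r}")
        cat, _, val = item.rpartition(dialect.profile_kv_sep)
        profile[cat.strip()] = _parse_float(val.strip(), where)
    return profile


def parse_ego_frame(df: pd.DataFrame, dialect: Dialect | None = None) -> list[EgoRecord]:
    """Validate a raw ego table into records (row numbers count from 1)."""
    dialect = dialect or Dialect()
    if "ego_id" not in df.columns or "age_months" not in df.columns:
        raise RosterError("ego table must have at least ego_id and age_months columns")
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        where = f"ego table row {i}"
        ego_id = _cell(row, "ego_id")
        if not ego_id:
            raise RosterError(f"{where}: field 'ego_id': empty")
        try:
            races = _parse_races(_cell(row, "races"), dialect, where)
            if races is None:
                raise RosterError(f"{where}: field 'races': empty")
            records.append(
                EgoRecord(
                    ego_id=ego_id,
                    age_months=_parse_float(_cell(row, "age_months"), where),
                    races=races,
                    languages=_parse_languages(_cell(row, "languages"), dialect)
                    or frozenset(),
                    childcare_out_of_home=_parse_bool(
                        _cell(row, "childcare_out_of_home"), where
                    ),
                    urbanicity=_cell(row, "urbanicity") or None,
                    protocol=_cell(row, "protocol") or None,
                    neighborhood_race_profile=_parse_profile(
                        _cell(row, "neighborhood_race_profile"), dialect, where
                    ),
                    neighborhood_language_profile=_parse_profile(
                        _cell(row, "neighborhood_language_profile"), dialect, where
                    ),
                )
            )
        except (RosterError, VocabularyError, TypeError) as err:
            if str(err).startswith(("ego table row", f"ego {ego_id}")):
                raise
            raise RosterError(f"{where}: {err}") from None
    ids = [r.ego_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise RosterError(f"duplicate ego_id values: {dupes}")
    return records


def parse_alter_frame(
    df: pd.DataFrame, dialect: Dialect | None = None
) -> list[AlterRecord]:
    """Validate a raw alter table into records (row numbers count from 1)."""
    dialect = dialect or Dialect()
    for col in ("ego_id", "alter_id"):
        if col not in df.columns:
            raise RosterError(f"alter table must have an {col!r} column")
    records = []
    seen: set[tuple[str, str]] = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        where = f"alter table row {i}"
        key = (_cell(row, "ego_id"), _cell(row, "alter_id"))
        if key in seen:
            raise RosterError(f"{where}: duplicate (ego_id, alter_id) pair {key}")
        seen.add(key)
        try:
            records.append(
                AlterRecord(
                    ego_id=key[0],
                    alter_id=key[1],
                    relationship=_cell(row, "relationship"),
                    contexts=frozenset(_split_multi(_cell(row, "contexts"), dialect)),
                    is_group=_parse_bool(_cell(row, "is_group"), where) or False,
                    age_years=_parse_float(_cell(row, "age_years"), where),
                    races=_parse_races(_cell(row, "races"), dialect, where),
                    languages=_parse_languages(_cell(row, "languages"), dialect),
                    preverbal=_parse_bool(_cell(row, "preverbal"), where) or False,
                    intensity_activities=_parse_float(
                        _cell(row, "intensity_activities"), where
                    ),
                    intensity_closeness=_parse_float(
                        _cell(row, "intensity_closeness"), where
                    ),
                    intensity_hours=_parse_float(_cell(row, "intensity_hours"), where),
                )
            )
        except (RosterError, VocabularyError) as err:
            if str(err).startswith(("alter table row", "alter ")):
                raise
            raise RosterError(f"{where}: {err}") from None
    return records


def _read_table(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(
            path, sep=dialect.delimiter, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty roster table: %s", path)
        return pd.DataFrame()


def read_ego_table(path: str | Path, dialect: Dialect | None = None) -> list[EgoRecord]:
    """Read and validate an ego table; an empty file yields an empty list."""
    dialect = dialect or Dialect()
    df = _read_table(path, dialect)
    if df.empty and not len(df.columns):
        return []
    return parse_ego_frame(df, dialect)


def read_alter_table(
    path: str | Path, dialect: Dialect | None = None
) -> list[AlterRecord]:
    """Read and validate an alter table; an empty file yields an empty list."""
    dialect = dialect or Dialect()
    df = _read_table(path, dialect)
    if df.empty and not len(df.columns):
        return []
    return parse_alter_frame(df, dialect)


def _fmt_multi(values, dialect: Dialect) -> str:
    return dialect.multi_value_sep.join(sorted(values))


def _fmt_profile(profile: Optional[Mapping[str, float]], dialect: Dialect) -> str:
    if profile is None:
        return ""
    return dialect.multi_value_sep.join(
        f"{cat}{dialect.profile_kv_sep}{profile[cat]:.12g}" for cat in sorted(profile)
    )


def _fmt_opt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def ego_frame(records: Sequence[EgoRecord], dialect: Dialect | None = None) -> pd.DataFrame:
    dialect = dialect or Dialect()
    rows = [
        {
            "ego_id": r.ego_id,
            "age_months": _fmt_opt(float(r.age_months)),
            "races": _fmt_multi(r.races, dialect),
            "languages": _fmt_multi(r.languages, dialect),
            "childcare_out_of_home": _fmt_opt(r.childcare_out_of_home),
            "urbanicity": _fmt_opt(r.urbanicity),
            "protocol": _fmt_opt(r.protocol),
            "neighborhood_race_profile": _fmt_profile(
                r.neighborhood_race_profile, dialect
            ),
            "neighborhood_language_profile": _fmt_profile(
                r.neighborhood_language_profile, dialect
            ),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=EGO_COLUMNS)


def alter_frame(
    records: Sequence[AlterRecord], dialect: Dialect | None = None
) -> pd.DataFrame:
    dialect = dialect or Dialect()
    rows = [
        {
            "ego_id": r.ego_id,
            "alter_id": r.alter_id,
            "relationship": r.relationship,
            "is_group": _fmt_opt(bool(r.is_group)),
            "age_years": _fmt_opt(r.age_years),
            "races": _fmt_multi(r.races, dialect) if r.races else "",
            "languages": _fmt_multi(r.languages, dialect) if r.languages else "",
            "preverbal": _fmt_opt(bool(r.preverbal)),
            "contexts": _fmt_multi(r.contexts, dialect),
            "intensity_activities": _fmt_opt(r.intensity_activities),
            "intensity_closeness": _fmt_opt(r.intensity_closeness),
            "intensity_hours": _fmt_opt(r.intensity_hours),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ALTER_COLUMNS)


def write_ego_table(
    records: Sequence[EgoRecord], path: str | Path, dialect: Dialect | None = None
) -> None:
    dialect = dialect or Dialect()
    ego_frame(records, dialect).to_csv(
        path, sep=dialect.delimiter, index=False, quoting=csv.QUOTE_MINIMAL
    )


def write_alter_table(
    records: Sequence[AlterRecord], path: str | Path, dialect: Dialect | None = None
) -> None:
    dialect = dialect or Dialect()
    alter_frame(records, dialect).to_csv(
        path, sep=dialect.delimiter, index=False, quoting=csv.QUOTE_MINIMAL
    )


def assemble_network(ego: EgoRecord, alters: Sequence[AlterRecord]) -> EgoNetwork:
    """Build an :class:`EgoNetwork`: infer ties from shared contexts and
    partition the alters into connected components.

    An empty alter list is invalid input — every surveyed child interacts
    with at least their family.
    """
    if not alters:
        raise RosterError(f"ego {ego.ego_id}: network has no alters")
    for a in alters:
        if a.ego_id != ego.ego_id:
            raise RosterError(
                f"alter {a.alter_id} belongs to ego {a.ego_id}, not {ego.ego_id}"
            )
    ties = structure.infer_ties(alters)
    components = structure.find_components(alters, ties)
    return EgoNetwork(ego=ego, alters=list(alters), ties=ties.pairs, components=components)


def _as_nx(net: EgoNetwork):
    import networkx as nx

    graph = nx.Graph()
    graph.add_node(net.ego.ego_id, role="ego")
    for a in net.alters:
        graph.add_node(a.alter_id, role="group" if a.is_group else "alter")
        graph.add_edge(net.ego.ego_id, a.alter_id, kind="spoke")
    for a, b in sorted(net.ties):
        graph.add_edge(a, b, kind="tie")
    return graph


def export_graph(net: EgoNetwork, path: str | Path, fmt: str = "edgelist") -> None:
    """Export the star-plus-ties graph: one node for the ego and each alter,
    spokes from ego to every alter, plus the inferred alter-alter ties.

    Formats: "edgelist" (tab-separated ``u v`` lines) or "graphml".
    """
    path = Path(path)
    graph = _as_nx(net)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in sorted(
                (tuple(sorted(e)) for e in graph.edges()), key=lambda e: (e[0], e[1])
            ):
                fh.write(f"{u}\t{v}\n")
    elif fmt == "graphml":
        import networkx as nx

        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; use 'edgelist' or 'graphml'")


def read_edge_list(path: str | Path, ego_id: str) -> frozenset[tuple[str, str]]:
    """Read an exported edge list back into the alter-alter tie set
    (edges touching ``ego_id`` are the ego spokes and are dropped)."""
    ties = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 2:
                continue
            u, v = parts
            if ego_id in (u, v):
                continue
            ties.add((u, v) if u < v else (v, u))
    return frozenset(ties)
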