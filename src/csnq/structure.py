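"""Structural metrics of an ego network: ties, density, components.

Alter-alter ties are not surveyed pairwise (that would make a parent
interview prohibitively long); they are inferred from shared interaction
contexts: two alters are tied iff at least one context contains both. Every
component of the resulting alter graph is therefore a union of overlapping
contexts — the family, plus each out-of-home activity the child attends.

Density is 2T / (N(N-1)) for T ties among N alters; the component ratio
(C-1)/(N-1) is a size-normalized fragmentation measure, 0 for a single
component and 1 when every alter is isolated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .records import AlterRecord

__all__ = ["TieSet", "infer_ties", "density", "find_components", "component_ratio"]


@dataclass(frozen=True)
class TieSet:
    """Unordered alter-alter pairs; the ego never appears."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")

    @property
    def n_ties(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return tuple(sorted((a, b))) in self.pairs


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def infer_ties(alters: Sequence[AlterRecord]) -> TieSet:
    """Tie (a, b) iff a and b share at least one context.

    Group nodes participate through their contexts (a class group node is
    tied to the named friends from that class).
    """
    pairs = {
        _pair(a.alter_id, b.alter_id)
        for a, b in itertools.combinations(alters, 2)
        if a.contexts & b.contexts
    }
    return TieSet(frozenset(pairs))


def density(n_ties: int, n_alters: int) -> Optional[float]:
    """Fraction of possible alter-alter ties present: 2T / (N(N-1)).

    1 means every pair of alters knows each other. Undefined (None) for
    fewer than two alters.
    """
    if n_alters < 2:
        return None
    possible = n_alters * (n_alters - 1) // 2
    if n_ties < 0 or n_ties > possible:
        raise ValueError(f"{n_ties} ties impossible for {n_alters} alters")
    return 2.0 * n_ties / (n_alters * (n_alters - 1))


def find_components(
    alters: Sequence[AlterRecord] | Iterable[str], ties: TieSet
) -> list[frozenset[str]]:
    """Connected components of the alter-alter tie graph, ego removed.

    Isolated alters each form their own component, so C >= 1 whenever the
    network is nonempty. Components are returned sorted by their smallest
    member id for deterministic output.
    """
    graph = nx.Graph()
    for a in alters:
        graph.add_node(a.alter_id if isinstance(a, AlterRecord) else a)
    graph.add_edges_from(ties.pairs)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=min)


def component_ratio(n_components: int, n_alters: int) -> Optional[float]:
    """(C - 1) / (N - 1); larger values mean a more fragmented network.

    Undefined (None) for a single-alter network.
    """
    if not 1 <= n_components <= max(n_alters, 1):
        raise ValueError(f"invalid component count {n_components} for N={n_alters}")
    if n_alters < 2:
        return None
    return (n_components - 1) / (n_alters - 1)
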