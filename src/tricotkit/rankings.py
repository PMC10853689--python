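"""Convert best/worst triadic responses into (partial) rankings.

A complete response (best and worst both reported) yields the full strict
order of the three options. A response with only a best yields
``best > {other two}``; only a worst yields ``{other two} > worst``. Empty
responses are dropped (and counted). Rankings are stored over option labels;
the blind A/B/C positions exist only at the response layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .design import TrialDesign

__all__ = [
    "TricotResponse",
    "Ranking",
    "RankingSet",
    "ResponseError",
    "response_to_ranking",
    "build_ranking_set",
    "win_graph_connectivity",
    "ConnectivityReport",
]

_POSITIONS = ("A", "B", "C")


class ResponseError(ValueError):
    """Raised for contradictory or unresolvable responses."""


@dataclass(frozen=True)
class TricotResponse:
    package_id: int
    trait: str
    best: str | None = None
    worst: str | None = None

    def __post_init__(self) -> None:
        for val, label in ((self.best, "best"), (self.worst, "worst")):
            if val is not None and val not in _POSITIONS:
                raise ResponseError(
                    f"package {self.package_id}: {label} position {val!r} "
                    f"not one of {_POSITIONS}"
                )
        if self.best is not None and self.best == self.worst:
            raise ResponseError(
                f"package {self.package_id}: best and worst are both {self.best!r}"
            )


@dataclass(frozen=True)
class Ranking:
    """Ordered groups of options, most to least preferred; ties within a group."""

    groups: tuple[tuple[str, ...], ...]
    package_id: int
    trait: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", tuple(tuple(g) for g in self.groups)
        )
        flat = [o for g in self.groups for o in g]
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("ranking groups must be non-empty")
        if len(set(flat)) != len(flat):
            raise ValueError("ranking groups must be disjoint")
        if len(flat) < 2:
            raise ValueError("ranking must involve at least 2 options")

    @property
    def options(self) -> tuple[str, ...]:
        return tuple(o for g in self.groups for o in g)

    def is_strict(self) -> bool:
        return all(len(g) == 1 for g in self.groups)


@dataclass(frozen=True)
class RankingSet:
    universe: tuple[str, ...]
    rankings: tuple[Ranking, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", tuple(self.universe))
        object.__setattr__(self, "rankings", tuple(self.rankings))
        universe = set(self.universe)
        for r in self.rankings:
            stray = set(r.options) - universe
            if stray:
                raise ValueError(
                    f"ranking for package {r.package_id} uses options outside "
                    f"the universe: {sorted(stray)}"
                )

    def __len__(self) -> int:
        return len(self.rankings)


def response_to_ranking(
    response: TricotResponse, design: TrialDesign
) -> Ranking | None:
    """Resolve A/B/C answers to option labels and build the implied ranking.

    Returns None when neither best nor worst was reported.
    """
    pkg = design.package(response.package_id)
    if response.best is None and response.worst is None:
        return None
    options = {pos: pkg.option_at(pos) for pos in _POSITIONS}
    if response.best is not None and response.worst is not None:
        middle = next(
            p for p in _POSITIONS if p not in (response.best, response.worst)
        )
        groups = (
            (options[response.best],),
            (options[middle],),
            (options[response.worst],),
        )
    elif response.best is not None:
        rest = tuple(options[p] for p in _POSITIONS if p != response.best)
        groups = ((options[response.best],), rest)
    else:
        rest = tuple(options[p] for p in _POSITIONS if p != response.worst)
        groups = (rest, (options[response.worst],))
    return Ranking(groups=groups, package_id=response.package_id, trait=response.trait)


def build_ranking_set(
    responses: list[TricotResponse], design: TrialDesign, trait: str
) -> RankingSet:
    """Filter responses to one trait and convert them, counting drops.

    Every input row for the trait is either converted or counted in
    ``n_dropped`` (empty responses); rows for other traits are ignored.
    """
    rankings = []
    dropped = 0
    for resp in responses:
        if resp.trait != trait:
            continue
        ranking = response_to_ranking(resp, design)
        if ranking is None:
            dropped += 1
        else:
            rankings.append(ranking)
    return RankingSet(
        universe=design.option_names, rankings=tuple(rankings), n_dropped=dropped
    )


@dataclass(frozen=True)
class ConnectivityReport:
    strongly_connected: bool
    components: tuple[frozenset[str], ...]


def win_graph_connectivity(rankings: RankingSet) -> ConnectivityReport:
    """Estimability check: is the directed "beats" graph strongly connected?

    An edge i -> j exists when i was ranked strictly above j in some ranking.
    The maximum-likelihood worths are finite and unique (up to scaling) only
    when this graph is strongly connected over the universe.
    """
    g = nx.DiGraph()
    g.add_nodes_from(rankings.universe)
    for r in rankings.rankings:
        for gi in range(len(r.groups)):
            for gj in range(gi + 1, len(r.groups)):
                for winner in r.groups[gi]:
                    for loser in r.groups[gj]:
                        g.add_edge(winner, loser)
    components = tuple(
        frozenset(c) for c in nx.strongly_connected_components(g)
    )
    return ConnectivityReport(
        strongly_connected=len(components) == 1, components=components
    )
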