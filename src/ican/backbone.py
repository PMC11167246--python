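"""Carbon-chain indexing and per-carbon neighborhood directories.

The encoding's column order is defined by a deterministic walk of the
carbon-induced subgraph: depth-first from the carbon with the smallest
atom ordinal, branches taken in ascending ordinal order and each followed
to exhaustion, ring closures opened (a carbon reached again through a
cycle is not revisited). Neighborhoods are then read off the *full* atom
graph, hydrogens included: the level-n neighborhood of a carbon is the
multiset of elements at shortest-path distance exactly n.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .chem_io import MolGraph

__all__ = ["CarbonIndexing", "NeighborDirectory", "index_carbons", "build_neighbor_directory"]


@dataclass(frozen=True)
class CarbonIndexing:
    """Backbone carbons in traversal order; position i is the i-th column carbon."""

    order: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order)

    def __getitem__(self, i: int) -> int:
        return self.order[i]


@dataclass
class NeighborDirectory:
    """carbon ordinal -> level (1..max_level) -> element multiset at that distance."""

    levels: dict[int, dict[int, Counter]]
    max_level: int

    def counts(self, carbon: int, level: int) -> Counter:
        return self.levels[carbon].get(level, Counter())

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize for inspection; counters become plain dicts."""
        payload = {
            str(c): {str(l): dict(cnt) for l, cnt in by_level.items()}
            for c, by_level in self.levels.items()
        }
        text = json.dumps({"max_level": self.max_level, "neighborhoods": payload}, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def index_carbons(graph: MolGraph) -> CarbonIndexing:
    """Assign a deterministic backbone index to every carbon atom.

    Depth-first preorder over the carbon-induced subgraph: start at the
    smallest carbon ordinal, explore unvisited carbon neighbors in
    ascending ordinal order, follow each branch to exhaustion, never
    revisit a carbon (cycles are opened into a linear walk). Additional
    connected components are walked the same way in ascending order of
    their smallest carbon ordinal.
    """
    carbons = graph.carbons()
    if not carbons:
        raise ValueError("molecule has no carbon atoms")
    carbon_set = set(carbons)

    visited: set[int] = set()
    order: list[int] = []

    def walk(start: int) -> None:
        # iterative preorder DFS; push neighbors in descending ordinal so the
        # smallest is explored (to exhaustion) first
        stack = [start]
        while stack:
            node = stack.pop()
            if node in visited:
                continue
            visited.add(node)
            order.append(node)
            nbrs = sorted(
                (n for n in graph.graph.neighbors(node) if n in carbon_set and n not in visited),
                reverse=True,
            )
            stack.extend(nbrs)

    for c in carbons:  # ascending ordinal, so each new component starts minimal
        if c not in visited:
            walk(c)
    return CarbonIndexing(tuple(order))


def build_neighbor_directory(
    graph: MolGraph, indexing: CarbonIndexing, max_level: int
) -> NeighborDirectory:
    """Collect element multisets at exact shortest-path distances 1..max_level.

    Distances are breadth-first over the full atom graph (hydrogens are
    nodes); every atom appears at exactly one level — its distance — and
    the source carbon itself at none.
    """
    if max_level < 1:
        raise ValueError(f"max_level must be >= 1, got {max_level}")
    levels: dict[int, dict[int, Counter]] = {}
    for carbon in indexing:
        dist = nx.single_source_shortest_path_length(graph.graph, carbon, cutoff=max_level)
        by_level: dict[int, Counter] = {l: Counter() for l in range(1, max_level + 1)}
        for node, d in dist.items():
            if d == 0:
                continue
            by_level[d][graph.element(node)] += 1
        levels[carbon] = by_level
    return NeighborDirectory(levels=levels, max_level=max_level)
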