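"""Deterministic synthetic molecular-graph generators.

These produce connected, simple, carbon-only (by default) graphs — bare
topological skeletons rather than valence-correct molecules, which is all
the topological descriptor families read. Identical recipe and seed give an
identical graph on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import AtomRecord, MolecularGraph

__all__ = ["GraphRecipe", "generate"]

KINDS = (
    "path",
    "cycle",
    "random_tree",
    "random_connected",
    "ring_with_tail",
    "two_rings_bridged",
)


@dataclass(frozen=True)
class GraphRecipe:
    """What to generate: a structural kind, atom count, seed and elements."""

    kind: str
    n: int
    seed: int = 0
    element_palette: tuple[str, ...] = ("C",)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown recipe kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _edges_path(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(n - 1)]


def _edges_cycle(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if n < 3:
        raise ValueError("a cycle needs at least 3 atoms")
    return [(i, (i + 1) % n) for i in range(n)]


def _edges_random_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    # random attachment: vertex i joins a uniformly chosen earlier vertex
    return [(int(rng.integers(0, i)), i) for i in range(1, n)]


def _edges_random_connected(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random sparse connected graph: a random tree plus ~n/3 extra edges."""
    edges = _edges_random_tree(n, rng)
    present = {frozenset(e) for e in edges}
    extra = int(rng.integers(0, max(1, n // 3) + 1))
    attempts = 0
    while extra > 0 and attempts < 20 * n:
        attempts += 1
        u, v = int(rng.integers(0, n)), int(rng.integers(0, n))
        if u == v or frozenset((u, v)) in present:
            continue
        present.add(frozenset((u, v)))
        edges.append((u, v))
        extra -= 1
    return edges


def _edges_ring_with_tail(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if n < 4:
        raise ValueError("ring_with_tail needs at least 4 atoms")
    ring = max(3, (n + 1) // 2)
    edges = [(i, (i + 1) % ring) for i in range(ring)]
    for i in range(ring, n):
        edges.append((i - 1 if i > ring else 0, i))
    return edges


def _edges_two_rings_bridged(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if n < 7:
        raise ValueError("two_rings_bridged needs at least 7 atoms")
    r1 = 3
    r2 = 3
    bridge = n - r1 - r2
    edges = [(i, (i + 1) % r1) for i in range(r1)]
    # bridge path from atom 0 to the second ring
    prev = 0
    for b in range(bridge):
        edges.append((prev, r1 + b))
        prev = r1 + b
    start = r1 + bridge
    ring2 = list(range(start, start + r2))
    for k in range(r2):
        edges.append((ring2[k], ring2[(k + 1) % r2]))
    edges.append((prev, ring2[0]))
    # drop the duplicate closure when the bridge is empty
    seen: set[frozenset[int]] = set()
    unique = []
    for e in edges:
        key = frozenset(e)
        if key not in seen:
            seen.add(key)
            unique.append(e)
    return unique


_BUILDERS = {
    "path": _edges_path,
    "cycle": _edges_cycle,
    "random_tree": _edges_random_tree,
    "random_connected": _edges_random_connected,
    "ring_with_tail": _edges_ring_with_tail,
    "two_rings_bridged": _edges_two_rings_bridged,
}


def generate(recipe: GraphRecipe) -> MolecularGraph:
    """Build the deterministic connected graph described by ``recipe``."""
    rng = np.random.default_rng(recipe.seed)
    edges = _BUILDERS[recipe.kind](recipe.n, rng) if recipe.n > 1 else []
    palette = recipe.element_palette
    if len(palette) == 1:
        symbols = [palette[0]] * recipe.n
    else:
        symbols = [palette[int(rng.integers(0, len(palette)))] for _ in range(recipe.n)]
    atoms = tuple(AtomRecord.from_symbol(s) for s in symbols)
    bonds = tuple((u, v, 1.0) for u, v in edges)
    name = f"{recipe.kind}-{recipe.n}-s{recipe.seed}"
    return MolecularGraph(atoms=atoms, bonds=bonds, name=name)
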