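"""Independent brute-force oracles.

Ground truth for the optimised algorithms, kept deliberately naive and
sharing no code with the modules they validate: longest paths by exhaustive
enumeration of every simple path, subgraph classes by exhaustive edge-subset
enumeration with union-find connectivity, and simple-path listings by plain
recursion. All refuse inputs large enough for the exponential cost to bite.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .graph import MolecularGraph

__all__ = ["oracle_longest_paths", "oracle_subgraphs", "oracle_simple_paths"]

_MAX_N_PATHS = 14
_MAX_N_SUBGRAPHS = 10


def _adjacency(mol: MolecularGraph) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for i, j, _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def oracle_longest_paths(mol: MolecularGraph) -> np.ndarray:
    """Longest simple-path edge count between every atom pair, by exhaustive
    recursion over all simple paths. Refuses graphs with more than
    14 atoms."""
    n = mol.n_atoms
    if n > _MAX_N_PATHS:
        raise ValueError(f"oracle limited to {_MAX_N_PATHS} atoms, got {n}")
    adj = _adjacency(mol)
    out = np.zeros((n, n), dtype=int)

    def walk(start: int, node: int, length: int, visited: list[bool]) -> None:
        for nb in adj[node]:
            if visited[nb]:
                continue
            if length + 1 > out[start, nb]:
                out[start, nb] = length + 1
            visited[nb] = True
            walk(start, nb, length + 1, visited)
            visited[nb] = False

    for s in range(n):
        visited = [False] * n
        visited[s] = True
        walk(s, s, 0, visited)
    return np.maximum(out, out.T)


def _union_find_connected(edge_subset: Sequence[tuple[int, int]]) -> bool:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edge_subset:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    roots = {find(x) for x in parent}
    return len(roots) == 1


def _longest_path_in_subset(edge_subset: Sequence[tuple[int, int]]) -> int:
    adj: dict[int, list[int]] = {}
    for u, v in edge_subset:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    best = 0

    def walk(node: int, length: int, visited: set[int]) -> None:
        nonlocal best
        best = max(best, length)
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                walk(nb, length + 1, visited)
                visited.discard(nb)

    for start in adj:
        walk(start, 0, {start})
    return best


def oracle_subgraphs(mol: MolecularGraph, kind: str, order: int) -> list[frozenset[int]]:
    """All connected subgraphs of a Kier--Hall class and order, as atom sets,
    by exhaustive enumeration of edge subsets. Refuses graphs with more than
    10 atoms.

    Classes: ``path`` (no branching), ``chain`` (exactly one cycle),
    ``cluster`` (branched, no three-edge path — a star), ``path_cluster``
    (branched with a three-edge path).
    """
    if mol.n_atoms > _MAX_N_SUBGRAPHS:
        raise ValueError(f"oracle limited to {_MAX_N_SUBGRAPHS} atoms")
    if order == 0:
        if kind != "path":
            return []
        return [frozenset({v}) for v in range(mol.n_atoms)]
    edges = [(i, j) for i, j, _ in mol.bonds]
    out: list[frozenset[int]] = []
    for subset in combinations(edges, order):
        if not _union_find_connected(subset):
            continue
        verts = {v for e in subset for v in e}
        degrees: dict[int, int] = {v: 0 for v in verts}
        for u, v in subset:
            degrees[u] += 1
            degrees[v] += 1
        mu = order - len(verts) + 1
        if mu >= 2:
            continue
        if mu == 1:
            cls = "chain"
        elif max(degrees.values()) <= 2:
            cls = "path"
        elif _longest_path_in_subset(subset) <= 2:
            cls = "cluster"
        else:
            cls = "path_cluster"
        if cls == kind:
            out.append(frozenset(verts))
    return out


def oracle_simple_paths(mol: MolecularGraph) -> list[tuple[int, ...]]:
    """Every simple path with at least one edge, exactly once up to
    direction reversal (reported from the lower-numbered endpoint). Refuses
    graphs with more than 10 atoms."""
    n = mol.n_atoms
    if n > _MAX_N_SUBGRAPHS:
        raise ValueError(f"oracle limited to {_MAX_N_SUBGRAPHS} atoms")
    adj = _adjacency(mol)
    out: list[tuple[int, ...]] = []

    def walk(path: list[int], visited: set[int]) -> None:
        node = path[-1]
        for nb in adj[node]:
            if nb in visited:
                continue
            path.append(nb)
            visited.add(nb)
            if path[0] < path[-1]:
                out.append(tuple(path))
            walk(path, visited)
            visited.discard(nb)
            path.pop()

    for start in range(n):
        walk([start], {start})
    return out
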