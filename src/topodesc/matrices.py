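"""Adjacency, topological-distance and detour matrices with spectral aggregates.

The detour matrix (longest simple-path length between every atom pair) is
NP-hard in general, but molecular graphs are sparse and rich in articulation
points. The algorithm here exploits that: the graph is decomposed into
biconnected blocks, the longest path is found exhaustively inside each block
(blocks are small), and entries between blocks are obtained by summing the
block-internal longest paths along the unique chain of articulation points
joining the two atoms in the block-cut tree.

All three matrix kinds share a 13-aggregate spectral suite; the log-sum-exp
of the eigenvalue spectrum (``LogEE``) is evaluated with the shifted LSE
trick ``x* + log(sum(exp(x_i - x*)))`` so it stays finite for eigenvalues far
beyond the naive form's overflow point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import DisconnectedGraphError, EmptyGraphError, MolecularGraph

__all__ = [
    "SquareMatrixBundle",
    "BlockDecomposition",
    "adjacency_matrix",
    "distance_matrix",
    "detour_matrix",
    "articulation_decompose",
    "lse",
    "spectral_aggregates",
    "AGGREGATE_NAMES",
]

AGGREGATE_NAMES = (
    "SpAbs", "SpMax", "SpDiam", "SpAD", "SpMAD", "LogEE",
    "SM1", "VE1", "VE2", "VE3", "VR1", "VR2", "VR3",
)


@dataclass(frozen=True)
class SquareMatrixBundle:
    """A symmetric zero-diagonal atom-pair matrix plus its spectral data.

    ``edges`` carries the molecular graph's heavy-atom edge list; it is
    needed by the Randic-style VR aggregates, which sum over bonds.
    """

    matrix: np.ndarray
    kind: str
    edges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if m.size and not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if m.size and not np.all(np.diag(m) == 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @cached_property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda_1 >= ... >= lambda_n)."""
        return np.linalg.eigh(self.matrix)[0][::-1].copy()

    @cached_property
    def leading_eigenvector(self) -> np.ndarray:
        """Absolute components of an eigenvector for lambda_1.

        Component signs are discarded: only |c_i| enters any descriptor, so
        values are invariant to the eigensolver's sign convention. When the
        top eigenvalue is degenerate the choice of vector within the
        eigenspace is solver-dependent; ``top_eigenvalue_degenerate`` flags
        that case.
        """
        w, v = np.linalg.eigh(self.matrix)
        return np.abs(v[:, -1])

    @cached_property
    def top_eigenvalue_degenerate(self) -> bool:
        w = self.eigenvalues
        return len(w) > 1 and math.isclose(w[0], w[1], rel_tol=1e-9, abs_tol=1e-9)


@dataclass(frozen=True)
class BlockDecomposition:
    """Biconnected decomposition: blocks, cut vertices and their tree.

    ``block_cut_tree`` has nodes ``("block", index)`` and ``("cut", atom)``,
    with an edge whenever the articulation point belongs to the block. Every
    edge of the molecule lies in exactly one block.
    """

    articulation_points: frozenset[int]
    blocks: tuple[frozenset[int], ...]
    block_cut_tree: nx.Graph = field(hash=False, compare=False)


def _require_connected(mol: MolecularGraph) -> None:
    if mol.n_atoms == 0:
        raise EmptyGraphError("no atoms")
    if not mol.is_connected:
        raise DisconnectedGraphError("graph has multiple fragments")


def adjacency_matrix(mol: MolecularGraph) -> SquareMatrixBundle:
    """0/1 heavy-atom adjacency matrix (bond orders are ignored)."""
    n = mol.n_atoms
    m = np.zeros((n, n))
    for i, j, _ in mol.bonds:
        m[i, j] = m[j, i] = 1.0
    return SquareMatrixBundle(matrix=m, kind="adjacency", edges=mol.edge_list())


def distance_matrix(mol: MolecularGraph) -> SquareMatrixBundle:
    """Topological distance matrix: shortest-path edge counts (BFS)."""
    _require_connected(mol)
    n = mol.n_atoms
    rows, cols = [], []
    for i, j, _ in mol.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    d = shortest_path(adj, method="D", unweighted=True)
    return SquareMatrixBundle(matrix=d, kind="distance", edges=mol.edge_list())


def articulation_decompose(mol: MolecularGraph) -> BlockDecomposition:
    """Standard biconnected decomposition via low-link depth-first search."""
    _require_connected(mol)
    g = mol.to_networkx()
    cuts = frozenset(nx.articulation_points(g))
    blocks: list[frozenset[int]] = []
    for comp_edges in nx.biconnected_component_edges(g):
        verts: set[int] = set()
        for u, v in comp_edges:
            verts.add(u)
            verts.add(v)
        blocks.append(frozenset(verts))
    if not blocks and mol.n_atoms == 1:
        blocks = [frozenset({0})]
    tree = nx.Graph()
    for b_idx, verts in enumerate(blocks):
        tree.add_node(("block", b_idx))
        for v in verts & cuts:
            tree.add_edge(("block", b_idx), ("cut", v))
    return BlockDecomposition(
        articulation_points=cuts,
        blocks=tuple(blocks),
        block_cut_tree=tree,
    )


def _block_longest_paths(adj: Sequence[set[int]], vertices: frozenset[int]) -> dict[tuple[int, int], int]:
    """All-pairs longest simple path inside one biconnected block.

    Exhaustive depth-first search restricted to the block's vertex set;
    feasible because blocks of molecular graphs are small.
    """
    verts = sorted(vertices)
    best: dict[tuple[int, int], int] = {}
    if len(verts) == 1:
        return best

    local_adj = {v: adj[v] & vertices for v in verts}

    def record(s: int, t: int, length: int) -> None:
        key = (s, t) if s < t else (t, s)
        if best.get(key, 0) < length:
            best[key] = length

    for start in verts:
        visited = {start}
        stack: list[tuple[int, "iter"]] = [(start, iter(local_adj[start]))]
        depth = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for nb in it:
                if nb not in visited:
                    visited.add(nb)
                    depth += 1
                    record(start, nb, depth)
                    stack.append((nb, iter(local_adj[nb])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                visited.discard(node)
                depth -= 1
    return best


def detour_matrix(mol: MolecularGraph) -> SquareMatrixBundle:
    """Detour matrix: longest simple-path edge count between every pair.

    Computed per biconnected block by exhaustive DFS, then merged across the
    block-cut tree: for atoms in different blocks the detour distance is the
    sum of block-internal longest paths along the unique articulation-point
    chain joining them.
    """
    _require_connected(mol)
    n = mol.n_atoms
    out = np.zeros((n, n))
    if n > 1:
        dec = articulation_decompose(mol)
        adj = mol.adjacency()
        block_paths = [_block_longest_paths(adj, b) for b in dec.blocks]

        def block_lp(b_idx: int, u: int, v: int) -> int:
            if u == v:
                return 0
            key = (u, v) if u < v else (v, u)
            return block_paths[b_idx][key]

        # map each vertex to its anchor node in the block-cut tree
        blocks_of: dict[int, list[int]] = {v: [] for v in range(n)}
        for b_idx, verts in enumerate(dec.blocks):
            for v in verts:
                blocks_of[v].append(b_idx)
        tree = dec.block_cut_tree

        def tree_node(v: int):
            if v in dec.articulation_points:
                return ("cut", v)
            return ("block", blocks_of[v][0])

        for u in range(n):
            for v in range(u + 1, n):
                common = set(blocks_of[u]) & set(blocks_of[v])
                if common:
                    total = block_lp(common.pop(), u, v)
                else:
                    node_path = nx.shortest_path(tree, tree_node(u), tree_node(v))
                    total = 0
                    entry = u
                    for k, node in enumerate(node_path):
                        if node[0] != "block":
                            continue
                        b_idx = node[1]
                        exit_v = (
                            node_path[k + 1][1] if k + 1 < len(node_path) else v
                        )
                        total += block_lp(b_idx, entry, exit_v)
                        entry = exit_v
                out[u, v] = out[v, u] = total
    return SquareMatrixBundle(matrix=out, kind="detour", edges=mol.edge_list())


def lse(values: Sequence[float]) -> float:
    """Overflow-safe log-sum-exp: ``x* + log(sum(exp(x_i - x*)))``.

    Equals ``log(sum(exp(x_i)))`` analytically but remains finite for
    arguments far beyond the naive form's floating-point overflow point.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("lse of an empty sequence")
    x_star = float(np.max(x))
    if math.isinf(x_star):
        return x_star
    return x_star + math.log(float(np.sum(np.exp(x - x_star))))


def spectral_aggregates(bundle: SquareMatrixBundle) -> Mapping[str, float]:
    """The 13-aggregate spectral suite shared by all matrix kinds.

    Graph-energy style sums over the eigenvalue spectrum plus
    Randic-eigenvector (VE/VR) terms. ``LogEE`` always routes through
    :func:`lse`. Entries that are undefined for the input (a zero leading-
    eigenvector component in a VR denominator, ``log`` of zero) come back as
    non-finite floats; the descriptor layer converts those to missing values.
    """
    n = bundle.n
    if n == 0:
        raise EmptyGraphError("no atoms")
    w = bundle.eigenvalues
    c = bundle.leading_eigenvector
    out: dict[str, float] = {}
    out["SpAbs"] = float(np.sum(np.abs(w)))
    out["SpMax"] = float(w[0])
    out["SpDiam"] = float(w[0] - w[-1])
    out["SpAD"] = float(np.sum(np.abs(w - np.mean(w))))
    out["SpMAD"] = out["SpAD"] / n
    out["LogEE"] = lse(w)
    out["SM1"] = float(np.sum(w))
    ve1 = float(np.sum(c))
    out["VE1"] = ve1
    out["VE2"] = ve1 / n
    out["VE3"] = math.log(ve1 * n / 10.0) if ve1 > 0 else float("-inf")
    vr1 = 0.0
    ok = True
    for u, v in bundle.edges:
        prod = c[u] * c[v]
        if prod <= 0.0:
            ok = False
            break
        vr1 += prod ** -0.5
    if not ok:
        out["VR1"] = out["VR2"] = out["VR3"] = float("nan")
    else:
        out["VR1"] = vr1
        out["VR2"] = vr1 / n
        out["VR3"] = math.log(vr1 * n / 10.0) if vr1 > 0 else float("-inf")
    return out
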