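"""The in-scope 2D descriptor families and their presets.

Thirteen families are provided: ABCIndex, AtomCount, BalabanJ, Chi,
DetourMatrix, DistanceMatrix, EccentricConnectivityIndex, Framework,
KappaShapeIndex, MolecularId, RingCount, WienerIndex and ZagrebIndex. Four
of them carry algorithmic improvements over the common implementations:

* Chi enumerates connected subgraphs by depth-first search instead of
  pattern matching, so arbitrary orders are reachable;
* DetourMatrix goes through the articulation-point block decomposition in
  :mod:`topodesc.matrices`;
* Framework only counts framework atoms (iterative pruning of terminal
  atoms) without enumerating or materialising the scaffold;
* MolecularId caches edge weights and path products so each partial
  product is computed once.

All descriptors operate on the hydrogen-suppressed graph; AtomCount's
hydrogen tally uses the per-atom implicit-hydrogen counts.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction
from typing import Any, Callable, Iterable, Sequence

import numpy as np

from . import matrices
from .core import Context, Descriptor, TimeBudgetExceeded, UnsupportedAtomError
from .graph import EmptyGraphError, MolecularGraph

__all__ = ["preset", "all_presets", "family_names", "FAMILY_ORDER"]

_HALOGENS = ("F", "Cl", "Br", "I")


# ---------------------------------------------------------------------------
# shared intermediates (built once per molecule through the context cache)
# ---------------------------------------------------------------------------

def _heavy(ctx: Context) -> MolecularGraph:
    return ctx.intermediate(
        "heavy_graph", lambda c: c.mol.subgraph(c.mol.heavy_indices)
    )


def _delta(ctx: Context) -> np.ndarray:
    """Simple delta: heavy-atom degree per heavy atom."""

    def build(c: Context) -> np.ndarray:
        mol = _heavy(c)
        d = np.zeros(mol.n_atoms, dtype=int)
        for i, j, _ in mol.bonds:
            d[i] += 1
            d[j] += 1
        return d

    return ctx.intermediate("delta", build)


def _valence_delta(ctx: Context) -> np.ndarray:
    """Kier--Hall valence delta: (Zv - h) for second-row elements and
    lighter, (Zv - h)/(Z - Zv - 1) beyond."""

    def build(c: Context) -> np.ndarray:
        mol = _heavy(c)
        out = np.zeros(mol.n_atoms)
        for i, a in enumerate(mol.atoms):
            zv, h, z = a.valence_electrons, a.implicit_hydrogens, a.atomic_number
            if z <= 10:
                out[i] = zv - h
            else:
                denom = z - zv - 1
                if denom <= 0:
                    raise UnsupportedAtomError(
                        f"valence delta undefined for {a.element}"
                    )
                out[i] = (zv - h) / denom
        return out

    return ctx.intermediate("valence_delta", build)


def _bundle(ctx: Context, kind: str) -> matrices.SquareMatrixBundle:
    builders: dict[str, Callable[[MolecularGraph], matrices.SquareMatrixBundle]] = {
        "adjacency": matrices.adjacency_matrix,
        "distance": matrices.distance_matrix,
        "detour": matrices.detour_matrix,
    }
    return ctx.intermediate(
        ("matrix", kind), lambda c: builders[kind](_heavy(c))
    )


def _aggregates(ctx: Context, kind: str) -> dict[str, float]:
    return ctx.intermediate(
        ("aggregates", kind),
        lambda c: dict(matrices.spectral_aggregates(_bundle(c, kind))),
    )


def _sssr(ctx: Context) -> list[frozenset[int]]:
    """Smallest set of smallest rings (minimum cycle basis of the heavy graph)."""

    def build(c: Context) -> list[frozenset[int]]:
        import networkx as nx

        g = _heavy(c).to_networkx()
        return [frozenset(cycle) for cycle in nx.minimum_cycle_basis(g)]

    return ctx.intermediate("sssr", build)


# ---------------------------------------------------------------------------
# connected-subgraph enumeration by depth-first search (Chi, path counts)
# ---------------------------------------------------------------------------

def connected_edge_subgraphs(
    edges: Sequence[tuple[int, int]], m: int
) -> list[frozenset[int]]:
    """All connected subgraphs with exactly ``m`` edges, as edge-index sets.

    Depth-first enumeration on the line graph with exclusive-neighbourhood
    extension, so every subgraph is produced exactly once — no pattern
    matching, hence no ceiling on the order.
    """
    k = len(edges)
    if m < 1 or k == 0:
        return []
    ladj: list[set[int]] = [set() for _ in range(k)]
    for a in range(k):
        ea = set(edges[a])
        for b in range(a + 1, k):
            if ea & set(edges[b]):
                ladj[a].add(b)
                ladj[b].add(a)
    results: list[frozenset[int]] = []

    def extend(sub: set[int], ext: set[int], root: int) -> None:
        if len(sub) == m:
            results.append(frozenset(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            excl = {
                u
                for u in ladj[w]
                if u > root and u not in sub and not any(u in ladj[s] for s in sub)
            }
            extend(sub | {w}, ext | excl, root)

    for v in range(k):
        extend({v}, {u for u in ladj[v] if u > v}, v)
    return results


def classify_subgraph(
    edge_idx: frozenset[int], edges: Sequence[tuple[int, int]]
) -> str | None:
    """Kier--Hall subgraph class of a connected edge subgraph.

    ``path``: tree, no branching. ``chain``: exactly one cycle.
    ``cluster``: branched tree with no three-edge path (a star).
    ``path_cluster``: any other branched tree. Subgraphs with two or more
    independent cycles fall outside the four classes (``None``).
    """
    deg: dict[int, int] = {}
    adj: dict[int, list[int]] = {}
    for ei in edge_idx:
        u, v = edges[ei]
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    m = len(edge_idx)
    mu = m - len(deg) + 1
    if mu == 1:
        return "chain"
    if mu > 1:
        return None
    if max(deg.values()) <= 2:
        return "path"
    # tree diameter by double BFS
    def far(src: int) -> tuple[int, int]:
        seen = {src: 0}
        q = deque([src])
        best = (src, 0)
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + 1
                    if seen[y] > best[1]:
                        best = (y, seen[y])
                    q.append(y)
        return best

    end, _ = far(next(iter(deg)))
    _, diam = far(end)
    return "cluster" if diam <= 2 else "path_cluster"


def _chi_subgraphs(ctx: Context, kind: str, order: int) -> list[frozenset[int]]:
    """Vertex sets of all subgraphs of the given class and order."""

    def build(c: Context) -> dict[str, list[frozenset[int]]]:
        mol = _heavy(c)
        by_kind: dict[str, list[frozenset[int]]] = {
            "path": [],
            "chain": [],
            "cluster": [],
            "path_cluster": [],
        }
        if order == 0:
            by_kind["path"] = [frozenset({v}) for v in range(mol.n_atoms)]
            return by_kind
        edges = mol.edge_list()
        for sub in connected_edge_subgraphs(edges, order):
            k = classify_subgraph(sub, edges)
            if k is not None:
                verts = frozenset(v for ei in sub for v in edges[ei])
                by_kind[k].append(verts)
        return by_kind

    return ctx.intermediate(("chi_subgraphs", order), build)[kind]


# ---------------------------------------------------------------------------
# AtomCount
# ---------------------------------------------------------------------------

class AtomCount(Descriptor):
    """Counts of atoms: totals, hydrogens, per element, halogens, ring
    spiro/bridgehead atoms."""

    family = "AtomCount"

    def __init__(self, kind: str) -> None:
        self.kind = kind

    @property
    def name(self) -> str:
        return f"n{self.kind}"

    def parameters(self) -> dict[str, Any]:
        return {"kind": self.kind}

    def compute(self, mol: MolecularGraph, ctx: Context) -> int:
        heavy = _heavy(ctx)
        kind = self.kind
        n_explicit_h = sum(1 for a in mol.atoms if a.element == "H")
        n_h = n_explicit_h + sum(a.implicit_hydrogens for a in heavy.atoms)
        if kind == "Atom":
            return heavy.n_atoms + n_h
        if kind == "HeavyAtom":
            return heavy.n_atoms
        if kind == "H":
            return n_h
        if kind == "X":
            return sum(1 for a in heavy.atoms if a.element in _HALOGENS)
        if kind == "Spiro":
            return len(_spiro_atoms(heavy, _sssr(ctx)))
        if kind == "Bridgehead":
            return len(_bridgehead_atoms(heavy, _sssr(ctx)))
        return sum(1 for a in heavy.atoms if a.element == kind)


def _spiro_atoms(mol: MolecularGraph, rings: list[frozenset[int]]) -> set[int]:
    out: set[int] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            shared = rings[i] & rings[j]
            if len(shared) == 1:
                out |= shared
    return out


def _bridgehead_atoms(mol: MolecularGraph, rings: list[frozenset[int]]) -> set[int]:
    """Atoms at the ends of a bridge shared by two rings (>= 2 shared bonds)."""
    adj = mol.adjacency()
    out: set[int] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            shared = rings[i] & rings[j]
            if len(shared) >= 3:
                for a in shared:
                    if len(adj[a] & shared) == 1:
                        out.add(a)
    return out


# ---------------------------------------------------------------------------
# Zagreb, Wiener, Balaban J, eccentric connectivity, ABC
# ---------------------------------------------------------------------------

class ZagrebIndex(Descriptor):
    """First/second Zagreb indices and their modified (reciprocal) forms.

    The modified variants are accumulated as exact rationals and converted
    to float only at the end, so e.g. the modified second Zagreb index of a
    branched alkane is exact (4/3, not 1.3333...3).
    """

    family = "ZagrebIndex"

    def __init__(self, version: int, modified: bool) -> None:
        self.version = version
        self.modified = modified

    @property
    def name(self) -> str:
        return f"{'m' if self.modified else ''}Zagreb{self.version}"

    def parameters(self) -> dict[str, Any]:
        return {"version": self.version, "modified": self.modified}

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        heavy = _heavy(ctx)
        d = _delta(ctx)
        if self.version == 1:
            terms = (Fraction(int(di)) ** 2 for di in d)
        else:
            terms = (
                Fraction(int(d[i])) * Fraction(int(d[j]))
                for i, j, _ in heavy.bonds
            )
        if self.modified:
            total = sum((Fraction(1) / t for t in terms), Fraction(0))
        else:
            total = sum(terms, Fraction(0))
        return float(total)


class WienerIndex(Descriptor):
    """Wiener path number (half-sum of distances) and polarity number
    (atom pairs at distance exactly three)."""

    family = "WienerIndex"

    def __init__(self, polarity: bool) -> None:
        self.polarity = polarity

    @property
    def name(self) -> str:
        return "WPol" if self.polarity else "WPath"

    def parameters(self) -> dict[str, Any]:
        return {"polarity": self.polarity}

    def compute(self, mol: MolecularGraph, ctx: Context) -> int:
        bundle = _bundle(ctx, "distance")
        d = bundle.matrix
        if self.polarity:
            return int(np.sum(d == 3) // 2)
        return int(round(float(np.sum(d)) / 2.0))


class BalabanJ(Descriptor):
    """Balaban's distance connectivity index J.

    J = M/(mu+1) * sum over bonds (s_u s_v)^(-1/2), with M the bond count,
    mu the cyclomatic number and s_i the distance-matrix row sums; computed
    on the hydrogen-suppressed graph.
    """

    family = "BalabanJ"
    name = "BalabanJ"  # type: ignore[assignment]

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        heavy = _heavy(ctx)
        if heavy.n_atoms < 2:
            raise EmptyGraphError("Balaban J needs at least two heavy atoms")
        d = _bundle(ctx, "distance").matrix
        s = d.sum(axis=1)
        m_edges = len(heavy.bonds)
        mu = m_edges - heavy.n_atoms + 1
        total = sum((s[i] * s[j]) ** -0.5 for i, j, _ in heavy.bonds)
        return m_edges / (mu + 1.0) * total


class EccentricConnectivityIndex(Descriptor):
    """Sum over atoms of degree times eccentricity (max row distance)."""

    family = "EccentricConnectivityIndex"
    name = "ECIndex"  # type: ignore[assignment]

    def compute(self, mol: MolecularGraph, ctx: Context) -> int:
        d = _bundle(ctx, "distance").matrix
        ecc = d.max(axis=1) if d.size else np.zeros(0)
        delta = _delta(ctx)
        return int(round(float(np.sum(delta * ecc))))


class ABCIndex(Descriptor):
    """Atom-bond connectivity index (degree or Graovac--Ghorbani variant)."""

    family = "ABCIndex"

    def __init__(self, graovac_ghorbani: bool) -> None:
        self.graovac_ghorbani = graovac_ghorbani

    @property
    def name(self) -> str:
        return "ABCGG" if self.graovac_ghorbani else "ABC"

    def parameters(self) -> dict[str, Any]:
        return {"graovac_ghorbani": self.graovac_ghorbani}

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        heavy = _heavy(ctx)
        if not heavy.bonds:
            raise EmptyGraphError("ABC index needs at least one bond")
        if not self.graovac_ghorbani:
            d = _delta(ctx)
            return float(
                sum(
                    math.sqrt((d[i] + d[j] - 2) / (d[i] * d[j]))
                    for i, j, _ in heavy.bonds
                )
            )
        dist = _bundle(ctx, "distance").matrix
        total = 0.0
        for i, j, _ in heavy.bonds:
            nu = int(np.sum(dist[:, i] < dist[:, j]))
            nv = int(np.sum(dist[:, j] < dist[:, i]))
            total += math.sqrt((nu + nv - 2) / (nu * nv))
        return total


# ---------------------------------------------------------------------------
# Chi connectivity (DFS subgraph enumeration) and kappa shape
# ---------------------------------------------------------------------------

_KIND_CODES = {"path": "p", "chain": "ch", "cluster": "c", "path_cluster": "pc"}


class Chi(Descriptor):
    """Kier--Hall chi connectivity: sum over subgraphs of a class/order of
    the product of reciprocal square-root deltas over the subgraph's atoms.

    Subgraphs are enumerated by depth-first search, so any order is
    reachable. Averaged variants divide by the subgraph count.
    """

    family = "Chi"

    def __init__(self, kind: str, order: int, valence: bool, averaged: bool = False) -> None:
        if kind not in _KIND_CODES:
            raise ValueError(f"unknown subgraph kind {kind!r}")
        self.kind = kind
        self.order = order
        self.valence = valence
        self.averaged = averaged

    @property
    def name(self) -> str:
        return (
            ("A" if self.averaged else "")
            + f"X{_KIND_CODES[self.kind]}-{self.order}"
            + ("dv" if self.valence else "d")
        )

    def parameters(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "order": self.order,
            "valence": self.valence,
            "averaged": self.averaged,
        }

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        subs = _chi_subgraphs(ctx, self.kind, self.order)
        delta = _valence_delta(ctx) if self.valence else _delta(ctx)
        total = 0.0
        for verts in subs:
            prod = 1.0
            for v in verts:
                if delta[v] <= 0:
                    raise ZeroDivisionError(f"delta zero at atom {v}")
                prod *= delta[v] ** -0.5
            total += prod
        if self.averaged:
            return total / len(subs)  # no subgraphs -> divide_by_zero missing
        return total


class KappaShapeIndex(Descriptor):
    """Kier kappa shape indices (first through third order, no alpha
    correction) from path counts P_m enumerated by depth-first search."""

    family = "KappaShapeIndex"

    def __init__(self, order: int) -> None:
        if order not in (1, 2, 3):
            raise ValueError("kappa order must be 1, 2 or 3")
        self.order = order

    @property
    def name(self) -> str:
        return f"Kier{self.order}"

    def parameters(self) -> dict[str, Any]:
        return {"order": self.order}

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        a = _heavy(ctx).n_atoms
        minimum = 3 if self.order == 1 else 4
        if a < minimum:
            raise EmptyGraphError(
                f"kappa{self.order} needs at least {minimum} heavy atoms"
            )
        p_m = len(_chi_subgraphs(ctx, "path", self.order))
        if self.order == 1:
            num = a * (a - 1) ** 2
        elif self.order == 2:
            num = (a - 1) * (a - 2) ** 2
        elif a % 2 == 1:
            num = (a - 1) * (a - 3) ** 2
        else:
            num = (a - 3) * (a - 2) ** 2
        return num / p_m ** 2  # P_m = 0 -> divide_by_zero missing


# ---------------------------------------------------------------------------
# Ring counts and framework
# ---------------------------------------------------------------------------

class RingCount(Descriptor):
    """Number of n-membered rings in the SSSR."""

    family = "RingCount"

    def __init__(self, ring_size: int) -> None:
        if ring_size < 3:
            raise ValueError("ring size must be >= 3")
        self.ring_size = ring_size

    @property
    def name(self) -> str:
        return f"n{self.ring_size}Ring"

    def parameters(self) -> dict[str, Any]:
        return {"ring_size": self.ring_size}

    def compute(self, mol: MolecularGraph, ctx: Context) -> int:
        return sum(1 for r in _sssr(ctx) if len(r) == self.ring_size)


class Framework(Descriptor):
    """Fraction of heavy atoms in the molecular framework (ring systems plus
    linkers), obtained by iteratively deleting terminal heavy atoms.

    Only the count of framework atoms is maintained — the scaffold itself is
    never enumerated or materialised.
    """

    family = "Framework"
    name = "fMF"  # type: ignore[assignment]

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        heavy = _heavy(ctx)
        n = heavy.n_atoms
        if n == 0:
            raise EmptyGraphError("no heavy atoms")
        adj = [set(s) for s in heavy.adjacency()]
        alive = n
        queue = deque(v for v in range(n) if len(adj[v]) <= 1)
        dead = set(queue)
        while queue:
            v = queue.popleft()
            alive -= 1
            for nb in adj[v]:
                adj[nb].discard(v)
                if len(adj[nb]) <= 1 and nb not in dead:
                    dead.add(nb)
                    queue.append(nb)
            adj[v].clear()
        return alive / n


# ---------------------------------------------------------------------------
# Randic molecular ID (cached path products)
# ---------------------------------------------------------------------------

def molecular_id_contributions(
    mol: MolecularGraph, budget: int | None = None
) -> np.ndarray:
    """Per-atom molecular-ID weights w(v) = 1 + half the sum of path products.

    A simple path's weight is the product over its bonds of
    (delta_u delta_v)^(-1/2). Bond weights are computed once and the running
    product is extended incrementally during the depth-first search, so no
    partial product is ever recomputed. ``budget`` caps the number of path
    extensions (raises :class:`TimeBudgetExceeded` beyond it).
    """
    n = mol.n_atoms
    adj = mol.adjacency()
    deg = np.zeros(n, dtype=int)
    for i, j, _ in mol.bonds:
        deg[i] += 1
        deg[j] += 1
    wedge: dict[tuple[int, int], float] = {}
    for i, j, _ in mol.bonds:
        w = (int(deg[i]) * int(deg[j])) ** -0.5
        wedge[(i, j)] = wedge[(j, i)] = w
    s = np.zeros(n)
    steps = 0

    def dfs(start: int, node: int, prod: float, visited: set[int]) -> None:
        nonlocal steps
        for nb in adj[node]:
            if nb in visited:
                continue
            steps += 1
            if budget is not None and steps > budget:
                raise TimeBudgetExceeded(f"molecular-ID path budget {budget}")
            p = prod * wedge[(node, nb)]
            s[start] += p
            visited.add(nb)
            dfs(start, nb, p, visited)
            visited.discard(nb)

    for v in range(n):
        dfs(v, v, 1.0, {v})
    return 1.0 + s / 2.0


class MolecularId(Descriptor):
    """Randic molecular ID, total or restricted to an atom subset, with an
    averaged (per-heavy-atom) variant."""

    family = "MolecularId"

    _SUBSETS = ("all", "h", "C", "N", "O", "X")

    def __init__(self, subset: str, averaged: bool = False, budget: int | None = None) -> None:
        if subset not in self._SUBSETS:
            raise ValueError(f"unknown subset {subset!r}")
        self.subset = subset
        self.averaged = averaged
        self.budget = budget

    @property
    def name(self) -> str:
        base = "AMID" if self.averaged else "MID"
        return base if self.subset == "all" else f"{base}_{self.subset}"

    def parameters(self) -> dict[str, Any]:
        return {"subset": self.subset, "averaged": self.averaged}

    def _mask(self, mol: MolecularGraph) -> np.ndarray:
        if self.subset == "all":
            return np.ones(mol.n_atoms, dtype=bool)
        if self.subset == "h":
            return np.array([a.implicit_hydrogens > 0 for a in mol.atoms])
        if self.subset == "X":
            return np.array([a.element in _HALOGENS for a in mol.atoms])
        return np.array([a.element == self.subset for a in mol.atoms])

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        heavy = _heavy(ctx)
        if heavy.n_atoms == 0:
            raise EmptyGraphError("no heavy atoms")
        matrices._require_connected(heavy)
        budget = self.budget
        w = ctx.intermediate(
            ("molecular_id", budget),
            lambda c: molecular_id_contributions(_heavy(c), budget=budget),
        )
        total = float(np.sum(w[self._mask(heavy)]))
        if self.averaged:
            return total / heavy.n_atoms
        return total


# ---------------------------------------------------------------------------
# Matrix-spectrum families
# ---------------------------------------------------------------------------

_MATRIX_SUFFIX = {"adjacency": "A", "distance": "D", "detour": "Dt"}


class MatrixAggregate(Descriptor):
    """One of the 13 spectral aggregates of a named atom-pair matrix."""

    def __init__(self, kind: str, aggregate: str) -> None:
        if aggregate not in matrices.AGGREGATE_NAMES:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        self.kind = kind
        self.aggregate = aggregate
        self.family = {
            "adjacency": "AdjacencyMatrix",
            "distance": "DistanceMatrix",
            "detour": "DetourMatrix",
        }[kind]

    @property
    def name(self) -> str:
        return f"{self.aggregate}_{_MATRIX_SUFFIX[self.kind]}"

    def parameters(self) -> dict[str, Any]:
        return {"kind": self.kind, "aggregate": self.aggregate}

    def compute(self, mol: MolecularGraph, ctx: Context) -> float:
        return _aggregates(ctx, self.kind)[self.aggregate]


class DetourIndex(Descriptor):
    """Half-sum of the detour-matrix entries."""

    family = "DetourMatrix"
    name = "DetourIndex"  # type: ignore[assignment]

    def compute(self, mol: MolecularGraph, ctx: Context) -> int:
        d = _bundle(ctx, "detour").matrix
        return int(round(float(np.sum(d)) / 2.0))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset_abc() -> list[Descriptor]:
    return [ABCIndex(False), ABCIndex(True)]


def _preset_atom_count() -> list[Descriptor]:
    kinds = ["Atom", "HeavyAtom", "H", "B", "C", "N", "O", "S", "P",
             "F", "Cl", "Br", "I", "X", "Spiro", "Bridgehead"]
    return [AtomCount(k) for k in kinds]


def _preset_balaban_j() -> list[Descriptor]:
    return [BalabanJ()]


#: subgraph-order ranges of the default chi preset per class
CHI_ORDERS = {
    "path": range(0, 8),
    "chain": range(3, 8),
    "cluster": range(3, 7),
    "path_cluster": range(4, 7),
}


def _preset_chi(orders: dict[str, Iterable[int]] | None = None) -> list[Descriptor]:
    ranges = {k: list(v) for k, v in CHI_ORDERS.items()}
    if orders:
        for k, v in orders.items():
            ranges[k] = list(v)
    out: list[Descriptor] = []
    for kind, rng in ranges.items():
        for order in rng:
            out.append(Chi(kind, order, valence=False))
            out.append(Chi(kind, order, valence=True))
            if kind == "path":
                out.append(Chi(kind, order, valence=False, averaged=True))
                out.append(Chi(kind, order, valence=True, averaged=True))
    return out


def _preset_matrix(kind: str) -> Callable[[], list[Descriptor]]:
    def factory() -> list[Descriptor]:
        out: list[Descriptor] = [
            MatrixAggregate(kind, agg) for agg in matrices.AGGREGATE_NAMES
        ]
        if kind == "detour":
            out.append(DetourIndex())
        return out

    return factory


def _preset_eccentric() -> list[Descriptor]:
    return [EccentricConnectivityIndex()]


def _preset_framework() -> list[Descriptor]:
    return [Framework()]


def _preset_kappa() -> list[Descriptor]:
    return [KappaShapeIndex(k) for k in (1, 2, 3)]


def _preset_molecular_id(budget: int | None = None) -> list[Descriptor]:
    out: list[Descriptor] = []
    for subset in MolecularId._SUBSETS:
        out.append(MolecularId(subset, averaged=False, budget=budget))
        out.append(MolecularId(subset, averaged=True, budget=budget))
    return out


def _preset_ring_count(min_n: int = 3, max_n: int = 12) -> list[Descriptor]:
    if max_n < 12:
        raise ValueError("max_n must be >= 12")
    return [RingCount(n) for n in range(min_n, max_n + 1)]


def _preset_wiener() -> list[Descriptor]:
    return [WienerIndex(False), WienerIndex(True)]


def _preset_zagreb() -> list[Descriptor]:
    return [
        ZagrebIndex(1, False),
        ZagrebIndex(2, False),
        ZagrebIndex(1, True),
        ZagrebIndex(2, True),
    ]


_FAMILIES: dict[str, Callable[..., list[Descriptor]]] = {
    "ABCIndex": _preset_abc,
    "AtomCount": _preset_atom_count,
    "BalabanJ": _preset_balaban_j,
    "Chi": _preset_chi,
    "DetourMatrix": _preset_matrix("detour"),
    "DistanceMatrix": _preset_matrix("distance"),
    "EccentricConnectivityIndex": _preset_eccentric,
    "Framework": _preset_framework,
    "KappaShapeIndex": _preset_kappa,
    "MolecularId": _preset_molecular_id,
    "RingCount": _preset_ring_count,
    "WienerIndex": _preset_wiener,
    "ZagrebIndex": _preset_zagreb,
}

#: registration order of the full default descriptor set
FAMILY_ORDER = tuple(_FAMILIES)


def family_names() -> tuple[str, ...]:
    return FAMILY_ORDER


def preset(family: str, **overrides: Any) -> list[Descriptor]:
    """The named family's default descriptor list.

    Overrides extend parameter ranges without source modification, e.g.
    ``preset("RingCount", max_n=16)`` adds 13- to 16-membered ring counters.
    """
    try:
        factory = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown descriptor family {family!r}") from None
    return factory(**overrides)


def all_presets() -> list[Descriptor]:
    out: list[Descriptor] = []
    for family in FAMILY_ORDER:
        out.extend(preset(family))
    return out
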