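"""Hydrogen-suppressed molecular graph model.

The substrate of every descriptor in this package is a labelled, undirected
simple graph: heavy atoms as vertices (with element, formal charge, implicit
hydrogen count, aromaticity flag and valence-electron count) and bonds as
edges with an order in {1, 2, 3, aromatic}. 3D coordinates are never stored:
every descriptor computed here is a pure function of the 2D graph, so
roto-translation of the input molecule cannot change any value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

AROMATIC_BOND = 1.5

#: outer-shell (valence) electron counts for the elements descriptors support
_OUTER_ELECTRONS = {
    "H": 1, "He": 2,
    "Li": 1, "Be": 2, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Ne": 8,
    "Na": 1, "Mg": 2, "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7, "Ar": 8,
    "K": 1, "Ca": 2, "As": 5, "Se": 6, "Br": 7, "Kr": 8,
    "I": 7, "Xe": 8, "Sn": 4, "Te": 6, "Sb": 5,
}

_ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "As": 33, "Se": 34,
    "Br": 35, "Kr": 36, "Sn": 50, "Sb": 51, "Te": 52, "I": 53, "Xe": 54,
}


class EmptyGraphError(ValueError):
    """Raised when a descriptor needs atoms but the graph has none."""


class DisconnectedGraphError(ValueError):
    """Raised by distance/detour computations on multi-fragment graphs."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or explicit hydrogen) atom of a molecular graph.

    ``implicit_hydrogens`` counts hydrogens suppressed from the explicit
    graph; ``valence_electrons`` is the outer-shell electron count used by
    the Kier--Hall valence delta.
    """

    element: str
    atomic_number: int
    formal_charge: int = 0
    implicit_hydrogens: int = 0
    aromatic: bool = False
    valence_electrons: int = 0

    def __post_init__(self) -> None:
        if self.atomic_number < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.atomic_number}")
        if self.implicit_hydrogens < 0:
            raise ValueError("implicit hydrogen count must be >= 0")

    @classmethod
    def from_symbol(
        cls,
        element: str,
        *,
        implicit_hydrogens: int = 0,
        formal_charge: int = 0,
        aromatic: bool = False,
    ) -> "AtomRecord":
        """Build a record from an element symbol using periodic-table data."""
        try:
            z = _ATOMIC_NUMBERS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
        return cls(
            element=element,
            atomic_number=z,
            formal_charge=formal_charge,
            implicit_hydrogens=implicit_hydrogens,
            aromatic=aromatic,
            valence_electrons=_OUTER_ELECTRONS[element],
        )


@dataclass(frozen=True)
class PreprocessPolicy:
    """How a molecule is normalised before descriptor evaluation.

    Exactly one hydrogen mode applies: ``explicit_hydrogens`` is either
    ``"remove"`` (suppress H atoms into per-atom counts) or ``"add"``
    (materialise implicit hydrogens as explicit vertices).
    """

    explicit_hydrogens: str = "remove"
    kekulize: bool = False
    perceive_aromaticity: bool = False
    desalt: bool = False

    def __post_init__(self) -> None:
        if self.explicit_hydrogens not in ("remove", "add"):
            raise ValueError("explicit_hydrogens must be 'remove' or 'add'")


@dataclass(frozen=True)
class MolecularGraph:
    """Immutable labelled molecular graph.

    ``bonds`` holds ``(i, j, order)`` triples with 0-based atom indices and
    order in ``{1, 2, 3, AROMATIC_BOND}``. A record that failed to parse is
    represented by an empty graph with ``parse_error`` set; descriptor
    evaluation turns it into missing values rather than aborting a batch.
    """

    atoms: tuple[AtomRecord, ...] = ()
    bonds: tuple[tuple[int, int, float], ...] = ()
    name: str = ""
    parse_error: str | None = None
    meta: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if a.element != "H")

    def neighbors(self, atom: int) -> tuple[int, ...]:
        out = []
        for i, j, _ in self.bonds:
            if i == atom:
                out.append(j)
            elif j == atom:
                out.append(i)
        return tuple(out)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def edge_list(self) -> tuple[tuple[int, int], ...]:
        return tuple((i, j) for i, j, _ in self.bonds)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    @property
    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return False
        return nx.is_connected(self.to_networkx())

    def with_meta(self, **entries: str) -> "MolecularGraph":
        merged = dict(self.meta)
        merged.update(entries)
        return dataclasses.replace(self, meta=tuple(sorted(merged.items())))

    # -- graph surgery used by preprocessing -----------------------------

    def subgraph(self, keep: Iterable[int]) -> "MolecularGraph":
        """Induced subgraph on ``keep``, re-indexed in ascending old order."""
        keep_sorted = sorted(set(keep))
        remap = {old: new for new, old in enumerate(keep_sorted)}
        atoms = tuple(self.atoms[i] for i in keep_sorted)
        bonds = tuple(
            (remap[i], remap[j], order)
            for i, j, order in self.bonds
            if i in remap and j in remap
        )
        return dataclasses.replace(self, atoms=atoms, bonds=bonds)

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms so that new index ``perm[i]`` holds old atom ``i``."""
        if sorted(perm) != list(range(self.n_atoms)):
            raise ValueError("perm must be a permutation of atom indices")
        atoms: list[AtomRecord | None] = [None] * self.n_atoms
        for old, new in enumerate(perm):
            atoms[new] = self.atoms[old]
        bonds = tuple((perm[i], perm[j], order) for i, j, order in self.bonds)
        return dataclasses.replace(self, atoms=tuple(atoms), bonds=bonds)


def heavy_degree(mol: MolecularGraph, atom: int) -> int:
    """Number of heavy-atom neighbours of ``atom`` (the simple delta)."""
    if not (0 <= atom < mol.n_atoms):
        raise IndexError(f"atom index {atom} out of range")
    return sum(1 for nb in mol.neighbors(atom) if mol.atoms[nb].element != "H")


def _remove_explicit_hydrogens(mol: MolecularGraph) -> MolecularGraph:
    h_idx = {i for i, a in enumerate(mol.atoms) if a.element == "H"}
    if not h_idx:
        return mol
    extra_h = [0] * mol.n_atoms
    for i, j, _ in mol.bonds:
        if i in h_idx and j not in h_idx:
            extra_h[j] += 1
        elif j in h_idx and i not in h_idx:
            extra_h[i] += 1
    keep = [i for i in range(mol.n_atoms) if i not in h_idx]
    atoms = tuple(
        dataclasses.replace(
            mol.atoms[i],
            implicit_hydrogens=mol.atoms[i].implicit_hydrogens + extra_h[i],
        )
        for i in keep
    )
    remap = {old: new for new, old in enumerate(keep)}
    bonds = tuple(
        (remap[i], remap[j], order)
        for i, j, order in mol.bonds
        if i in remap and j in remap
    )
    return dataclasses.replace(mol, atoms=atoms, bonds=bonds)


def _add_explicit_hydrogens(mol: MolecularGraph) -> MolecularGraph:
    atoms = list(mol.atoms)
    bonds = list(mol.bonds)
    h_record = AtomRecord.from_symbol("H")
    for i, a in enumerate(mol.atoms):
        for _ in range(a.implicit_hydrogens):
            atoms.append(h_record)
            bonds.append((i, len(atoms) - 1, 1.0))
        if a.implicit_hydrogens:
            atoms[i] = dataclasses.replace(a, implicit_hydrogens=0)
    return dataclasses.replace(mol, atoms=tuple(atoms), bonds=tuple(bonds))


def _kekulize(mol: MolecularGraph) -> MolecularGraph:
    """Assign alternating single/double orders to aromatic bonds.

    Uses a maximum-cardinality matching on the aromatic-bond subgraph: matched
    edges become double bonds, the remainder single. For RDKit-parsed input
    prefer sanitized Kekulé orders from the parser; this graph-level fallback
    serves programmatically built aromatic graphs.
    """
    aromatic_edges = [(i, j) for i, j, order in mol.bonds if order == AROMATIC_BOND]
    if not aromatic_edges:
        return mol
    sub = nx.Graph(aromatic_edges)
    matching = nx.max_weight_matching(sub, maxcardinality=True)
    matched = {frozenset(e) for e in matching}
    bonds = tuple(
        (i, j, (2.0 if frozenset((i, j)) in matched else 1.0))
        if order == AROMATIC_BOND
        else (i, j, order)
        for i, j, order in mol.bonds
    )
    return dataclasses.replace(mol, bonds=bonds)


def preprocess(mol: MolecularGraph, policy: PreprocessPolicy | None = None) -> MolecularGraph:
    """Apply a :class:`PreprocessPolicy`; deterministic and idempotent.

    ``desalt`` keeps only the largest connected component by heavy-atom
    count (ties broken by lowest atom index, which makes the operation
    deterministic). Aromaticity re-perception requires parser support and is
    handled at the parse boundary; flags already on the graph are kept.
    """
    if policy is None:
        policy = PreprocessPolicy()
    out = mol
    if policy.desalt and out.n_atoms:
        comps = out.connected_components()
        def key(c: set[int]) -> tuple[int, int]:
            heavies = sum(1 for i in c if out.atoms[i].element != "H")
            return (-heavies, min(c))
        out = out.subgraph(sorted(comps, key=key)[0])
    if policy.explicit_hydrogens == "remove":
        out = _remove_explicit_hydrogens(out)
    else:
        out = _add_explicit_hydrogens(out)
    if policy.kekulize:
        out = _kekulize(out)
    return out
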