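# Methods

## Scope and model

`topodesc` computes 2D topological descriptors: pure functions of the
labelled, hydrogen-suppressed molecular graph. Atoms carry element, atomic
number Z, formal charge, implicit-hydrogen count h, an aromaticity flag and
the outer-shell electron count Zᵛ; bonds carry an order in {1, 2, 3,
aromatic}. Coordinates are never read, so every descriptor is trivially
invariant under roto-translation, and the test suite additionally verifies
invariance under arbitrary atom relabelling for every registered
descriptor.

### Preprocessing

Molecule preprocessing changes descriptor values, so it is pinned down
rather than left to the caller:

* **Parsing.** RDKit parses SMILES and SDF (V2000) and sanitises the
  molecule; aromaticity perception therefore follows RDKit's default model,
  which is recorded in the graph metadata (`aromaticity_model`).
* **Hydrogen convention.** All descriptor families operate on the
  hydrogen-suppressed graph; the calculator removes explicit hydrogens
  before evaluation and folds them into per-atom counts. This is what makes
  e.g. the Balaban J literature values reproducible. AtomCount's hydrogen
  tally (`nH`, `nAtom`) uses those counts.
* **Desalting** keeps the largest connected component by heavy-atom count,
  ties broken by lowest atom index (deterministic).
* **Kekulization** on graphs without an RDKit record assigns double bonds
  along a maximum-cardinality matching of the aromatic-bond subgraph. None
  of the in-scope descriptors read bond orders, so this is cosmetic here,
  but the operation is exposed and idempotent.
* Multi-fragment input without desalting: descriptors that need a connected
  graph (everything distance- or detour-based, Balaban J, molecular ID)
  return a `disconnected` missing value, because inter-fragment distance is
  undefined; additive descriptors (atom counts, Zagreb, chi, ring counts,
  framework) naturally sum over fragments.

Preprocessing is idempotent: applying a policy twice equals applying it
once (tested).

## The framework

A `Descriptor` is a named, parameterised unit returning one scalar (or a
`MissingValue`) per molecule. A `Calculator` keeps descriptors in
registration order, rejects duplicate names, and evaluates each exactly
once per molecule. Shared intermediates — the distance matrix, delta
vectors, subgraph enumerations, the SSSR — are built through a per-molecule
context cache, created for one molecule and discarded afterwards, which
bounds memory for arbitrarily long batches. Disabling the cache changes no
value (tested), only the work done.

**Missing values are data, not control flow.** Every failure mode is mapped
to a typed reason: `parse_failure`, `disconnected`, `empty_graph`,
`divide_by_zero`, `unsupported_atom`, `dependency_failure`, `timeout`. No
exception escapes `calculate()`; a `strict=True` mode re-raises for
debugging. `ResultSet` offers `fill_missing` (default NaN), `drop_missing`
and `asdict` views.

**Descriptor arithmetic.** Descriptors compose under `+ − × ÷ ** neg` with
auto-generated names; a missing operand yields a missing composite with
reason `dependency_failure`, and division by zero at evaluation time yields
`divide_by_zero`.

**Parallelism** is process-based over molecules with chunk size
⌈n/4p⌉. Output order equals input order and results are identical to the
serial path (tested for p ∈ {2, 3, 4}); a failure on one molecule fills that
molecule's row with missing values and leaves the others untouched.

**scikit-learn surface.** The calculator doubles as a transformer: `fit`
freezes the descriptor list, `transform` yields an
(n_molecules × n_descriptors) float matrix with NaN for missing, and
`get_feature_names_out` returns descriptor names, so it drops into
`Pipeline`/`ColumnTransformer` compositions.

## Algorithms

### Detour matrix by articulation-point decomposition

Longest simple paths are NP-hard, but every simple path between atoms in
different biconnected blocks must pass through the unique chain of
articulation points connecting them in the block-cut tree. The algorithm:

1. decompose the graph into biconnected blocks and cut vertices (networkx's
   low-link DFS);
2. inside each block, compute all-pairs longest paths by exhaustive DFS —
   blocks of molecular graphs are small even when the molecule is large;
3. for atoms u, v in different blocks, walk the block-cut-tree path and sum
   the block-internal longest paths between consecutive articulation
   points (entry/exit vertices), starting at u and ending at v.

Correctness rests on the additivity of step 3, which holds because a simple
path cannot re-enter a block after leaving it through its single shared cut
vertex. The implementation is validated against an independent exhaustive
whole-graph DFS oracle on 100 seeded random connected graphs (n ≤ 12) and
against the distance matrix on 50 random trees (where both are the unique
simple path length). No per-molecule timeout is imposed by default; the
molecular-ID search accepts an optional work budget that returns a
`timeout` missing value when exceeded.

### Chi by DFS subgraph enumeration

Connected subgraphs with m edges are enumerated once per order via
exclusive-neighbourhood extension on the line graph (each subgraph produced
exactly once) and classified: `chain` has exactly one independent cycle;
trees split into `path` (no branch vertex), `cluster` (branched, diameter
≤ 2 — a star) and `path_cluster` (branched with a three-edge path);
subgraphs with ≥ 2 independent cycles fall outside the four classes. The
default preset covers path orders 0–7 (simple, valence, and both averaged
variants), chain 3–7, cluster 3–6 and path-cluster 4–6 (simple and
valence), 56 descriptors in total; the order ranges were chosen to realise
that published family size. The enumeration is validated against an
exhaustive edge-subset classification oracle on 50 random graphs (n ≤ 10)
for every kind and order.

### Kappa, molecular ID, framework

Path counts P₁–P₃ for the kappa indices reuse the chi path enumeration.
Kappa is implemented without the Kier alpha correction (the plain
A/P-count formulas); whether an alpha-corrected variant is wanted is left
to the caller as future surface, and the choice is documented here because
implementations differ.

The Randić molecular ID accumulates per-atom weights
w(v) = 1 + ½ Σ_paths Π_bonds (δᵤδᵥ)^(−1/2) over all simple paths ending at
v. Bond weights are precomputed and path products extended incrementally
(each partial product computed once); equality with an uncached
recompute-per-path oracle is asserted to 1e−12 on every test graph.

The framework fraction fMF iteratively deletes degree-1 heavy atoms with a
queue and degree counters, tracking only the surviving-atom count; fMF ∈
[0, 1] with fMF = 0 exactly for acyclic molecules.

### Spectral aggregates

All three matrix kinds (adjacency, distance, detour) share 13 aggregates:
SpAbs = Σ|λᵢ|, SpMax = λ₁, SpDiam = λ₁ − λₙ, SpAD = Σ|λᵢ − λ̄|,
SpMAD = SpAD/n, LogEE = lse(λ), SM1 = Σλᵢ, VE1 = Σ|cᵢ|, VE2 = VE1/n,
VE3 = log(VE1·n/10), VR1 = Σ_bonds (|cᵤ||cᵥ|)^(−1/2), VR2 = VR1/n,
VR3 = log(VR1·n/10), with λ the eigenvalues (dense symmetric
eigendecomposition) and c the leading eigenvector. These formulas follow
the conventional matrix-descriptor definitions; only the family
cardinalities (13, and 14 for detour including the detour index) are
externally fixed.

Numerical choices: eigenvector components enter only as absolute values, so
results are invariant to the eigensolver's sign convention; when the top
eigenvalue is degenerate the eigenvector choice is solver-dependent and the
matrix bundle flags it (`top_eigenvalue_degenerate`) — VE/VR values on such
graphs may differ between implementations. A zero component in a VR
denominator, or log of zero, becomes a `divide_by_zero` missing value.
`LogEE` always routes through the shifted log-sum-exp
`x* + log Σ exp(xᵢ − x*)`, finite for eigenvalue magnitudes far beyond the
naive form's overflow point (~709); the safe-range deviation from the naive
form is at machine precision (regression-tested at 1e−12).

### SSSR and ring-derived counts

Ring perception uses the minimum cycle basis of the heavy graph as the
smallest set of smallest rings. Ring counters cover sizes 3–12 by default
and extend to larger macrocycle sizes by parameter
(`preset("RingCount", max_n=16)`) without source modification. Spiro atoms
are atoms shared by two SSSR rings whose intersection is exactly that atom;
bridgeheads are the endpoints of a bridge (ring-pair intersection of ≥ 3
atoms, i.e. ≥ 2 shared bonds).

## Synthetic data and oracles

The generator produces deterministic connected simple graphs — paths,
cycles, random trees (random attachment), random sparse connected graphs
(tree plus ~n/3 extra edges), rings with tails, bridged ring pairs —
carbon-only by default with optional element palettes. These are bare
topological skeletons, not valence-correct molecules: the descriptor
families in scope read connectivity, element identity and hydrogen counts
only, so skeletons exercise exactly the code paths real molecules do.
What passing these suites does **not** show: behaviour on
chemistry-specific preprocessing (aromatic perception corner cases,
charged/exotic species), which is exercised separately via RDKit-parsed
SMILES in the unit tests.

The oracles are deliberately naive and share no code with the algorithms
they check: exhaustive simple-path recursion for longest paths (refuses
n > 14), exhaustive edge-subset enumeration with union-find connectivity
for subgraph classes (refuses n > 10), and plain recursion for simple-path
listings. Oracle size caps and suite sizes (100 random graphs for detour,
50 for chi/trees, 20–25 for molecular ID) keep the full suite and the
acceptance script each under a few minutes on one CPU while covering every
branch structure the merge logic can encounter (trees, single rings, fused
and bridged rings, ring–tail junctions).

## Known limitations

* Aromaticity re-perception on programmatically built (non-RDKit) graphs is
  not available; flags are taken as constructed.
* The kappa indices omit the alpha correction (see above).
* VE/VR aggregates are implementation-defined on graphs with a degenerate
  leading eigenvalue (flagged, see above).
* RingCount counts SSSR members only; rings outside the minimum cycle basis
  (e.g. the 6-ring envelope of some cage systems) are not counted.
* No 3D descriptors, conformer generation, tautomer/protonation
  enumeration, or InChI support.
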