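# topodesc

2D topological molecular descriptors for QSPR/QSAR feature generation, with
a scikit-learn transformer interface and a CSV-producing command line.

Molecular descriptors turn a molecule's symbolic structure into numbers that
structure–property models can consume. `topodesc` computes thirteen curated
families of 2D (purely graph-topological) descriptors — 135 values per
molecule by default — on the hydrogen-suppressed molecular graph:

| Family | Descriptors | Notes |
|---|---|---|
| ABCIndex | 2 | atom-bond connectivity, Graovac–Ghorbani variant |
| AtomCount | 16 | totals, hydrogens, per-element, halogens, spiro/bridgehead |
| BalabanJ | 1 | distance connectivity index J |
| Chi | 56 | Kier–Hall χ for path/chain/cluster/path-cluster subgraphs |
| DetourMatrix | 14 | 13 spectral aggregates + detour index |
| DistanceMatrix | 13 | spectral aggregates of the topological distance matrix |
| EccentricConnectivityIndex | 1 | Σᵢ δᵢ·ecc(i) |
| Framework | 1 | fraction of heavy atoms in the ring-and-linker framework |
| KappaShapeIndex | 3 | Kier κ₁–κ₃ |
| MolecularId | 12 | Randić molecular ID and subset/averaged variants |
| RingCount | 10 | n-membered SSSR rings, n = 3…12 (extensible) |
| WienerIndex | 2 | path and polarity numbers |
| ZagrebIndex | 4 | Zagreb and modified Zagreb indices |

Four descriptors use algorithms chosen for speed and reach rather than the
conventional implementations:

* **DetourMatrix** — the entry (i, j) is the length of the *longest* simple
  path between atoms i and j, an NP-hard problem in general. Molecular
  graphs are sparse and full of articulation points, so the graph is split
  into biconnected blocks, the longest path is found exhaustively inside
  each (small) block, and entries across blocks are the sums of
  block-internal longest paths along the unique articulation-point chain
  joining the two atoms.
* **Chi** — connected subgraphs of each class and order are enumerated by
  depth-first search rather than pattern matching, so arbitrary orders are
  reachable: χ = Σ_subgraphs Π_{atoms} δ^(−1/2) with δ either the heavy-atom
  degree or the Kier–Hall valence delta δᵛ = (Zᵛ−h)/(Z−Zᵛ−1) (Z > 10) or
  Zᵛ−h otherwise.
* **Framework** — the framework atom count is maintained directly during
  iterative pruning of terminal atoms; the scaffold is never materialised.
* **MolecularId** — bond weights (δᵤδᵥ)^(−1/2) and running path products are
  cached and extended incrementally during the path search instead of being
  recomputed per path.

Spectral aggregates (`LogEE`) evaluate the log-sum-exp of the eigenvalue
spectrum with the shifted form `x* + log Σ exp(xᵢ − x*)`, which stays finite
where the naive `log Σ exp(xᵢ)` overflows.

Failures never abort a batch: each is returned as a typed `MissingValue`
carrying its cause (parse failure, disconnected graph, division by zero,
…), and parallel batch computation is guaranteed to return exactly the
serial results in input order.

## Worked example

```python
from topodesc import Calculator, from_smiles

calc = Calculator(["WienerIndex", "ZagrebIndex", "BalabanJ",
                   "Framework", "DetourMatrix"])
res = calc(from_smiles("CC(C)c1ccc(C)cc1", name="p-cymene"))
for key in ("WPath", "WPol", "Zagreb1", "Zagreb2", "BalabanJ",
            "fMF", "DetourIndex"):
    print(f"{key:12s} {res[key]}")
```

prints

```
WPath        120
WPol         11
Zagreb1      46.0
Zagreb2      50.0
BalabanJ     2.2599025962240935
fMF          0.6
DetourIndex  204
```

`WPath = 120` is the half-sum of all topological distances over the ten
heavy atoms; `WPol = 11` counts atom pairs exactly three bonds apart;
`Zagreb1/Zagreb2` sum squared degrees and bonded degree products;
`BalabanJ` is the distance-connectivity index; `fMF = 0.6` says six of the
ten heavy atoms survive iterative terminal pruning (the aromatic ring);
`DetourIndex = 204` is the half-sum of longest-path distances, larger than
`WPath` because paths around the ring may take the long way.

The same object is a scikit-learn transformer:

```python
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

pipe = make_pipeline(Calculator("all"), StandardScaler())
X = pipe.fit_transform([from_smiles(s) for s in smiles_list])
```

Descriptor arithmetic builds interaction features:

```python
z1, z2 = preset("ZagrebIndex")[:2]
calc = Calculator([z1 * z2])      # evaluates the product term per molecule
```

And the CLI writes a CSV table, in parallel, for SMILES or SDF input:

```bash
topodesc molecules.smi -o descriptors.csv -p 4 --families WienerIndex,Chi
```

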