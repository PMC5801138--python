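"""Reading molecules from SMILES and SDF (MDL V2000) sources.

RDKit does the parsing and sanitisation (including aromaticity perception,
whose model is recorded in the graph metadata); records are converted into
:class:`~topodesc.graph.MolecularGraph` at this boundary, translating SDF's
1-based atom numbering to the package's 0-based convention. A record that
fails to parse becomes a placeholder graph flagged with ``parse_error`` so a
batch never aborts on one bad molecule.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

from rdkit import Chem, RDLogger

from .graph import AROMATIC_BOND, AtomRecord, MolecularGraph

RDLogger.DisableLog("rdApp.*")

_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_BOND,
}

_PT = Chem.GetPeriodicTable()


def from_rdkit(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    """Convert an RDKit molecule (already sanitised) to a MolecularGraph."""
    atoms = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        atoms.append(
            AtomRecord(
                element=atom.GetSymbol(),
                atomic_number=z,
                formal_charge=atom.GetFormalCharge(),
                implicit_hydrogens=atom.GetTotalNumHs(includeNeighbors=False),
                aromatic=atom.GetIsAromatic(),
                valence_electrons=_PT.GetNOuterElecs(z),
            )
        )
    bonds = tuple(
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDERS.get(b.GetBondType(), 1.0),
        )
        for b in mol.GetBonds()
    )
    if not name and mol.HasProp("_Name"):
        name = mol.GetProp("_Name")
    return MolecularGraph(
        atoms=tuple(atoms),
        bonds=bonds,
        name=name,
        meta=(("aromaticity_model", "rdkit-default"),),
    )


def _parse_failure(name: str, message: str) -> MolecularGraph:
    return MolecularGraph(name=name, parse_error=message)


def _read_smiles_text(text: str) -> list[MolecularGraph]:
    out: list[MolecularGraph] = []
    record = 0
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        record += 1
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"mol{record}"
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            out.append(_parse_failure(name, f"unparseable SMILES: {smiles!r}"))
        else:
            out.append(from_rdkit(rdmol, name=name))
    return out


def _read_sdf_text(text: str) -> list[MolecularGraph]:
    out: list[MolecularGraph] = []
    # split into records on the $$$$ delimiter, preserving input order
    blocks = text.split("$$$$")
    records = [b for b in blocks if b.strip()]
    for idx, block in enumerate(records, start=1):
        block = block.lstrip("\n")
        title = block.splitlines()[0].strip() if block.splitlines() else ""
        name = title or f"mol{idx}"
        rdmol = Chem.MolFromMolBlock(block, sanitize=True, removeHs=False)
        if rdmol is None:
            out.append(_parse_failure(name, f"unparseable SDF record {idx}"))
        else:
            out.append(from_rdkit(rdmol, name=name))
    return out


def read_molecules(path_or_text: str | os.PathLike, format: str = "smiles") -> list[MolecularGraph]:
    """Read molecules from a file path or raw text.

    Parameters
    ----------
    path_or_text:
        Path to a file, or the raw text of a SMILES list / SDF. A string
        that names an existing file is treated as a path.
    format:
        ``"smiles"`` (one record per line, optional whitespace-separated
        name, blank lines skipped), ``"sdf"`` (V2000 blocks, record name
        from the title line) or ``"auto"`` (by file extension; defaults to
        SMILES for raw text).

    Returns
    -------
    list of MolecularGraph, one per record in input order; unparseable
    records yield placeholder graphs with ``parse_error`` set.
    """
    text: str
    is_path = isinstance(path_or_text, os.PathLike) or (
        isinstance(path_or_text, str)
        and ("\n" not in path_or_text)
        and os.path.exists(path_or_text)
    )
    if isinstance(path_or_text, os.PathLike) and not os.path.exists(path_or_text):
        raise FileNotFoundError(path_or_text)
    if is_path:
        path = Path(path_or_text)
        text = path.read_text()
        if format == "auto":
            format = "sdf" if path.suffix.lower() in (".sdf", ".mol") else "smiles"
    else:
        text = str(path_or_text)
        if format == "auto":
            format = "sdf" if "V2000" in text else "smiles"

    if format == "smiles":
        return _read_smiles_text(text)
    if format == "sdf":
        return _read_sdf_text(text)
    raise ValueError(f"unknown format {format!r}")


def from_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a single SMILES string (raises on failure, unlike batch reads)."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return from_rdkit(rdmol, name=name or smiles)
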