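"""Typed heavy-atom molecular graphs and the LogBB endpoint utility.

Structures are parsed with RDKit from SMILES or SDF (V2000) input and
normalized into a light :class:`MolecularGraph`: heavy atoms only, with
hydrogens folded into per-atom counts, aromaticity perceived by RDKit's
default model, stereochemistry discarded (fragments are 2D topological),
and only the largest connected component retained (salt/solvent stripping).
Formal charges are retained; no neutralization is applied.

The endpoint is LogBB = log10(C_brain / C_plasma), the log ratio of total
brain to plasma concentration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RD_TO_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RD = {v: k for k, v in _RD_TO_ORDER.items()}


class StructureParseError(ValueError):
    """Raised when a structure cannot be parsed; carries the offending id."""

    def __init__(self, message: str, compound_id: str = ""):
        super().__init__(message)
        self.compound_id = compound_id


@dataclass(frozen=True)
class Atom:
    """A heavy atom with its hydrogen count and valence environment."""

    element: str
    formal_charge: int = 0
    n_hydrogens: int = 0
    valence_state: int = 0  # total bond-order sum including hydrogens
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    """An undirected bond between two heavy-atom indices."""

    i: int
    j: int
    order: str  # one of BOND_ORDERS

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must be distinct")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class MolecularGraph:
    """Heavy-atom graph with typed atoms and bonds."""

    atoms: list[Atom]
    bonds: list[Bond]
    id: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b} out of atom range")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def bond_lookup(self) -> dict[tuple[int, int], str]:
        """Map of sorted endpoint pairs to bond order."""
        return {
            (min(b.i, b.j), max(b.i, b.j)): b.order for b in self.bonds
        }

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit molecule from the typed graph."""
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNumExplicitHs(a.n_hydrogens)
            ra.SetNoImplicit(True)
            ra.SetIsAromatic(a.aromatic)
            rw.AddAtom(ra)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, _ORDER_TO_RD[b.order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


@dataclass
class CompoundRecord:
    """A compound with optional experimental LogBB (log10 units)."""

    id: str
    graph: MolecularGraph
    logbb: float | None = None
    smiles: str = field(default="", repr=False)

    def __post_init__(self):
        if self.logbb is not None and not math.isfinite(self.logbb):
            raise ValueError(f"non-finite LogBB for {self.id}")


def _graph_from_mol(mol: Chem.Mol, compound_id: str = "") -> MolecularGraph:
    # keep the largest connected component (salt/mixture stripping)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            valence_state=a.GetTotalValence(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RD_TO_ORDER.get(b.GetBondType())
        if order is None:
            raise StructureParseError(
                f"unsupported bond type {b.GetBondType()}", compound_id
            )
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds, id=compound_id)


def parse_structure(
    text: str, dialect: str = "smiles", compound_id: str = ""
) -> MolecularGraph:
    """Parse a SMILES string or an SDF/Mol V2000 block into a MolecularGraph.

    Hydrogens are folded into per-atom counts; only heavy atoms appear in
    the graph.  Aromaticity is perceived by RDKit's default model so that
    equal structures yield equal graphs regardless of input atom order.
    """
    if dialect == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif dialect == "sdf":
        mol = Chem.MolFromMolBlock(text, removeHs=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if mol is None:
        raise StructureParseError(
            f"cannot parse {dialect} input for {compound_id or text!r}",
            compound_id,
        )
    if mol.GetNumAtoms() == 0:
        raise StructureParseError("empty structure", compound_id)
    return _graph_from_mol(mol, compound_id)


def compute_logbb(c_brain: float, c_plasma: float) -> float:
    """LogBB = log10(C_brain / C_plasma); both concentrations in the same units."""
    if c_brain <= 0 or c_plasma <= 0:
        raise ValueError("concentrations must be strictly positive")
    return math.log10(c_brain / c_plasma)


def canonical_structure_key(graph: MolecularGraph) -> str:
    """Order-independent structure key: canonical non-isomeric SMILES.

    Equal for any two graphs that are isomorphic with identical atom and
    bond typing; used for duplicate detection and dataset overlap analysis.
    """
    return Chem.MolToSmiles(graph.to_rdkit(), isomericSmiles=False)


def read_smiles_csv(
    path: str | Path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    logbb_col: str = "logbb",
) -> tuple[list[CompoundRecord], list[dict]]:
    """Read a compound table; returns (records, rejects).

    Rows that fail to parse are routed to the rejects list with a reason,
    never raised.
    """
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cid = str(row.get(id_col, "")).strip()
            smi = str(row.get(smiles_col, "")).strip()
            raw = row.get(logbb_col)
            logbb = None
            if raw not in (None, ""):
                try:
                    logbb = float(raw)
                except ValueError:
                    rejects.append({"id": cid, "reason": "bad_endpoint", "input": raw})
                    continue
            try:
                graph = parse_structure(smi, "smiles", cid)
            except StructureParseError as exc:
                rejects.append({"id": cid, "reason": "parse_failure", "input": smi,
                                "detail": str(exc)})
                continue
            records.append(CompoundRecord(cid, graph, logbb, smiles=smi))
    return records, rejects


def read_sdf(path: str | Path, logbb_prop: str = "logbb") -> tuple[list[CompoundRecord], list[dict]]:
    """Read a V2000 SDF file; LogBB taken from the named property if present."""
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        cid = f"sdf_{i}"
        if mol is None:
            rejects.append({"id": cid, "reason": "parse_failure", "input": f"record {i}"})
            continue
        if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        logbb = None
        if mol.HasProp(logbb_prop):
            try:
                logbb = float(mol.GetProp(logbb_prop))
            except ValueError:
                rejects.append({"id": cid, "reason": "bad_endpoint",
                                "input": mol.GetProp(logbb_prop)})
                continue
        try:
            records.append(CompoundRecord(cid, _graph_from_mol(mol, cid), logbb))
        except StructureParseError as exc:
            rejects.append({"id": cid, "reason": "parse_failure", "detail": str(exc)})
    return records, rejects


def write_key_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Export id, canonical structure key and LogBB as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "structure_key", "logbb"])
        for rec in records:
            writer.writerow([
                rec.id,
                canonical_structure_key(rec.graph),
                "" if rec.logbb is None else rec.logbb,
            ])
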