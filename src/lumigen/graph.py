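"""Molecular graph data model and SMILES interoperability.

Molecules are heavy-atom graphs: hydrogens are never stored as nodes, only as
per-atom explicit counts plus whatever implicit hydrogens the valence model
assigns.  Parsing, canonicalization and final-molecule sanitization (including
kekulizability of aromatic systems) are delegated to RDKit; the in-house
:class:`MolecularGraph` exists so that partially built molecules — which are not
generally sanitizable — can be represented, edited and valence-checked during
autoregressive generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomDescriptor",
    "BondType",
    "MolecularGraph",
    "ParseError",
    "ValenceReport",
    "DEFAULT_ELEMENTS",
    "parse_structure",
    "write_structure",
    "canonical_form",
    "validate_valence",
    "conjugated_components",
    "max_valence",
]

#: Default supported element set (atomic numbers): the common organic palette.
DEFAULT_ELEMENTS = frozenset({5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53})

#: Elements that may carry aromatic bonds.
AROMATIC_ELEMENTS = frozenset({5, 6, 7, 8, 15, 16})

# Maximum total valence (bond order + hydrogens) for the neutral element.
_MAX_VALENCE = {5: 3, 6: 4, 7: 3, 8: 2, 9: 1, 14: 4, 15: 5, 16: 6, 17: 1, 35: 1, 53: 1}

_SYMBOL = {5: "B", 6: "C", 7: "N", 8: "O", 9: "F", 14: "Si", 15: "P", 16: "S",
           17: "Cl", 35: "Br", 53: "I"}


class ParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid molecule."""


class BondType(Enum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4

    @property
    def order(self) -> float:
        """Integer bond order; aromatic bonds are handled separately by the
        valence model (see :func:`lumigen.trajectory.effective_valence`)."""
        return {BondType.SINGLE: 1.0, BondType.DOUBLE: 2.0,
                BondType.TRIPLE: 3.0, BondType.AROMATIC: 1.0}[self]


_TO_RDKIT_BOND = {
    BondType.SINGLE: Chem.BondType.SINGLE,
    BondType.DOUBLE: Chem.BondType.DOUBLE,
    BondType.TRIPLE: Chem.BondType.TRIPLE,
    BondType.AROMATIC: Chem.BondType.AROMATIC,
}
_FROM_RDKIT_BOND = {v: k for k, v in _TO_RDKIT_BOND.items()}


@dataclass(frozen=True, order=True)
class AtomDescriptor:
    """Heavy atom as it appears in an Add action: element, charge and the
    number of hydrogens that must be written explicitly (e.g. pyrrole N–H)."""

    atomic_number: int
    formal_charge: int = 0
    explicit_h: int = 0

    def __post_init__(self) -> None:
        if self.atomic_number not in _MAX_VALENCE:
            raise ValueError(f"unsupported element Z={self.atomic_number}")
        if not -2 <= self.formal_charge <= 2:
            raise ValueError(f"formal charge {self.formal_charge} out of [-2, 2]")
        if self.explicit_h < 0 or self.explicit_h > max_valence(
            self.atomic_number, self.formal_charge
        ):
            raise ValueError(
                f"explicit H count {self.explicit_h} exceeds valence of "
                f"{_SYMBOL[self.atomic_number]}"
            )

    @property
    def symbol(self) -> str:
        return _SYMBOL[self.atomic_number]

    def to_json(self) -> dict:
        return {
            "z": self.atomic_number,
            "charge": self.formal_charge,
            "explicit_h": self.explicit_h,
        }

    @classmethod
    def from_json(cls, d: dict) -> "AtomDescriptor":
        return cls(d["z"], d["charge"], d["explicit_h"])


def max_valence(atomic_number: int, formal_charge: int = 0) -> int:
    """Maximum allowed total valence for an element/charge combination.

    Cations of N, O, P, S gain a bond per unit charge (ammonium, oxonium);
    cations of C/B and all anions lose one, except borates which gain.
    """
    base = _MAX_VALENCE[atomic_number]
    q = formal_charge
    if q == 0:
        return base
    if q > 0:
        return base + q if atomic_number in (7, 8, 15, 16) else max(base - q, 0)
    if atomic_number == 5:  # borate
        return base + abs(q)
    return max(base - abs(q), 0)


class MolecularGraph:
    """Editable heavy-atom graph.

    Atoms are indexed by insertion order; bonds are stored once per unordered
    pair.  An atom is flagged aromatic exactly when it carries at least one
    aromatic bond, so the flag never needs separate bookkeeping.
    """

    __slots__ = ("atoms", "_bonds", "_adj")

    def __init__(self) -> None:
        self.atoms: list[AtomDescriptor] = []
        self._bonds: dict[tuple[int, int], BondType] = {}
        self._adj: list[dict[int, BondType]] = []

    # -- construction -----------------------------------------------------

    def add_atom(self, atom: AtomDescriptor) -> int:
        self.atoms.append(atom)
        self._adj.append({})
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, bond: BondType) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i}, {j}) references a missing atom (n={n})")
        if i == j:
            raise ValueError(f"self-loop on atom {i}")
        key = (min(i, j), max(i, j))
        if key in self._bonds:
            raise ValueError(f"duplicate bond between atoms {i} and {j}")
        self._bonds[key] = bond
        self._adj[i][j] = bond
        self._adj[j][i] = bond

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph()
        g.atoms = list(self.atoms)
        g._bonds = dict(self._bonds)
        g._adj = [dict(d) for d in self._adj]
        return g

    # -- inspection -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def bonds(self) -> dict[tuple[int, int], BondType]:
        return self._bonds

    def bond_between(self, i: int, j: int) -> BondType | None:
        return self._adj[i].get(j)

    def neighbors(self, i: int) -> dict[int, BondType]:
        return self._adj[i]

    def aromatic_bond_count(self, i: int) -> int:
        return sum(1 for b in self._adj[i].values() if b is BondType.AROMATIC)

    def is_aromatic_atom(self, i: int) -> bool:
        return self.aromatic_bond_count(i) > 0

    @property
    def aromatic_flags(self) -> list[bool]:
        return [self.is_aromatic_atom(i) for i in range(self.n_atoms)]

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return False
        seen = {0}
        stack = [0]
        while stack:
            for j in self._adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms

    def permuted(self, order: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms so that new index k holds old atom ``order[k]``."""
        inv = {old: new for new, old in enumerate(order)}
        g = MolecularGraph()
        for old in order:
            g.add_atom(self.atoms[old])
        for (i, j), b in self._bonds.items():
            g.add_bond(inv[i], inv[j], b)
        return g

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MolecularGraph)
            and self.atoms == other.atoms
            and self._bonds == other._bonds
        )

    def __repr__(self) -> str:
        return f"<MolecularGraph {self.n_atoms} atoms, {len(self._bonds)} bonds>"

    # -- RDKit interchange -------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        mol = Chem.RWMol()
        for a in self.atoms:
            atom = Chem.Atom(a.atomic_number)
            atom.SetFormalCharge(a.formal_charge)
            atom.SetNumExplicitHs(a.explicit_h)
            mol.AddAtom(atom)
        for (i, j), b in self._bonds.items():
            mol.AddBond(i, j, _TO_RDKIT_BOND[b])
        for i in range(self.n_atoms):
            if self.is_aromatic_atom(i):
                mol.GetAtomWithIdx(i).SetIsAromatic(True)
        out = mol.GetMol()
        if sanitize:
            Chem.SanitizeMol(out)
        return out

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        g = cls()
        for atom in mol.GetAtoms():
            g.add_atom(
                AtomDescriptor(
                    atom.GetAtomicNum(),
                    atom.GetFormalCharge(),
                    atom.GetNumExplicitHs(),
                )
            )
        for bond in mol.GetBonds():
            g.add_bond(
                bond.GetBeginAtomIdx(),
                bond.GetEndAtomIdx(),
                _FROM_RDKIT_BOND[bond.GetBondType()],
            )
        return g


# -- SMILES I/O -------------------------------------------------------------


def parse_structure(
    smiles: str, elements: frozenset[int] = DEFAULT_ELEMENTS
) -> MolecularGraph:
    """Parse a SMILES string into a sanitized :class:`MolecularGraph`.

    Aromaticity is perceived and implicit hydrogens assigned by RDKit's
    sanitization.  Atoms outside the supported element set are rejected.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable or valence-violating SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in elements:
            raise ParseError(
                f"unsupported element {atom.GetSymbol()} (atom {atom.GetIdx()}) "
                f"in {smiles!r}"
            )
    return MolecularGraph.from_rdkit(mol)


def write_structure(g: MolecularGraph) -> str:
    """Canonical SMILES of a completed, valid graph."""
    return Chem.MolToSmiles(g.to_rdkit(sanitize=True))


def canonical_form(g: MolecularGraph) -> str:
    """Order-independent canonical string; the database key used throughout."""
    try:
        return write_structure(g)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"cannot canonicalize invalid graph: {exc}") from exc


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string directly (convenience for DB keys)."""
    return canonical_form(parse_structure(smiles))


def fragment_smiles(g: MolecularGraph) -> str:
    """Best-effort SMILES of a possibly incomplete fragment, for inspection.

    Partial aromatic systems are not kekulizable, so full sanitization is
    skipped; ring perception alone is enough for the writer.
    """
    if g.n_atoms == 0:
        return ""
    mol = g.to_rdkit(sanitize=False)
    try:
        Chem.FastFindRings(mol)
        return Chem.MolToSmiles(mol, canonical=False)
    except Exception:
        return "<unwritable fragment>"


# -- validity ---------------------------------------------------------------


@dataclass
class ValenceReport:
    ok: bool
    problems: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_valence(g: MolecularGraph) -> ValenceReport:
    """Full-molecule validity: every atom's valence admissible and every
    aromatic system kekulizable, per RDKit sanitization.

    Returns a report rather than raising, with one diagnostic per offence.
    """
    try:
        g.to_rdkit(sanitize=True)
        return ValenceReport(ok=True)
    except Exception as exc:
        problems = [f"sanitization failed: {exc}"]
    # per-atom diagnostics on failure, using the conventional
    # 1.5-per-aromatic-bond sum (heuristic: aromatic heteroatoms donating a
    # lone pair legitimately exceed it, but sanitization has the final word)
    for i, a in enumerate(g.atoms):
        total = sum(b.order for b in g.neighbors(i).values())
        if g.is_aromatic_atom(i):
            total += 0.5 * g.aromatic_bond_count(i)
        total += a.explicit_h
        if total > max_valence(a.atomic_number, a.formal_charge) + 0.5:
            problems.append(
                f"atom {i} ({a.symbol}{a.formal_charge:+d}): bond order sum "
                f"{total} exceeds max valence "
                f"{max_valence(a.atomic_number, a.formal_charge)}"
            )
    return ValenceReport(ok=False, problems=problems)


def is_valid_molecule(g: MolecularGraph) -> bool:
    """Completed-molecule predicate: sanitizable and connected."""
    if g.n_atoms == 0 or not g.is_connected():
        return False
    try:
        g.to_rdkit(sanitize=True)
    except Exception:
        return False
    return True


# -- conjugation ------------------------------------------------------------


def conjugated_components(g: MolecularGraph) -> list[list[tuple[int, int, BondType]]]:
    """Partition the conjugated bonds into connected components.

    A bond is conjugated when it participates in an alternating or aromatic
    pi system (sp/sp2 backbone, including lone-pair conjugation), as flagged
    by RDKit's conjugation perception.  Each component is returned as a list
    of ``(i, j, BondType)`` with ``i < j``, sorted for determinism.
    """
    mol = g.to_rdkit(sanitize=True)
    edges = []
    for bond in mol.GetBonds():
        if bond.GetIsConjugated():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            edges.append((min(i, j), max(i, j)))
    if not edges:
        return []
    # union-find over atoms touched by conjugated bonds
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[tuple[int, int, BondType]]] = {}
    for i, j in edges:
        groups.setdefault(find(i), []).append((i, j, g.bond_between(i, j)))
    return [sorted(v) for _, v in sorted(groups.items())]


def _iter_smiles_lines(path: str) -> Iterator[tuple[str, str | None]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            yield parts[0], (parts[1] if len(parts) > 1 else None)


def read_smiles_file(path: str) -> list[str]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    return [smi for smi, _ in _iter_smiles_lines(path)]


def write_smiles_file(path: str, smiles: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
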