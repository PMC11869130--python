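"""Action-sequence decomposition and replay of molecular graphs.

A molecule is built by three kinds of actions — Add an atom with a bond,
Connect two existing atoms (ring closure), Terminate — and training data for
the conditional model is produced by decomposing each molecule into such a
sequence with a stochastic depth-first search: the start atom and the child
visit order are drawn from a seeded RNG, so one molecule yields many action
sequences, all replaying to the same canonical structure.

Legality of actions on a partial graph is defined by an intermediate valence
model.  Aromatic bonds contribute one unit of valence per bond plus a single
pi increment for atoms that donate one electron to the ring (carbon, and
nitrogen without hydrogen); lone-pair donors (O, S, N–H) get no increment.
Two extra rules keep every reachable state workable: an atom with exactly one
aromatic bond must keep a free valence (a ring in progress can always be
extended or closed), and a ring-closing aromatic Connect must leave the cyclic
aromatic core kekulizable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Union


import numpy as np
from rdkit import Chem

from .graph import (
    AROMATIC_ELEMENTS,
    AtomDescriptor,
    BondType,
    MolecularGraph,
    canonical_form,
    fragment_smiles,
    is_valid_molecule,
    max_valence,
)

__all__ = [
    "AddAction",
    "ConnectAction",
    "TerminateAction",
    "Action",
    "Trajectory",
    "TrajectoryError",
    "AtomVocabulary",
    "ActionSpace",
    "legal_actions",
    "apply_action",
    "decompose",
    "replay",
    "intermediate_valid",
    "free_valence",
]

BOND_TYPES = (BondType.SINGLE, BondType.DOUBLE, BondType.TRIPLE, BondType.AROMATIC)
N_BOND_TYPES = len(BOND_TYPES)
_BOND_INDEX = {b: k for k, b in enumerate(BOND_TYPES)}


class TrajectoryError(ValueError):
    """Structural error while applying or replaying actions."""


@dataclass(frozen=True)
class AddAction:
    """Add ``atom`` bonded to existing atom ``attach_to`` with ``bond``.

    The very first atom of a molecule has ``attach_to`` and ``bond`` None.
    """

    atom: AtomDescriptor
    attach_to: int | None = None
    bond: BondType | None = None

    def to_json(self) -> dict:
        return {
            "kind": "add",
            "atom": self.atom.to_json(),
            "attach_to": self.attach_to,
            "bond": self.bond.name if self.bond else None,
        }


@dataclass(frozen=True)
class ConnectAction:
    """Bond two existing atoms ``i`` and ``j`` — always ring-forming on a
    connected partial graph."""

    i: int
    j: int
    bond: BondType

    def to_json(self) -> dict:
        return {"kind": "connect", "i": self.i, "j": self.j, "bond": self.bond.name}


@dataclass(frozen=True)
class TerminateAction:
    def to_json(self) -> dict:
        return {"kind": "terminate"}


Action = Union[AddAction, ConnectAction, TerminateAction]


def action_from_json(d: dict) -> Action:
    kind = d["kind"]
    if kind == "add":
        return AddAction(
            AtomDescriptor.from_json(d["atom"]),
            d["attach_to"],
            BondType[d["bond"]] if d["bond"] else None,
        )
    if kind == "connect":
        return ConnectAction(d["i"], d["j"], BondType[d["bond"]])
    if kind == "terminate":
        return TerminateAction()
    raise ValueError(f"unknown action kind {kind!r}")


# -- intermediate valence model ---------------------------------------------


def _pi_increment(atom: AtomDescriptor) -> int:
    """Pi-electron valence increment for an atom once it carries an aromatic
    bond: 1 for single-electron donors, 0 for lone-pair donors."""
    z = atom.atomic_number
    if z in (5, 6):
        return 1
    if z == 7 and atom.explicit_h == 0:
        return 1
    return 0


def effective_valence(g: MolecularGraph, i: int) -> float:
    a = g.atoms[i]
    total = float(a.explicit_h)
    n_arom = 0
    for b in g.neighbors(i).values():
        if b is BondType.AROMATIC:
            n_arom += 1
            total += 1.0
        else:
            total += b.order
    if n_arom > 0:
        total += _pi_increment(a)
    return total


def valence_arrays(g: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
    """Free valence and aromatic-bond count of every atom, in one pass."""
    A = g.n_atoms
    order = np.zeros(A)
    n_arom = np.zeros(A, dtype=int)
    for (i, j), b in g.bonds.items():
        if b is BondType.AROMATIC:
            n_arom[i] += 1
            n_arom[j] += 1
            order[i] += 1.0
            order[j] += 1.0
        else:
            order[i] += b.order
            order[j] += b.order
    free = np.empty(A)
    for i, a in enumerate(g.atoms):
        total = order[i] + a.explicit_h
        if n_arom[i] > 0:
            total += _pi_increment(a)
        free[i] = max_valence(a.atomic_number, a.formal_charge) - total
    return free, n_arom


def free_valence(g: MolecularGraph, i: int) -> float:
    a = g.atoms[i]
    return max_valence(a.atomic_number, a.formal_charge) - effective_valence(g, i)


def _aromatic_component_labels(g: MolecularGraph) -> dict[int, int]:
    """Connected-component label of each atom in the aromatic-bond subgraph."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j), b in g.bonds.items():
        if b is BondType.AROMATIC:
            parent.setdefault(i, i)
            parent.setdefault(j, j)
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return {a: find(a) for a in parent}


def _aromatic_adjacency(g: MolecularGraph) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for (i, j), b in g.bonds.items():
        if b is BondType.AROMATIC:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
    return adj


def _aromatic_distance(
    adj: dict[int, list[int]], src: int, skip: tuple[int, int] | None = None
) -> dict[int, int]:
    """BFS bond distances from ``src`` inside the aromatic subgraph,
    optionally ignoring one edge."""
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if skip and {u, v} == set(skip):
                    continue
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


#: allowed aromatic ring sizes; the standard 5- to 7-membered systems
MIN_AROMATIC_RING = 5
MAX_AROMATIC_RING = 7
#: cap on atoms per connected aromatic system (about four fused rings): the
#: action model targets small-molecule chromophores, and the cap also bounds
#: the cost of legality checks on degenerate states
MAX_AROMATIC_SYSTEM = 20


def _component_ok(g: MolecularGraph, atoms: set[int],
                  adj: dict[int, list[int]]) -> bool:
    """Ring-size and kekulizability rules for one aromatic component."""
    if len(atoms) > MAX_AROMATIC_SYSTEM:
        return False
    cyclic: list[tuple[int, int]] = []
    for i in atoms:
        for j in adj.get(i, ()):
            if i < j:
                dist = _aromatic_distance(adj, i, skip=(i, j))
                if j in dist:  # edge lies on a cycle
                    ring = dist[j] + 1
                    if not MIN_AROMATIC_RING <= ring <= MAX_AROMATIC_RING:
                        return False
                    cyclic.append((i, j))
    if not cyclic:
        return True
    return _cyclic_core_sanitizable(g, cyclic)


def _cyclic_core_sanitizable(g: MolecularGraph,
                             cyclic: list[tuple[int, int]]) -> bool:
    """Is the given set of cyclic aromatic bonds a self-consistent
    (kekulizable) aromatic system once free valences are hydrogen-filled?"""
    atoms = sorted({a for e in cyclic for a in e})
    remap = {a: k for k, a in enumerate(atoms)}
    mol = Chem.RWMol()
    for a in atoms:
        d = g.atoms[a]
        atom = Chem.Atom(d.atomic_number)
        atom.SetFormalCharge(d.formal_charge)
        atom.SetNumExplicitHs(d.explicit_h)
        atom.SetIsAromatic(True)
        mol.AddAtom(atom)
    for i, j in cyclic:
        mol.AddBond(remap[i], remap[j], Chem.BondType.AROMATIC)
    try:
        Chem.SanitizeMol(mol.GetMol())
    except Exception:
        return False
    return True


def intermediate_valid(g: MolecularGraph) -> bool:
    """Validity predicate for partial (in-construction) graphs.

    Accepts states that can still be completed: valences within bounds,
    aromatic bonds only on aromatic-capable elements with at most three per
    atom, a reserved free valence on atoms with a single aromatic bond, each
    connected aromatic system bounded in size with rings restricted to the
    standard 5-7-membered sizes, and every cyclic aromatic core kekulizable.
    """
    for i, a in enumerate(g.atoms):
        n_arom = g.aromatic_bond_count(i)
        if n_arom > 0 and a.atomic_number not in AROMATIC_ELEMENTS:
            return False
        if n_arom > 3:
            return False
        free = free_valence(g, i)
        if free < 0:
            return False
        if n_arom == 1 and free < 1:
            return False
    adj = _aromatic_adjacency(g)
    labels = _aromatic_component_labels(g)
    comps: dict[int, set[int]] = {}
    for a, lab in labels.items():
        comps.setdefault(lab, set()).add(a)
    return all(_component_ok(g, atoms, adj) for atoms in comps.values())


# -- applying actions --------------------------------------------------------


def apply_action(g: MolecularGraph, action: Action) -> MolecularGraph:
    """Return a new graph with ``action`` applied.

    Only structural errors are raised (bad indices, duplicate bonds); chemical
    legality is the business of :func:`legal_actions`.
    """
    out = g.copy()
    try:
        if isinstance(action, AddAction):
            if action.attach_to is None:
                if g.n_atoms != 0 or action.bond is not None:
                    raise TrajectoryError(
                        "unattached Add is only legal as the first action"
                    )
                out.add_atom(action.atom)
            else:
                if action.bond is None:
                    raise TrajectoryError("attached Add requires a bond type")
                new = out.add_atom(action.atom)
                out.add_bond(action.attach_to, new, action.bond)
        elif isinstance(action, ConnectAction):
            out.add_bond(action.i, action.j, action.bond)
        elif isinstance(action, TerminateAction):
            pass
        else:  # pragma: no cover
            raise TrajectoryError(f"unknown action {action!r}")
    except (IndexError, ValueError) as exc:
        if isinstance(exc, TrajectoryError):
            raise
        raise TrajectoryError(str(exc)) from exc
    return out


# -- vocabulary --------------------------------------------------------------


class AtomVocabulary:
    """The Add-action atom alphabet, normally harvested from training data."""

    def __init__(self, atoms: Iterable[AtomDescriptor]):
        self.atoms: list[AtomDescriptor] = sorted(set(atoms))
        if not self.atoms:
            raise ValueError("empty atom vocabulary")
        self._index = {a: k for k, a in enumerate(self.atoms)}
        # per (vocab, bond type): is the new atom's valence admissible, with a
        # reserved slot when it arrives on an aromatic bond
        V = len(self.atoms)
        self.feasible = np.zeros((V, N_BOND_TYPES), dtype=bool)
        for v, a in enumerate(self.atoms):
            mv = max_valence(a.atomic_number, a.formal_charge)
            for b, bt in enumerate(BOND_TYPES):
                if bt is BondType.AROMATIC:
                    if a.atomic_number not in AROMATIC_ELEMENTS:
                        continue
                    left = mv - 1 - _pi_increment(a) - a.explicit_h
                    self.feasible[v, b] = left >= 1
                else:
                    self.feasible[v, b] = mv - bt.order - a.explicit_h >= 0

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomDescriptor]:
        return iter(self.atoms)

    def index(self, atom: AtomDescriptor) -> int:
        return self._index[atom]

    def __contains__(self, atom: AtomDescriptor) -> bool:
        return atom in self._index

    @classmethod
    def from_molecules(cls, mols: Iterable[MolecularGraph]) -> "AtomVocabulary":
        seen: set[AtomDescriptor] = set()
        for g in mols:
            seen.update(g.atoms)
        return cls(seen)

    def to_json(self) -> list[dict]:
        return [a.to_json() for a in self.atoms]

    @classmethod
    def from_json(cls, data: list[dict]) -> "AtomVocabulary":
        return cls(AtomDescriptor.from_json(d) for d in data)


# -- legal action enumeration ------------------------------------------------


class ActionSpace:
    """Deterministic enumeration of the candidate action space of a state
    with a boolean legality mask.

    Candidate layout: index 0 is Terminate; then Add actions ordered by
    (attachment atom, vocabulary atom, bond type); then Connect actions by
    (i, j, bond type) over pairs i < j.  On the empty state the Adds are the
    unattached first-atom additions, one per vocabulary entry.
    """

    def __init__(self, state: MolecularGraph, vocab: AtomVocabulary):
        self.state = state
        self.vocab = vocab
        A, V, B = state.n_atoms, len(vocab), N_BOND_TYPES
        self.n_atoms = A

        if A == 0:
            self.n_candidates = 1 + V
            mask = np.zeros(self.n_candidates, dtype=bool)
            mask[1:] = True  # any single atom is a legal start
            self.mask = mask
            self._pairs = np.zeros((0, 2), dtype=int)
            return

        free, n_arom = valence_arrays(state)
        pi_inc = np.array([_pi_increment(a) for a in state.atoms])
        capable = np.array(
            [a.atomic_number in AROMATIC_ELEMENTS for a in state.atoms]
        )

        comp = _aromatic_component_labels(state)
        comp_size: dict[int, int] = {}
        for a, lab in comp.items():
            comp_size[lab] = comp_size.get(lab, 0) + 1

        def _size(i: int) -> int:
            return comp_size.get(comp.get(i, -1), 1)

        # minimum free valence an existing atom needs to accept one more bond
        # of each type, including the single-aromatic-bond reservation
        need = np.empty((A, B))
        for b, bt in enumerate(BOND_TYPES):
            if bt is BondType.AROMATIC:
                first = n_arom == 0
                need[:, b] = np.where(first, 1 + pi_inc + 1, 1.0)
                full_system = np.array(
                    [_size(i) + 1 > MAX_AROMATIC_SYSTEM for i in range(A)]
                )
                need[~capable | (n_arom >= 3) | full_system, b] = np.inf
            else:
                need[:, b] = bt.order + (n_arom == 1)

        site_ok = free[:, None] >= need  # (A, B)
        add_mask = site_ok[:, None, :] & vocab.feasible[None, :, :]  # (A, V, B)

        ii, jj = np.triu_indices(A, k=1)
        self._pairs = np.stack([ii, jj], axis=1)
        bonded = np.array(
            [state.bond_between(int(i), int(j)) is not None for i, j in self._pairs],
            dtype=bool,
        )
        conn_mask = site_ok[ii] & site_ok[jj] & ~bonded[:, None]  # (P, B)

        # aromatic Connects: joining two aromatic systems must respect the
        # size cap; closing a ring inside one system needs an allowed ring
        # size (cheap BFS prefilter) and a kekulizable cyclic core (full
        # per-component recheck, only for genuine closures)
        b_arom = _BOND_INDEX[BondType.AROMATIC]
        arom_adj = _aromatic_adjacency(state)
        dist_cache: dict[int, dict[int, int]] = {}
        for p in np.nonzero(conn_mask[:, b_arom])[0]:
            i, j = int(self._pairs[p, 0]), int(self._pairs[p, 1])
            if comp.get(i, -1) != comp.get(j, -2):  # different systems
                if _size(i) + _size(j) > MAX_AROMATIC_SYSTEM:
                    conn_mask[p, b_arom] = False
                continue
            if i not in dist_cache:
                dist_cache[i] = _aromatic_distance(arom_adj, i)
            ring = dist_cache[i].get(j, 10**9) + 1
            if not MIN_AROMATIC_RING <= ring <= MAX_AROMATIC_RING:
                conn_mask[p, b_arom] = False
                continue
            trial = state.copy()
            trial.add_bond(i, j, BondType.AROMATIC)
            trial_adj = _aromatic_adjacency(trial)
            atoms = set(_aromatic_distance(trial_adj, i))
            if not _component_ok(trial, atoms, trial_adj):
                conn_mask[p, b_arom] = False

        term_ok = is_valid_molecule(state)
        self.n_candidates = 1 + A * V * B + len(self._pairs) * B
        mask = np.empty(self.n_candidates, dtype=bool)
        mask[0] = term_ok
        mask[1 : 1 + A * V * B] = add_mask.reshape(-1)
        mask[1 + A * V * B :] = conn_mask.reshape(-1)
        self.mask = mask

    # -- candidate <-> action mapping -------------------------------------

    def action_at(self, idx: int) -> Action:
        A, V, B = self.n_atoms, len(self.vocab), N_BOND_TYPES
        if idx == 0:
            return TerminateAction()
        if A == 0:
            return AddAction(self.vocab.atoms[idx - 1], None, None)
        idx -= 1
        n_add = A * V * B
        if idx < n_add:
            i, rem = divmod(idx, V * B)
            v, b = divmod(rem, B)
            return AddAction(self.vocab.atoms[v], i, BOND_TYPES[b])
        idx -= n_add
        p, b = divmod(idx, B)
        i, j = self._pairs[p]
        return ConnectAction(int(i), int(j), BOND_TYPES[b])

    def index_of(self, action: Action) -> int:
        A, V, B = self.n_atoms, len(self.vocab), N_BOND_TYPES
        if isinstance(action, TerminateAction):
            return 0
        if isinstance(action, AddAction):
            v = self.vocab.index(action.atom)
            if action.attach_to is None:
                if A != 0:
                    raise KeyError("unattached Add on a non-empty state")
                return 1 + v
            return 1 + (action.attach_to * V + v) * B + _BOND_INDEX[action.bond]
        if isinstance(action, ConnectAction):
            i, j = min(action.i, action.j), max(action.i, action.j)
            p = (i * (2 * A - i - 1)) // 2 + (j - i - 1)
            return 1 + A * V * B + p * B + _BOND_INDEX[action.bond]
        raise KeyError(f"unknown action {action!r}")

    def is_legal(self, action: Action) -> bool:
        try:
            return bool(self.mask[self.index_of(action)])
        except KeyError:
            return False

    @property
    def legal_indices(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]

    def legal_list(self) -> list[Action]:
        return [self.action_at(int(k)) for k in self.legal_indices]

    @property
    def n_legal(self) -> int:
        return int(self.mask.sum())


def legal_actions(state: MolecularGraph, vocab: AtomVocabulary) -> ActionSpace:
    """Enumerate the legal next actions of a partial graph.

    Every Add that respects both atoms' valences, every ring-forming Connect
    between unbonded open-valence atoms, and Terminate whenever the state is a
    complete valid molecule.  The returned :class:`ActionSpace` carries the
    full candidate enumeration and its legality mask.
    """
    return ActionSpace(state, vocab)


# -- trajectories ------------------------------------------------------------


@dataclass
class Trajectory:
    """An ordered action sequence ending in Terminate, with lazily replayed
    intermediate states."""

    actions: list[Action]

    def __len__(self) -> int:
        return len(self.actions)

    def final_graph(self) -> MolecularGraph:
        return replay(self.actions)

    def iter_steps(self) -> Iterator[tuple[MolecularGraph, Action]]:
        """Yield ``(state_before, action)`` for every step."""
        g = MolecularGraph()
        for a in self.actions:
            yield g, a
            g = apply_action(g, a)

    def states(self) -> list[MolecularGraph]:
        return [s.copy() for s, _ in self.iter_steps()]

    def to_jsonl(self) -> str:
        lines = []
        for state, action in self.iter_steps():
            lines.append(
                json.dumps({"state": fragment_smiles(state), "action": action.to_json()})
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "Trajectory":
        actions = [
            action_from_json(json.loads(line)["action"])
            for line in text.splitlines()
            if line.strip()
        ]
        return cls(actions)


def replay(
    t: Trajectory | Sequence[Action], require_terminate: bool = False
) -> MolecularGraph:
    """Apply an action sequence from the empty graph and return the result.

    Raises :class:`TrajectoryError` on structural violations: out-of-range
    atom indices, duplicate bonds, or actions after Terminate.
    """
    actions = t.actions if isinstance(t, Trajectory) else list(t)
    g = MolecularGraph()
    terminated = False
    for a in actions:
        if terminated:
            raise TrajectoryError("action after Terminate")
        if isinstance(a, TerminateAction):
            terminated = True
        g = apply_action(g, a)
    if require_terminate and not terminated:
        raise TrajectoryError("sequence does not end in Terminate")
    return g


def decompose(
    g: MolecularGraph, seed: int | np.random.Generator
) -> Trajectory:
    """Decompose a complete molecule into one stochastic DFS action sequence.

    The start atom is uniform over heavy atoms and the child visit order is a
    uniform shuffle, both drawn from the seeded RNG.  Ring-closure bonds are
    emitted as Connect actions at the moment the search discovers the second
    endpoint, ordered by the already-assigned atom index when several close at
    once.  Replaying the result reproduces the molecule up to atom relabeling
    (identical canonical form).
    """
    if g.n_atoms == 0:
        raise TrajectoryError("cannot decompose an empty graph")
    if not g.is_connected():
        raise TrajectoryError("cannot decompose a disconnected graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    start = int(rng.integers(g.n_atoms))
    new_index: dict[int, int] = {}
    actions: list[Action] = []
    # stack of (original atom, original parent); preorder DFS
    stack: list[tuple[int, int | None]] = [(start, None)]
    while stack:
        u, parent = stack.pop()
        if u in new_index:
            continue
        nu = len(new_index)
        new_index[u] = nu
        if parent is None:
            actions.append(AddAction(g.atoms[u], None, None))
        else:
            actions.append(
                AddAction(g.atoms[u], new_index[parent], g.bond_between(parent, u))
            )
        # most recently discovered endpoint first: in fused ring systems this
        # closes the smallest ring before the enclosing perimeter
        closures = sorted(
            (w for w in g.neighbors(u) if w in new_index and w != parent),
            key=lambda w: -new_index[w],
        )
        for w in closures:
            actions.append(ConnectAction(nu, new_index[w], g.bond_between(u, w)))
        children = [w for w in g.neighbors(u) if w not in new_index]
        rng.shuffle(children)
        for w in reversed(children):
            stack.append((w, u))
    actions.append(TerminateAction())
    return Trajectory(actions)


def roundtrip_ok(g: MolecularGraph, seed: int) -> bool:
    """Decompose-then-replay sanity check used throughout the test stack."""
    return canonical_form(replay(decompose(g, seed))) == canonical_form(g)
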