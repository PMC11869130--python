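"""Synthetic stand-in for the experimental optical-property database and its
property evaluator.

Real training data for this kind of generator is a large table of
molecule/solvent pairs with seven measured optical properties.  This module
fabricates a statistically similar table at desk scale: a seeded sampler
builds valid molecules by guided legal-action walks, and a deterministic
surrogate oracle labels each molecule/solvent pair so that the well-known
structure of such data is reproduced —

* absorption tracks conjugation length (bathochromic shift with DOC), so
  lambda_abs and lambda_emi correlate strongly;
* emission sits above absorption by a Stokes shift that grows with solvent
  polarity for charge-transfer (donor+acceptor) chromophores;
* the two bandwidths share a molecule-level latent and correlate;
* quantum yield is drawn independently of the wavelengths;
* lifetime is weakly linked to quantum yield.

The oracle is a toy: deterministic, monotone and tunable, not a claim about
photophysics.  Its job is to make conditioning effects recoverable end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

from .graph import (
    AtomDescriptor,
    BondType,
    MolecularGraph,
    canonical_form,
    is_valid_molecule,
    parse_structure,
)
from .metrics import degree_of_conjugation
from .model import Condition, PROPERTY_FIELDS
from .solvents import DEFAULT_SOLVENTS, SolventInfo, SolventTable, onsager_polarity
from .trajectory import (
    AddAction,
    ConnectAction,
    TerminateAction,
    apply_action,
    intermediate_valid,
)

__all__ = [
    "OracleParams",
    "OracleRecord",
    "sample_molecules",
    "oracle_properties",
    "build_database",
    "split_by_structure",
    "fill_missing",
    "training_pairs",
    "typical_condition",
    "DB_COLUMNS",
]

#: CSV dialect: one row per molecule/solvent pair.
DB_COLUMNS = (
    "smiles",
    "solvent",
    "lambda_abs_nm",
    "sigma_abs_cm1",
    "log_eps",
    "lambda_emi_nm",
    "sigma_emi_cm1",
    "phi",
    "tau_ns",
)

#: property name -> CSV column
COLUMN_OF = dict(zip(PROPERTY_FIELDS, DB_COLUMNS[2:]))

_C = AtomDescriptor(6)
_N = AtomDescriptor(7)
_NH = AtomDescriptor(7, 0, 1)
_NPLUS = AtomDescriptor(7, 1, 0)
_O = AtomDescriptor(8)
_OMINUS = AtomDescriptor(8, -1, 0)
_S = AtomDescriptor(16)
_F = AtomDescriptor(9)
_CL = AtomDescriptor(17)

# aromatic ring templates: (atom sequence); all bonds aromatic
_RING_TEMPLATES = [
    [_C] * 6,                 # benzene
    [_N] + [_C] * 5,          # pyridine
    [_S] + [_C] * 4,          # thiophene
    [_O] + [_C] * 4,          # furan
    [_NH] + [_C] * 4,         # pyrrole
]


@dataclass(frozen=True)
class OracleParams:
    """Constants of the surrogate property oracle (one versioned set)."""

    base_lambda: float = 262.0          # nm, absorption of a DOC-0 molecule
    doc_increment: float = 18.0         # nm of bathochromic shift per DOC bond
    stokes_base: float = 32.0           # nm, polarity-independent Stokes shift
    stokes_ict: float = 55.0            # nm per ICT unit at full polarity
    sigma_abs_base: float = 3300.0      # cm^-1
    sigma_emi_base: float = 3050.0      # cm^-1
    sigma_latent: float = 550.0         # shared molecule-level bandwidth latent
    log_eps_base: float = 3.15
    log_eps_per_atom: float = 0.055     # per conjugated atom
    tau_base: float = 0.8               # ns
    tau_phi: float = 8.0                # ns per unit quantum yield
    noise_lambda: float = 8.0
    noise_stokes: float = 5.0
    noise_sigma: float = 220.0
    noise_log_eps: float = 0.12
    noise_tau: float = 0.35
    noise_scale: float = 1.0            # 0 switches all noise off
    seed: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "OracleParams":
        return cls(**d)


@dataclass
class OracleRecord:
    """One database row: molecule, solvent, seven property values and a
    provenance flag per property (observed vs oracle-filled)."""

    smiles: str
    solvent_id: str
    values: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = {f: "observed" for f in PROPERTY_FIELDS}


# -- donor/acceptor counting -------------------------------------------------

_DONOR_SMARTS = [
    Chem.MolFromSmarts("[NX3;H2,H1;!$(N[C,S]=[O,S])]"),  # amino
    Chem.MolFromSmarts("[OX2;$(Oc),$(OC)]"),             # hydroxy/alkoxy
    Chem.MolFromSmarts("[nH]"),
]
_ACCEPTOR_SMARTS = [
    Chem.MolFromSmarts("[N+](=O)[O-]"),   # nitro
    Chem.MolFromSmarts("[CX2]#[NX1]"),    # cyano
    Chem.MolFromSmarts("[CX3]=[OX1]"),    # carbonyl
    Chem.MolFromSmarts("n"),              # azine nitrogen
]


def ict_strength(g: MolecularGraph) -> int:
    """Toy intramolecular charge-transfer strength: the number of matched
    donor/acceptor pairs, min(#donors, #acceptors)."""
    mol = g.to_rdkit(sanitize=True)
    n_don = sum(len(mol.GetSubstructMatches(p)) for p in _DONOR_SMARTS)
    n_acc = sum(len(mol.GetSubstructMatches(p)) for p in _ACCEPTOR_SMARTS)
    return int(min(n_don, n_acc))


def crippen_logp(g: MolecularGraph) -> float:
    return float(Crippen.MolLogP(g.to_rdkit(sanitize=True)))


# -- the oracle --------------------------------------------------------------


def oracle_properties(
    g: MolecularGraph,
    solvent: SolventInfo,
    params: OracleParams = OracleParams(),
) -> Condition:
    """Deterministic surrogate properties of a molecule in a solvent.

    All molecule-level noise is drawn from an RNG seeded by the canonical form,
    so the same molecule scored in two solvents shares its latents and differs
    only through the deterministic solvent terms — exactly the setting in
    which solvatochromic Stokes-shift comparisons make sense.
    """
    smiles = canonical_form(g)
    rng = np.random.default_rng(
        (zlib.crc32(smiles.encode()) ^ (params.seed * 0x9E3779B1)) & 0x7FFFFFFF
    )
    ns = params.noise_scale
    e_lam, latent, e_st, e_sa, e_se, e_le, phi_draw, e_tau = rng.standard_normal(8)

    doc = degree_of_conjugation(g).doc
    n_conj = len({a for comp in _conj_atoms(g) for a in comp})
    ict = ict_strength(g)
    pol = onsager_polarity(solvent.dielectric)

    lam_abs = params.base_lambda + params.doc_increment * doc \
        + ns * params.noise_lambda * e_lam
    lam_abs = float(np.clip(lam_abs, 250.0, 980.0))
    stokes = params.stokes_base + params.stokes_ict * ict * pol \
        + ns * params.noise_stokes * e_st
    stokes = max(stokes, 5.0)
    lam_emi = float(min(lam_abs + stokes, 1000.0))

    sig_abs = max(params.sigma_abs_base + params.sigma_latent * latent
                  + ns * params.noise_sigma * e_sa, 500.0)
    sig_emi = max(params.sigma_emi_base + params.sigma_latent * latent
                  + ns * params.noise_sigma * e_se, 500.0)
    log_eps = params.log_eps_base + params.log_eps_per_atom * n_conj \
        + ns * params.noise_log_eps * e_le
    phi = float(1.0 / (1.0 + np.exp(-1.2 * phi_draw)))  # independent of lambdas
    tau = max(params.tau_base + params.tau_phi * phi
              + ns * params.noise_tau * e_tau, 0.1)

    return Condition(
        lambda_abs=lam_abs, sigma_abs=float(sig_abs), log_eps=float(log_eps),
        lambda_emi=lam_emi, sigma_emi=float(sig_emi), phi=phi, tau=float(tau),
        solvent_id=solvent.solvent_id,
    )


def _conj_atoms(g: MolecularGraph):
    from .graph import conjugated_components

    for comp in conjugated_components(g):
        yield {a for i, j, _ in comp for a in (i, j)}


# -- molecule sampler --------------------------------------------------------


class _Builder:
    """Guided legal-action walk: every mutation is an Add/Connect action
    checked against the intermediate validity predicate before being kept."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.state = MolecularGraph()

    def apply(self, action) -> bool:
        new = apply_action(self.state, action)
        if not intermediate_valid(new):
            return False
        self.state = new
        return True

    def add(self, atom: AtomDescriptor, attach: int | None,
            bond: BondType | None) -> int | None:
        if self.state.n_atoms == 0:
            ok = self.apply(AddAction(atom, None, None))
        else:
            ok = self.apply(AddAction(atom, attach, bond))
        return self.state.n_atoms - 1 if ok else None

    def open_sites(self, need: float = 1.0) -> list[int]:
        from .trajectory import free_valence

        return [
            i for i in range(self.state.n_atoms)
            if free_valence(self.state, i) >= need
            and not (self.state.aromatic_bond_count(i) == 1)
        ]

    def add_ring(self, attach: int | None) -> list[int]:
        template = _RING_TEMPLATES[self.rng.integers(len(_RING_TEMPLATES))]
        template = list(template)
        self.rng.shuffle(template)  # rotate heteroatom position
        first = self.add(template[0],
                         attach, BondType.SINGLE if attach is not None else None)
        if first is None:
            return []
        ring = [first]
        for atom in template[1:]:
            nxt = self.add(atom, ring[-1], BondType.AROMATIC)
            if nxt is None:
                return ring
            ring.append(nxt)
        self.apply(ConnectAction(ring[-1], ring[0], BondType.AROMATIC))
        return ring

    def add_vinylene(self, attach: int) -> int | None:
        a = self.add(_C, attach, BondType.SINGLE)
        if a is None:
            return None
        return self.add(_C, a, BondType.DOUBLE)

    def add_substituent(self, attach: int) -> None:
        choice = self.rng.integers(9)
        if choice == 0:  # nitro
            n = self.add(_NPLUS, attach, BondType.SINGLE)
            if n is not None:
                self.add(_O, n, BondType.DOUBLE)
                self.add(_OMINUS, n, BondType.SINGLE)
        elif choice == 1:  # cyano
            c = self.add(_C, attach, BondType.SINGLE)
            if c is not None:
                self.add(_N, c, BondType.TRIPLE)
        elif choice == 2:  # amino
            self.add(_N, attach, BondType.SINGLE)
        elif choice == 3:  # hydroxy
            self.add(_O, attach, BondType.SINGLE)
        elif choice == 4:  # methoxy
            o = self.add(_O, attach, BondType.SINGLE)
            if o is not None:
                self.add(_C, o, BondType.SINGLE)
        elif choice == 5:  # acetyl-ish carbonyl
            c = self.add(_C, attach, BondType.SINGLE)
            if c is not None:
                self.add(_O, c, BondType.DOUBLE)
        elif choice == 6:
            self.add(_F, attach, BondType.SINGLE)
        elif choice == 7:
            self.add(_CL, attach, BondType.SINGLE)
        else:  # methyl
            self.add(_C, attach, BondType.SINGLE)

    def add_chain(self, attach: int | None, length: int,
                  hetero_p: float = 0.25) -> None:
        prev = attach
        last_hetero = True  # avoid heteroatom as very first when unattached
        for _ in range(length):
            r = self.rng.random()
            atom = _C
            if not last_hetero and r < hetero_p:
                atom = _O if self.rng.random() < 0.6 else _N
                last_hetero = True
            else:
                last_hetero = False
            bond = BondType.SINGLE
            if prev is None:
                nxt = self.add(atom, None, None)
            else:
                if (atom is _C and self.state.atoms[prev] == _C
                        and self.rng.random() < 0.15):
                    bond = BondType.DOUBLE
                nxt = self.add(atom, prev, bond)
            if nxt is None:
                return
            prev = nxt


def _build_one(rng: np.random.Generator) -> MolecularGraph:
    b = _Builder(rng)
    archetype = rng.choice(["aromatic", "chain", "hydrophilic"],
                           p=[0.55, 0.25, 0.20])
    if archetype == "aromatic":
        n_rings = 1 + rng.integers(3)  # 1..3
        ring = b.add_ring(None)
        for _ in range(n_rings - 1):
            sites = [i for i in b.open_sites() if b.state.is_aromatic_atom(i)]
            if not sites:
                break
            site = int(rng.choice(sites))
            if rng.random() < 0.45:  # conjugated vinylene bridge, then a ring
                end = b.add_vinylene(site)
                if end is not None:
                    b.add_ring(end)
            else:
                b.add_ring(site)
        for _ in range(rng.integers(4)):  # 0..3 substituents
            sites = b.open_sites()
            if not sites:
                break
            b.add_substituent(int(rng.choice(sites)))
    elif archetype == "chain":
        b.add_chain(None, 3 + int(rng.integers(8)), hetero_p=0.2)
        for _ in range(rng.integers(3)):
            sites = b.open_sites()
            if not sites:
                break
            b.add_substituent(int(rng.choice(sites)))
    else:  # hydrophilic: short heteroatom-rich chain
        b.add_chain(None, 3 + int(rng.integers(6)), hetero_p=0.55)
        for _ in range(1 + rng.integers(2)):
            sites = b.open_sites()
            if not sites:
                break
            site = int(rng.choice(sites))
            b.add(_O if rng.random() < 0.6 else _N, site, BondType.SINGLE)
    return b.state


def sample_molecules(
    n: int, seed: int, size_range: tuple[int, int] = (3, 30)
) -> list[MolecularGraph]:
    """Sample ``n`` valid connected molecules by guided legal-action walks.

    A mixture of aromatic-ring-seeded and chain-seeded walks spans degrees of
    conjugation from 0 to ~20.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[MolecularGraph] = []
    while len(out) < n:
        g = _build_one(rng)
        if size_range[0] <= g.n_atoms <= size_range[1] and is_valid_molecule(g):
            out.append(g)
    return out


# -- database assembly -------------------------------------------------------


def _condition_to_row(smiles: str, c: Condition) -> dict:
    row = {"smiles": smiles, "solvent": c.solvent_id}
    for f in PROPERTY_FIELDS:
        row[COLUMN_OF[f]] = getattr(c, f)
    return row


def build_database(
    n_molecules: int,
    seed: int,
    params: OracleParams = OracleParams(),
    solvents: SolventTable = DEFAULT_SOLVENTS,
    records_per_molecule: int = 2,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Assemble a synthetic molecule/solvent property table.

    Solvent assignment is lipophilicity-aware: hydrophilic (low log P)
    molecules are measured preferentially in water, lipophilic ones in
    toluene, mirroring the real-world tendency of solubility-driven solvent
    choice.  That coupling is what lets a trained generator pick up
    solvent-dependent structure preferences.  ``missing_rate`` blanks random
    property cells (NaN) to exercise the fill step.
    """
    rng = np.random.default_rng(seed + 7)
    mols = sample_molecules(n_molecules, seed)
    rows = []
    k = min(records_per_molecule, len(solvents))
    ids = solvents.ids
    for g in mols:
        smiles = canonical_form(g)
        lp = crippen_logp(g)
        w = np.array([
            np.exp(-1.2 * (lp - 1.5)) if s.hydrophilicity >= 0.9
            else np.exp(1.2 * (lp - 1.5)) if s.hydrophilicity <= 0.05
            else 1.0
            for s in solvents
        ])
        w = w / w.sum()
        chosen = rng.choice(len(ids), size=k, replace=False, p=w)
        for si in chosen:
            c = oracle_properties(g, solvents[ids[int(si)]], params)
            rows.append(_condition_to_row(smiles, c))
    df = pd.DataFrame(rows, columns=list(DB_COLUMNS))
    if missing_rate > 0:
        prop_cols = list(DB_COLUMNS[2:])
        blank = rng.random((len(df), len(prop_cols))) < missing_rate
        vals = df[prop_cols].to_numpy(dtype=float)
        vals[blank] = np.nan
        df[prop_cols] = vals
    return df


def split_by_structure(
    df: pd.DataFrame, ratio: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/test split on unique molecules, not rows: every solvent record of
    a molecule lands on the same side, so there is no structure leakage."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    unique = sorted(df["smiles"].unique())
    if len(unique) < 2:
        raise ValueError("need at least two unique molecules to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    n_test = int(round((1.0 - ratio) * len(unique)))
    n_test = min(max(n_test, 1), len(unique) - 1)
    test_set = {unique[i] for i in perm[:n_test]}
    in_test = df["smiles"].isin(test_set)
    return df[~in_test].reset_index(drop=True), df[in_test].reset_index(drop=True)


def fill_missing(
    df: pd.DataFrame,
    params: OracleParams = OracleParams(),
    solvents: SolventTable = DEFAULT_SOLVENTS,
    oracle: Callable[[MolecularGraph, SolventInfo], Condition] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace NaN property cells with oracle predictions.

    Returns the completed table and a same-shaped provenance table whose
    property cells read ``observed`` or ``filled``.  Observed values are never
    touched.
    """
    if oracle is None:
        oracle = lambda g, s: oracle_properties(g, s, params)  # noqa: E731
    out = df.copy()
    prov = df.copy()
    prop_cols = list(DB_COLUMNS[2:])
    prov[prop_cols] = "observed"
    cache: dict[str, MolecularGraph] = {}
    for idx, row in df.iterrows():
        missing = [c for c in prop_cols if pd.isna(row[c])]
        if not missing:
            continue
        g = cache.setdefault(row["smiles"], parse_structure(row["smiles"]))
        pred = oracle(g, solvents[row["solvent"]])
        for col in missing:
            f = next(f for f, c in COLUMN_OF.items() if c == col)
            out.at[idx, col] = getattr(pred, f)
            prov.at[idx, col] = "filled"
    return out, prov


def training_pairs(df: pd.DataFrame) -> list[tuple[MolecularGraph, Condition]]:
    """Turn database rows into (molecule, condition) training pairs."""
    cache: dict[str, MolecularGraph] = {}
    pairs = []
    for _, row in df.iterrows():
        g = cache.setdefault(row["smiles"], parse_structure(row["smiles"]))
        c = Condition(
            *(float(row[COLUMN_OF[f]]) for f in PROPERTY_FIELDS),
            solvent_id=row["solvent"],
        )
        pairs.append((g, c))
    return pairs


def typical_condition(
    df: pd.DataFrame,
    solvent_id: str,
    lambda_emi_quantile: float | None = None,
    band: float = 0.15,
    restrict_to_solvent: bool = True,
) -> Condition:
    """A realistic conditioning target read off the database: per-property
    medians of the rows in a solvent, optionally restricted to a band around a
    lambda_emi quantile (for low- vs high-emission targets).

    With ``restrict_to_solvent=False`` the medians come from the whole table
    and only the solvent id is stamped — the grid design where one property
    target is probed across several solvents.
    """
    sub = df[df["solvent"] == solvent_id] if restrict_to_solvent else df
    if sub.empty:
        raise ValueError(f"no records in solvent {solvent_id!r}")
    if solvent_id not in set(df["solvent"]):
        raise ValueError(f"no records in solvent {solvent_id!r}")
    if lambda_emi_quantile is not None:
        lo = sub["lambda_emi_nm"].quantile(
            max(lambda_emi_quantile - band, 0.0))
        hi = sub["lambda_emi_nm"].quantile(
            min(lambda_emi_quantile + band, 1.0))
        banded = sub[(sub["lambda_emi_nm"] >= lo) & (sub["lambda_emi_nm"] <= hi)]
        if not banded.empty:
            sub = banded
    med = {f: float(sub[COLUMN_OF[f]].median()) for f in PROPERTY_FIELDS}
    med["phi"] = float(np.clip(med["phi"], 0.0, 1.0))
    return Condition(**med, solvent_id=solvent_id)
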