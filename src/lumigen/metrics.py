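"""Evaluation stack for conditional molecular generation.

Validity / uniqueness / novelty of a generated batch, the fraction of
molecules meeting all seven property targets simultaneously (%M_TOP), the
Stokes shift, the Crippen log P, the degree of conjugation (DOC), a 2-D
chemical-space embedding of Morgan fingerprints, and exact canonical-form
lookup of generated molecules in a reference table.

Conventions (printed in every report): uniqueness is distinct-over-valid and
novelty is new-over-distinct, so novelty <= uniqueness <= validity holds for
any batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, rdFingerprintGenerator

from .graph import (
    MolecularGraph,
    ParseError,
    canonical_form,
    conjugated_components,
    is_valid_molecule,
    parse_structure,
)
from .model import Condition, PROPERTY_FIELDS

logger = logging.getLogger(__name__)

__all__ = [
    "PropertyWindow",
    "MetricsReport",
    "DOCResult",
    "generation_metrics",
    "fraction_within_target",
    "stokes_shift",
    "degree_of_conjugation",
    "logp",
    "chemical_space_map",
    "find_in_reference",
]


@dataclass(frozen=True)
class PropertyWindow:
    """Half-width tolerances deciding whether a molecule meets a target.

    Defaults are a pragmatic configuration standing in for the accuracy of a
    property predictor; the lifetime window is relative because lifetimes span
    orders of magnitude.
    """

    lambda_abs: float = 25.0    # nm
    sigma_abs: float = 700.0    # cm^-1
    log_eps: float = 0.35
    lambda_emi: float = 25.0    # nm
    sigma_emi: float = 700.0    # cm^-1
    phi: float = 0.12
    tau_rel: float = 0.50       # relative half-width on tau

    def __post_init__(self) -> None:
        if min(self.lambda_abs, self.sigma_abs, self.log_eps, self.lambda_emi,
               self.sigma_emi, self.phi, self.tau_rel) <= 0:
            raise ValueError("all window half-widths must be positive")

    def half_width(self, prop: str, target: float) -> float:
        if prop == "tau":
            return self.tau_rel * abs(target)
        return getattr(self, prop)

    def contains(self, target: Condition, scored: Condition) -> dict[str, bool]:
        return {
            f: abs(getattr(scored, f) - getattr(target, f))
            <= self.half_width(f, getattr(target, f))
            for f in PROPERTY_FIELDS
        }


@dataclass
class MetricsReport:
    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int
    validity: float
    uniqueness: float
    novelty: float
    conventions: str = (
        "validity = valid/generated; uniqueness = distinct/valid; "
        "novelty = unseen-in-training/distinct"
    )
    fraction_m_top: float | None = None
    per_property_rates: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "n_generated": self.n_generated,
            "n_valid": self.n_valid,
            "n_unique": self.n_unique,
            "n_novel": self.n_novel,
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "fraction_m_top": self.fraction_m_top,
            "per_property_rates": self.per_property_rates,
            "conventions": self.conventions,
        }


def _as_canonical(m: str | MolecularGraph) -> str | None:
    """Canonical form of a generated item, or None if it is not a valid
    molecule."""
    try:
        g = parse_structure(m) if isinstance(m, str) else m
        if not is_valid_molecule(g):
            return None
        return canonical_form(g)
    except (ParseError, ValueError):
        return None


def generation_metrics(
    generated: Sequence[str | MolecularGraph],
    training_set: Iterable[str] = (),
) -> MetricsReport:
    """Validity, uniqueness and novelty of a generated batch.

    ``training_set`` holds the canonical forms of the training molecules;
    anything not found there counts as novel.
    """
    if len(generated) == 0:
        raise ValueError("empty generated set")
    train = set(training_set)
    canon = [_as_canonical(m) for m in generated]
    valid = [c for c in canon if c is not None]
    distinct = sorted(set(valid))
    novel = [c for c in distinct if c not in train]
    return MetricsReport(
        n_generated=len(generated),
        n_valid=len(valid),
        n_unique=len(distinct),
        n_novel=len(novel),
        validity=len(valid) / len(generated),
        uniqueness=len(distinct) / len(valid) if valid else 0.0,
        novelty=len(novel) / len(distinct) if distinct else 0.0,
    )


def fraction_within_target(
    mols: Sequence[MolecularGraph],
    oracle: Callable[[MolecularGraph], Condition],
    target: Condition,
    window: PropertyWindow = PropertyWindow(),
) -> tuple[float, list[int], dict[str, float]]:
    """Fraction of molecules whose scored properties ALL lie within the
    target windows simultaneously (the %M_TOP criterion, as a fraction).

    Returns (fraction, indices of the members, per-property hit rates).
    Molecules the oracle fails on are excluded from the denominator and
    logged.
    """
    members: list[int] = []
    per_prop = {f: 0 for f in PROPERTY_FIELDS}
    n_scored = 0
    for k, g in enumerate(mols):
        try:
            scored = oracle(g)
        except Exception as exc:
            logger.warning("oracle failed on molecule %d: %s", k, exc)
            continue
        n_scored += 1
        hits = window.contains(target, scored)
        for f, ok in hits.items():
            per_prop[f] += ok
        if all(hits.values()):
            members.append(k)
    if n_scored == 0:
        return 0.0, [], {f: 0.0 for f in PROPERTY_FIELDS}
    rates = {f: v / n_scored for f, v in per_prop.items()}
    return len(members) / n_scored, members, rates


def stokes_shift(lambda_emi: float, lambda_abs: float) -> float:
    """Stokes shift in nm: emission minus absorption wavelength.

    May be negative for inconsistent inputs; callers treat that as a flag."""
    if lambda_emi <= 0 or lambda_abs <= 0:
        raise ValueError("wavelengths must be positive")
    shift = lambda_emi - lambda_abs
    if shift < 0:
        logger.warning("negative Stokes shift (%g nm): emission below absorption",
                       shift)
    return shift


@dataclass(frozen=True)
class DOCResult:
    """Degree of conjugation: length (in bonds) of the longest shortest path
    within any single conjugated component."""

    doc: int
    atom_pair: tuple[int, int] | None
    component: int | None


def degree_of_conjugation(g: MolecularGraph) -> DOCResult:
    """Number of bonds connecting the farthest pair of atoms within one
    conjugated component (paths restricted to conjugated bonds); 0 when the
    molecule has no conjugated bonds.  Ties resolve to the lowest-index atom
    pair."""
    comps = conjugated_components(g)
    best = DOCResult(0, None, None)
    for ci, comp in enumerate(comps):
        sub = nx.Graph((i, j) for i, j, _ in comp)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        for i in sorted(lengths):
            for j in sorted(lengths[i]):
                if i < j and lengths[i][j] > best.doc:
                    best = DOCResult(lengths[i][j], (i, j), ci)
    return best


def logp(g: MolecularGraph) -> float:
    """Crippen atom-contribution octanol/water log P (RDKit)."""
    return float(Crippen.MolLogP(g.to_rdkit(sanitize=True)))


def morgan_fingerprints(
    mols: Sequence[MolecularGraph], radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for k, g in enumerate(mols):
        fp = gen.GetFingerprint(g.to_rdkit(sanitize=True))
        fps[k, list(fp.GetOnBits())] = 1
    return fps


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.minimum(a, b).sum())
    union = float(np.maximum(a, b).sum())
    return inter / union if union else 0.0


def chemical_space_map(
    groups: dict[str, Sequence[MolecularGraph]],
    radius: int = 2,
    n_bits: int = 2048,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """2-D chemical-space embedding: Morgan fingerprints pushed through t-SNE.

    ``groups`` maps a label (e.g. reference / matched-target / generated) to
    its molecules; the output frame has columns label, smiles, x, y.
    Deterministic for a fixed seed.
    """
    from sklearn.manifold import TSNE

    labels, mols = [], []
    for name, ms in groups.items():
        labels += [name] * len(ms)
        mols += list(ms)
    if len(mols) < 10:
        raise ValueError("need at least 10 molecules for an embedding")
    fps = morgan_fingerprints(mols, radius=radius, n_bits=n_bits).astype(float)
    if perplexity is None:
        perplexity = min(30.0, (len(mols) - 1) / 3.0)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(fps)
    return pd.DataFrame(
        {
            "label": labels,
            "smiles": [canonical_form(g) for g in mols],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )


def find_in_reference(
    generated: Sequence[str | MolecularGraph],
    reference_db: pd.DataFrame,
) -> pd.DataFrame:
    """Exact canonical-form lookup of generated molecules in a reference
    property table (column ``smiles`` holding canonical forms).

    Returns the matching reference rows, one block per distinct generated
    molecule found, so target-vs-experimental property comparisons can be
    made downstream.  An empty frame is a legitimate result.
    """
    canon = {c for c in (_as_canonical(m) for m in generated) if c is not None}
    return reference_db[reference_db["smiles"].isin(sorted(canon))].reset_index(
        drop=True
    )


def histogram_csv(values: Sequence[float], bins: int = 40) -> pd.DataFrame:
    """Distribution summary as a (bin_left, bin_right, count) table, the
    plotting-friendly export format for property distributions."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
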