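"""Conditional action-probability model.

A small message-passing graph network encodes the partial molecule; the seven
z-scored optical properties, a learned solvent embedding and a dielectric
polarity feature encode the target condition.  Three heads — per-site Add
logits (vocabulary atom x bond type per attachment atom), per-pair Connect
logits and a Terminate logit — are flattened into one masked softmax over the
legal actions of the state, and the model is trained by teacher forcing on
stochastic DFS decompositions of the training molecules (one fresh
decomposition per molecule per epoch).

The architecture is deliberately the smallest permutation-equivariant encoder
that honours the interface; any encoder with the same contract could stand
behind it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat, logsumexp, segment_sum
from .graph import AtomDescriptor, BondType, MolecularGraph
from .solvents import SolventTable, DEFAULT_SOLVENTS, onsager_polarity
from .trajectory import (
    ActionSpace,
    Action,
    AtomVocabulary,
    BOND_TYPES,
    N_BOND_TYPES,
    Trajectory,
    decompose,
    legal_actions,
)

__all__ = [
    "DeadEndError",
    "Condition",
    "PROPERTY_FIELDS",
    "NormalizationStats",
    "ModelConfig",
    "ActionDistribution",
    "ConditionalActionModel",
    "encode_condition",
    "train",
]

#: Canonical ordering of the seven optical properties.
PROPERTY_FIELDS = (
    "lambda_abs",   # first absorption peak, nm
    "sigma_abs",    # absorption bandwidth, cm^-1
    "log_eps",      # log10 molar extinction coefficient
    "lambda_emi",   # first emission peak, nm
    "sigma_emi",    # emission bandwidth, cm^-1
    "phi",          # photoluminescence quantum yield
    "tau",          # photoluminescence lifetime, ns
)


class DeadEndError(RuntimeError):
    """A sampling walk reached a state with no legal action."""


@dataclass(frozen=True)
class Condition:
    """Target optical properties plus the solvent they should hold in."""

    lambda_abs: float
    sigma_abs: float
    log_eps: float
    lambda_emi: float
    sigma_emi: float
    phi: float
    tau: float
    solvent_id: str

    def __post_init__(self) -> None:
        vals = self.values()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all seven property values must be finite")
        if self.lambda_abs <= 0 or self.lambda_emi <= 0:
            raise ValueError("wavelengths must be positive")
        if self.sigma_abs <= 0 or self.sigma_emi <= 0:
            raise ValueError("bandwidths must be positive")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("lifetime must be positive")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROPERTY_FIELDS], dtype=float)

    def to_json(self) -> dict:
        d = {f: getattr(self, f) for f in PROPERTY_FIELDS}
        d["solvent"] = self.solvent_id
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Condition":
        return cls(*(d[f] for f in PROPERTY_FIELDS), solvent_id=d["solvent"])


@dataclass
class NormalizationStats:
    """Per-property mean/sd fitted on the training conditions."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, conditions: Iterable[Condition]) -> "NormalizationStats":
        vals = np.array([c.values() for c in conditions])
        if len(vals) == 0:
            raise ValueError("cannot fit normalization on an empty set")
        sd = vals.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mean=vals.mean(axis=0), sd=sd)

    def z(self, c: Condition) -> np.ndarray:
        return (c.values() - self.mean) / self.sd

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "NormalizationStats":
        return cls(np.array(d["mean"]), np.array(d["sd"]))


@dataclass
class ModelConfig:
    hidden: int = 32
    rounds: int = 2
    solvent_embed_dim: int = 4
    learning_rate: float = 5e-3
    epochs: int = 4
    seed: int = 0
    unknown_solvent_fallback: bool = True

    def __post_init__(self) -> None:
        if min(self.hidden, self.rounds, self.solvent_embed_dim, self.epochs) < 1:
            raise ValueError("model dimensions and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def encode_condition(
    c: Condition,
    stats: NormalizationStats,
    solvents: SolventTable,
    embeddings: np.ndarray | None = None,
    solvent_ids: Sequence[str] | None = None,
    fallback: bool = True,
) -> np.ndarray:
    """Numeric conditioning vector: seven z-scored properties, the solvent
    embedding (zeros for a solvent unseen in training, if the fallback is
    enabled) and the dielectric polarity feature.
    """
    if c.solvent_id not in solvents:
        raise KeyError(f"unknown solvent {c.solvent_id!r}")
    d = embeddings.shape[1] if embeddings is not None else 0
    if solvent_ids is not None and c.solvent_id in solvent_ids:
        emb = embeddings[list(solvent_ids).index(c.solvent_id)]
    elif fallback:
        emb = np.zeros(d)
    else:
        raise KeyError(f"solvent {c.solvent_id!r} not in the trained set")
    pol = onsager_polarity(solvents[c.solvent_id].dielectric)
    return np.concatenate([stats.z(c), emb, [pol]])


@dataclass
class ActionDistribution:
    """Masked softmax over a state's candidate actions: zero on every illegal
    action, normalized over the legal ones."""

    space: ActionSpace
    probs: np.ndarray  # full candidate-space length; zero where illegal

    def prob_of(self, action: Action) -> float:
        try:
            return float(self.probs[self.space.index_of(action)])
        except KeyError:
            return 0.0

    def sample(self, rng: np.random.Generator) -> tuple[Action, float, int]:
        legal = self.space.legal_indices
        p = self.probs[legal]
        k = int(rng.choice(len(legal), p=p / p.sum()))
        idx = int(legal[k])
        return self.space.action_at(idx), float(self.probs[idx]), idx


class ConditionalActionModel:
    """The trained generator core: graph + condition in, action distribution
    out."""

    def __init__(
        self,
        cfg: ModelConfig,
        vocab: AtomVocabulary,
        solvents: SolventTable,
        trained_solvents: list[str],
        stats: NormalizationStats,
    ):
        self.cfg = cfg
        self.vocab = vocab
        self.solvents = solvents
        self.trained_solvents = list(trained_solvents)
        self.stats = stats
        self.history: list[float] = []
        self.elements = sorted({a.atomic_number for a in vocab})
        self._elem_index = {z: k for k, z in enumerate(self.elements)}
        self._init_params()

    # -- parameters --------------------------------------------------------

    @property
    def n_features(self) -> int:
        # element one-hot (+1 "other"), charge one-hot (-2..2), explicit-H
        # one-hot (0..3+), aromatic flag, free-valence scalar
        return len(self.elements) + 1 + 5 + 4 + 1 + 1

    @property
    def cond_dim(self) -> int:
        return 7 + self.cfg.solvent_embed_dim + 1

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        H, F, C = self.cfg.hidden, self.n_features, self.cond_dim
        V, B, S = len(self.vocab), N_BOND_TYPES, len(self.trained_solvents)

        def he(shape):
            return Parameter(rng.standard_normal(shape) * np.sqrt(2.0 / shape[0]))

        def zeros(shape):
            return Parameter(np.zeros(shape))

        p: dict[str, Parameter] = {
            "W_in": he((F, H)), "b_in": zeros((H,)),
            "solvent_emb": Parameter(rng.standard_normal((max(S, 1),
                                     self.cfg.solvent_embed_dim)) * 0.1),
            "W_ctx": he((H + C, H)), "b_ctx": zeros((H,)),
            "W_s1": he((H, H)), "W_s2": he((H, H)), "b_site": zeros((H,)),
            # output heads start at zero: the untrained model is uniform
            "W_add": zeros((H, V * B)), "b_add": zeros((V * B,)),
            "W_first": zeros((H, V)), "b_first": zeros((V,)),
            "W_conn": zeros((H, B)), "b_conn": zeros((B,)),
            "W_term": zeros((H, 1)), "b_term": zeros((1,)),
        }
        for r in range(self.cfg.rounds):
            p[f"W_msg{r}"] = he((H + B, H))
            p[f"b_msg{r}"] = zeros((H,))
            p[f"W_upd{r}"] = he((2 * H, H))
            p[f"b_upd{r}"] = zeros((H,))
        self.params = p

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    # -- featurization -----------------------------------------------------

    def _atom_features(self, g: MolecularGraph) -> np.ndarray:
        from .trajectory import valence_arrays

        E = len(self.elements)
        free, n_arom = valence_arrays(g)
        X = np.zeros((g.n_atoms, self.n_features))
        for i, a in enumerate(g.atoms):
            X[i, self._elem_index.get(a.atomic_number, E)] = 1.0
            X[i, E + 1 + (a.formal_charge + 2)] = 1.0
            X[i, E + 6 + min(a.explicit_h, 3)] = 1.0
            X[i, E + 10] = float(n_arom[i] > 0)
            X[i, E + 11] = free[i] / 4.0
        return X

    def _condition_tensor(self, c: Condition) -> Tensor:
        z = Tensor(self.stats.z(c))
        if c.solvent_id in self.trained_solvents:
            emb = self.params["solvent_emb"].gather_rows(
                np.array([self.trained_solvents.index(c.solvent_id)])
            ).reshape(self.cfg.solvent_embed_dim)
        elif self.cfg.unknown_solvent_fallback:
            emb = Tensor(np.zeros(self.cfg.solvent_embed_dim))
        else:
            raise KeyError(f"solvent {c.solvent_id!r} not in the trained set")
        pol = Tensor(np.array([onsager_polarity(self.solvents[c.solvent_id].dielectric)]))
        return concat([z, emb, pol])

    def encode_condition(self, c: Condition) -> np.ndarray:
        """Numeric conditioning vector under this model's statistics."""
        return self._condition_tensor(c).data

    # -- forward -----------------------------------------------------------

    def _legal_logits(self, state: MolecularGraph, c: Condition,
                      space: ActionSpace) -> Tensor:
        """Logits of the legal candidates, in ascending candidate order."""
        p = self.params
        A, V, B = state.n_atoms, len(self.vocab), N_BOND_TYPES
        cond = self._condition_tensor(c)

        if A == 0:
            u = concat([Tensor(np.zeros(self.cfg.hidden)), cond])
            u = (u @ p["W_ctx"] + p["b_ctx"]).relu()
            first = u @ p["W_first"] + p["b_first"]
            legal = space.legal_indices  # == 1..V
            return first.take(legal - 1)

        X = Tensor(self._atom_features(state))
        h = (X @ p["W_in"] + p["b_in"]).relu()
        if state.bonds:
            src, dst, eoh = [], [], []
            for (i, j), b in state.bonds.items():
                k = BOND_TYPES.index(b)
                src += [i, j]
                dst += [j, i]
                one = np.zeros(B)
                one[k] = 1.0
                eoh += [one, one]
            src = np.array(src)
            dst = np.array(dst)
            E = Tensor(np.array(eoh))
            for r in range(self.cfg.rounds):
                m_in = concat([h.gather_rows(src), E], axis=1)
                msg = (m_in @ p[f"W_msg{r}"] + p[f"b_msg{r}"]).relu()
                agg = segment_sum(msg, dst, A)
                h = (concat([h, agg], axis=1) @ p[f"W_upd{r}"] + p[f"b_upd{r}"]).relu()

        g_read = h.sum(axis=0)
        u = (concat([g_read, cond]) @ p["W_ctx"] + p["b_ctx"]).relu()
        site = (h @ p["W_s1"] + (u @ p["W_s2"] + p["b_site"])).relu()

        legal = space.legal_indices
        n_add = A * V * B
        add_sel = legal[(legal >= 1) & (legal <= n_add)] - 1
        conn_sel = legal[legal > n_add] - 1 - n_add
        parts: list[Tensor] = []
        if space.mask[0]:
            parts.append((u @ p["W_term"] + p["b_term"]))
        if len(add_sel):
            add_logits = site @ p["W_add"] + p["b_add"]  # (A, V*B)
            parts.append(add_logits.take(add_sel))
        if len(conn_sel):
            pairs = space._pairs
            pf = site.gather_rows(pairs[:, 0]) + site.gather_rows(pairs[:, 1])
            conn_logits = pf @ p["W_conn"] + p["b_conn"]  # (P, B)
            parts.append(conn_logits.take(conn_sel))
        return parts[0] if len(parts) == 1 else concat(parts)

    def action_distribution(
        self, state: MolecularGraph, c: Condition,
        space: ActionSpace | None = None,
    ) -> ActionDistribution:
        """Masked softmax over the legal next actions of ``state``."""
        if space is None:
            space = legal_actions(state, self.vocab)
        if space.n_legal == 0:
            # only degenerate sampling walks can get here (an unclosable
            # aromatic path at the system-size cap with everything else
            # saturated); decomposition-side states always admit an action
            raise DeadEndError("state admits no legal action")
        logits = self._legal_logits(state, c, space).data
        logits = logits - logits.max()
        ex = np.exp(logits)
        probs = np.zeros(space.n_candidates)
        probs[space.legal_indices] = ex / ex.sum()
        return ActionDistribution(space=space, probs=probs)

    # -- training ----------------------------------------------------------

    def trajectory_nll(self, traj: Trajectory, c: Condition) -> Tensor:
        """Mean negative log probability of the recorded actions (the teacher
        forcing loss of one trajectory)."""
        losses: list[Tensor] = []
        for state, action in traj.iter_steps():
            space = legal_actions(state, self.vocab)
            idx = space.index_of(action)
            if not space.mask[idx]:
                raise ValueError(
                    f"recorded action {action!r} is not legal in its state; "
                    "the molecule lies outside the action model"
                )
            pos = int(np.searchsorted(space.legal_indices, idx))
            logits = self._legal_logits(state, c, space)
            losses.append(logsumexp(logits) - logits.take(np.array([pos])).sum())
        total = losses[0]
        for l in losses[1:]:
            total = total + l
        return total * (1.0 / len(losses))

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.cfg),
            "vocab": self.vocab.to_json(),
            "solvents": self.solvents.to_json(),
            "trained_solvents": self.trained_solvents,
            "stats": self.stats.to_json(),
            "history": self.history,
        }
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "ConditionalActionModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            model = cls(
                ModelConfig(**meta["config"]),
                AtomVocabulary.from_json(meta["vocab"]),
                SolventTable.from_json(meta["solvents"]),
                meta["trained_solvents"],
                NormalizationStats.from_json(meta["stats"]),
            )
            model.history = list(meta["history"])
            for k in model.params:
                model.params[k].data = np.array(archive[f"param_{k}"])
        return model


def train(
    db: Sequence[tuple[MolecularGraph, Condition]],
    cfg: ModelConfig | None = None,
    solvents: SolventTable = DEFAULT_SOLVENTS,
    log: bool = False,
) -> ConditionalActionModel:
    """Teacher-forced training on (molecule, condition) pairs.

    Each epoch draws a fresh stochastic decomposition of every molecule (data
    augmentation over action orderings) and minimizes the mean per-step
    negative log likelihood with Adam, one update per trajectory.  Fully
    deterministic given (db, cfg): the config seed drives initialization,
    shuffling and decomposition.
    """
    if len(db) == 0:
        raise ValueError("empty training set")
    cfg = cfg or ModelConfig()
    for _, c in db:
        if c.solvent_id not in solvents:
            raise KeyError(f"condition references unknown solvent {c.solvent_id!r}")
    vocab = AtomVocabulary.from_molecules(g for g, _ in db)
    stats = NormalizationStats.fit([c for _, c in db])
    trained_solvents = sorted({c.solvent_id for _, c in db})
    model = ConditionalActionModel(cfg, vocab, solvents, trained_solvents, stats)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(db))
        total, steps = 0.0, 0
        for k in order:
            g, c = db[k]
            traj = decompose(g, rng)
            opt.zero_grad()
            loss = model.trajectory_nll(traj, c)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, molecule {k}"
                )
            loss.backward()
            opt.step()
            total += loss.item() * len(traj)
            steps += len(traj)
        model.history.append(total / steps)
        if log:
            print(f"epoch {epoch + 1}/{cfg.epochs}: mean step NLL {total / steps:.4f}")
    return model
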