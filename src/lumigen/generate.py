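"""Sampling molecules from a trained conditional action model.

Generation is plain ancestral sampling: from the empty graph (or a scaffold)
the model's masked action distribution is sampled step by step until it picks
Terminate or the step cap is hit.  Because the selection is stochastic, less
likely actions are sometimes taken, which is what gives the generator its
structural diversity; the same request with the same seed reproduces the same
molecules exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import MolecularGraph, canonical_form, is_valid_molecule
from .model import Condition, ConditionalActionModel, DeadEndError
from .trajectory import (
    Action,
    TerminateAction,
    Trajectory,
    apply_action,
    legal_actions,
)

__all__ = ["GenerationRequest", "MoleculeRecord", "GenerationResult", "generate"]


@dataclass(frozen=True)
class GenerationRequest:
    condition: Condition
    n_molecules: int = 1
    scaffold: MolecularGraph | None = None
    max_steps: int = 120
    seed: int = 0
    keep_invalid: bool = False
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.max_steps < 1:
            raise ValueError("n_molecules and max_steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.scaffold is not None and not is_valid_molecule(self.scaffold):
            raise ValueError("scaffold must be a valid connected molecule")


@dataclass
class MoleculeRecord:
    """One generation attempt: the action trace with per-step chosen-action
    probabilities, the final graph, and how the attempt ended."""

    graph: MolecularGraph | None
    actions: list[Action]
    step_probs: list[float]
    valid: bool
    truncated: bool
    smiles: str | None = None

    @property
    def trace_likelihood(self) -> float:
        return float(np.prod(self.step_probs)) if self.step_probs else 1.0


@dataclass
class GenerationResult:
    request: GenerationRequest
    records: list[MoleculeRecord] = field(default_factory=list)

    @property
    def molecules(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.valid]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records if r.valid]

    @property
    def validity(self) -> float:
        return len(self.molecules) / len(self.records) if self.records else 0.0


def _sample_one(
    model: ConditionalActionModel,
    req: GenerationRequest,
    rng: np.random.Generator,
) -> MoleculeRecord:
    state = req.scaffold.copy() if req.scaffold is not None else MolecularGraph()
    actions: list[Action] = []
    probs: list[float] = []
    for _ in range(req.max_steps):
        space = legal_actions(state, model.vocab)
        try:
            dist = model.action_distribution(state, req.condition, space)
        except DeadEndError:
            # unclosable aromatic path with everything else saturated: the
            # walk cannot be completed; count it like a truncation
            break
        if req.temperature == 1.0:
            action, prob, _ = dist.sample(rng)
        else:
            legal = space.legal_indices
            w = dist.probs[legal] ** (1.0 / req.temperature)
            idx = int(legal[rng.choice(len(legal), p=w / w.sum())])
            action = space.action_at(idx)
            prob = float(dist.probs[idx])  # the model's own probability
        actions.append(action)
        probs.append(prob)
        if isinstance(action, TerminateAction):
            return MoleculeRecord(
                graph=state,
                actions=actions,
                step_probs=probs,
                valid=True,
                truncated=False,
                smiles=canonical_form(state),
            )
        state = apply_action(state, action)
    # step cap reached without Terminate: counted invalid
    return MoleculeRecord(
        graph=state if req.keep_invalid else None,
        actions=actions,
        step_probs=probs,
        valid=False,
        truncated=True,
    )


def generate(req: GenerationRequest, model: ConditionalActionModel) -> GenerationResult:
    """Sample ``req.n_molecules`` molecules under the request's condition.

    Each record keeps its full action trace and per-step chosen-action
    probabilities so the sampling path can be audited against the checkpointed
    model.  Scaffold atoms and bonds are never removed — the action vocabulary
    has no deletions — so every output contains the scaffold as a subgraph.
    """
    rng = np.random.default_rng(req.seed)
    result = GenerationResult(request=req)
    for _ in range(req.n_molecules):
        # truncated records are kept for accounting; their graphs are dropped
        # unless the request says otherwise
        result.records.append(_sample_one(model, req, rng))
    return result


def trace_likelihood(
    model: ConditionalActionModel,
    req: GenerationRequest,
    record: MoleculeRecord,
) -> float:
    """Recompute the probability of a stored action trace under the model;
    equals the product of the record's per-step probabilities."""
    state = req.scaffold.copy() if req.scaffold is not None else MolecularGraph()
    total = 1.0
    for action in record.actions:
        dist = model.action_distribution(state, req.condition)
        total *= dist.prob_of(action)
        if not isinstance(action, TerminateAction):
            state = apply_action(state, action)
    return total


def trajectories_of(result: GenerationResult) -> list[Trajectory]:
    """Action traces of the valid molecules as replayable trajectories
    (scaffold-free requests only)."""
    if result.request.scaffold is not None:
        raise ValueError("traces of scaffolded runs do not replay from scratch")
    return [Trajectory(r.actions) for r in result.records if r.valid]
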