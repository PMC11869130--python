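"""Shared test oracles, independent of the implementation paths they check."""

from __future__ import annotations

import numpy as np

from lumigen.graph import MolecularGraph, is_valid_molecule
from lumigen.trajectory import (
    AtomVocabulary,
    TerminateAction,
    TrajectoryError,
    apply_action,
    intermediate_valid,
    legal_actions,
)


def brute_force_mask(g: MolecularGraph, vocab: AtomVocabulary):
    """Apply-every-candidate-and-validate enumeration of legal actions.

    Uses only the public action-application and validity predicates, never
    the incremental arithmetic of the fast enumerator.  Returns the fast
    enumerator's ActionSpace (for the candidate layout) plus the brute-force
    mask to compare against.
    """
    space = legal_actions(g, vocab)
    mask = np.zeros(space.n_candidates, dtype=bool)
    for idx in range(space.n_candidates):
        action = space.action_at(idx)
        if isinstance(action, TerminateAction):
            mask[idx] = is_valid_molecule(g)
            continue
        try:
            new = apply_action(g, action)
        except TrajectoryError:
            continue
        mask[idx] = intermediate_valid(new)
    return space, mask


def bfs_diameter(edges: list[tuple[int, int]]) -> int:
    """All-pairs BFS longest-shortest-path oracle over an edge list."""
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    best = 0
    for src in adj:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        best = max(best, max(dist.values()))
    return best
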