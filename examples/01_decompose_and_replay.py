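"""Decompose a molecule into build actions and replay it.

Nitrobenzene is broken into an Add/Connect/Terminate sequence by a seeded
stochastic depth-first search; different seeds give different orderings, and
every ordering replays to the same canonical structure.
"""

from lumigen import canonical_form, decompose, parse_structure, replay

nitrobenzene = parse_structure("O=[N+]([O-])c1ccccc1")
print(f"nitrobenzene: {nitrobenzene.n_atoms} heavy atoms")

for seed in (0, 1):
    traj = decompose(nitrobenzene, seed)
    print(f"\nseed {seed}: {len(traj)} actions")
    for k, action in enumerate(traj.actions):
        print(f"  {k:2d}  {action}")
    rebuilt = replay(traj)
    print("replays to:", canonical_form(rebuilt))

# Both sequences rebuild O=[N+]([O-])c1ccccc1 exactly: the action alphabet
# (atom additions with a bond, ring-closing connections, termination) is a
# lossless encoding of the molecular graph.
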