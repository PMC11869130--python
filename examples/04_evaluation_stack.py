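"""The evaluation toolkit on a hand-made batch.

Validity / uniqueness / novelty of a generated list, the joint
seven-property target criterion (%M_TOP), Stokes shift, Crippen log P,
degree of conjugation, a t-SNE chemical-space map and exact reference
lookup.
"""

from lumigen import (
    Condition,
    DEFAULT_SOLVENTS,
    PropertyWindow,
    canonical_form,
    chemical_space_map,
    degree_of_conjugation,
    find_in_reference,
    fraction_within_target,
    generation_metrics,
    logp,
    oracle_properties,
    parse_structure,
    stokes_shift,
)
from lumigen.synthdata import build_database, sample_molecules

generated = ["c1ccccc1", "C1=CC=CC=C1", "CCO", "CC(=O)O", "C(", "c1ccncc1"]
training = {canonical_form(parse_structure(s)) for s in ["c1ccccc1"]}
rep = generation_metrics(generated, training)
print(f"validity {rep.validity:.2f}  uniqueness {rep.uniqueness:.2f}  "
      f"novelty {rep.novelty:.2f}")
print(rep.conventions)

target = Condition(380.0, 4700.0, 3.6, 550.0, 3800.0, 0.01, 2.0, "water")
mols = sample_molecules(200, seed=3)
frac, members, rates = fraction_within_target(
    mols,
    lambda g: oracle_properties(g, DEFAULT_SOLVENTS["water"]),
    target,
    PropertyWindow(),
)
print(f"\n%M_TOP at the example target: {100 * frac:.1f}% "
      f"({len(members)} of {len(mols)} inside all seven windows)")
print("per-property hit rates:",
      {k: round(v, 2) for k, v in rates.items()})
# Unconditioned random molecules almost never satisfy seven windows at once
# - which is exactly why generation needs to be property-conditioned.

print(f"\nStokes shift for (550, 380) nm: {stokes_shift(550, 380):.0f} nm")
stilbene = parse_structure("c1ccccc1/C=C/c1ccccc1")
print(f"stilbene: DOC = {degree_of_conjugation(stilbene).doc} bonds, "
      f"log P = {logp(stilbene):.2f}")

coords = chemical_space_map(
    {"reference": sample_molecules(30, seed=4),
     "generated": sample_molecules(30, seed=5)}, seed=0)
print(f"\nt-SNE map: {len(coords)} molecules ->",
      coords[["x", "y"]].abs().mean().round(1).to_dict())

reference = build_database(100, seed=6)
hits = find_in_reference(reference["smiles"].head(3).tolist(), reference)
print(f"reference lookup: {hits['smiles'].nunique()} molecules matched, "
      f"{len(hits)} property records returned")
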