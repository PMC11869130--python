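# Methods

This note documents the models, conventions and numerical choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the desk-scale experiments do and do not demonstrate.

## Molecular representation

Molecules are heavy-atom graphs. Each atom carries (atomic number, formal
charge, explicit-hydrogen count); bonds are single, double, triple or
aromatic; hydrogens beyond the explicit count are implicit and derived from
valence. The supported element set defaults to the common organic palette
{B, C, N, O, F, Si, P, S, Cl, Br, I}; parsing rejects anything else.
Parsing, canonicalization, aromaticity perception, final-molecule
sanitization, Crippen log P, Morgan fingerprints and bond-conjugation flags
are delegated to RDKit; the in-house graph class exists because partial
molecules under construction are not generally sanitizable and need their
own editing and valence bookkeeping.

## Intermediate valence model

During generation a state may contain half-built rings, so validity is
checked with an incremental model rather than full sanitization:

* non-aromatic bonds contribute their integer order;
* each aromatic bond contributes one unit, plus a single π increment for
  atoms donating one electron to the ring (C and B; N without hydrogen) and
  none for lone-pair donors (O, S, N–H). A naive 1.5-per-aromatic-bond sum
  was rejected because it miscounts pyrrole-type N–H (2 × 1.5 + 1 H = 4
  against an allowed valence of 3);
* an atom with exactly one aromatic bond must retain a free valence, so a
  ring in progress can always be extended or closed — without this
  reservation, saturated states with dangling aromatic bonds would admit no
  legal action;
* aromatic rings are restricted to the standard 5–7-membered sizes and a
  connected aromatic system is capped at 20 atoms (about four fused rings)
  — the regime of small-molecule chromophores. The cap also bounds the cost
  of legality checks on degenerate random-walk states;
* whenever a Connect closes an aromatic cycle, the cyclic aromatic core
  (hydrogen-filled) must sanitize in RDKit, which rejects unkekulizable
  systems such as an all-carbon aromatic five-ring.

Terminate is legal exactly when the state sanitizes as a complete connected
molecule; RDKit has the final word on full-molecule validity. The fast
legality enumerator is arithmetic (free-valence arrays plus a BFS ring-size
prefilter, with the core sanitization only for genuine ring closures) and is
verified against a brute-force apply-every-candidate-and-validate oracle
over the exhaustive closure of all ≤ 6-atom states reachable from
single-atom seeds, plus aromatic fragment states.

Two deliberate consequences: (1) molecules whose aromatic systems violate
the size rules (azulenes, porphyrin-scale macrocycles) are outside the
action model and cannot be used as training input; (2) a degenerate sampling
walk can reach a dead end (an unclosable aromatic path with everything else
saturated). Dead ends raise a dedicated error and are counted like
truncations by the generator; decomposition-side states always admit their
recorded action.

## Decomposition

Training sequences come from a stochastic depth-first search: start atom
uniform over heavy atoms, child order a uniform shuffle, both drawn from the
caller's seed. Ring-closure bonds are emitted as Connect actions at the
moment the search discovers the second endpoint; when several closures are
pending at one atom they are emitted most-recently-discovered first, which
closes the smallest ring of a fused system before its enclosing perimeter
(ascending order would propose the 10-membered perimeter of naphthalene
before its chord, which the ring-size rule rejects). One molecule therefore
yields many action sequences, all replaying to the same canonical form; a
fresh decomposition per molecule per epoch acts as data augmentation over
orderings.

## Conditional model

The encoder is a small message-passing network: atom features (element
one-hot with an "other" slot, charge, explicit-H count, aromatic flag,
scaled free valence) are embedded to a hidden width of 32 and updated for 2
rounds of bond-typed message passing with sum aggregation; the graph readout
is the sum of atom states. The condition vector is the seven z-scored
properties (statistics fitted on the training conditions and stored in the
checkpoint), a 4-dimensional learned embedding of the solvent id, and the
Onsager polarity factor (ε_r − 1)/(ε_r + 2) as a numeric feature; solvents
unseen in training fall back to a zero embedding with the polarity feature
kept. Readout and condition feed a context vector that conditions three
heads — per-site Add logits (vocabulary atom × bond type per attachment
atom), per-pair Connect logits from summed endpoint states, and a Terminate
logit — flattened into one masked softmax over the legal candidates.
Output heads are zero-initialized, so an untrained model is exactly uniform
over legal actions.

Training minimizes the mean per-step negative log likelihood with Adam
(learning rate 5 × 10⁻³), one update per trajectory; all randomness
(initialization, shuffling, decomposition) derives from the config seed, so
a training run is bit-reproducible. The atom vocabulary is harvested from
the training molecules, never hard-coded. Checkpoints are single `.npz`
archives holding weights at full precision plus the config, vocabulary,
solvent table and normalization statistics; save → load → inference is
bit-identical.

The encoder is permutation-equivariant, which has a testable consequence:
on a state with non-trivial automorphisms (the two ends of an ethane
intermediate, symmetric ring positions) probability mass is split evenly
over equivalent actions, so "the model recovers a memorized trajectory"
means near-unit mass on the automorphism orbit of each recorded action, not
on one arbitrary representative.

No claim is made of reproducing any particular trained network; the
architecture is a deliberately small stand-in honouring the interface
(state, condition → distribution over legal actions), and the training core
is a compact reverse-mode autodiff module over NumPy written for this
package.

## Generation

Ancestral sampling from the masked distribution, starting from the empty
graph or a scaffold whose atoms and bonds are never removed. The step cap
defaults to 120 actions (80 in the bundled experiments); walks that hit the
cap or a dead end are recorded as invalid. Sampling temperature is exposed
but defaults to 1 (plain multinomial). Each record keeps its action trace
and per-step chosen-action probabilities, and the product of those
probabilities is checked against a from-scratch recomputation under the
checkpointed model.

## Surrogate property oracle

The oracle is a deterministic toy that reproduces the statistical structure
of solution-phase photophysics tables, not photophysics itself:

* λ_abs = 262 nm + 18 nm × DOC + noise (σ = 8 nm), clipped to [250, 980];
* Stokes shift = 32 nm + 55 nm × ICT × polarity + noise (σ = 5 nm), floored
  at 5 nm; λ_emi = λ_abs + Stokes, so emission always sits above absorption
  — stricter than reality, where rare records violate it;
* ICT strength is min(#donors, #acceptors) from a small SMARTS table
  (amino/alkoxy/pyrrole-type donors; nitro/cyano/carbonyl/azine acceptors)
  — a proxy that makes solvatochromism recoverable, not a photophysical
  claim;
* σ_abs and σ_emi share a molecule-level latent (hence correlate), log ε
  grows with the conjugated-atom count, Φ is an independent logistic draw,
  τ = 0.8 ns + 8 ns × Φ + noise;
* all molecule-level noise is seeded from the canonical SMILES, so the
  oracle is a pure function of (molecule, solvent, parameter set), and the
  same molecule scored in two solvents shares its latents — the setting in
  which per-molecule solvent comparisons are meaningful.

Molecule/solvent pairing in the synthetic database is lipophilicity-aware
(water records favour low-log P molecules, toluene the opposite, odds
scaled by e^{±1.2(log P − 1.5)}), emulating solubility-driven solvent choice;
this coupling is what a solvent-conditioned generator can learn. The
five solvents are water (ε_r 78.4), acetonitrile (37.5), dichloromethane
(8.93), THF (7.58) and toluene (2.38).

The molecule sampler mixes aromatic-ring-seeded walks (1–3 rings of
benzene/pyridine/thiophene/furan/pyrrole type, linked directly or through
vinylene bridges, with 0–3 donor/acceptor substituents) with aliphatic and
heteroatom-rich chain walks, giving DOC 0–20 and log P roughly −2 to 6.
What passing tests on this data shows is that the *pipeline* recovers
plantable structure–property relationships end to end; it says nothing
about accuracy on real spectroscopy, which would require the real database
and a real property predictor behind the same oracle interface.

## Property windows (%M_TOP)

A generated molecule "meets" a target when all seven scored properties lie
within per-property windows simultaneously (the joint criterion; per-property
hit rates are reported alongside for diagnosis). The default half-widths —
±25 nm on wavelengths, ±700 cm⁻¹ on bandwidths, ±0.35 on log ε, ±0.12 on Φ,
±50 % relative on τ — are a package configuration standing in for the
accuracy of a property predictor, and are expected to be replaced by the
user's predictor errors when real data are in play.

## Degree of conjugation

Conjugated bonds are taken from RDKit's conjugation perception (alternating
π systems including lone-pair conjugation); connected components of that
bond set are the conjugated backbones, and DOC is the largest bond-count
eccentricity — the longest shortest path — within any single component,
with ties resolved to the lowest-index atom pair. Ethane scores 0, benzene
and butadiene 3. An independent all-pairs BFS oracle cross-checks the
implementation in the tests.

## Experiment scale and determinism

The bundled experiments use a 2000-molecule database (one solvent record per
molecule), a hidden width of 32 with 2 message rounds, 3-4 training epochs,
and 300–500 molecules per generation run with an 80-step cap — sizes chosen
so the full pipeline runs comfortably on a single CPU while the conditional
and solvent effects are well resolved. Every stage seeds its own RNG from
one top-level seed. Known limitations: training cost scales with the number
of candidate actions (quadratic in atoms for ring closures), fused-ring
vocabularies outside the 5–7 ring-size window are unsupported, and the
novelty/uniqueness conventions, while standard, are one of several in use —
reports print them explicitly.
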