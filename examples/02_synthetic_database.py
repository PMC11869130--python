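"""Build a synthetic optical-property database and inspect its structure.

The sampler draws valid molecules spanning conjugation lengths 0-20; the
surrogate oracle labels each molecule/solvent pair with seven properties
whose correlations mirror real photophysics tables: absorption tracks
emission (both driven by conjugation), bandwidths correlate, quantum yield
is independent, and emission always sits above absorption (Stokes shift).
"""

import numpy as np

from lumigen import parse_structure, oracle_properties, DEFAULT_SOLVENTS
from lumigen.synthdata import build_database, split_by_structure

db = build_database(400, seed=1)
print(f"{len(db)} records over {db['smiles'].nunique()} molecules\n")
print(db.head(4).to_string(index=False))

corr = db[["lambda_abs_nm", "lambda_emi_nm", "phi"]].corr()
print(f"\ncorr(lambda_abs, lambda_emi) = {corr.iloc[0, 1]:.2f}  (strong)")
print(f"corr(phi, lambda_emi)        = {corr.iloc[2, 1]:.2f}  (none)")
print("Stokes shift always positive:",
      bool((db.lambda_emi_nm > db.lambda_abs_nm).all()))

# solvatochromism: a donor-acceptor dye gains Stokes shift in polar solvents
dye = parse_structure("Nc1ccc(cc1)[N+](=O)[O-]")
for sid in ("toluene", "acetonitrile"):
    c = oracle_properties(dye, DEFAULT_SOLVENTS[sid])
    print(f"p-nitroaniline in {sid:13s}: Stokes shift "
          f"{c.lambda_emi - c.lambda_abs:5.1f} nm")

# structure-based 9:1 split: all solvent records of a molecule stay together
train, test = split_by_structure(db, ratio=0.9, seed=2)
leak = set(train.smiles) & set(test.smiles)
print(f"\nsplit: {train.smiles.nunique()} train / {test.smiles.nunique()} "
      f"test molecules, structure leakage: {len(leak)}")
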