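import numpy as np
import pandas as pd
import pytest

from helpers import bfs_diameter
from lumigen.graph import canonical_form, conjugated_components, parse_structure
from lumigen.metrics import (
    PropertyWindow,
    chemical_space_map,
    degree_of_conjugation,
    find_in_reference,
    fraction_within_target,
    generation_metrics,
    logp,
    morgan_fingerprints,
    stokes_shift,
    tanimoto,
)
from lumigen.model import Condition
from lumigen.synthdata import sample_molecules


# 10 strings: 2 unparsable, 8 valid with 6 distinct canonical forms, of which
# 3 appear in the training set -> validity 0.8, uniqueness 0.75, novelty 0.5
FIXTURE_GENERATED = [
    "c1ccccc1", "C1=CC=CC=C1",      # same molecule, two spellings
    "CCO", "CCN", "CC(=O)O", "CCOC", "c1ccncc1",
    "OCC",                           # ethanol again
    "C(",                            # unparsable
    "notasmiles",                    # unparsable
]
FIXTURE_TRAINING = {
    canonical_form(parse_structure(s)) for s in ["c1ccccc1", "CCO", "CCN"]
}


class TestGenerationMetrics:
    def test_constructed_fixture_exact_fractions(self):
        rep = generation_metrics(FIXTURE_GENERATED, FIXTURE_TRAINING)
        assert rep.validity == 0.8
        assert rep.uniqueness == 0.75
        assert rep.novelty == 0.5

    def test_duplicating_the_batch_halves_uniqueness_only(self):
        rep1 = generation_metrics(FIXTURE_GENERATED, FIXTURE_TRAINING)
        rep2 = generation_metrics(FIXTURE_GENERATED * 2, FIXTURE_TRAINING)
        assert rep2.validity == rep1.validity
        assert rep2.uniqueness == rep1.uniqueness / 2
        assert rep2.novelty == rep1.novelty

    def test_identical_outputs_unique_fraction(self):
        rep = generation_metrics(["CCO"] * 5)
        assert rep.uniqueness == 1 / 5

    def test_generated_subset_of_training_has_zero_novelty(self):
        rep = generation_metrics(["CCO", "c1ccccc1"], FIXTURE_TRAINING)
        assert rep.novelty == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            generation_metrics([])


class TestFractionWithinTarget:
    target = Condition(450.0, 3500.0, 4.0, 520.0, 3200.0, 0.5, 3.0, "toluene")

    @staticmethod
    def _oracle_returning(cond):
        return lambda g: cond

    def test_all_exactly_at_target_gives_one(self):
        mols = sample_molecules(5, seed=0)
        frac, members, _ = fraction_within_target(
            mols, self._oracle_returning(self.target), self.target)
        assert frac == 1.0 and members == list(range(5))

    def test_narrow_windows_exclude_offset_scores(self):
        off = Condition(450.0 + 3.0, 3500.0, 4.0, 520.0, 3200.0, 0.5, 3.0,
                        "toluene")
        window = PropertyWindow(lambda_abs=1e-6)
        frac, members, rates = fraction_within_target(
            sample_molecules(5, seed=0), self._oracle_returning(off),
            self.target, window)
        assert frac == 0.0 and members == []
        assert rates["lambda_abs"] == 0.0 and rates["phi"] == 1.0

    def test_counts_k_of_n_with_joint_criterion(self):
        mols = sample_molecules(6, seed=1)
        inside = self.target
        outside = Condition(450.0, 3500.0, 4.0, 520.0, 3200.0, 0.95, 3.0,
                            "toluene")  # phi off-window only
        conds = [inside, outside, inside, outside, outside, inside]
        by_id = {id(g): c for g, c in zip(mols, conds)}
        oracle = lambda g: by_id[id(g)]  # noqa: E731
        frac, members, _ = fraction_within_target(mols, oracle, self.target)
        assert frac == pytest.approx(3 / 6)
        assert members == [0, 2, 5]

    def test_monotone_in_window_width(self):
        mols = sample_molecules(8, seed=2)
        rng = np.random.default_rng(0)
        by_id = {
            id(g): Condition(450 + rng.normal(0, 30), 3500, 4.0, 520, 3200,
                             0.5, 3.0, "toluene")
            for g in mols
        }
        oracle = lambda g: by_id[id(g)]  # noqa: E731
        fractions = [
            fraction_within_target(mols, oracle, self.target,
                                   PropertyWindow(lambda_abs=w))[0]
            for w in (5, 15, 40, 100)
        ]
        assert fractions == sorted(fractions)


class TestStokesShift:
    def test_target_values(self):
        assert stokes_shift(550.0, 380.0) == 170.0

    def test_zero_for_equal_wavelengths(self):
        assert stokes_shift(500.0, 500.0) == 0.0

    def test_solvatochromic_pair_stored_as_two_records(self):
        # one charge-transfer molecule measured in two solvents
        toluene = stokes_shift(480.0, 400.0)
        acn = stokes_shift(587.0, 400.0)
        assert toluene == 80.0 and acn == 187.0 and acn > toluene


class TestDegreeOfConjugation:
    @pytest.mark.parametrize("smiles, expected", [
        ("CC", 0),
        ("c1ccccc1", 3),
        ("C=CC=C", 3),
        ("C=Cc1ccccc1", 5),
    ])
    def test_spot_values(self, smiles, expected):
        assert degree_of_conjugation(parse_structure(smiles)).doc == expected

    def test_agrees_with_bfs_oracle_on_random_molecules(self):
        for g in sample_molecules(60, seed=9):
            comps = conjugated_components(g)
            expected = max(
                (bfs_diameter([(i, j) for i, j, _ in comp]) for comp in comps),
                default=0,
            )
            assert degree_of_conjugation(g).doc == expected

    def test_doc_bounded_by_conjugated_bond_count(self):
        for g in sample_molecules(30, seed=10):
            n_bonds = sum(len(c) for c in conjugated_components(g))
            res = degree_of_conjugation(g)
            assert 0 <= res.doc <= n_bonds
            assert (res.doc == 0) == (n_bonds == 0)


class TestLogP:
    def test_hydrophilic_below_hydrophobic(self):
        glycol = logp(parse_structure("OCCOCCO"))
        octylbenzene = logp(parse_structure("CCCCCCCCc1ccccc1"))
        assert glycol < octylbenzene

    def test_deterministic(self):
        g = parse_structure("Cc1ccc(O)cc1")
        assert logp(g) == logp(g)


class TestChemicalSpace:
    def test_duplicate_molecules_share_fingerprints(self):
        g1 = parse_structure("Cc1ccccc1")
        g2 = parse_structure("c1ccccc1C")
        fps = morgan_fingerprints([g1, g2])
        assert np.array_equal(fps[0], fps[1])

    def test_fixed_seed_reproducible(self):
        groups = {"a": sample_molecules(12, seed=3)}
        m1 = chemical_space_map(groups, seed=4)
        m2 = chemical_space_map(groups, seed=4)
        assert np.allclose(m1[["x", "y"]].to_numpy(), m2[["x", "y"]].to_numpy())

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            chemical_space_map({"a": sample_molecules(4, seed=3)})

    def test_disjoint_families_less_similar_between_than_within(self):
        aromatics = [parse_structure(s) for s in
                     ["c1ccccc1", "Cc1ccccc1", "c1ccncc1", "Oc1ccccc1"]]
        ethers = [parse_structure(s) for s in
                  ["CCOCC", "COCCOC", "CCOCCO", "COCCC"]]
        fa = morgan_fingerprints(aromatics)
        fe = morgan_fingerprints(ethers)
        within = np.mean([tanimoto(fa[i], fa[j])
                          for i in range(4) for j in range(i + 1, 4)] +
                         [tanimoto(fe[i], fe[j])
                          for i in range(4) for j in range(i + 1, 4)])
        between = np.mean([tanimoto(a, e) for a in fa for e in fe])
        assert between < within


class TestReferenceLookup:
    def _reference(self):
        return pd.DataFrame({
            "smiles": [canonical_form(parse_structure(s))
                       for s in ["c1ccccc1", "CCO"]],
            "solvent": ["toluene", "water"],
            "lambda_abs_nm": [320.0, 270.0],
        })

    def test_present_molecule_returns_its_record(self):
        hits = find_in_reference(["c1ccccc1"], self._reference())
        assert len(hits) == 1
        assert hits.loc[0, "lambda_abs_nm"] == 320.0

    def test_absent_molecule_returns_empty(self):
        assert find_in_reference(["CCCC"], self._reference()).empty

    def test_two_spellings_collapse_to_one_match(self):
        hits = find_in_reference(["C1=CC=CC=C1", "c1ccccc1"], self._reference())
        assert len(hits) == 1
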