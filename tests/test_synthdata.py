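import numpy as np
import pandas as pd
import pytest

from lumigen.graph import canonical_form, is_valid_molecule, parse_structure
from lumigen.metrics import degree_of_conjugation
from lumigen.model import PROPERTY_FIELDS
from lumigen.solvents import DEFAULT_SOLVENTS
from lumigen.synthdata import (
    COLUMN_OF,
    OracleParams,
    build_database,
    fill_missing,
    oracle_properties,
    sample_molecules,
    split_by_structure,
    typical_condition,
)


class TestSampler:
    def test_all_sampled_molecules_are_valid(self):
        mols = sample_molecules(100, seed=1)
        assert len(mols) == 100
        assert all(is_valid_molecule(g) for g in mols)

    def test_deterministic_given_seed(self):
        a = [canonical_form(g) for g in sample_molecules(40, seed=2)]
        b = [canonical_form(g) for g in sample_molecules(40, seed=2)]
        assert a == b

    def test_doc_distribution_spans_many_values(self):
        docs = {degree_of_conjugation(g).doc for g in sample_molecules(400, seed=3)}
        assert len(docs) >= 10


class TestOracle:
    def test_deterministic_for_identical_inputs(self):
        g = sample_molecules(1, seed=4)[0]
        s = DEFAULT_SOLVENTS["acetonitrile"]
        assert oracle_properties(g, s) == oracle_properties(g, s)

    def test_unconjugated_molecule_sits_at_baseline(self):
        g = parse_structure("CCCC")
        assert degree_of_conjugation(g).doc == 0
        p = OracleParams(noise_scale=0.0)
        c = oracle_properties(g, DEFAULT_SOLVENTS["toluene"], p)
        assert c.lambda_abs == pytest.approx(p.base_lambda)

    def test_polar_solvent_enlarges_stokes_shift_for_ict(self):
        donor_acceptor = parse_structure("Nc1ccc(cc1)[N+](=O)[O-]")
        shifts = {}
        for sid in ["toluene", "acetonitrile", "water"]:
            c = oracle_properties(donor_acceptor, DEFAULT_SOLVENTS[sid])
            shifts[sid] = c.lambda_emi - c.lambda_abs
        assert shifts["toluene"] < shifts["acetonitrile"] < shifts["water"]

    def test_statistical_structure_of_database(self):
        df = build_database(1000, seed=6)
        assert len(df) == 2000
        corr = df[["lambda_abs_nm", "lambda_emi_nm", "phi",
                   "sigma_abs_cm1", "sigma_emi_cm1"]].corr()
        assert corr.loc["lambda_abs_nm", "lambda_emi_nm"] > 0.8
        assert abs(corr.loc["phi", "lambda_emi_nm"]) < 0.15
        assert corr.loc["sigma_abs_cm1", "sigma_emi_cm1"] > 0.5
        # Stokes positivity: emission above absorption in every record
        assert (df["lambda_emi_nm"] > df["lambda_abs_nm"]).all()
        # plausibility ranges
        assert df["lambda_abs_nm"].between(250, 1000).all()
        assert df["phi"].between(0, 1).all()
        assert (df["tau_ns"] > 0).all()


class TestSplit:
    def test_nine_to_one_on_unique_molecules(self):
        df = build_database(10, seed=7, records_per_molecule=1)
        assert df["smiles"].nunique() == 10
        train, test = split_by_structure(df, ratio=0.9, seed=1)
        assert test["smiles"].nunique() == 1
        assert train["smiles"].nunique() == 9

    def test_all_solvent_records_of_a_molecule_stay_together(self):
        df = build_database(40, seed=8, records_per_molecule=3)
        train, test = split_by_structure(df, ratio=0.8, seed=2)
        assert set(train["smiles"]) & set(test["smiles"]) == set()
        counts = df.groupby("smiles").size()
        for side in (train, test):
            for smi, n in side.groupby("smiles").size().items():
                assert n == counts[smi]

    def test_reproducible_under_seed(self):
        df = build_database(30, seed=9)
        t1 = split_by_structure(df, seed=5)[1]
        t2 = split_by_structure(df, seed=5)[1]
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_molecules_rejected(self):
        df = build_database(1, seed=10, records_per_molecule=1)
        with pytest.raises(ValueError):
            split_by_structure(df)


class TestFillMissing:
    def test_single_missing_cell_filled_others_untouched(self):
        df = build_database(5, seed=11, records_per_molecule=1)
        df.loc[2, "tau_ns"] = np.nan
        before = df.copy()
        filled, prov = fill_missing(df)
        assert filled["tau_ns"].notna().all()
        assert prov.loc[2, "tau_ns"] == "filled"
        untouched = [c for c in df.columns if c != "tau_ns"]
        pd.testing.assert_frame_equal(filled[untouched], before[untouched])

    def test_fully_observed_table_unchanged(self):
        df = build_database(5, seed=12, records_per_molecule=1)
        filled, prov = fill_missing(df)
        pd.testing.assert_frame_equal(filled, df)
        assert (prov[[COLUMN_OF[f] for f in PROPERTY_FIELDS]] == "observed"
                ).all().all()

    def test_filled_cell_count_matches_missing_count(self):
        df = build_database(30, seed=13, missing_rate=0.2)
        n_missing = int(df.isna().sum().sum())
        assert n_missing > 0
        filled, prov = fill_missing(df)
        assert int(filled.isna().sum().sum()) == 0
        assert int((prov == "filled").sum().sum()) == n_missing


class TestTypicalCondition:
    def test_quantile_targets_are_ordered(self):
        df = build_database(150, seed=14)
        lo = typical_condition(df, "toluene", 0.1)
        hi = typical_condition(df, "toluene", 0.9)
        assert lo.lambda_emi < hi.lambda_emi
        assert lo.solvent_id == hi.solvent_id == "toluene"

    def test_unknown_solvent_rejected(self):
        df = build_database(10, seed=15)
        with pytest.raises(ValueError):
            typical_condition(df, "hexafluorobenzene")
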