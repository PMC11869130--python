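import numpy as np
import pytest

from helpers import brute_force_mask
from lumigen.graph import AtomDescriptor, BondType, MolecularGraph, \
    canonical_form, parse_structure
from lumigen.synthdata import sample_molecules
from lumigen.trajectory import (
    AddAction,
    ConnectAction,
    TerminateAction,
    Trajectory,
    TrajectoryError,
    AtomVocabulary,
    apply_action,
    decompose,
    intermediate_valid,
    legal_actions,
    replay,
)


class TestDecomposeReplay:
    def test_methane_is_add_then_terminate(self):
        traj = decompose(parse_structure("C"), seed=0)
        assert len(traj) == 2
        assert isinstance(traj.actions[0], AddAction)
        assert traj.actions[0].attach_to is None
        assert isinstance(traj.actions[1], TerminateAction)

    @pytest.mark.parametrize("smiles", [
        "O=[N+]([O-])c1ccccc1",      # nitrobenzene
        "Nc1ccc(cc1)[N+](=O)[O-]",   # p-nitroaniline
        "c1ccc2ccccc2c1",            # fused rings
        "CC(=O)Oc1ccccc1C(=O)O",
    ])
    def test_roundtrip_reproduces_canonical_form(self, smiles):
        g = parse_structure(smiles)
        for seed in range(10):
            assert canonical_form(replay(decompose(g, seed))) == canonical_form(g)

    def test_hundred_seeds_on_p_nitroaniline(self):
        g = parse_structure("Nc1ccc(cc1)[N+](=O)[O-]")
        ref = canonical_form(g)
        trajs = {tuple(map(str, decompose(g, s).actions)) for s in range(100)}
        assert len(trajs) > 1  # genuinely stochastic
        assert all(
            canonical_form(replay(decompose(g, s))) == ref for s in range(100)
        )

    def test_deterministic_given_seed(self):
        g = parse_structure("CCOc1ccccc1")
        assert decompose(g, 13).actions == decompose(g, 13).actions

    def test_disconnected_input_rejected(self):
        g = MolecularGraph()
        g.add_atom(AtomDescriptor(6))
        g.add_atom(AtomDescriptor(6))
        with pytest.raises(TrajectoryError):
            decompose(g, 0)

    def test_intermediate_states_connected_and_valid(self):
        g = parse_structure("O=[N+]([O-])c1ccc(N)cc1")
        for seed in range(5):
            for state, _ in decompose(g, seed).iter_steps():
                if state.n_atoms:
                    assert state.is_connected()
                    assert intermediate_valid(state)


class TestReplayErrors:
    def test_out_of_range_connect(self):
        actions = [
            AddAction(AtomDescriptor(6)),
            AddAction(AtomDescriptor(6), 0, BondType.SINGLE),
            AddAction(AtomDescriptor(6), 1, BondType.SINGLE),
            ConnectAction(0, 5, BondType.SINGLE),
        ]
        with pytest.raises(TrajectoryError):
            replay(actions)

    def test_duplicate_bond(self):
        actions = [
            AddAction(AtomDescriptor(6)),
            AddAction(AtomDescriptor(6), 0, BondType.SINGLE),
            ConnectAction(0, 1, BondType.SINGLE),
        ]
        with pytest.raises(TrajectoryError):
            replay(actions)

    def test_action_after_terminate(self):
        actions = [
            AddAction(AtomDescriptor(6)),
            TerminateAction(),
            AddAction(AtomDescriptor(6), 0, BondType.SINGLE),
        ]
        with pytest.raises(TrajectoryError):
            replay(actions)


class TestLegalActions:
    def test_empty_state_only_first_atom_adds(self, basic_vocab):
        space = legal_actions(MolecularGraph(), basic_vocab)
        acts = space.legal_list()
        assert len(acts) == len(basic_vocab)
        assert all(isinstance(a, AddAction) and a.attach_to is None for a in acts)
        assert not space.is_legal(TerminateAction())

    def test_saturated_molecule_only_terminate(self, basic_vocab):
        space = legal_actions(parse_structure("FC(F)(F)F"), basic_vocab)
        assert [type(a) for a in space.legal_list()] == [TerminateAction]

    def test_nitrogen_cation_addition_to_benzene(self, basic_vocab):
        benzene = parse_structure("c1ccccc1")
        space = legal_actions(benzene, basic_vocab)
        n_plus = AtomDescriptor(7, 1, 0)
        assert any(
            isinstance(a, AddAction) and a.atom == n_plus
            and a.bond is BondType.SINGLE
            for a in space.legal_list()
        )

    def test_every_legal_action_yields_valid_state(self, basic_vocab):
        g = parse_structure("C=Cc1ccco1")
        space = legal_actions(g, basic_vocab)
        for a in space.legal_list():
            if not isinstance(a, TerminateAction):
                assert intermediate_valid(apply_action(g, a))

    @pytest.mark.parametrize("smiles", ["CC", "C=CC", "c1ccccc1", "c1cc[nH]c1"])
    def test_matches_brute_force_enumeration(self, smiles, basic_vocab):
        space, oracle_mask = brute_force_mask(parse_structure(smiles), basic_vocab)
        assert (space.mask == oracle_mask).all()

    def test_decomposition_actions_are_always_legal(self, basic_vocab):
        for smiles in ["O=[N+]([O-])c1ccccc1", "c1ccc2[nH]ccc2c1",
                       "Cc1ccccc1C=Cc1ccncc1"]:
            g = parse_structure(smiles)
            for seed in range(5):
                for state, action in decompose(g, seed).iter_steps():
                    assert legal_actions(state, basic_vocab).is_legal(action)


class TestSerialization:
    def test_trajectory_jsonl_roundtrip(self):
        g = parse_structure("Nc1ccc(cc1)[N+](=O)[O-]")
        traj = decompose(g, 3)
        restored = Trajectory.from_jsonl(traj.to_jsonl())
        assert restored.actions == traj.actions
        assert canonical_form(restored.final_graph()) == canonical_form(g)
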