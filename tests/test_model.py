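import numpy as np
import pytest

from lumigen.autodiff import Adam
from lumigen.graph import parse_structure
from lumigen.model import (
    Condition,
    ConditionalActionModel,
    ModelConfig,
    NormalizationStats,
    encode_condition,
    train,
)
from lumigen.solvents import DEFAULT_SOLVENTS
from lumigen.synthdata import build_database, training_pairs
from lumigen.trajectory import decompose, legal_actions


FIG_CONDITION = Condition(380.0, 4700.0, 3.6, 550.0, 3800.0, 0.01, 2.0, "water")


def _stats():
    return NormalizationStats(mean=np.array([400, 4000, 4, 500, 3500, 0.3, 3.0]),
                              sd=np.array([100, 500, 0.5, 120, 500, 0.2, 2.0]))


class TestConditionEncoding:
    def test_property_at_training_mean_scores_zero(self):
        stats = _stats()
        c = Condition(400, 4000, 4.0, 500, 3500, 0.3, 3.0, "water")
        vec = encode_condition(c, stats, DEFAULT_SOLVENTS)
        assert np.allclose(vec[:7], 0.0)

    def test_target_condition_encodes_finite(self):
        emb = np.arange(8.0).reshape(2, 4)
        vec = encode_condition(FIG_CONDITION, _stats(), DEFAULT_SOLVENTS,
                               embeddings=emb, solvent_ids=["water", "toluene"])
        assert vec.shape == (7 + 4 + 1,)
        assert np.all(np.isfinite(vec))
        assert np.allclose(vec[7:11], emb[0])

    def test_unknown_solvent_fallback_and_error(self):
        emb = np.ones((1, 4))
        vec = encode_condition(FIG_CONDITION, _stats(), DEFAULT_SOLVENTS,
                               embeddings=emb, solvent_ids=["toluene"])
        assert np.allclose(vec[7:11], 0.0)  # zero embedding, polarity kept
        assert vec[-1] > 0.9
        with pytest.raises(KeyError):
            encode_condition(FIG_CONDITION, _stats(), DEFAULT_SOLVENTS,
                             embeddings=emb, solvent_ids=["toluene"],
                             fallback=False)

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition(380, 4700, 3.6, 550, 3800, 1.5, 2.0, "water")
        with pytest.raises(ValueError):
            Condition(-380, 4700, 3.6, 550, 3800, 0.5, 2.0, "water")


class TestActionDistribution:
    def test_normalized_with_zero_illegal_mass(self, tiny_model):
        cond = FIG_CONDITION
        for smiles in ["C", "c1ccccc1", "C=CCO"]:
            dist = tiny_model.action_distribution(parse_structure(smiles), cond)
            assert abs(dist.probs.sum() - 1.0) < 1e-9
            illegal = ~dist.space.mask
            assert np.all(dist.probs[illegal] == 0.0)

    def test_untrained_model_is_uniform(self, small_db):
        pairs = training_pairs(small_db)[:10]
        vocab_mols = [g for g, _ in pairs]
        from lumigen.trajectory import AtomVocabulary
        model = ConditionalActionModel(
            ModelConfig(seed=0), AtomVocabulary.from_molecules(vocab_mols),
            DEFAULT_SOLVENTS, ["water"], NormalizationStats.fit(
                [c for _, c in pairs]),
        )
        dist = model.action_distribution(parse_structure("CCO"), FIG_CONDITION)
        p = dist.probs[dist.space.legal_indices]
        assert np.allclose(p, 1.0 / len(p))

    def test_support_equals_legal_set(self, tiny_model):
        g = parse_structure("Nc1ccccc1")
        space = legal_actions(g, tiny_model.vocab)
        dist = tiny_model.action_distribution(g, FIG_CONDITION, space)
        assert np.array_equal(dist.probs > 0, space.mask)

    def test_permutation_equivariance(self, tiny_model):
        g = parse_structure("O=[N+]([O-])c1ccc(N)cc1")
        dist = tiny_model.action_distribution(g, FIG_CONDITION)
        rng = np.random.default_rng(1)
        order = list(rng.permutation(g.n_atoms))
        inv = {old: new for new, old in enumerate(order)}
        g2 = g.permuted(order)
        dist2 = tiny_model.action_distribution(g2, FIG_CONDITION)
        from lumigen.trajectory import AddAction, ConnectAction
        for a in dist.space.legal_list():
            if isinstance(a, AddAction) and a.attach_to is not None:
                b = AddAction(a.atom, inv[a.attach_to], a.bond)
            elif isinstance(a, ConnectAction):
                b = ConnectAction(inv[a.i], inv[a.j], a.bond)
            else:
                b = a
            assert dist2.prob_of(b) == pytest.approx(dist.prob_of(a), abs=1e-9)


class TestTraining:
    def test_overfit_single_trajectory_recovers_actions(self):
        """Repeated training on one fixed trajectory drives the probability of
        each recorded action to ~1, up to graph symmetry: a permutation-
        equivariant encoder must split mass evenly over automorphism-
        equivalent actions (e.g. the two ends of an ethane intermediate), so
        the recovered quantity is the mass of the recorded action's orbit."""
        from lumigen.graph import canonical_form
        from lumigen.trajectory import TerminateAction, apply_action

        g = parse_structure("Nc1ccc(cc1)[N+](=O)[O-]")
        model = train([(g, FIG_CONDITION)], ModelConfig(epochs=1, seed=3))
        traj = decompose(g, 11)
        opt = Adam(model.parameters(), lr=2e-2)
        for _ in range(250):
            opt.zero_grad()
            loss = model.trajectory_nll(traj, FIG_CONDITION)
            loss.backward()
            opt.step()

        def frag_key(graph):
            from rdkit import Chem

            mol = graph.to_rdkit(sanitize=False)
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
            return Chem.MolToSmiles(mol)

        def orbit_mass(state, dist, action):
            if isinstance(action, TerminateAction):
                return dist.prob_of(action)
            target = frag_key(apply_action(state, action))
            mass = 0.0
            for idx in dist.space.legal_indices:
                a = dist.space.action_at(int(idx))
                if isinstance(a, TerminateAction):
                    continue
                if frag_key(apply_action(state, a)) == target:
                    mass += dist.probs[idx]
            return mass

        for state, action in traj.iter_steps():
            dist = model.action_distribution(state, FIG_CONDITION)
            assert orbit_mass(state, dist, action) > 0.95

    def test_loss_decreases_over_epochs(self, small_db):
        model = train(training_pairs(small_db)[:60],
                      ModelConfig(epochs=3, seed=5))
        assert model.history[-1] < model.history[0]

    def test_training_is_deterministic(self, small_db):
        pairs = training_pairs(small_db)[:20]
        h1 = train(pairs, ModelConfig(epochs=2, seed=9)).history
        h2 = train(pairs, ModelConfig(epochs=2, seed=9)).history
        assert h1 == h2

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            train([], ModelConfig())


class TestCheckpoint:
    def test_save_load_bit_identical_distribution(self, tiny_model, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        tiny_model.save(path)
        loaded = ConditionalActionModel.load(path)
        g = parse_structure("Cc1ccc(O)cc1")
        d1 = tiny_model.action_distribution(g, FIG_CONDITION)
        d2 = loaded.action_distribution(g, FIG_CONDITION)
        assert np.array_equal(d1.probs, d2.probs)
        assert loaded.history == tiny_model.history
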