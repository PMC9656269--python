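"""GDM fusion: profiles, GA, deviation updates, weight identities,
baseline fusers, and the ensemble fit/predict contract."""

import numpy as np
import pytest

from harfuse import gdm
from harfuse.elm import predict_labels, train_elm
from harfuse.errors import ConfigurationError, ContractError
from harfuse.features import FeatureTable, apply_normalizer, fit_normalizer
import pandas as pd


def _random_profile(rng, m=4, n=50, c=3, mode="crisp"):
    scores = [rng.normal(size=(n, c)) for _ in range(m)]
    return gdm.make_profile(scores, [f"k{j}" for j in range(c)], mode=mode)


class TestMakeProfile:
    def test_crisp_rows_are_one_hot(self, rng):
        p = _random_profile(rng, mode="crisp")
        assert np.all(np.isin(p.U, [0.0, 1.0]))
        np.testing.assert_allclose(p.U.sum(axis=2), 1.0)

    def test_soft_rows_on_simplex(self, rng):
        p = _random_profile(rng, mode="soft")
        assert np.all(p.U >= 0)
        np.testing.assert_allclose(p.U.sum(axis=2), 1.0, atol=1e-9)

    def test_softmax_hand_value(self):
        p = gdm.make_profile([np.array([[2.0, 1.0, 1.0]])],
                             ["a", "b", "c"], mode="soft")
        np.testing.assert_allclose(p.U[0, 0], [0.5761, 0.2119, 0.2119],
                                   atol=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            gdm.make_profile([np.zeros((3, 2)), np.zeros((4, 2))], ["a", "b"])


class TestChromosome:
    def test_decode_ratios(self):
        genes = np.array([
            [0, 1, 0, 0, 0, 0, 0, 0],   # 64
            [0, 1, 0, 0, 0, 0, 0, 0],   # 64
            [1, 0, 0, 0, 0, 0, 0, 0],   # 128
        ])
        np.testing.assert_allclose(gdm.decode_chromosome(genes),
                                   [0.25, 0.25, 0.5])

    def test_equal_genes_uniform(self):
        genes = np.tile([0, 1, 1], (4, 1))
        np.testing.assert_allclose(gdm.decode_chromosome(genes), 0.25)

    def test_single_gene(self):
        np.testing.assert_allclose(gdm.decode_chromosome(np.array([[1, 0]])),
                                   [1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ContractError):
            gdm.decode_chromosome(np.zeros((2, 4), dtype=int))


class TestGAFitness:
    def test_reciprocal_of_errors(self, rng):
        p = _random_profile(rng, m=1, n=10, c=2)
        y = p.decided_indices[0].copy()
        y[:2] = 1 - y[:2]  # two errors for the single uniform-weight expert
        f = gdm.ga_fitness(np.array([1.0]), p, y)
        assert f == pytest.approx(1.0 / (2 + 1e-6))

    def test_perfect_recognition_is_finite_maximal(self, rng):
        p = _random_profile(rng, m=1, n=10, c=2)
        f = gdm.ga_fitness(np.array([1.0]), p, p.decided_indices[0])
        assert f == pytest.approx(1e6, rel=1e-3)

    def test_strictly_monotone_in_correct_count(self, rng):
        # expert 0 perfect, expert 1 always wrong: weights decide
        y = rng.integers(0, 3, size=30)
        U = np.zeros((2, 30, 3))
        U[0, np.arange(30), y] = 1.0
        U[1, np.arange(30), (y + 1) % 3] = 1.0
        p = gdm.DecisionProfile(U=U, class_order=["a", "b", "c"])
        good = gdm.ga_fitness(np.array([0.9, 0.1]), p, y)
        bad = gdm.ga_fitness(np.array([0.1, 0.9]), p, y)
        assert good > bad


class TestGAOptimize:
    def test_seeded_runs_identical(self, rng):
        p = _random_profile(rng, m=3, n=40)
        y = np.asarray(p.class_order, dtype=object)[rng.integers(0, 3, size=40)]
        cfg = gdm.GAConfig(population=10, generations=5, seed=11)
        np.testing.assert_array_equal(gdm.ga_optimize(p, y, cfg),
                                      gdm.ga_optimize(p, y, cfg))

    def test_single_expert_weight_is_one(self, rng):
        p = _random_profile(rng, m=1)
        assert gdm.ga_optimize(p, np.zeros(50, dtype=int)).tolist() == [1.0]

    def test_finds_weights_at_least_as_fit_as_uniform(self, rng):
        """One perfect expert among chance experts: the GA should match
        or beat uniform weighting."""
        n, c, m = 200, 3, 4
        y = rng.integers(0, c, size=n)
        U = np.zeros((m, n, c))
        U[0, np.arange(n), y] = 1.0
        for k in range(1, m):
            U[k, np.arange(n), rng.integers(0, c, size=n)] = 1.0
        p = gdm.DecisionProfile(U=U, class_order=list("abc"))
        labels = np.asarray(list("abc"), dtype=object)[y]
        cfg = gdm.GAConfig(population=30, generations=50, seed=2)
        alpha = gdm.ga_optimize(p, labels, cfg)
        assert gdm.ga_fitness(alpha, p, y) >= gdm.ga_fitness(
            np.full(m, 1 / m), p, y)


class TestGroupDecision:
    def test_weighted_sum_example(self):
        G = gdm.group_decision(np.array([0.6, 0.4]),
                               np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        np.testing.assert_allclose(G, [0.6, 0.4, 0.0])

    def test_identical_experts_reproduce_their_vector(self):
        u = np.array([0.2, 0.5, 0.3])
        G = gdm.group_decision(np.array([0.5, 0.5]), np.stack([u, u]))
        np.testing.assert_allclose(G, u)

    def test_uniform_crisp_equals_plurality_oracle(self, rng):
        classes = list("abc")
        for _ in range(200):
            p = _random_profile(rng, m=5, n=8, c=3)
            G = gdm.group_decide_batch(np.full(5, 0.2), p.U)
            fused = np.argmax(G, axis=1)
            for x in range(8):
                votes = [0, 0, 0]
                for k in range(5):
                    votes[int(p.decided_indices[k, x])] += 1
                oracle = max(range(3), key=lambda j: (votes[j], -j))
                assert fused[x] == oracle


class TestDeviations:
    def test_zero_when_expert_equals_group(self, rng):
        G = rng.dirichlet(np.ones(3), size=10)
        r = gdm.deviations(np.stack([G, G]), G)
        np.testing.assert_allclose(r, 0.0)

    def test_hand_value(self):
        r = gdm.deviations(np.array([[[1.0, 0.0]]]), np.array([[0.5, 0.5]]))
        assert r[0] == pytest.approx(0.5)

    def test_sample_permutation_invariant(self, rng):
        U = rng.dirichlet(np.ones(3), size=(4, 20))
        G = rng.dirichlet(np.ones(3), size=20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(gdm.deviations(U, G),
                                   gdm.deviations(U[:, perm], G[perm]))


class TestWeightUpdate:
    def test_hand_worked_update(self):
        beta = gdm.update_objective_weights(
            np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.4, 0.4]), 0.05)
        np.testing.assert_allclose(beta, [0.55, 0.275, 0.175], atol=1e-12)
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_deviations_no_update(self):
        beta = np.array([0.6, 0.4])
        np.testing.assert_array_equal(
            gdm.update_objective_weights(beta, np.array([0.3, 0.3])), beta)

    def test_simplex_conserved_over_many_updates(self, rng):
        beta = rng.dirichlet(np.ones(5))
        for _ in range(100):
            beta = gdm.update_objective_weights(beta, rng.uniform(size=5))
            assert np.all(beta >= 0)
            assert beta.sum() == pytest.approx(1.0, abs=1e-9)


class TestCombineWeights:
    @pytest.mark.parametrize("phi, expect", [(1.0, "alpha"), (0.0, "beta")])
    def test_endpoints(self, phi, expect):
        alpha, beta = np.array([0.8, 0.2]), np.array([0.2, 0.8])
        lam = gdm.combine_weights(alpha, beta, phi)
        np.testing.assert_allclose(lam, alpha if expect == "alpha" else beta)

    def test_symmetric_midpoint(self):
        lam = gdm.combine_weights(np.array([0.8, 0.2]), np.array([0.2, 0.8]), 0.5)
        np.testing.assert_allclose(lam, [0.5, 0.5])


def _expert_tables(rng, n=60):
    """Two separable single-channel groups + labels, as one table."""
    y = np.array(["a", "b"] * (n // 2))
    base = np.where(y == "a", 0.2, 0.8)[:, None]
    df = pd.DataFrame({
        "g1:0:mean": (base + rng.normal(0, 0.05, size=(n, 1))).ravel(),
        "g2:1:mean": (base + rng.normal(0, 0.05, size=(n, 1))).ravel(),
    })
    groups = {"g1": ["g1:0:mean"], "g2": ["g2:1:mean"]}
    return FeatureTable(values=df, labels=y, groups=groups)


class TestFitPredictEnsemble:
    def test_single_expert_weight_and_predictions(self, rng):
        table = _expert_tables(rng)
        models = {"g1": train_elm(table.group_matrix("g1"), table.labels,
                                  hidden=10, seed=0, group_id="g1")}
        ens = gdm.fit_gdm_ensemble(models, table, expert_ids=["g1"])
        assert ens.weights.lam.tolist() == [1.0]
        np.testing.assert_array_equal(
            gdm.predict_ensemble(ens, table),
            predict_labels(models["g1"], table.group_matrix("g1")))

    def test_identical_experts_keep_alpha(self, rng):
        table = _expert_tables(rng)
        m = train_elm(table.group_matrix("g1"), table.labels, hidden=10, seed=0)
        models = {"g1": m, "g2": m}  # same model object: identical decisions
        cfg = gdm.GAConfig(population=8, generations=4, seed=1)
        ens = gdm.fit_gdm_ensemble(models, table, ga_config=cfg)
        np.testing.assert_allclose(ens.weights.lam, ens.weights.alpha)

    def test_phi_one_reproduces_ga_baseline(self, rng):
        p = _random_profile(rng, m=4, n=60)
        y = np.asarray(p.class_order, dtype=object)[
            rng.integers(0, 3, size=60)]
        cfg = gdm.GAConfig(population=12, generations=8, seed=5)
        w = gdm.fit_gdm_weights(p, y, phi=1.0, ga_config=cfg)
        np.testing.assert_array_equal(w.lam, gdm.ga_optimize(p, y, cfg))

    def test_crisp_uniform_lambda_equals_majority_vote(self, rng):
        p = _random_profile(rng, m=5, n=100)
        G = gdm.group_decide_batch(np.full(5, 0.2), p.U)
        co = np.asarray(p.class_order, dtype=object)
        fused = co[np.argmax(G, axis=1)]
        np.testing.assert_array_equal(
            fused, gdm.majority_vote(p.decided_labels, p.class_order))

    def test_fit_is_deterministic(self, rng):
        table = _expert_tables(rng)
        models = {
            g: train_elm(table.group_matrix(g), table.labels, hidden=10,
                         seed=i, group_id=g)
            for i, g in enumerate(["g1", "g2"])
        }
        cfg = gdm.GAConfig(population=8, generations=4, seed=3)
        a = gdm.fit_gdm_ensemble(models, table, ga_config=cfg)
        b = gdm.fit_gdm_ensemble(models, table, ga_config=cfg)
        np.testing.assert_array_equal(a.weights.lam, b.weights.lam)
        np.testing.assert_array_equal(gdm.predict_ensemble(a, table),
                                      gdm.predict_ensemble(b, table))

    def test_missing_group_rejected(self, rng):
        table = _expert_tables(rng)
        models = {"g1": train_elm(table.group_matrix("g1"), table.labels,
                                  hidden=10, seed=0)}
        ens = gdm.fit_gdm_ensemble(models, table, expert_ids=["g1"])
        bad = FeatureTable(values=table.values[["g2:1:mean"]].copy(),
                           labels=table.labels,
                           groups={"g2": ["g2:1:mean"]})
        with pytest.raises(ContractError):
            gdm.predict_ensemble(ens, bad)


class TestBaselineFusers:
    def test_agreeing_experts_all_fusers_agree(self, rng):
        n, c = 30, 3
        y = rng.integers(0, c, size=n)
        U = np.zeros((3, n, c))
        U[:, np.arange(n), y] = 1.0
        p = gdm.DecisionProfile(U=U, class_order=list("abc"))
        labels = np.asarray(list("abc"), dtype=object)[y]
        fusers = gdm.baseline_fusers(
            p, labels, gdm.GAConfig(population=6, generations=3, seed=0))
        for lam in fusers.values():
            G = gdm.group_decide_batch(lam, p.U)
            np.testing.assert_array_equal(np.argmax(G, axis=1), y)

    def test_wa_weights_sum_to_one_and_track_accuracy(self, rng):
        p = _random_profile(rng, m=4, n=80)
        y = p.decided_labels[0]  # expert 0 perfectly accurate
        fusers = gdm.baseline_fusers(
            p, y, gdm.GAConfig(population=6, generations=3, seed=0))
        wa = fusers["wa"]
        assert wa.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(wa) == 0

    def test_mv_matches_vote_counting_oracle(self, rng):
        for _ in range(100):
            p = _random_profile(rng, m=5, n=6)
            mv = gdm.majority_vote(p.decided_labels, p.class_order)
            for x in range(6):
                votes = {}
                for k in range(5):
                    votes[p.decided_labels[k, x]] = votes.get(
                        p.decided_labels[k, x], 0) + 1
                top = max(votes.values())
                winners = [cls for cls in p.class_order
                           if votes.get(cls, 0) == top]
                assert mv[x] == winners[0]
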