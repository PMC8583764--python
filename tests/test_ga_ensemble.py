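"""Weighted voting, normalization, GA phases and ensemble fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import q8fuse as q
from q8fuse.ga_ensemble import PooledFitness, _normalize_batch, _rank_desc

ALPHA = q.DEFAULT_ALPHABET


def _wm(values, ids=("A", "B")):
    return q.WeightMatrix(classifier_ids=tuple(ids[: len(values)]), values=np.asarray(values))


class TestWeightedVote:
    def test_single_classifier_unit_weights_is_own_argmax(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(8))[None, :]
        w = _wm(np.ones((1, 8)), ids=("A",))
        assert q.weighted_vote(p, w) == int(p[0].argmax())

    def test_hand_computed_two_classifier_case(self):
        # classes B and E: scores are 0.6*1 vs 0.8*1 -> E wins
        p = np.zeros((2, 8))
        p[0, :2] = (0.6, 0.4)
        p[1, :2] = (0.2, 0.8)
        w = np.zeros((2, 8))
        w[0, 0] = 1.0  # classifier 1 votes only on B
        w[1, 1] = 1.0  # classifier 2 votes only on E
        assert q.weighted_vote(p, _wm(w)) == ALPHA.index_of("E")

    def test_all_zero_weights_tie_breaks_to_class_B(self):
        p = np.full((2, 8), 1 / 8)
        assert q.weighted_vote(p, _wm(np.zeros((2, 8)))) == ALPHA.index_of("B")

    def test_highest_tie_break(self):
        p = np.full((1, 8), 1 / 8)
        w = np.ones((1, 8))
        assert q.weighted_vote(p, _wm(w, ids=("A",)), tie_break="highest") == 7

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-3, 1e3))
    def test_positive_scaling_never_changes_label(self, seed, scale):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(8), size=3)
        w = rng.uniform(0, 1, size=(3, 8))
        assert q.weighted_vote(p, _wm(w, ids="ABC")) == q.weighted_vote(
            p, _wm(w * scale, ids="ABC")
        )


class TestNormalization:
    def test_divide_by_max(self):
        w = _wm(np.array([[0.2, 0.4, 0.8, 0, 0, 0, 0, 0]]), ids=("A",))
        out = q.normalize_individual(w)
        np.testing.assert_allclose(out.values[0, :3], [0.25, 0.5, 1.0])

    def test_max_one_unchanged(self):
        vals = np.zeros((1, 8))
        vals[0, 3] = 1.0
        vals[0, 5] = 0.4
        np.testing.assert_array_equal(q.normalize_weights(vals), vals)

    def test_constant_individual_becomes_all_ones(self):
        out = q.normalize_weights(np.full((2, 8), 0.3))
        np.testing.assert_allclose(out, 1.0)

    def test_all_zero_repaired_with_rng(self):
        rng = np.random.default_rng(1)
        out = q.normalize_weights(np.zeros((2, 8)), rng)
        assert out.max() > 0

    def test_batch_normalization_max_is_one(self):
        rng = np.random.default_rng(2)
        pop = rng.uniform(0, 1, size=(50, 3, 8))
        pop = _normalize_batch(pop, rng)
        np.testing.assert_allclose(pop.max(axis=(1, 2)), 1.0)


class TestInitPopulation:
    def test_population_size_and_selectors(self):
        cfg = q.GAConfig()
        pop = q.init_population(cfg, 5, np.random.default_rng(0))
        assert pop.shape == (2005, 5, 8)  # 2000 random + 5 selectors
        # selector c is 1 on all classes of classifier c, 0 elsewhere
        np.testing.assert_array_equal(pop[-5][0], np.ones(8))
        assert pop[-5][1:].sum() == 0

    def test_five_classifiers_forty_weights(self):
        pop = q.init_population(q.GAConfig(), 5, np.random.default_rng(0))
        assert pop[0].size == 40

    def test_seeded_init_is_bit_identical(self):
        cfg = q.GAConfig(seed=3)
        a = q.init_population(cfg, 3, np.random.default_rng(cfg.seed))
        b = q.init_population(cfg, 3, np.random.default_rng(cfg.seed))
        np.testing.assert_array_equal(a, b)

    def test_config_arithmetic_enforced(self):
        with pytest.raises(ValueError, match="half the population"):
            q.GAConfig(population_size=2000, n_parents=100, n_crossover=800)


class TestGAPhase:
    def _fitness_and_pop(self, cfg, n_clf=2, seed=0):
        ds = q.make_toy_dataset(6, (20, 40), seed=seed)
        profiles = [q.SkillProfile.uniform(f"c{i}", 0.4 + 0.1 * i) for i in range(n_clf)]
        pset = q.make_planted_predictions(ds, profiles, seed=seed + 1)
        fitness = PooledFitness(pset, ds.labels())
        rng = np.random.default_rng(cfg.seed)
        return fitness, q.init_population(cfg, n_clf, rng), rng

    def test_interim_pool_arithmetic(self, small_ga_config):
        cfg = small_ga_config
        # parents + crossover offspring == half the population; mutants restore it
        assert cfg.n_parents + cfg.n_crossover == cfg.population_size // 2
        assert cfg.n_mutants == cfg.population_size // 2
        fitness, pop, rng = self._fitness_and_pop(cfg)
        res = q.ga_phase(pop, fitness, cfg, rng)
        assert res.final_pool.shape[0] == cfg.population_size

    def test_best_q8_is_non_decreasing(self, small_ga_config):
        fitness, pop, rng = self._fitness_and_pop(small_ga_config)
        res = q.ga_phase(pop, fitness, small_ga_config, rng)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))

    def test_early_stop_on_stagnation(self):
        cfg = q.GAConfig(
            population_size=40, n_parents=4, n_crossover=16,
            max_generations=500, patience=5, seed=0,
        )
        # constant fitness can never strictly improve -> stop at patience
        fitness = lambda batch: np.zeros(batch.shape[0] if batch.ndim == 3 else 1)
        pop = q.init_population(cfg, 2, np.random.default_rng(0))
        res = q.ga_phase(pop, fitness, cfg, np.random.default_rng(0))
        assert res.generations == cfg.patience

    def test_normalized_individuals_have_unit_max(self, small_ga_config):
        fitness, pop, rng = self._fitness_and_pop(small_ga_config)
        res = q.ga_phase(pop, fitness, small_ga_config, rng)
        np.testing.assert_allclose(res.final_pool.max(axis=(1, 2)), 1.0)


class TestLocalSearch:
    def test_pool_size_and_elitism(self, small_ga_config):
        cfg = small_ga_config
        rng = np.random.default_rng(0)
        top = rng.uniform(0, 1, (cfg.ls_pool, 2, 8))
        calls = []

        def fitness(batch):
            calls.append(batch.shape[0])
            return batch.mean(axis=(1, 2))

        res = q.local_search_phase(top, fitness, cfg, rng)
        # one evaluation of the entrants, then ls_pool mutants per generation
        assert calls[0] == cfg.ls_pool
        assert all(c == cfg.ls_pool for c in calls[1:])
        assert res.final_pool.shape[0] == cfg.ls_pool
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))

    def test_zero_sigma_zero_rate_is_noop(self, small_ga_config):
        import dataclasses

        cfg = dataclasses.replace(small_ga_config, ls_sigma=0.0, mutation_rate=0.0)
        rng = np.random.default_rng(1)
        top = _normalize_batch(rng.uniform(0, 1, (cfg.ls_pool, 2, 8)), rng)
        fitness = lambda b: b.mean(axis=(1, 2))
        res = q.local_search_phase(top, fitness, cfg, rng)
        assert res.best_q8 == pytest.approx(float(fitness(top).max()))

    def test_wrong_entrant_count_rejected(self, small_ga_config):
        with pytest.raises(q.ValidationError, match="entrants"):
            q.local_search_phase(
                np.zeros((3, 2, 8)), lambda b: np.zeros(len(b)), small_ga_config,
                np.random.default_rng(0),
            )


class TestFitEnsemble:
    def test_complementary_skills_beat_both_individuals(
        self, toy_dataset, complementary_pset, small_ga_config
    ):
        labels = toy_dataset.labels()
        res = q.fit_ensemble(complementary_pset, labels, config=small_ga_config)
        q_a = q.q8_accuracy(complementary_pset.argmax_labels("A"), labels)
        q_b = q.q8_accuracy(complementary_pset.argmax_labels("B"), labels)
        assert res.q8 > max(q_a, q_b)

    def test_single_classifier_never_below_its_own_q8(self, toy_dataset, small_ga_config):
        # the seeded selector guarantees at least the classifier's raw
        # argmax Q8; per-class weights act as class priors, so the GA
        # may legitimately end strictly above it
        labels = toy_dataset.labels()
        pset = q.make_planted_predictions(
            toy_dataset, [q.SkillProfile.uniform("only", 0.6)], seed=3
        )
        res = q.fit_ensemble(pset, labels, config=small_ga_config)
        assert res.q8 >= q.q8_accuracy(pset.argmax_labels("only"), labels)

    def test_duplicated_classifier_adds_no_information(self, toy_dataset, small_ga_config):
        # a duplicate only re-scales class scores: the fused labels of
        # any duplicate-pair weighting equal a single-classifier vote
        # with the summed weights, so the reachable family is unchanged
        labels = toy_dataset.labels()
        single = q.make_planted_predictions(
            toy_dataset, [q.SkillProfile.uniform("c", 0.6)], seed=4
        )
        dup = q.PredictionSet(
            classifier_ids=("c1", "c2"),
            probs={pid: np.concatenate([arr, arr]) for pid, arr in single.probs.items()},
        )
        res = q.fit_ensemble(dup, labels, config=small_ga_config)
        assert res.q8 >= q.q8_accuracy(single.argmax_labels("c"), labels)
        w_eff = q.WeightMatrix(("c",), res.weights.values.sum(axis=0, keepdims=True) / 2)
        collapsed = q.apply_ensemble(single, w_eff)
        fused = q.apply_ensemble(dup, res.weights)
        for pid in labels:
            np.testing.assert_array_equal(fused.labels[pid], collapsed.labels[pid])

    def test_identical_seed_identical_weights(self, toy_dataset, complementary_pset, small_ga_config):
        r1 = q.fit_ensemble(complementary_pset, toy_dataset.labels(), config=small_ga_config)
        r2 = q.fit_ensemble(complementary_pset, toy_dataset.labels(), config=small_ga_config)
        np.testing.assert_array_equal(r1.weights.values, r2.weights.values)
        assert r1.q8 == r2.q8

    def test_mismatched_shapes_error_before_evolution(self, toy_dataset, complementary_pset):
        labels = toy_dataset.labels()
        first = next(iter(labels))
        labels[first] = labels[first][:-1]
        with pytest.raises(q.ValidationError):
            q.fit_ensemble(complementary_pset, labels)


class TestApplyEnsemble:
    def test_reproduces_fitted_q8_on_validation(
        self, toy_dataset, complementary_pset, small_ga_config
    ):
        labels = toy_dataset.labels()
        res = q.fit_ensemble(complementary_pset, labels, config=small_ga_config)
        fused = q.apply_ensemble(complementary_pset, res.weights)
        assert q.q8_accuracy(fused.labels, labels) == pytest.approx(res.q8, abs=1e-12)

    def test_selector_weights_reproduce_that_classifier(self, complementary_pset):
        w = np.zeros((2, 8))
        w[1] = 1.0
        res = q.apply_ensemble(complementary_pset, _wm(w))
        own = complementary_pset.argmax_labels("B")
        for pid in own:
            np.testing.assert_array_equal(res.labels[pid], own[pid])

    def test_all_abstention_rows_flagged(self):
        probs = np.zeros((1, 4, 8))
        probs[0, :2] = np.eye(8)[3]
        pset = q.PredictionSet(classifier_ids=("t",), probs={"p": probs})
        res = q.apply_ensemble(pset, _wm(np.ones((1, 8)), ids=("t",)))
        np.testing.assert_array_equal(res.no_vote["p"], [False, False, True, True])
        assert res.labels["p"][2] == 0  # tie-break label on abstention

    def test_classifier_order_mismatch_lists_both(self, complementary_pset):
        w = q.WeightMatrix(classifier_ids=("B", "A"), values=np.ones((2, 8)))
        with pytest.raises(q.ValidationError, match=r"\['A', 'B'\].*\['B', 'A'\]"):
            q.apply_ensemble(complementary_pset, w)


class TestForwardReverseFusion:
    def test_idempotent_on_equal_inputs(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(8), size=6)
        np.testing.assert_allclose(q.fuse_forward_reverse(p, p), p)

    def test_symmetric_one_hot_average(self):
        a = np.zeros((1, 8)); a[0, 0] = 1.0
        b = np.zeros((1, 8)); b[0, 1] = 1.0
        out = q.fuse_forward_reverse(a, b)
        np.testing.assert_allclose(out[0, :2], [0.5, 0.5])
        assert out[0, 2:].sum() == 0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        a = rng.dirichlet(np.ones(8), size=20)
        b = rng.dirichlet(np.ones(8), size=20)
        np.testing.assert_allclose(q.fuse_forward_reverse(a, b).sum(axis=1), 1.0, atol=1e-9)

    def test_double_zero_rows_stay_zero_with_warning(self):
        a = np.zeros((2, 8)); b = np.zeros((2, 8))
        a[0, 2] = b[0, 2] = 1.0
        with pytest.warns(UserWarning, match="all-zero"):
            out = q.fuse_forward_reverse(a, b)
        assert out[1].sum() == 0


class TestSerialization:
    def test_weight_matrix_json_round_trip(self):
        rng = np.random.default_rng(7)
        w = q.WeightMatrix(("x", "y"), rng.uniform(0, 1, (2, 8)), provenance="crossover")
        back = q.WeightMatrix.from_json(w.to_json())
        assert back.classifier_ids == ("x", "y")
        np.testing.assert_allclose(back.values, w.values)
        assert back.provenance == "crossover"

    def test_prediction_files_round_trip(self, tmp_path, toy_dataset, complementary_pset):
        paths = q.write_prediction_files(complementary_pset, tmp_path)
        back = q.read_prediction_files(paths)
        assert back.classifier_ids == complementary_pset.classifier_ids
        for pid in complementary_pset.probs:
            np.testing.assert_allclose(
                back.probs[pid], complementary_pset.probs[pid], atol=1e-7
            )

    def test_prediction_rows_must_sum_to_one_or_zero(self):
        probs = np.full((1, 2, 8), 0.2)
        pset = q.PredictionSet(classifier_ids=("c",), probs={"p": probs})
        with pytest.raises(q.ValidationError, match="sums to"):
            pset.validate()
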