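"""The evolutionary engine: dipole seeding, fitness, operators, selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from evotsp import (EvoConfig, ExpressionMatrix, Individual, LabelVector,
                    WeightedPair, classify, crossover,
                    effective_pair_from_dipole, evolve, fit_evotsp, fitness,
                    init_population, mutate, select_next_generation)
from evotsp.baselines import KTspModel, predict as baseline_predict
from evotsp.evo import (MUT_ADD, MUT_SIGN, MUT_WEIGHT, DipoleError,
                        rank_selection_probabilities)

from conftest import make_random_dataset


class TestDipole:
    def test_returned_pair_orders_differently_across_the_dipole(self):
        expr, labels = make_random_dataset(30, 20, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            pair = effective_pair_from_dipole(expr, labels, rng)
            # an effective pair never selects only one class on tie-free data:
            # its relation holds in some sample and fails in another
            pred = classify(Individual([pair]), expr)
            assert set(pred.tolist()) == {0, 1}
            assert pair.weight == 1.0
            assert pair.i != pair.j

    def test_single_pair_classifier_separates_its_dipole(self):
        # replay: drawing with a cloned generator exposes q and w, and the
        # pair built from them must classify them into different classes
        expr, labels = make_random_dataset(25, 24, seed=3)
        for seed in range(300):
            rng = np.random.default_rng(seed)
            replay = np.random.default_rng(seed)
            idx1 = np.flatnonzero(labels.y == 0)
            idx2 = np.flatnonzero(labels.y == 1)
            q = int(idx1[replay.integers(len(idx1))])
            w = int(idx2[replay.integers(len(idx2))])
            pair = effective_pair_from_dipole(expr, labels, rng)
            pred = classify(Individual([pair]), expr, sample_indices=[q, w])
            assert pred[0] == 0 and pred[1] == 1

    def test_constant_matrix_exhausts_retries(self):
        expr = ExpressionMatrix(np.ones((5, 6)), tuple("abcde"),
                                tuple(f"s{k}" for k in range(6)))
        labels = LabelVector(("A",) * 3 + ("B",) * 3, ("A", "B"))
        with pytest.raises(DipoleError, match="after 50 draws"):
            effective_pair_from_dipole(expr, labels,
                                       np.random.default_rng(0), retry_limit=50)


class TestInitPopulation:
    def test_size_k_range_and_unit_weights(self):
        expr, labels = make_random_dataset(40, 30, seed=5)
        pop = init_population(expr, labels, EvoConfig(seed=7))
        assert len(pop) == 100
        for ind in pop:
            assert 1 <= ind.k <= 5
            assert 2 <= ind.u <= 2 * ind.k
            assert all(p.weight == 1.0 for p in ind.pairs)

    def test_same_seed_reproduces_population(self):
        expr, labels = make_random_dataset(40, 30, seed=5)
        a = init_population(expr, labels, EvoConfig(seed=9))
        b = init_population(expr, labels, EvoConfig(seed=9))
        assert [[p.canonical() for p in ind.pairs] for ind in a] == \
            [[p.canonical() for p in ind.pairs] for ind in b]

    def test_k_distribution_uniform_on_1_to_5(self):
        expr, labels = make_random_dataset(20, 20, seed=2)
        cfg = EvoConfig(population_size=10_000, seed=123)
        counts = np.bincount([ind.k for ind in
                              init_population(expr, labels, cfg)],
                             minlength=6)[1:6]
        _, pval = chisquare(counts)
        assert pval > 0.01


class TestClassifyAndFitness:
    def test_single_pair_vote(self):
        expr = ExpressionMatrix([[0.5, 2.0], [1.0, 1.0]], ("a", "b"),
                                ("s1", "s2"))
        ind = Individual([WeightedPair(0, 1, less_votes_c1=True)])
        assert classify(ind, expr).tolist() == [0, 1]

    def test_weighted_vote_beats_two_unit_votes(self):
        # pair voting C1 with weight 4 against two unit pairs voting C2
        expr = ExpressionMatrix(
            [[1.0, 1.0], [2.0, 2.0], [9.0, 9.0], [8.0, 8.0], [7.0, 7.0],
             [6.0, 6.0]], tuple("abcdef"), ("s1", "s2"))
        ind = Individual([
            WeightedPair(0, 1, True, weight=4.0),   # 1 < 2 → C1
            WeightedPair(2, 3, True, weight=1.0),   # 9 < 8 false → C2
            WeightedPair(4, 5, True, weight=1.0),   # 7 < 6 false → C2
        ])
        assert classify(ind, expr).tolist() == [0, 0]

    def test_equal_weights_match_ktsp_majority(self):
        # odd-k unweighted individuals are exactly k-TSP majority voters
        rng = np.random.default_rng(44)
        for trial in range(100):
            expr, labels = make_random_dataset(12, 11, seed=trial + 500)
            k = int(rng.choice([1, 3, 5]))
            pairs = []
            used = rng.choice(12, size=2 * k, replace=False)
            for t in range(k):
                pairs.append(WeightedPair(int(used[2 * t]),
                                          int(used[2 * t + 1]), True))
            ind = Individual([p.copy() for p in pairs])
            model = KTspModel(
                pairs=tuple((f"g{p.i}", f"g{p.j}", True, None)
                            for p in pairs),
                k=k, class_order=("A", "B"))
            mine = [labels.class_order[c] for c in classify(ind, expr)]
            assert mine == baseline_predict(model, expr)

    def test_fitness_arithmetic(self):
        # perfect single-pair classifier: 1 − 0.005·(2+2) = 0.98
        expr = ExpressionMatrix([[1, 1, 5, 5], [3, 3, 2, 2]], ("a", "b"),
                                ("s1", "s2", "s3", "s4"))
        labels = LabelVector(("A", "A", "B", "B"), ("A", "B"))
        ind = Individual([WeightedPair(0, 1, True)])
        assert fitness(ind, expr, labels, alpha=0.005) == pytest.approx(0.98)
        ind.invalidate()
        assert fitness(ind, expr, labels, alpha=0.0) == 1.0

    def test_fitness_affine_in_alpha(self):
        expr, labels = make_random_dataset(10, 20, seed=21)
        ind = Individual([WeightedPair(0, 1, True), WeightedPair(2, 3, False),
                          WeightedPair(0, 4, True)])
        slope = -(2 * ind.k + ind.u)
        vals = []
        for alpha in (0.0, 0.005, 0.02):
            ind.invalidate()
            vals.append(fitness(ind, expr, labels, alpha))
        assert vals[1] - vals[0] == pytest.approx(slope * 0.005)
        assert vals[2] - vals[0] == pytest.approx(slope * 0.02)

    def test_redundant_pair_costs_exactly_its_penalty(self):
        expr, labels = make_random_dataset(10, 20, seed=22)
        base = Individual([WeightedPair(0, 1, True, weight=4.0)])
        # duplicate of the same rule at tiny weight cannot flip any decision
        extra = Individual([WeightedPair(0, 1, True, weight=4.0),
                            WeightedPair(0, 1, True, weight=1.0)])
        alpha = 0.005
        f0 = fitness(base, expr, labels, alpha)
        f1 = fitness(extra, expr, labels, alpha)
        delta_u = extra.u - base.u  # 0: same genes
        assert f0 - f1 == pytest.approx(alpha * (2 + delta_u))


class TestOperators:
    def _two_individuals(self):
        a = Individual([WeightedPair(0, 1, True), WeightedPair(2, 3, False)])
        b = Individual([WeightedPair(4, 5, True), WeightedPair(6, 7, True),
                        WeightedPair(8, 9, False)])
        return a, b

    def test_exchange_preserves_pair_multiset_and_counts(self):
        rng = np.random.default_rng(0)
        a, b = self._two_individuals()
        before = sorted(p.canonical() for p in a.pairs + b.pairs)
        crossover(a, b, a.copy(), rng, p_exchange_variant=1.0)
        assert (a.k, b.k) == (2, 3)
        assert sorted(p.canonical() for p in a.pairs + b.pairs) == before
        assert a.cached_fitness is None and b.cached_fitness is None

    def test_injection_copies_a_pair_from_best(self):
        rng = np.random.default_rng(1)
        a, b = self._two_individuals()
        best = Individual([WeightedPair(10, 11, True, weight=8.0)])
        b_before = [p.canonical() for p in b.pairs]
        crossover(a, b, best, rng, p_exchange_variant=0.0)
        assert any(p.canonical() == (10, 11, True, 8.0) for p in a.pairs)
        assert [p.canonical() for p in b.pairs] == b_before  # b untouched

    def test_weight_mutation_halves_or_doubles(self):
        expr, labels = make_random_dataset(10, 10, seed=1)
        seen = set()
        for seed in range(40):
            ind = Individual([WeightedPair(0, 1, True, weight=1.0)])
            mutate(ind, expr, labels, np.random.default_rng(seed),
                   variant=MUT_WEIGHT)
            seen.add(ind.pairs[0].weight)
        assert seen == {0.5, 2.0}

    def test_sign_switch_is_an_involution(self):
        expr, labels = make_random_dataset(10, 10, seed=1)
        ind = Individual([WeightedPair(3, 7, True, weight=2.0)])
        rng = np.random.default_rng(5)
        mutate(ind, expr, labels, rng, variant=MUT_SIGN)
        assert ind.pairs[0].less_votes_c1 is False
        mutate(ind, expr, labels, rng, variant=MUT_SIGN)
        assert ind.pairs[0].canonical() == WeightedPair(3, 7, True, 2.0).canonical()

    def test_add_grows_past_the_initialization_cap(self):
        expr, labels = make_random_dataset(10, 10, seed=1)
        rng = np.random.default_rng(2)
        ind = Individual([effective_pair_from_dipole(expr, labels, rng)
                          for _ in range(5)])
        mutate(ind, expr, labels, rng, variant=MUT_ADD)
        assert ind.k == 6

    def test_remove_on_singleton_redraws_instead_of_emptying(self):
        expr, labels = make_random_dataset(10, 10, seed=1)
        for seed in range(30):
            ind = Individual([WeightedPair(0, 1, True)])
            mutate(ind, expr, labels, np.random.default_rng(seed))
            assert ind.k >= 1

    def test_gene_exchange_never_creates_self_pair(self):
        expr, labels = make_random_dataset(6, 10, seed=1)
        from evotsp.evo import MUT_EXCHANGE_GENE
        for seed in range(60):
            ind = Individual([WeightedPair(2, 3, True)])
            mutate(ind, expr, labels, np.random.default_rng(seed),
                   variant=MUT_EXCHANGE_GENE)
            assert ind.pairs[0].i != ind.pairs[0].j


class TestSelection:
    def test_linear_rank_probabilities(self):
        probs = rank_selection_probabilities(4)
        assert probs.tolist() == [1 / 10, 2 / 10, 3 / 10, 4 / 10]
        assert rank_selection_probabilities(100).sum() == pytest.approx(1.0)

    def test_elite_copy_and_constant_size(self):
        expr, labels = make_random_dataset(15, 20, seed=8)
        rng = np.random.default_rng(3)
        pop = init_population(expr, labels, EvoConfig(population_size=20,
                                                      seed=4), rng)
        fits = [fitness(ind, expr, labels, 0.005) for ind in pop]
        nxt = select_next_generation(pop, fits, rng)
        assert len(nxt) == 20
        best = max(fits)
        assert nxt[0].cached_fitness == best
        # elitist slot is a copy, not an alias
        src = pop[int(np.argmax(fits))]
        assert nxt[0] is not src


class TestEvolve:
    def test_history_best_fitness_never_decreases(self):
        expr, labels = make_random_dataset(50, 30, seed=10)
        cfg = EvoConfig(population_size=30, stall_generations=40,
                        max_generations=120, seed=6)
        _, history = evolve(expr, labels, cfg)
        best = history["best_fitness"]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_stall_triggers_on_immediate_perfection(self):
        # a perfect planted pair appears in generation 0 with high probability
        # given dipole seeding; once fitness plateaus the stall counter stops
        # the run long before max_generations
        from evotsp import PlantSpec, generate
        expr, labels, _ = generate(PlantSpec(n_genes=20, n_samples=40,
                                             planted_pairs=((0, 1),),
                                             noise_eps=0.0, seed=12))
        cfg = EvoConfig(population_size=50, stall_generations=50,
                        max_generations=5000, seed=2)
        _, history = evolve(expr, labels, cfg)
        assert len(history["best_fitness"]) <= 400

    def test_identical_seeds_identical_outcome(self):
        expr, labels = make_random_dataset(30, 24, seed=15)
        cfg = EvoConfig(population_size=25, stall_generations=25,
                        max_generations=80, seed=99)
        best_a, hist_a = evolve(expr, labels, cfg)
        best_b, hist_b = evolve(expr, labels, cfg)
        assert best_a.sort_key() == best_b.sort_key()
        assert hist_a == hist_b

    def test_model_json_round_trip(self):
        from evotsp.evo import EvoTspModel
        expr, labels = make_random_dataset(20, 20, seed=16)
        cfg = EvoConfig(population_size=20, stall_generations=15,
                        max_generations=40, seed=3)
        model = fit_evotsp(expr, labels, cfg)
        back = EvoTspModel.from_dict(model.to_dict())
        assert back.pairs == model.pairs
        assert back.predict(expr) == model.predict(expr)

    def test_pipeline_rank_invariance(self):
        expr, labels = make_random_dataset(25, 20, seed=17)
        cfg = EvoConfig(population_size=20, stall_generations=20,
                        max_generations=60, seed=5)
        m1 = fit_evotsp(expr, labels, cfg)
        m2 = fit_evotsp(ExpressionMatrix(expr.values ** 3 + 1.0,
                                         expr.gene_ids, expr.sample_ids),
                        labels, cfg)
        assert m1.pairs == m2.pairs
        assert m1.fitness == m2.fitness
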