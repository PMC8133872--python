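import itertools

import numpy as np
import pytest

from ehbcs import (
    FitnessConfig,
    SearchConfig,
    SubsetFitness,
    make_folds,
    make_selector,
    normalize_features,
    run_bcs,
    run_bga,
    run_bpso,
    run_ehbcs,
)

ALGORITHMS = ["ehbcs", "bcs", "bga", "bpso"]


def _oracle_fitness(data):
    datan = normalize_features(data)
    plan = make_folds(datan, seed=0)
    return SubsetFitness(datan, FitnessConfig(), fold_plan=plan)


@pytest.mark.parametrize("algo", ALGORITHMS)
class TestCommonContract:
    def test_perfect_feature_recovered(self, separable_data, algo):
        # feature 0 equals the label, so {0} is the global optimum
        fit = _oracle_fitness(separable_data)
        for seed in range(5):
            sel = make_selector(
                algo, n_iter=30, random_state=seed, fitness_fn=fit, normalize="none"
            )
            sel.fit(separable_data.features, separable_data.labels)
            assert sel.support_[0]
            acc = fit.report(sel.get_support().astype(np.int8)).avg_acc
            assert acc == 1.0

    def test_zero_iterations_returns_initial_best(self, small_planted_data, algo):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        sel = make_selector(
            algo, n_iter=0, random_state=1, fitness_fn=fit, normalize="none"
        )
        sel.fit(data.features, data.labels)
        assert len(sel.trajectory_) == 0
        assert sel.best_fitness_ == sel.result_.initial_best_fitness

    def test_reproducible_from_seed(self, small_planted_data, algo):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        results = []
        for _ in range(2):
            sel = make_selector(
                algo, n_iter=10, random_state=3, fitness_fn=fit, normalize="none"
            )
            sel.fit(data.features, data.labels)
            results.append(sel.result_)
        a, b = results
        np.testing.assert_array_equal(a.best_bits, b.best_bits)
        np.testing.assert_array_equal(a.trajectory, b.trajectory)
        assert a.best_fitness == b.best_fitness
        assert a.n_evaluations == b.n_evaluations

    def test_trajectory_is_best_so_far(self, small_planted_data, algo):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        sel = make_selector(
            algo, n_iter=25, random_state=0, fitness_fn=fit, normalize="none"
        )
        sel.fit(data.features, data.labels)
        traj = sel.trajectory_
        assert len(traj) == 25
        assert (np.diff(traj) >= 0).all()
        assert traj[0] >= sel.result_.initial_best_fitness
        assert sel.best_fitness_ == traj[-1] == traj.max()

    def test_never_exceeds_exhaustive_optimum(self, small_planted_data, algo):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        d = data.n_features
        optimum = max(
            fit(np.array(bits, dtype=np.int8))
            for bits in itertools.product([0, 1], repeat=d)
            if any(bits)
        )
        sel = make_selector(
            algo, n_iter=20, random_state=2, fitness_fn=fit, normalize="none"
        )
        sel.fit(data.features, data.labels)
        assert sel.best_fitness_ <= optimum + 1e-12

    def test_evaluation_budget_accounting(self, small_planted_data, algo):
        data, _ = small_planted_data
        base = _oracle_fitness(data)
        calls = []

        def counted(bits):
            calls.append(bits.tobytes())
            return base(bits)

        sel = make_selector(
            algo, n_pop=8, n_iter=5, random_state=0, fitness_fn=counted, normalize="none"
        )
        sel.fit(data.features, data.labels)
        res = sel.result_
        # distinct underlying calls == reported evaluations; repeats are hits
        assert res.n_evaluations == len(calls) == len(set(calls))
        assert res.n_cache_hits >= 0

    def test_transform_masks_columns(self, small_planted_data, algo):
        data, _ = small_planted_data
        sel = make_selector(algo, n_pop=8, n_iter=3, random_state=0)
        Xt = sel.fit(data.features, data.labels).transform(data.features)
        assert Xt.shape == (data.n_cases, sel.get_support().sum())


class TestEHBCSSpecifics:
    def test_relief_weights_exposed_and_signal_bearing(self, planted_data):
        data, truth = planted_data
        sel = make_selector("ehbcs", n_pop=10, n_iter=2, random_state=0)
        sel.fit(data.features, data.labels)
        w = sel.relief_weights_.w
        assert len(w) == data.n_features
        noise = sorted(set(range(data.n_features)) - truth)
        assert w[sorted(truth)].mean() > np.mean(w[noise])

    def test_precomputed_weights_skip_relief(self, small_planted_data):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        w = np.linspace(-0.5, 0.5, data.n_features)
        sel = make_selector(
            "ehbcs",
            relief_weights=w,
            n_iter=5,
            random_state=0,
            fitness_fn=fit,
            normalize="none",
        )
        sel.fit(data.features, data.labels)
        np.testing.assert_array_equal(sel.relief_weights_.w, w)

    def test_weight_length_mismatch_rejected(self, small_planted_data):
        data, _ = small_planted_data
        sel = make_selector("ehbcs", relief_weights=np.ones(3), n_iter=1)
        with pytest.raises(ValueError, match="length"):
            sel.fit(data.features, data.labels)

    def test_functional_wrapper_matches_estimator(self, small_planted_data):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        cfg = SearchConfig(algorithm="ehbcs", n_pop=10, n_iter=8, seed=4,
                           params={"normalize": "none"})
        res = run_ehbcs(data, config=cfg, fitness_fn=fit)
        sel = make_selector(
            "ehbcs", n_pop=10, n_iter=8, random_state=4, fitness_fn=fit,
            normalize="none",
        )
        sel.fit(data.features, data.labels)
        np.testing.assert_array_equal(res.best_bits, sel.result_.best_bits)
        assert res.best_fitness == sel.result_.best_fitness


class TestFunctionalWrappers:
    @pytest.mark.parametrize(
        "runner", [run_bcs, run_bga, run_bpso], ids=["bcs", "bga", "bpso"]
    )
    def test_baselines_run_and_report(self, small_planted_data, runner):
        data, _ = small_planted_data
        fit = _oracle_fitness(data)
        cfg = SearchConfig(algorithm="bga", n_pop=8, n_iter=5, seed=0,
                           params={"normalize": "none"})
        cfg.algorithm = runner.__name__.removeprefix("run_")
        res = runner(data, config=cfg, fitness_fn=fit)
        assert 0 < res.best_fitness <= 1
        assert res.to_dict()["n_evaluations"] == res.n_evaluations

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            SearchConfig(algorithm="tabu")
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_selector("tabu")


class TestSklearnIntegration:
    def test_clone_and_get_params_round_trip(self):
        from sklearn.base import clone

        sel = make_selector("ehbcs", n_iter=7, p_c=0.6, random_state=5)
        cloned = clone(sel)
        assert cloned.get_params()["n_iter"] == 7
        assert cloned.get_params()["p_c"] == 0.6

    def test_pipeline_composition(self, small_planted_data):
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import Pipeline

        data, _ = small_planted_data
        pipe = Pipeline(
            [
                ("select", make_selector("ehbcs", n_pop=8, n_iter=3, random_state=0)),
                ("clf", KNeighborsClassifier(n_neighbors=3)),
            ]
        )
        pipe.fit(data.features, data.labels)
        acc = pipe.score(data.features, data.labels)
        assert 0.5 <= acc <= 1.0

    def test_non_binary_target_rejected(self):
        X = np.random.default_rng(0).random((30, 4))
        y = np.arange(30) % 3
        with pytest.raises(ValueError, match="binary"):
            make_selector("bga", n_iter=1).fit(X, y)
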