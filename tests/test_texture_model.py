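import numpy as np
import pandas as pd
import pytest

from extrurtd.errors import TrainingDivergenceError
from extrurtd.texture_model import (
    FEATURE_COLUMNS,
    GAParams,
    MetricReport,
    MinMaxScaler,
    NetworkParams,
    PSOParams,
    TrainConfig,
    evaluate,
    forward,
    ga_minimize,
    gradients,
    init_network,
    load_model,
    optimize_ga,
    optimize_pso,
    pso_minimize,
    run_experiment,
    save_model,
    select_hidden_nodes,
    train_bp,
)


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def linear_dataset(n=130, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 4))
    y = X @ np.array([1.5, -2.0, 0.7, 1.1]) + 5.0
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df["hardness"] = y
    df.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    return df


# -------------------------------------------------------------- network


class TestInitNetwork:
    def test_deterministic_per_seed(self):
        a, b = init_network(5, seed=3), init_network(5, seed=3)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_shapes(self):
        p = init_network(7, seed=0)
        assert p.W1.shape == (4, 7)
        assert p.b1.shape == (7,)
        assert p.W2.shape == (7, 1)
        assert p.b2.shape == (1,)

    def test_range(self):
        p = init_network(50, seed=1)
        flat = p.flatten()
        assert flat.min() >= -1.0 and flat.max() <= 1.0

    def test_flatten_round_trip(self):
        p = init_network(4, seed=2)
        q = NetworkParams.from_flat(p.flatten(), 4)
        np.testing.assert_array_equal(p.W1, q.W1)
        np.testing.assert_array_equal(p.b1, q.b1)
        np.testing.assert_array_equal(p.W2, q.W2)
        np.testing.assert_array_equal(p.b2, q.b2)

    def test_hidden_rule_returns_candidate(self):
        df = linear_dataset(60, seed=5)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["hardness"].to_numpy()
        y = (y - y.min()) / (y.max() - y.min())
        cfg = TrainConfig(max_iters=100, seed=0)
        h = select_hidden_nodes(X, y, cfg, a_range=range(1, 4))
        base = round(np.sqrt(5))
        assert h in {base + a for a in range(1, 4)}


class TestForward:
    def test_zero_weights_give_bias(self):
        p = NetworkParams(
            W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 1)), b2=np.array([0.7])
        )
        np.testing.assert_allclose(forward(p, np.ones((5, 4))), 0.7)

    def test_hand_computed_two_hidden_nodes(self):
        # pencil-and-paper case: x = (1, 0, 0, 0)
        W1 = np.zeros((4, 2))
        W1[0, 0], W1[0, 1] = 1.0, -1.0
        p = NetworkParams(
            W1=W1,
            b1=np.array([0.0, 0.5]),
            W2=np.array([[2.0], [1.0]]),
            b2=np.array([0.25]),
        )
        x = np.array([1.0, 0.0, 0.0, 0.0])
        h1 = 1 / (1 + np.exp(-1.0))
        h2 = 1 / (1 + np.exp(0.5))
        assert forward(p, x)[0] == pytest.approx(2 * h1 + h2 + 0.25, rel=1e-12)

    def test_deterministic(self):
        p = init_network(6, seed=0)
        x = np.random.default_rng(1).uniform(0, 1, (10, 4))
        np.testing.assert_array_equal(forward(p, x), forward(p, x))

    def test_shape_mismatch(self):
        p = init_network(3, seed=0)
        with pytest.raises(ValueError):
            forward(p, np.ones((2, 5)))


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = init_network(rng.integers(2, 6), seed=seed)
        X = rng.uniform(0, 1, (9, 4))
        y = rng.uniform(0, 1, 9)
        analytic = gradients(p, X, y).flatten()
        eps = 1e-6
        flat = p.flatten()
        h = p.n_hidden

        def loss(vec):
            q = NetworkParams.from_flat(vec, h)
            return float(np.mean((forward(q, X) - y) ** 2))

        numeric = np.empty_like(flat)
        for i in range(flat.size):
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            numeric[i] = (loss(up) - loss(dn)) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, atol=1e-6)


class TestTrainBP:
    def test_loss_trace_decreases_on_average(self):
        df = linear_dataset(100, seed=1)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["hardness"].to_numpy()
        y = (y - y.min()) / (y.max() - y.min())
        p0 = init_network(5, seed=0)
        _, trace = train_bp(p0, X, y, TrainConfig(learning_rate=0.1))
        assert trace[-1] < trace[0]
        # nonincreasing on average: second half below first half
        assert trace[len(trace) // 2 :].mean() < trace[: len(trace) // 2].mean()

    def test_noiseless_linear_target_low_mape(self):
        # lr follows the loss scale of min-max-normalized targets; the
        # default 0.01 underfits within 1000 iterations on this target
        df = linear_dataset(130, seed=0)
        cfg = TrainConfig(learning_rate=0.1, n_train=90, n_test=28, seed=3)
        res = run_experiment(df, "hardness", "none", cfg)
        assert res.report.mape < 2.0

    def test_single_repeated_point_converges_to_constant(self):
        X = np.tile(np.array([0.3, 0.6, 0.2, 0.9]), (20, 1))
        y = np.full(20, 0.4)
        p0 = init_network(3, seed=1)
        trained, trace = train_bp(
            p0, X, y, TrainConfig(learning_rate=0.5, max_iters=5000)
        )
        assert trace[-1] <= 1e-5  # stopped at min_error
        assert forward(trained, X[0])[0] == pytest.approx(0.4, abs=0.01)

    def test_divergence_raises(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (10, 4)) * 1e3
        y = rng.uniform(0, 1, 10) * 1e6
        p0 = init_network(4, seed=0)
        with np.errstate(over="ignore"), pytest.raises(TrainingDivergenceError):
            train_bp(p0, X, y, TrainConfig(learning_rate=10.0, max_iters=2000))

    def test_deterministic_per_seed(self):
        df = linear_dataset(130, seed=2)
        cfg = TrainConfig(seed=8)
        a = run_experiment(df, "hardness", "none", cfg)
        b = run_experiment(df, "hardness", "none", cfg)
        np.testing.assert_array_equal(a.predictions, b.predictions)


# ------------------------------------------------------------ optimizers


class TestPSO:
    def test_sphere_benchmark(self):
        params = PSOParams(n_particles=30, iters=100, bound=5.12)
        for seed in (0, 1, 2):
            _, best = pso_minimize(sphere, 10, params, seed=seed)
            assert best < 1e-3

    def test_single_particle_zero_velocity_returns_init(self):
        # degenerate swarm: zero iterations, so the best initial particle wins
        calls = []

        def f(x):
            calls.append(x.copy())
            return sphere(x)

        params = PSOParams(n_particles=2, iters=0)
        best, _ = pso_minimize(f, 3, params, seed=5)
        np.testing.assert_array_equal(best, min(calls[:2], key=sphere))

    def test_seeded_reproducibility(self):
        params = PSOParams(iters=20)
        a = pso_minimize(sphere, 5, params, seed=9)
        b = pso_minimize(sphere, 5, params, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_rejects_tiny_swarm(self):
        with pytest.raises(ValueError):
            PSOParams(n_particles=1)


class TestGA:
    def test_sphere_benchmark(self):
        params = GAParams(population=30, generations=100, bound=5.12)
        for seed in (0, 1, 2):
            _, best = ga_minimize(sphere, 10, params, seed=seed)
            assert best < 1e-3

    def test_elitism_best_fitness_nonincreasing(self):
        # no crossover, no mutation: elitism alone forbids regression
        params = GAParams(
            population=12, generations=30, crossover_rate=0.0, mutation_rate=0.0
        )
        history = []

        def recording(x):
            v = sphere(x)
            history.append(v)
            return v

        _, best = ga_minimize(recording, 6, params, seed=4)
        pop = params.population
        gens = len(history) // pop
        gen_best = [min(history[g * pop : (g + 1) * pop]) for g in range(gens)]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(gen_best, gen_best[1:]))

    def test_seeded_reproducibility(self):
        params = GAParams(generations=15)
        a = ga_minimize(sphere, 5, params, seed=2)
        b = ga_minimize(sphere, 5, params, seed=2)
        np.testing.assert_array_equal(a[0], b[0])

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError):
            GAParams(population=1)


class TestOptimizedInitialWeights:
    def test_wrappers_return_valid_networks(self, noisy_dataset):
        df = noisy_dataset
        X = df[list(FEATURE_COLUMNS)].to_numpy()[:40]
        y = df["hardness"].to_numpy()[:40]
        scaler_y = (y - y.min()) / (y.max() - y.min())
        cfg = TrainConfig(n_hidden=4, seed=0)
        pso_net = optimize_pso(X, scaler_y, cfg, PSOParams(iters=5))
        ga_net = optimize_ga(X, scaler_y, cfg, GAParams(generations=5))
        assert pso_net.n_hidden == 4 and ga_net.n_hidden == 4
        assert np.all(np.isfinite(pso_net.flatten()))
        assert np.all(np.isfinite(ga_net.flatten()))


# --------------------------------------------------------------- metrics


class TestEvaluate:
    def test_hand_arithmetic(self):
        # actuals {1, 2}, predictions {2, 4}
        report = evaluate(np.array([2.0, 4.0]), np.array([1.0, 2.0]))
        assert report.mae == pytest.approx(1.5)
        assert report.rmse == pytest.approx(np.sqrt(2.5))
        assert report.mape == pytest.approx(100.0)  # mean(|e|/actual) in percent

    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 3.0])
        report = evaluate(x, x)
        assert report.mae == 0.0
        assert report.rmse == 0.0
        assert report.mape == 0.0
        assert report.r == pytest.approx(1.0)

    def test_anticorrelated(self):
        report = evaluate(np.array([3.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert report.r == pytest.approx(-1.0)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pred = rng.normal(5, 2, 30)
            act = rng.normal(5, 2, 30)
            report = evaluate(pred, act)
            assert report.rmse >= report.mae - 1e-12
            assert -1.0 <= report.r <= 1.0

    def test_zero_actual_policy(self):
        pred = np.array([1.0, 2.0, 3.0])
        act = np.array([0.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            evaluate(pred, act)
        report = evaluate(pred, act, zero_policy="exclude")
        assert report.mape == pytest.approx(0.0)


class TestMinMaxScaler:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 7, (20, 4))
        s = MinMaxScaler().fit(X)
        np.testing.assert_allclose(s.inverse_transform(s.transform(X)), X, atol=1e-12)

    def test_train_range_maps_to_unit(self):
        X = np.array([[0.0], [5.0], [10.0]])
        s = MinMaxScaler().fit(X)
        t = s.transform(X)
        assert t.min() == 0.0 and t.max() == 1.0

    def test_no_test_leakage(self):
        train = np.array([[0.0], [10.0]])
        test = np.array([[20.0]])
        s = MinMaxScaler().fit(train)
        assert s.transform(test)[0, 0] == pytest.approx(2.0)  # outside [0,1]


# ------------------------------------------------------------ experiment


class TestRunExperiment:
    def test_split_disjoint_and_sized(self, noisy_dataset):
        res = run_experiment(noisy_dataset, "hardness", "none", TrainConfig(seed=0))
        assert len(res.train_index) == 90
        assert len(res.test_index) == 28
        assert set(res.train_index).isdisjoint(res.test_index)

    def test_requires_enough_rows(self, noisy_dataset):
        with pytest.raises(ValueError, match="rows"):
            run_experiment(noisy_dataset.head(50), "hardness", "none", TrainConfig())

    def test_missing_column(self, noisy_dataset):
        with pytest.raises(ValueError, match="missing"):
            run_experiment(noisy_dataset.drop(columns=["hardness"]), "hardness")

    def test_seeded_metrics_identical(self, noisy_dataset):
        cfg = TrainConfig(seed=4)
        a = run_experiment(noisy_dataset, "hardness", "pso", cfg,
                           pso_params=PSOParams(iters=10))
        b = run_experiment(noisy_dataset, "hardness", "pso", cfg,
                           pso_params=PSOParams(iters=10))
        assert a.report == b.report

    def test_deviations_definition(self, noisy_dataset):
        res = run_experiment(noisy_dataset, "hardness", "none", TrainConfig(seed=1))
        np.testing.assert_allclose(res.deviations, res.predictions - res.actuals)

    def test_model_save_load_predict(self, noisy_dataset, tmp_path):
        from extrurtd.texture_model import predict_with_model

        res = run_experiment(noisy_dataset, "chewiness", "none", TrainConfig(seed=2))
        path = tmp_path / "model.json"
        save_model(res, path)
        params, fscaler, tscaler, payload = load_model(path)
        assert payload["attribute"] == "chewiness"
        preds = predict_with_model(path, noisy_dataset.iloc[list(res.test_index)])
        np.testing.assert_allclose(preds, res.predictions, atol=1e-9)
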