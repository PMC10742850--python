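"""BP regression network with PSO/GA-optimized initial weights.

A single-hidden-layer feed-forward network (4 inputs, sigmoid hidden layer,
linear output) maps image features to one texture attribute. Training is
full-batch gradient descent on mean squared error. Optionally, the initial
weights and biases are chosen by particle swarm optimization or a real-coded
genetic algorithm over the flattened parameter vector, with fitness equal to
the training-set MSE of the untrained network. Error metrics are MAE, RMSE,
MAPE and the Pearson correlation of the test set.

The network, its gradients, and both optimizers are implemented here from
first principles (numpy only); they are the object under test, so no
black-box learning library is used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import TrainingDivergenceError

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "PSOParams",
    "GAParams",
    "MetricReport",
    "MinMaxScaler",
    "ExperimentResult",
    "init_network",
    "select_hidden_nodes",
    "forward",
    "gradients",
    "train_bp",
    "pso_minimize",
    "ga_minimize",
    "optimize_pso",
    "optimize_ga",
    "evaluate",
    "run_experiment",
    "save_model",
    "load_model",
]

N_INPUT = 4
N_OUTPUT = 1

TEXTURE_ATTRIBUTES = (
    "hardness",
    "stickiness",
    "chewiness",
    "adhesiveness",
    "resilience",
    "cohesion",
    "elasticity",
)

FEATURE_COLUMNS = ("L_star", "a_star", "b_star", "contrast")


# ---------------------------------------------------------------------------
# parameters and configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    """Weights/biases of the 4 -> n_hidden -> 1 network."""

    W1: np.ndarray  # (4, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h, 1)
    b2: np.ndarray  # (1,)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1.ravel(), self.W2.ravel(), self.b2.ravel()]
        )

    @classmethod
    def from_flat(cls, vec: np.ndarray, n_hidden: int) -> "NetworkParams":
        vec = np.asarray(vec, dtype=float)
        sizes = [N_INPUT * n_hidden, n_hidden, n_hidden * N_OUTPUT, N_OUTPUT]
        if vec.size != sum(sizes):
            raise ValueError("flat vector length does not match layer sizes")
        idx = np.cumsum(sizes)[:-1]
        w1, b1, w2, b2 = np.split(vec, idx)
        return cls(
            W1=w1.reshape(N_INPUT, n_hidden),
            b1=b1.copy(),
            W2=w2.reshape(n_hidden, N_OUTPUT),
            b2=b2.copy(),
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    min_error: float = 1e-5
    max_iters: int = 1000
    n_train: int = 90
    n_test: int = 28
    n_hidden: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.min_error <= 0 or self.max_iters < 1:
            raise ValueError("learning_rate, min_error, max_iters must be positive")
        if self.n_train < 1 or self.n_test < 1 or self.n_hidden < 1:
            raise ValueError("n_train, n_test, n_hidden must be >= 1")


@dataclass(frozen=True)
class PSOParams:
    n_particles: int = 30
    iters: int = 50
    inertia: float = 0.9
    inertia_end: float = 0.4  # linear decay; set equal to inertia for constant
    cognitive: float = 1.5
    social: float = 1.5
    bound: float = 1.0  # search box [-bound, bound]^dim

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("swarm size must be >= 2")


@dataclass(frozen=True)
class GAParams:
    population: int = 30
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sd: float = 0.2
    mutation_decay: float = 0.95
    tournament_k: int = 3
    elitism: int = 1
    bound: float = 1.0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass(frozen=True)
class MetricReport:
    mae: float
    rmse: float
    mape: float  # percent
    r: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def init_network(n_hidden: int, seed: int) -> NetworkParams:
    """Uniform random parameters in [-1, 1], deterministic per seed."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    return NetworkParams(
        W1=rng.uniform(-1, 1, (N_INPUT, n_hidden)),
        b1=rng.uniform(-1, 1, n_hidden),
        W2=rng.uniform(-1, 1, (n_hidden, N_OUTPUT)),
        b2=rng.uniform(-1, 1, N_OUTPUT),
    )


def forward(params: NetworkParams, features: np.ndarray) -> np.ndarray:
    """Predictions for features of shape (n, 4) (or (4,) for one sample)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"expected {params.W1.shape[0]} features, got {X.shape[1]}"
        )
    hidden = _sigmoid(X @ params.W1 + params.b1)
    return (hidden @ params.W2 + params.b2).ravel()


def _mse(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    resid = forward(params, X) - y
    return float(np.mean(resid**2))


def gradients(
    params: NetworkParams, X: np.ndarray, y: np.ndarray
) -> NetworkParams:
    """Analytic gradients of mean squared error w.r.t. every parameter."""
    X = np.atleast_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    hidden = _sigmoid(X @ params.W1 + params.b1)  # (n, h)
    pred = (hidden @ params.W2 + params.b2).ravel()
    dpred = (2.0 / n) * (pred - y)  # (n,)
    dW2 = hidden.T @ dpred[:, None]  # (h, 1)
    db2 = np.array([dpred.sum()])
    dhidden = dpred[:, None] @ params.W2.T  # (n, h)
    dz = dhidden * hidden * (1.0 - hidden)
    dW1 = X.T @ dz  # (4, h)
    db1 = dz.sum(axis=0)
    return NetworkParams(W1=dW1, b1=db1, W2=dW2, b2=db2)


def train_bp(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> tuple[NetworkParams, np.ndarray]:
    """Full-batch gradient descent on MSE.

    Stops when the loss drops below ``config.min_error`` or after
    ``config.max_iters`` updates. Returns the trained parameters and the
    loss trace (loss before each update, plus the final loss).
    """
    p = params.copy()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    lr = config.learning_rate
    trace = [_mse(p, X, y)]
    for _ in range(config.max_iters):
        if trace[-1] <= config.min_error:
            break
        g = gradients(p, X, y)
        p.W1 -= lr * g.W1
        p.b1 -= lr * g.b1
        p.W2 -= lr * g.W2
        p.b2 -= lr * g.b2
        loss = _mse(p, X, y)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                f"loss became non-finite; reduce learning_rate={lr}"
            )
        trace.append(loss)
    return p, np.asarray(trace)


def select_hidden_nodes(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    a_range: Sequence[int] = range(1, 11),
    val_fraction: float = 0.25,
) -> int:
    """Pick hidden size h = round(sqrt(n_in + n_out)) + a by validation MSE.

    The candidate offsets ``a`` are scanned over a held-out slice of the
    training data; ties go to the smaller network.
    """
    base = round(np.sqrt(N_INPUT + N_OUTPUT))
    rng = np.random.default_rng(config.seed)
    n = len(y)
    order = rng.permutation(n)
    n_val = max(1, int(n * val_fraction))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    best_h, best_mse = base + a_range[0], np.inf
    for a in a_range:
        h = base + a
        p0 = init_network(h, config.seed)
        trained, _ = train_bp(p0, X[fit_idx], y[fit_idx], config)
        mse = _mse(trained, X[val_idx], y[val_idx])
        if mse < best_mse - 1e-12:
            best_h, best_mse = h, mse
    return best_h


# ---------------------------------------------------------------------------
# population optimizers (generic minimizers + network-specific wrappers)
# ---------------------------------------------------------------------------


def pso_minimize(
    f: Callable[[np.ndarray], float],
    dim: int,
    params: PSOParams = PSOParams(),
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Global-best particle swarm minimization of ``f`` over [-bound, bound]^dim.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x) with
    velocities clamped to the box width. Returns (best position, best value).
    """
    rng = np.random.default_rng(seed)
    lo, hi = -params.bound, params.bound
    vmax = hi - lo
    x = rng.uniform(lo, hi, (params.n_particles, dim))
    v = rng.uniform(-vmax, vmax, (params.n_particles, dim)) * 0.1
    fx = np.array([f(xi) for xi in x])
    pbest, fpbest = x.copy(), fx.copy()
    g = int(np.argmin(fpbest))
    gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    for it in range(params.iters):
        frac = it / max(params.iters - 1, 1)
        w = params.inertia + (params.inertia_end - params.inertia) * frac
        r1 = rng.random((params.n_particles, dim))
        r2 = rng.random((params.n_particles, dim))
        v = (
            w * v
            + params.cognitive * r1 * (pbest - x)
            + params.social * r2 * (gbest - x)
        )
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        fx = np.array([f(xi) for xi in x])
        improved = fx < fpbest
        pbest[improved] = x[improved]
        fpbest[improved] = fx[improved]
        g = int(np.argmin(fpbest))
        if fpbest[g] < fgbest:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    return gbest, fgbest


def ga_minimize(
    f: Callable[[np.ndarray], float],
    dim: int,
    params: GAParams = GAParams(),
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Real-coded genetic algorithm: tournament selection, arithmetic
    crossover, Gaussian mutation with geometrically decaying step size,
    and elitism. Returns (best individual, best value)."""
    rng = np.random.default_rng(seed)
    lo, hi = -params.bound, params.bound
    pop = rng.uniform(lo, hi, (params.population, dim))
    fit = np.array([f(ind) for ind in pop])
    best_i = int(np.argmin(fit))
    best, fbest = pop[best_i].copy(), float(fit[best_i])
    sd = params.mutation_sd * (hi - lo)
    for _ in range(params.generations):
        order = np.argsort(fit)
        elite = pop[order[: params.elitism]].copy()
        children = []
        while len(children) < params.population - params.elitism:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, params.population, params.tournament_k)
                parents.append(pop[contenders[np.argmin(fit[contenders])]])
            p1, p2 = parents
            if rng.random() < params.crossover_rate:
                u = rng.random(dim)
                c1 = u * p1 + (1 - u) * p2
                c2 = (1 - u) * p1 + u * p2
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mask = rng.random(dim) < params.mutation_rate
                child[mask] += rng.normal(0.0, sd, int(mask.sum()))
                np.clip(child, lo, hi, out=child)
                children.append(child)
        pop = np.vstack([elite, np.asarray(children[: params.population - params.elitism])])
        fit = np.array([f(ind) for ind in pop])
        i = int(np.argmin(fit))
        if fit[i] < fbest:
            best, fbest = pop[i].copy(), float(fit[i])
        sd *= params.mutation_decay
    return best, fbest


def _fitness_on(X: np.ndarray, y: np.ndarray, n_hidden: int):
    def fitness(vec: np.ndarray) -> float:
        return _mse(NetworkParams.from_flat(vec, n_hidden), X, y)

    return fitness


def optimize_pso(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    pso_params: PSOParams = PSOParams(),
) -> NetworkParams:
    """Initial network weights/biases chosen by PSO on training-set MSE."""
    dim = NetworkParams.from_flat(
        np.zeros(N_INPUT * config.n_hidden + config.n_hidden + config.n_hidden + 1),
        config.n_hidden,
    ).flatten().size
    vec, _ = pso_minimize(
        _fitness_on(X, y, config.n_hidden), dim, pso_params, seed=config.seed
    )
    return NetworkParams.from_flat(vec, config.n_hidden)


def optimize_ga(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    ga_params: GAParams = GAParams(),
) -> NetworkParams:
    """Initial network weights/biases chosen by a GA on training-set MSE."""
    dim = N_INPUT * config.n_hidden + config.n_hidden + config.n_hidden * N_OUTPUT + N_OUTPUT
    vec, _ = ga_minimize(
        _fitness_on(X, y, config.n_hidden), dim, ga_params, seed=config.seed
    )
    return NetworkParams.from_flat(vec, config.n_hidden)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def evaluate(
    predictions: np.ndarray,
    actuals: np.ndarray,
    zero_policy: Literal["error", "exclude"] = "error",
) -> MetricReport:
    """MAE, RMSE, MAPE (percent of actual), Pearson r.

    MAPE divides by the actual value; zero actuals either raise or are
    excluded from the MAPE average per ``zero_policy``.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    act = np.asarray(actuals, dtype=float).ravel()
    if pred.shape != act.shape or pred.size < 2:
        raise ValueError("predictions and actuals must match and have length >= 2")
    err = pred - act
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    nonzero = act != 0
    if not np.all(nonzero):
        if zero_policy == "error":
            raise ValueError("actuals contain zeros; MAPE undefined")
        if not np.any(nonzero):
            raise ValueError("all actuals are zero; MAPE undefined")
    mape = float(np.mean(np.abs(err[nonzero] / act[nonzero])) * 100.0)
    if np.std(pred) == 0 or np.std(act) == 0:
        r = 0.0 if mae > 0 else 1.0
    else:
        r = float(np.corrcoef(pred, act)[0, 1])
    return MetricReport(mae=mae, rmse=rmse, mape=mape, r=r)


# ---------------------------------------------------------------------------
# experiment pipeline
# ---------------------------------------------------------------------------


class MinMaxScaler:
    """Min-max scaling to [0, 1], fit on training data only."""

    def __init__(self) -> None:
        self.lo: np.ndarray | None = None
        self.span: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.lo = X.min(axis=0)
        span = X.max(axis=0) - self.lo
        self.span = np.where(span == 0, 1.0, span)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler not fitted")
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.lo) / self.span

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler not fitted")
        return np.atleast_2d(np.asarray(X, dtype=float)) * self.span + self.lo


@dataclass
class ExperimentResult:
    attribute: str
    optimizer: str
    report: MetricReport
    predictions: np.ndarray
    actuals: np.ndarray
    deviations: np.ndarray  # predictions - actuals
    params: NetworkParams
    feature_scaler: MinMaxScaler
    target_scaler: MinMaxScaler
    loss_trace: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray
    config: TrainConfig


def run_experiment(
    dataset: pd.DataFrame,
    attribute: str,
    optimizer: Literal["none", "pso", "ga"] = "none",
    config: TrainConfig = TrainConfig(),
    pso_params: PSOParams = PSOParams(),
    ga_params: GAParams = GAParams(),
) -> ExperimentResult:
    """Split, scale, (optionally) optimize initial weights, train, evaluate.

    The dataset needs the four feature columns plus ``attribute``. The split
    is a seeded permutation: first ``n_train`` rows train, next ``n_test``
    test. Scalers are fit on the training rows only; metrics are computed on
    the unscaled test-set predictions.
    """
    missing = [c for c in (*FEATURE_COLUMNS, attribute) if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing columns {missing}")
    n = len(dataset)
    if n < config.n_train + config.n_test:
        raise ValueError(
            f"dataset has {n} rows; need >= n_train + n_test = "
            f"{config.n_train + config.n_test}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    train_idx = order[: config.n_train]
    test_idx = order[config.n_train : config.n_train + config.n_test]

    X = dataset.loc[:, FEATURE_COLUMNS].to_numpy(dtype=float)
    y = dataset[attribute].to_numpy(dtype=float)

    fscaler = MinMaxScaler().fit(X[train_idx])
    tscaler = MinMaxScaler().fit(y[train_idx, None])
    Xtr = fscaler.transform(X[train_idx])
    ytr = tscaler.transform(y[train_idx, None]).ravel()

    if optimizer == "none":
        init = init_network(config.n_hidden, config.seed)
    elif optimizer == "pso":
        init = optimize_pso(Xtr, ytr, config, pso_params)
    elif optimizer == "ga":
        init = optimize_ga(Xtr, ytr, config, ga_params)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    trained, trace = train_bp(init, Xtr, ytr, config)

    Xte = fscaler.transform(X[test_idx])
    pred_scaled = forward(trained, Xte)
    pred = tscaler.inverse_transform(pred_scaled[:, None]).ravel()
    actual = y[test_idx]
    report = evaluate(pred, actual, zero_policy="exclude")

    return ExperimentResult(
        attribute=attribute,
        optimizer=optimizer,
        report=report,
        predictions=pred,
        actuals=actual,
        deviations=pred - actual,
        params=trained,
        feature_scaler=fscaler,
        target_scaler=tscaler,
        loss_trace=trace,
        train_index=train_idx,
        test_index=test_idx,
        config=config,
    )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(result: ExperimentResult, path) -> None:
    payload = {
        "attribute": result.attribute,
        "optimizer": result.optimizer,
        "n_hidden": result.params.n_hidden,
        "W1": result.params.W1.tolist(),
        "b1": result.params.b1.tolist(),
        "W2": result.params.W2.tolist(),
        "b2": result.params.b2.tolist(),
        "feature_scaler": {
            "lo": result.feature_scaler.lo.tolist(),
            "span": result.feature_scaler.span.tolist(),
        },
        "target_scaler": {
            "lo": result.target_scaler.lo.tolist(),
            "span": result.target_scaler.span.tolist(),
        },
        "config": asdict(result.config),
        "test_metrics": result.report.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path) -> tuple[NetworkParams, MinMaxScaler, MinMaxScaler, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    params = NetworkParams(
        W1=np.asarray(payload["W1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        W2=np.asarray(payload["W2"], dtype=float),
        b2=np.asarray(payload["b2"], dtype=float),
    )
    fscaler = MinMaxScaler()
    fscaler.lo = np.asarray(payload["feature_scaler"]["lo"], dtype=float)
    fscaler.span = np.asarray(payload["feature_scaler"]["span"], dtype=float)
    tscaler = MinMaxScaler()
    tscaler.lo = np.asarray(payload["target_scaler"]["lo"], dtype=float)
    tscaler.span = np.asarray(payload["target_scaler"]["span"], dtype=float)
    return params, fscaler, tscaler, payload


def predict_with_model(path, features: pd.DataFrame) -> np.ndarray:
    """Apply a saved model to a feature table (CLI helper)."""
    params, fscaler, tscaler, _ = load_model(path)
    X = features.loc[:, FEATURE_COLUMNS].to_numpy(dtype=float)
    pred_scaled = forward(params, fscaler.transform(X))
    return tscaler.inverse_transform(pred_scaled[:, None]).ravel()
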