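"""Binary wrapper feature selection by PSO, GWO, and their hybrid.

All three metaheuristics evolve a population of continuous positions.
For feature selection each position is mapped to a binary mask through
a stochastic sigmoid transfer (bit j set iff sigmoid(x_j) exceeds a
fresh uniform draw; an all-zero mask is repaired by forcing the bit
with the largest sigmoid value), and the mask is scored by the wrapper
fitness

    fitness = w_acc * accuracy(mask) + w_feat * (p - k) / p

where accuracy(mask) is the holdout accuracy of an internal classifier
trained on the masked columns only, p the total and k the selected
feature count.  Fitness is maximized.

Update rules
------------
PSO      v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);  x <- x + v.
         Inertia w decays linearly (0.9 -> 0.4 by default), velocities
         are clamped to [-6, 6] (the sigmoid's saturation range).
GWO      per wolf and leader L in {alpha, beta, delta}:
         A = 2 a r - a, C = 2 r (fresh r per use), D_L = |C x_L - x|,
         x_L' = x_L - A D_L; new position is the mean of the three
         guide points.  The exploration scalar a decays 2 -> 0.
hybrid   the GWO guide points replace the PSO attractors:
         v <- w (v + c1 r1 (x1 - x) + c2 r2 (x2 - x) + c3 r3 (x3 - x)),
         x <- x + v, with velocity clamping as in PSO.  This is the
         published low-level HPSOGWO hybridization in which the social
         pull of the particle swarm is redirected toward the wolf
         hierarchy; the inertia weight damps the attraction terms too,
         which is what makes the late (small-a) phase exploitative.

Leaders (alpha >= beta >= delta by fitness) and the global best are
the best distinct evaluations seen so far, so the best-fitness history
is monotone non-decreasing.  The same machinery runs plain continuous
maximization (``run_swarm`` with ``binary=False``), which is how the
optimizers are validated on analytic benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .texture import FeatureTable

__all__ = [
    "Agent",
    "SwarmState",
    "SelectConfig",
    "SelectionResult",
    "binarize",
    "fitness",
    "WrapperFitness",
    "pso_update",
    "gwo_update",
    "hybrid_update",
    "run_swarm",
    "select_features",
]

VELOCITY_CLAMP = 6.0

_ALGORITHMS = ("pso", "gwo", "psogwo")


@dataclass
class SelectConfig:
    algorithm: str = "psogwo"
    pop_size: int = 20
    iterations: int = 50
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    c3: float = 0.5  # hybrid GWO-pull coefficient
    weight_acc: float = 0.9
    weight_feature: float = 0.1
    evaluator: str = "1nn"  # or "fast_rbfnn"
    holdout_fraction: float = 0.3
    seed: int = 0
    target_k: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if abs(self.weight_acc + self.weight_feature - 1.0) > 1e-12:
            raise ValueError("weight_acc + weight_feature must equal 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class Agent:
    position: np.ndarray
    velocity: np.ndarray
    mask: np.ndarray | None = None
    fitness: float = -np.inf
    best_position: np.ndarray | None = None
    best_mask: np.ndarray | None = None
    best_fitness: float = -np.inf


@dataclass
class SwarmState:
    agents: list
    evaluate: Callable
    binary: bool
    n_iterations: int
    iteration: int = 0
    global_best_position: np.ndarray | None = None
    global_best_mask: np.ndarray | None = None
    global_best_fitness: float = -np.inf
    # leaders: (fitness, position) best-so-far triple, alpha first
    leaders: list = field(default_factory=list)
    history: list = field(default_factory=list)
    n_evaluations: int = 0


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic sigmoid transfer from continuous position to mask."""
    s = expit(np.asarray(position, dtype=np.float64))
    bits = s > rng.random(s.size)
    if not bits.any():
        bits[int(np.argmax(s))] = True
    return bits


class WrapperFitness:
    """Holdout-accuracy wrapper objective over masked feature columns.

    The stratified train/holdout split is drawn once from the config
    seed, so the objective is a deterministic function of the mask and
    repeated masks hit a cache.
    """

    def __init__(self, table: FeatureTable, cfg: SelectConfig):
        if np.unique(table.y).size < 2:
            raise ValueError("wrapper fitness requires at least two classes")
        self.table = table
        self.cfg = cfg
        idx = np.arange(len(table.y))
        self.train_idx, self.test_idx = train_test_split(
            idx,
            test_size=cfg.holdout_fraction,
            stratify=table.y,
            random_state=cfg.seed % (2**32),
        )
        self.n_features = table.n_features
        self._cache: dict[bytes, float] = {}

    def accuracy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        Xtr = self.table.X[np.ix_(self.train_idx, np.flatnonzero(mask))]
        Xte = self.table.X[np.ix_(self.test_idx, np.flatnonzero(mask))]
        ytr = self.table.y[self.train_idx]
        yte = self.table.y[self.test_idx]
        if self.cfg.evaluator == "1nn":
            clf = KNeighborsClassifier(n_neighbors=1)
            clf.fit(Xtr, ytr)
            return float(clf.score(Xte, yte))
        elif self.cfg.evaluator == "fast_rbfnn":
            from .fast_rbfnn import FastRBFConfig, fit_multiclass
            from .texture import FeatureTable as _FT

            names = [self.table.feature_names[k] for k in np.flatnonzero(mask)]
            sub = _FT(Xtr, ytr, names)
            model = fit_multiclass(sub, None, FastRBFConfig(seed=self.cfg.seed))
            return float(np.mean(model.predict(Xte) == yte))
        raise ValueError(f"unknown evaluator {self.cfg.evaluator!r}")

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no features")
        key = mask.tobytes()
        if key not in self._cache:
            acc = self.accuracy(mask)
            k = int(mask.sum())
            self._cache[key] = (
                self.cfg.weight_acc * acc
                + self.cfg.weight_feature * (self.n_features - k) / self.n_features
            )
        return self._cache[key]


def fitness(mask, table: FeatureTable, cfg: SelectConfig, rng=None) -> float:
    """Wrapper fitness of a single mask (convenience over WrapperFitness)."""
    return WrapperFitness(table, cfg)(mask)


# ---------------------------------------------------------------------------
# population bookkeeping

def _evaluate(agent: Agent, state: SwarmState, rng: np.random.Generator) -> None:
    if state.binary:
        agent.mask = binarize(agent.position, rng)
        agent.fitness = float(state.evaluate(agent.mask))
    else:
        agent.mask = None
        agent.fitness = float(state.evaluate(agent.position))
    state.n_evaluations += 1
    if agent.fitness > agent.best_fitness:
        agent.best_fitness = agent.fitness
        agent.best_position = agent.position.copy()
        agent.best_mask = None if agent.mask is None else agent.mask.copy()
    if agent.fitness > state.global_best_fitness:
        state.global_best_fitness = agent.fitness
        state.global_best_position = agent.position.copy()
        state.global_best_mask = None if agent.mask is None else agent.mask.copy()
    _offer_leader(state, agent.fitness, agent.position)


def _offer_leader(state: SwarmState, fit: float, position: np.ndarray) -> None:
    """Insert a candidate into the best-so-far (alpha, beta, delta) triple."""
    state.leaders.append((fit, position.copy()))
    state.leaders.sort(key=lambda t: -t[0])
    del state.leaders[3:]


def _inertia(cfg: SelectConfig, t: int, T: int) -> float:
    frac = t / max(T - 1, 1)
    return cfg.w_start + (cfg.w_end - cfg.w_start) * frac


def _gwo_a(t: int, T: int) -> float:
    return 2.0 * (1.0 - t / max(T - 1, 1))


def _guide_points(
    x: np.ndarray,
    leaders: Sequence,
    a: float,
    rng: np.random.Generator,
    pin_c: float | None = None,
    pin_a: float | None = None,
) -> list:
    """GWO guide points x1, x2, x3 toward the alpha/beta/delta leaders.

    ``pin_c``/``pin_a`` freeze the stochastic coefficients (test hook)."""
    guides = []
    for _, xl in leaders:
        if pin_a is None:
            A = 2.0 * a * rng.random(x.size) - a
        else:
            A = np.full(x.size, pin_a)
        C = np.full(x.size, pin_c) if pin_c is not None else 2.0 * rng.random(x.size)
        D = np.abs(C * xl - x)
        guides.append(xl - A * D)
    return guides


def pso_update(state: SwarmState, cfg: SelectConfig, rng: np.random.Generator) -> SwarmState:
    """One particle-swarm iteration: velocity, position, re-evaluation."""
    w = _inertia(cfg, state.iteration, state.n_iterations)
    for ag in state.agents:
        r1 = rng.random(ag.position.size)
        r2 = rng.random(ag.position.size)
        ag.velocity = (
            w * ag.velocity
            + cfg.c1 * r1 * (ag.best_position - ag.position)
            + cfg.c2 * r2 * (state.global_best_position - ag.position)
        )
        np.clip(ag.velocity, -VELOCITY_CLAMP, VELOCITY_CLAMP, out=ag.velocity)
        ag.position = ag.position + ag.velocity
        _evaluate(ag, state, rng)
    state.iteration += 1
    state.history.append(state.global_best_fitness)
    return state


def gwo_update(
    state: SwarmState,
    cfg: SelectConfig,
    rng: np.random.Generator,
    pin_c: float | None = None,
    pin_a: float | None = None,
) -> SwarmState:
    """One grey-wolf iteration: move every wolf to the mean of its three
    leader-guided points."""
    a = _gwo_a(state.iteration, state.n_iterations)
    leaders = [(f, p.copy()) for f, p in state.leaders]  # static within one round
    for ag in state.agents:
        guides = _guide_points(ag.position, leaders, a, rng, pin_c, pin_a)
        ag.position = np.mean(guides, axis=0)
        _evaluate(ag, state, rng)
    state.iteration += 1
    state.history.append(state.global_best_fitness)
    return state


def hybrid_update(
    state: SwarmState,
    cfg: SelectConfig,
    rng: np.random.Generator,
    pin_c: float | None = None,
    pin_a: float | None = None,
) -> SwarmState:
    """One hybrid iteration: particle velocities pulled toward the three
    GWO guide points instead of the personal/global bests."""
    w = _inertia(cfg, state.iteration, state.n_iterations)
    a = _gwo_a(state.iteration, state.n_iterations)
    leaders = [(f, p.copy()) for f, p in state.leaders]  # static within one round
    for ag in state.agents:
        x1, x2, x3 = _guide_points(ag.position, leaders, a, rng, pin_c, pin_a)
        r1 = rng.random(ag.position.size)
        r2 = rng.random(ag.position.size)
        r3 = rng.random(ag.position.size)
        ag.velocity = w * (
            ag.velocity
            + cfg.c1 * r1 * (x1 - ag.position)
            + cfg.c2 * r2 * (x2 - ag.position)
            + cfg.c3 * r3 * (x3 - ag.position)
        )
        np.clip(ag.velocity, -VELOCITY_CLAMP, VELOCITY_CLAMP, out=ag.velocity)
        ag.position = ag.position + ag.velocity
        _evaluate(ag, state, rng)
    # the wolf hierarchy is refreshed against the global best each round
    if state.global_best_position is not None:
        _offer_leader(state, state.global_best_fitness, state.global_best_position)
    state.iteration += 1
    state.history.append(state.global_best_fitness)
    return state


_UPDATERS = {"pso": pso_update, "gwo": gwo_update, "psogwo": hybrid_update}


def init_state(
    evaluate: Callable,
    dim: int,
    cfg: SelectConfig,
    rng: np.random.Generator,
    binary: bool,
) -> SwarmState:
    """Uniform U(-1, 1) positions, zero velocities, initial evaluation."""
    agents = [
        Agent(position=rng.uniform(-1.0, 1.0, dim), velocity=np.zeros(dim))
        for _ in range(cfg.pop_size)
    ]
    state = SwarmState(
        agents=agents, evaluate=evaluate, binary=binary, n_iterations=cfg.iterations
    )
    for ag in agents:
        _evaluate(ag, state, rng)
    return state


def run_swarm(
    evaluate: Callable,
    dim: int,
    cfg: SelectConfig,
    binary: bool = False,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Run ``cfg.iterations`` rounds of the configured updater; maximizes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = init_state(evaluate, dim, cfg, rng, binary)
    step = _UPDATERS[cfg.algorithm]
    for _ in range(cfg.iterations):
        step(state, cfg, rng)
    return state


@dataclass(frozen=True, eq=False)
class SelectionResult:
    mask: np.ndarray
    fitness: float
    history: list
    algorithm: str
    seed: int
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "mask": [int(b) for b in self.mask],
            "n_selected": int(np.sum(self.mask)),
            "fitness": float(self.fitness),
            "history": [float(v) for v in self.history],
            "seed": int(self.seed),
            "n_evaluations": int(self.n_evaluations),
        }


def select_features(table: FeatureTable, cfg: SelectConfig) -> SelectionResult:
    """Wrapper selection over the table's columns; deterministic per seed.

    With ``cfg.target_k`` set, the best mask among those of exactly k
    bits is returned (falling back to the k largest sigmoid activations
    of the best position if no k-bit mask was ever sampled).
    """
    rng = np.random.default_rng(cfg.seed)
    objective = WrapperFitness(table, cfg)
    dim = table.n_features

    best_k: dict[int, tuple[float, np.ndarray]] = {}

    def evaluate(mask: np.ndarray) -> float:
        f = objective(mask)
        if cfg.target_k is not None:
            k = int(mask.sum())
            if k == cfg.target_k and (k not in best_k or f > best_k[k][0]):
                best_k[k] = (f, mask.copy())
        return f

    state = init_state(evaluate, dim, cfg, rng, binary=True)
    step = _UPDATERS[cfg.algorithm]
    for _ in range(cfg.iterations):
        step(state, cfg, rng)

    mask = state.global_best_mask
    fit = state.global_best_fitness
    if cfg.target_k is not None:
        if cfg.target_k in best_k:
            fit, mask = best_k[cfg.target_k]
        else:
            s = expit(state.global_best_position)
            mask = np.zeros(dim, dtype=bool)
            mask[np.argsort(-s)[: cfg.target_k]] = True
            fit = objective(mask)
    return SelectionResult(
        mask=np.asarray(mask, dtype=bool),
        fitness=float(fit),
        history=list(state.history),
        algorithm=cfg.algorithm,
        seed=cfg.seed,
        n_evaluations=state.n_evaluations,
    )
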