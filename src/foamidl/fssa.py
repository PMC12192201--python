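"""Fuzzy salp swarm algorithm (FSSA): bound-constrained population optimiser.

A salp chain explores a box-constrained search space toward the best-known
position (the "food source").  The run is split in two halves:

* first half (exploration): each salp proposes a candidate by three
  encircling moves around the current best with coefficients A = 2*a*r1 - a
  and C = 2*r2 (a decays linearly 2 -> 0 over the whole run), averages them,
  then takes a fuzzy step of size alpha toward the best, where alpha is a
  Gaussian fuzzy membership of the candidate's fitness relative to the
  population's fitness distribution — near-average candidates move furthest;
* second half (exploitation): the classical leader/follower salp updates —
  the leader samples around the food source with a control coefficient c1
  that decays linearly from c_max to c_min, and each follower moves to the
  midpoint of itself and its predecessor in chain order.

Greedy selection keeps a move only if it strictly improves fitness
(minimisation), so the best-so-far trace is non-increasing.  The population
shrinks linearly from n_max to n_min, discarding the worst salps.  All
positions are clamped to the bounds after every update.

The classifier hook flattens the global classifier's final linear layer into
the decision vector and maximises validation accuracy (ties broken by
cross-entropy); the incoming parameters seed the first salp, so refinement
can never reduce validation accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volio import ValidationError

__all__ = [
    "FSSAConfig",
    "SalpPopulation",
    "initialize_population",
    "c1_decay",
    "adaptive_c1",
    "leader_update",
    "follower_update",
    "exploration_update",
    "fuzzy_perturbation",
    "gfm",
    "greedy_select",
    "adapt_population",
    "optimize",
    "refine_classifier",
]


@dataclass
class FSSAConfig:
    """Run-length, population and control-parameter settings.

    ``c1_schedule`` selects the exploitation-phase leader coefficient:
    ``"adaptive"`` (linear c_max -> c_min decay, the default) or
    ``"classic"`` (the canonical 2*exp(-(4t/T)^2) decay).
    ``sort_chain`` re-sorts salps by fitness each iteration before the
    follower chain update (off by default: chain order = array order).
    """

    n_max: int = 30
    n_min: int = 10
    t_max: int = 200
    c_max: float = 0.95
    c_min: float = 0.05
    gfm_m: float = 2.0
    seed: int = 0
    c1_schedule: str = "adaptive"
    sort_chain: bool = False
    exploration: bool = True  # False: classical leader/follower for all iterations

    def __post_init__(self):
        if self.n_min > self.n_max:
            raise ValidationError(f"n_min {self.n_min} > n_max {self.n_max}")
        if not (0 < self.c_min < self.c_max < 1):
            raise ValidationError("require 0 < c_min < c_max < 1")
        if self.t_max < 2:
            raise ValidationError(f"t_max must be >= 2, got {self.t_max}")
        if self.c1_schedule not in ("adaptive", "classic"):
            raise ValidationError(f"unknown c1 schedule {self.c1_schedule!r}")


@dataclass
class SalpPopulation:
    """Positions, fitness, best-known (food) state and box bounds."""

    positions: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,)
    lb: np.ndarray
    ub: np.ndarray
    food: np.ndarray | None = None
    food_fitness: float = math.inf
    iteration: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def update_food(self) -> None:
        """Food = best position ever observed (minimisation)."""
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.food_fitness:
            self.food_fitness = float(self.fitness[i])
            self.food = self.positions[i].copy()

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]


def initialize_population(
    n: int, bounds: tuple[np.ndarray, np.ndarray], seed: int | np.random.Generator = 0
) -> SalpPopulation:
    """Uniform positions lb + U(0,1) * (ub - lb); fitness unevaluated (inf)."""
    lb = np.atleast_1d(np.asarray(bounds[0], dtype=float))
    ub = np.atleast_1d(np.asarray(bounds[1], dtype=float))
    if lb.shape != ub.shape:
        raise ValidationError("lb and ub must have the same shape")
    if np.any(lb >= ub):
        raise ValidationError("require lb < ub on every axis")
    if n < 2:
        raise ValidationError(f"population size must be >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = lb + rng.uniform(size=(n, lb.size)) * (ub - lb)
    return SalpPopulation(
        positions=pos,
        fitness=np.full(n, math.inf),
        lb=lb,
        ub=ub,
        rng=rng,
    )


def c1_decay(t: int, t_max: int) -> float:
    """Classical salp-swarm exploration coefficient 2*exp(-(4t/T_max)^2)."""
    return 2.0 * math.exp(-((4.0 * t / t_max) ** 2))


def adaptive_c1(t: int, cfg: FSSAConfig) -> float:
    """Linear decay of the control coefficient from c_max to c_min."""
    c1 = cfg.c_max - (cfg.c_max - cfg.c_min) * t / cfg.t_max
    return float(np.clip(c1, cfg.c_min, cfg.c_max))


def leader_update(pop: SalpPopulation, c1: float) -> np.ndarray:
    """Leader samples around the food source, branch on C3 >= 0.5 per axis."""
    if pop.food is None:
        raise ValidationError("food position not evaluated yet")
    c2 = pop.rng.uniform(size=pop.d)
    c3 = pop.rng.uniform(size=pop.d)
    step = c1 * ((pop.ub - pop.lb) * c2 + pop.lb)
    x = np.where(c3 >= 0.5, pop.food + step, pop.food - step)
    return pop.clamp(x)


def follower_update(positions: np.ndarray, lb, ub) -> np.ndarray:
    """Sequential chain update: each salp i >= 1 moves to the midpoint of
    itself and its (already updated) predecessor."""
    out = positions.copy()
    for i in range(1, out.shape[0]):
        out[i] = np.clip(0.5 * (out[i] + out[i - 1]), lb, ub)
    return out


def exploration_update(pop: SalpPopulation, x_i: np.ndarray, t: int, t_max: int) -> np.ndarray:
    """Encircling-style candidate around the best position (first half).

    Three moves x_k = x_best - A_k * |C_k * x_best - x_i| with fresh
    A_k = 2*a*r1 - a and C_k = 2*r2 per term and per dimension, averaged;
    a decays linearly from 2 to 0 over the full run.
    """
    if pop.food is None:
        raise ValidationError("food position not evaluated yet")
    a = 2.0 * (1.0 - t / t_max)
    moves = []
    for _ in range(3):
        r1 = pop.rng.uniform(size=pop.d)
        r2 = pop.rng.uniform(size=pop.d)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        moves.append(pop.food - A * np.abs(C * pop.food - x_i))
    return pop.clamp(np.mean(moves, axis=0))


def fuzzy_perturbation(x_new: np.ndarray, x_best: np.ndarray, alpha: float,
                       lb=None, ub=None) -> np.ndarray:
    """Step of relative size alpha toward the best: x + alpha*(x_best - x)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    out = x_new + alpha * (x_best - x_new)
    if lb is not None:
        out = np.clip(out, lb, ub)
    return out


def gfm(x: float, c: float, s: float, m: float = 2.0) -> float:
    """Gaussian fuzzy membership exp(-0.5 * |(x - c)/s|^m), in (0, 1]."""
    if s <= 0:
        raise ValidationError(f"spread s must be > 0, got {s}")
    if m <= 0:
        raise ValidationError(f"shape exponent m must be > 0, got {m}")
    # the expression is strictly positive; guard against float underflow
    return float(max(np.exp(-0.5 * np.abs((x - c) / s) ** m),
                     np.nextafter(0.0, 1.0)))


def greedy_select(
    x_old: np.ndarray, f_old: float, x_new: np.ndarray, f_new: float
) -> tuple[np.ndarray, float]:
    """Keep the new position iff it strictly improves fitness; ties keep old."""
    if f_new < f_old:
        return x_new, f_new
    return x_old, f_old


def adapt_population(t: int, cfg: FSSAConfig) -> int:
    """Linear population shrinkage round(n_max + (n_min - n_max) * t / T_max)."""
    return int(round(cfg.n_max + (cfg.n_min - cfg.n_max) * t / cfg.t_max))


def _evaluate(fitness_fn, x: np.ndarray) -> float:
    f = float(fitness_fn(x))
    if math.isnan(f):
        raise ValidationError(f"fitness function returned NaN at position {x!r}")
    return f


def optimize(
    fitness_fn,
    bounds: tuple,
    cfg: FSSAConfig | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Run the FSSA on a box; returns (best position, best fitness, trace).

    ``x0`` optionally seeds the first salp (e.g. a classifier's current
    parameters).  The trace records per-iteration best fitness, population
    size and c1.
    """
    cfg = cfg or FSSAConfig()
    pop = initialize_population(cfg.n_max, bounds, cfg.seed)
    if x0 is not None:
        pop.positions[0] = pop.clamp(np.asarray(x0, dtype=float))
    pop.fitness = np.array([_evaluate(fitness_fn, x) for x in pop.positions])
    pop.update_food()

    trace: list[dict] = []
    for t in range(1, cfg.t_max + 1):
        pop.iteration = t
        c1 = (
            adaptive_c1(t, cfg)
            if cfg.c1_schedule == "adaptive"
            else c1_decay(t, cfg.t_max)
        )

        if cfg.sort_chain:
            order = np.argsort(pop.fitness)
            pop.positions = pop.positions[order]
            pop.fitness = pop.fitness[order]

        if cfg.exploration and t < cfg.t_max / 2:
            # exploration: encircle the best, fuzzy step, greedy selection
            mu = float(np.mean(pop.fitness))
            sd = max(float(np.std(pop.fitness)), 1e-12)
            for i in range(pop.n):
                cand = exploration_update(pop, pop.positions[i], t, cfg.t_max)
                f_cand = _evaluate(fitness_fn, cand)
                alpha = gfm(f_cand, mu, sd, cfg.gfm_m)
                x_new = fuzzy_perturbation(cand, pop.food, alpha, pop.lb, pop.ub)
                f_new = _evaluate(fitness_fn, x_new)
                # the un-perturbed candidate also counts as observed
                if f_cand < f_new:
                    x_new, f_new = cand, f_cand
                pop.positions[i], pop.fitness[i] = greedy_select(
                    pop.positions[i], pop.fitness[i], x_new, f_new
                )
        else:
            # exploitation: classical leader/follower chain + greedy selection
            work = pop.positions.copy()
            work[0] = leader_update(pop, c1)
            cand = follower_update(work, pop.lb, pop.ub)
            for i in range(pop.n):
                f_new = _evaluate(fitness_fn, cand[i])
                pop.positions[i], pop.fitness[i] = greedy_select(
                    pop.positions[i], pop.fitness[i], cand[i], f_new
                )

        pop.update_food()

        n_next = adapt_population(t, cfg)
        if n_next < pop.n:
            keep = np.argsort(pop.fitness)[:n_next]
            keep.sort()  # preserve chain order among survivors
            pop.positions = pop.positions[keep]
            pop.fitness = pop.fitness[keep]

        trace.append(
            {
                "iter": t,
                "best_fitness": pop.food_fitness,
                "pop_size": pop.n,
                "c1": c1,
            }
        )

    return pop.food.copy(), pop.food_fitness, trace


# ---------------------------------------------------------------------------
# classifier refinement hook


def refine_classifier(
    model,
    val_bags: list,
    cfg: FSSAConfig | None = None,
    radius: float = 0.5,
) -> tuple:
    """Refine the global classifier's final linear layer with the FSSA.

    The layer's weights and biases are flattened into the decision vector;
    bounds are the current values +/- ``radius``.  Fitness is negative
    validation accuracy with a small cross-entropy tie-break, and the input
    parameters seed the first salp, so the returned model's validation
    accuracy is never below the input's.  Penultimate-layer activations for
    the validation bags are computed once, making each fitness evaluation a
    single dense-layer pass.

    Returns ``(model, trace)`` with the best-found parameters installed.
    """
    from ._engine import Tensor

    if not val_bags:
        raise ValidationError("validation set is empty")
    cfg = cfg or FSSAConfig(n_max=12, n_min=6, t_max=30)

    fc = model.classifier.fc
    w_shape, b_shape = fc.weight.shape, fc.bias.shape
    x0 = np.concatenate([fc.weight.data.reshape(-1), fc.bias.data.reshape(-1)])
    if radius < 0:
        raise ValidationError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return model, []

    # cache penultimate features: everything before the final linear layer
    model.eval_mode()
    feats = []
    labels = []
    for bag in val_bags:
        patches = Tensor(
            np.asarray(bag.stacked(dtype=model.dtype))[:, None]
        )
        features, effect = model.patchnet(patches)
        if "no_attention" in model.ablation_flags:
            weighted = features.mean(axis=1)
        else:
            weighted, _ = model.pooling(features, effect)
        clf = model.classifier
        x = weighted.reshape(1, *weighted.shape)
        h = clf.bn1(clf.conv1(x)).relu()
        h = clf.bn2(clf.conv2(h)).relu()
        feats.append(h.data.reshape(-1))
        labels.append(bag.label)
    feats = np.stack(feats)  # (n_val, n_features)
    labels = np.asarray(labels)

    n_w = fc.weight.data.size

    def fitness(vec: np.ndarray) -> float:
        W = vec[:n_w].reshape(w_shape)
        b = vec[n_w:].reshape(b_shape)
        logits = feats @ W.T + b  # (n_val, 2)
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=1, keepdims=True)
        calls = (probs[:, 1] >= 0.5).astype(int)
        acc = float(np.mean(calls == labels))
        ce = float(np.mean(-np.log(np.maximum(probs[np.arange(len(labels)), labels], 1e-300))))
        return -acc + 1e-6 * min(ce, 1e3)

    bounds = (x0 - radius, x0 + radius)
    best, _, trace = optimize(fitness, bounds, cfg, x0=x0)
    fc.weight.data = best[:n_w].reshape(w_shape).astype(fc.weight.data.dtype)
    fc.bias.data = best[n_w:].reshape(b_shape).astype(fc.bias.data.dtype)
    return model, trace
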