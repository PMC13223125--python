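"""Smoluchowski Kookaburra wrapper feature selection.

A population of candidate positions in [lb, ub]^k encodes feature
subsets (coordinate selected when its value exceeds 0.5). Fitness is the
inner-validation accuracy of a fast surrogate classifier on the masked
columns, evaluated on the training fold only. Each iteration picks a
"prey" position by a Smoluchowski-style selection -- sampling members
with probability proportional to fitness times a diffusion kernel
exp(-||x - x*||^2 / (2 sigma_t^2)) whose variance decays as 1/t, an
Einstein-Smoluchowski schedule that concentrates the search around the
incumbent best over time -- then applies an exploration move toward the
prey and an exploitation move around it, both accepted greedily.

The plain-KOA baseline (``smoluchowski=False``) uses the current global
best as prey with no diffusion kernel, for ablation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass
class SKOAConfig:
    population: int = 30          # a: number of kookaburras
    max_iter: int = 50            # T_max
    lb: float = 0.0
    ub: float = 1.0
    smoluchowski: bool = True
    sigma0: Optional[float] = None  # diffusion scale; default sqrt(k)/2
    inner_val_fraction: float = 0.3
    surrogate_C: float = 1.0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lb >= self.ub:
            raise ValueError("lb must be strictly below ub")


@dataclass
class SKOAState:
    positions: np.ndarray          # (a, k)
    fitness: np.ndarray            # (a,)
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    rng: np.random.Generator
    config: SKOAConfig
    trace: list[float] = field(default_factory=list)


@dataclass
class FeatureMask:
    selected: np.ndarray  # boolean over feature columns
    fold_id: Optional[int] = None

    @property
    def count(self) -> int:
        return int(self.selected.sum())

    def column_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def initialize(
    a: int, k: int, lb: float, ub: float, seed: int,
    config: Optional[SKOAConfig] = None,
) -> SKOAState:
    """Uniform initialization e_gc = (ub - lb) * alpha + lb, alpha ~ U(0,1)."""
    config = config or SKOAConfig(population=a)
    if lb >= ub:
        raise ValueError("lb must be strictly below ub")
    rng = np.random.default_rng(seed)
    positions = (ub - lb) * rng.uniform(size=(a, k)) + lb
    return SKOAState(
        positions=positions,
        fitness=np.full(a, -np.inf),
        best_position=positions[0].copy(),
        best_fitness=-np.inf,
        iteration=0,
        rng=rng,
        config=config,
    )


def binarize(position: np.ndarray) -> FeatureMask:
    """Select coordinates strictly above 0.5; all-zero masks fall back to
    the single maximal coordinate so a mask is never empty."""
    position = np.asarray(position, dtype=float)
    selected = position > 0.5
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(position))] = True
    return FeatureMask(selected=selected)


def make_surrogate_fitness(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    inner_val_fraction: float = 0.3,
    C: float = 1.0,
) -> Callable[[FeatureMask], float]:
    """Fitness = inner-validation accuracy of a regularized linear model.

    The inner split is a stratified holdout of the supplied (training)
    rows; results are cached by mask so repeated evaluations are free.
    Column order within the mask cannot affect the result because masked
    columns are taken in index order.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("fitness requires both classes in the training fold")
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=inner_val_fraction, stratify=y,
        random_state=seed,
    )
    if np.unique(y[idx_va]).size < 2 or np.unique(y[idx_tr]).size < 2:
        raise ValueError("single-class inner split; enlarge the training fold")
    cache: dict[bytes, float] = {}

    def fitness(mask: FeatureMask) -> float:
        cols = mask.column_indices()
        if cols.size == 0:
            raise ValueError("empty feature mask")
        key = mask.selected.tobytes()
        if key not in cache:
            clf = LogisticRegression(max_iter=200, C=C, random_state=seed)
            clf.fit(X[np.ix_(idx_tr, cols)], y[idx_tr])
            cache[key] = float(
                (clf.predict(X[np.ix_(idx_va, cols)]) == y[idx_va]).mean()
            )
        return cache[key]

    return fitness


def smoluchowski_select_prey(state: SKOAState) -> np.ndarray:
    """Sample a prey position with diffusion-weighted fitness probability.

    weight_i is proportional to Fit(x_i) * exp(-||x_i - x*||^2 / (2 s_t^2))
    with s_t^2 = sigma0^2 / t. All-zero weights fall back to uniform.
    """
    cfg = state.config
    t = max(state.iteration, 1)
    k = state.positions.shape[1]
    sigma0 = cfg.sigma0 if cfg.sigma0 is not None else np.sqrt(k) / 2.0
    var_t = max(sigma0**2 / t, 1e-12)
    sq = ((state.positions - state.best_position) ** 2).sum(axis=1)
    fit = np.clip(state.fitness, 0.0, None)
    weights = fit * np.exp(-sq / (2.0 * var_t))
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        probs = np.full(len(weights), 1.0 / len(weights))
    else:
        probs = weights / total
    choice = state.rng.choice(len(probs), p=probs)
    return state.positions[choice].copy()


def evaluate_population(
    state: SKOAState, fitness_fn: Callable[[FeatureMask], float]
) -> SKOAState:
    """Evaluate every member and record the elitist best (iteration 1)."""
    for g in range(len(state.positions)):
        state.fitness[g] = fitness_fn(binarize(state.positions[g]))
    best = int(np.argmax(state.fitness))
    state.best_fitness = float(state.fitness[best])
    state.best_position = state.positions[best].copy()
    state.trace.append(state.best_fitness)
    return state


def step(
    state: SKOAState, fitness_fn: Callable[[FeatureMask], float]
) -> SKOAState:
    """One SKOA iteration: exploration toward prey, exploitation around it.

    Exploration: x + C1 (P - x) with C1 ~ U(0, 2) per member; exploitation:
    p + C2 (x - p) with C2 = 2 (1 - t / T_max). Moves are accepted only on
    fitness improvement; positions are clipped to bounds; the elitist best
    never degrades.
    """
    cfg = state.config
    if state.best_fitness == -np.inf:
        evaluate_population(state, fitness_fn)
    state.iteration += 1

    prey = (
        smoluchowski_select_prey(state)
        if cfg.smoluchowski
        else state.best_position.copy()
    )
    c2 = 2.0 * (1.0 - state.iteration / cfg.max_iter)
    for g in range(len(state.positions)):
        c1 = state.rng.uniform(0.0, 2.0)
        for candidate in (
            state.positions[g] + c1 * (prey - state.positions[g]),
            prey + c2 * (state.positions[g] - prey),
        ):
            candidate = np.clip(candidate, cfg.lb, cfg.ub)
            f = fitness_fn(binarize(candidate))
            if f > state.fitness[g]:
                state.positions[g] = candidate
                state.fitness[g] = f
        if state.fitness[g] > state.best_fitness:
            state.best_fitness = float(state.fitness[g])
            state.best_position = state.positions[g].copy()
    state.trace.append(state.best_fitness)
    return state


def run(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    config: Optional[SKOAConfig] = None,
    fitness_fn: Optional[Callable[[FeatureMask], float]] = None,
    fold_id: Optional[int] = None,
) -> tuple[FeatureMask, list[float]]:
    """Full SKOA run; returns the best mask and the best-fitness trace."""
    config = config or SKOAConfig()
    k = np.asarray(X).shape[1] if X is not None else None
    if fitness_fn is None:
        fitness_fn = make_surrogate_fitness(
            X, y, seed=seed, inner_val_fraction=config.inner_val_fraction,
            C=config.surrogate_C,
        )
    state = initialize(config.population, k, config.lb, config.ub, seed, config)
    evaluate_population(state, fitness_fn)
    for _ in range(config.max_iter - 1):
        step(state, fitness_fn)
    mask = binarize(state.best_position)
    mask.fold_id = fold_id
    return mask, state.trace


def jaccard_stability(masks: Sequence[FeatureMask]) -> float:
    """Mean pairwise Jaccard index of selected-feature sets across folds."""
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    vals = []
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            a, b = masks[i].selected, masks[j].selected
            union = np.logical_or(a, b).sum()
            inter = np.logical_and(a, b).sum()
            vals.append(1.0 if union == 0 else inter / union)
    return float(np.mean(vals))


def retention_rate(selected_count: float, total_features: int) -> float:
    """Selected-subset share of the candidate feature space, in percent."""
    return 100.0 * selected_count / total_features
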