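"""Hyperparameter search spaces and a small Gaussian-process Bayesian
optimizer (expected improvement over a random candidate pool), with a
random-search fallback over the same spaces and budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple


Dimension = Union[Real, Integer, Categorical]

# Bounds are fixed here for reproducibility; the dimension lists per
# algorithm follow the model suite's tunables (see docs/methods.md).
SEARCH_SPACES: Dict[str, List[Dimension]] = {
    "LR": [
        Categorical("penalty", ("l1", "l2")),
        Real("C", 1e-3, 1e3, log=True),
    ],
    "RF": [
        Integer("min_samples_split", 2, 10),
        Integer("max_depth", 2, 20),
        Integer("n_estimators", 50, 500),
    ],
    "SVM": [
        Real("C", 1e-3, 1e3, log=True),
        Real("gamma", 1e-4, 10.0, log=True),
    ],
    # RBF kernel is the default; the categorical kernel search is opt-in.
    "SVM_kernel_search": [
        Categorical("kernel", ("rbf", "linear", "sigmoid", "poly")),
        Real("C", 1e-3, 1e3, log=True),
        Real("gamma", 1e-4, 10.0, log=True),
    ],
    "XGB": [
        Real("gamma", 0.0, 5.0),
        Real("learning_rate", 1e-3, 0.5, log=True),
        Integer("n_estimators", 50, 500),
    ],
    "GNB": [
        Real("var_smoothing", 1e-12, 1e-6, log=True),
    ],
    "MLP": [
        Real("alpha", 1e-5, 1e-1, log=True),
        Integer("max_iter", 200, 800),
        Integer("n_hidden_layers", 1, 3),
        Integer("n_neurons", 4, 128),
    ],
}


def _sample_point(space: Sequence[Dimension], rng: np.random.Generator) -> dict:
    point = {}
    for dim in space:
        if isinstance(dim, Categorical):
            point[dim.name] = dim.choices[rng.integers(len(dim.choices))]
        elif isinstance(dim, Integer):
            point[dim.name] = int(rng.integers(dim.low, dim.high + 1))
        else:
            if dim.log:
                point[dim.name] = float(
                    np.exp(rng.uniform(np.log(dim.low), np.log(dim.high)))
                )
            else:
                point[dim.name] = float(rng.uniform(dim.low, dim.high))
    return point


def _encode(space: Sequence[Dimension], point: dict) -> np.ndarray:
    """Map a point onto the unit cube for the GP surrogate."""
    coords = []
    for dim in space:
        v = point[dim.name]
        if isinstance(dim, Categorical):
            coords.append(dim.choices.index(v) / max(1, len(dim.choices) - 1))
        elif isinstance(dim, Integer):
            coords.append((v - dim.low) / max(1, dim.high - dim.low))
        elif dim.log:
            coords.append(
                (np.log(v) - np.log(dim.low)) / (np.log(dim.high) - np.log(dim.low))
            )
        else:
            coords.append((v - dim.low) / (dim.high - dim.low))
    return np.asarray(coords, dtype=float)


def gp_minimize_discrete(
    objective: Callable[[dict], float],
    space: Sequence[Dimension],
    n_iterations: int,
    rng: np.random.Generator,
    n_initial: int = 5,
    n_candidates: int = 256,
) -> tuple:
    """Sequential model-based maximization of ``objective`` (higher better).

    The first ``n_initial`` evaluations are random; afterwards a Matern-5/2
    GP is fit to the observed (encoded point, score) pairs and the next point
    maximizes expected improvement over a fresh random candidate pool.
    Returns (best_point, best_score, history).
    """
    n_initial = min(n_initial, n_iterations)
    evaluated: List[dict] = []
    scores: List[float] = []
    for _ in range(n_initial):
        point = _sample_point(space, rng)
        evaluated.append(point)
        scores.append(objective(point))
    while len(evaluated) < n_iterations:
        X = np.vstack([_encode(space, p) for p in evaluated])
        y = np.asarray(scores)
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=0.3),
            alpha=1e-6,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(X, y)
        candidates = [_sample_point(space, rng) for _ in range(n_candidates)]
        Xc = np.vstack([_encode(space, p) for p in candidates])
        mu, sigma = gp.predict(Xc, return_std=True)
        best = y.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
        point = candidates[int(np.argmax(ei))]
        evaluated.append(point)
        scores.append(objective(point))
    i_best = int(np.argmax(scores))
    return evaluated[i_best], scores[i_best], list(zip(evaluated, scores))


def random_search(
    objective: Callable[[dict], float],
    space: Sequence[Dimension],
    n_iterations: int,
    rng: np.random.Generator,
) -> tuple:
    evaluated = [_sample_point(space, rng) for _ in range(n_iterations)]
    scores = [objective(p) for p in evaluated]
    i_best = int(np.argmax(scores))
    return evaluated[i_best], scores[i_best], list(zip(evaluated, scores))


def optimize_hyperparameters(
    algorithm_key: str,
    X: np.ndarray,
    y: np.ndarray,
    space: Optional[Sequence[Dimension]] = None,
    n_iterations: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    method: str = "gp",
) -> dict:
    """Choose hyperparameters for one algorithm by sequential optimization.

    The objective is mean stratified k-fold CV accuracy of the algorithm
    built with the candidate configuration. ``method`` is "gp" (Gaussian
    process surrogate, default) or "random".
    """
    from .estimators import build_classifier  # local import avoids a cycle

    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("optimize_hyperparameters requires both classes present")
    if space is None:
        space = SEARCH_SPACES[algorithm_key]
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    def objective(point: dict) -> float:
        clf = build_classifier(algorithm_key, point, seed)
        return float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())

    search = gp_minimize_discrete if method == "gp" else random_search
    best, _score, _hist = search(objective, space, n_iterations, rng)
    return best
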