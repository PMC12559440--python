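"""Sequential model-based search over the fusion weight and learning rate.

The tunable space mirrors the two-model ensemble: a continuous fusion
weight w1 ∈ [0, 1] (the second model receives 1 − w1) and a learning rate
drawn from a small categorical set.  The objective is validation accuracy
of the fused ensemble; the search runs a fixed number of trials (ten by
default) and keeps the best.

Three proposal strategies are pluggable:

* ``random``  — uniform draws from the space;
* ``grid``    — fixed-order enumeration of a w1 grid crossed with the
  learning-rate choices, without repeats;
* ``surrogate`` — sequential model-based (Bayesian-style) optimization: a
  Gaussian-process regressor is fitted per learning rate on the observed
  (w1, accuracy) pairs and the next point maximizes expected improvement
  over a 101-point w1 grid.  With fewer than three past trials it falls
  back to random exploration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel

from .ensemble_fusion import (
    AdagradConfig,
    AttentionParams,
    ScalarWeights,
    fit_attention,
    fuse_table,
    fused_accuracy,
    scalar_fuse,
)
from .synthetic_data import MemberOutputTable

__all__ = [
    "SearchSpace",
    "SearchResult",
    "Trial",
    "fusion_objective",
    "propose_candidate",
    "run_search",
]

#: learning-rate choices explored by the tuner
DEFAULT_LEARNING_RATES = (0.018750, 0.01750, 0.002)
SURROGATE_MIN_HISTORY = 3
W1_GRID_POINTS = 101


@dataclass(frozen=True)
class SearchSpace:
    """w1 ∈ [w1_min, w1_max] (w2 = 1 − w1) × categorical learning rate."""

    w1_min: float = 0.0
    w1_max: float = 1.0
    learning_rates: tuple[float, ...] = DEFAULT_LEARNING_RATES
    grid_step: float = 0.05  # used by the grid strategy

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1_min <= self.w1_max <= 1.0:
            raise ValueError("w1 bounds must satisfy 0 <= min <= max <= 1")
        if not self.learning_rates:
            raise ValueError("at least one learning rate required")

    def w1_grid(self, n_points: int = W1_GRID_POINTS) -> np.ndarray:
        return np.linspace(self.w1_min, self.w1_max, n_points)

    def grid_points(self) -> list[tuple[float, float]]:
        """Fixed enumeration order without repeats.

        w1 grid values are visited coarse-to-fine (endpoints, then midpoints
        at doubling resolution) so that any trial-budget prefix spans the
        whole interval; learning rates cycle in declared order within each
        w1 value.
        """
        n = int(round((self.w1_max - self.w1_min) / self.grid_step)) + 1
        w1s = self.w1_min + self.grid_step * np.arange(n)
        order = _coarse_to_fine_order(n)
        return [(float(w1s[i]), lr) for i in order for lr in self.learning_rates]


def _coarse_to_fine_order(n: int) -> list[int]:
    """Permutation of range(n): endpoints first, then interval midpoints."""
    if n == 1:
        return [0]
    order = [0, n - 1]
    seen = {0, n - 1}
    intervals = [(0, n - 1)]
    while intervals:
        nxt: list[tuple[int, int]] = []
        for lo, hi in intervals:
            if hi - lo < 2:
                continue
            mid = (lo + hi) // 2
            if mid not in seen:
                order.append(mid)
                seen.add(mid)
            nxt.extend([(lo, mid), (mid, hi)])
        intervals = nxt
    return order


@dataclass
class Trial:
    """One evaluated hyperparameter point."""

    trial_index: int
    params: tuple[float, float]  # (w1, learning_rate)
    val_accuracy: float
    seed: int
    failed: bool = False
    error: str | None = None


@dataclass
class SearchResult:
    trials: list[Trial]
    best: Trial

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trials": [asdict(t) for t in self.trials],
            "best": asdict(self.best),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def propose_candidate(
    history: Sequence[Trial],
    space: SearchSpace,
    strategy: str = "surrogate",
    seed: int = 0,
) -> tuple[float, float]:
    """Propose the next (w1, learning_rate) point given past trials."""
    rng = np.random.default_rng(seed)
    ok_history = [t for t in history if not t.failed]

    if strategy == "random":
        w1 = float(rng.uniform(space.w1_min, space.w1_max))
        lr = float(space.learning_rates[rng.integers(len(space.learning_rates))])
        return (w1, lr)

    if strategy == "grid":
        pts = space.grid_points()
        return pts[len(history) % len(pts)]

    if strategy == "surrogate":
        if len(ok_history) < SURROGATE_MIN_HISTORY:
            return propose_candidate(history, space, "random", seed)
        best_acc = max(t.val_accuracy for t in ok_history)
        grid = space.w1_grid()
        best_point: tuple[float, float] | None = None
        best_ei = -np.inf
        for lr in space.learning_rates:
            pts = [t for t in ok_history if np.isclose(t.params[1], lr)]
            if len(pts) < 2:
                # unexplored learning rate: force exploration there
                return (float(rng.uniform(space.w1_min, space.w1_max)), float(lr))
            x = np.array([[t.params[0]] for t in pts])
            y = np.array([t.val_accuracy for t in pts])
            kernel = RBF(length_scale=0.2, length_scale_bounds=(0.02, 2.0)) + WhiteKernel(
                noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1)
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=int(seed) & 0x7FFFFFFF
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(x, y)
            mu, sigma = gp.predict(grid[:, None], return_std=True)
            ei = _expected_improvement(mu, sigma, best_acc)
            j = int(np.argmax(ei))
            if ei[j] > best_ei:
                best_ei = float(ei[j])
                best_point = (float(grid[j]), float(lr))
        assert best_point is not None
        return best_point

    raise ValueError(f"unknown strategy {strategy!r}")


def _trial_seed(master_seed: int, trial_index: int) -> int:
    """Stable per-trial seed below 2^31."""
    return int(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, trial_index]).generate_state(1)[0]
        >> 1
    )


def run_search(
    objective: Callable[[tuple[float, float]], float],
    space: SearchSpace,
    n_trials: int = 10,
    strategy: str = "surrogate",
    seed: int = 0,
) -> SearchResult:
    """Run the tuner: ``n_trials`` proposals, keep the argmax.

    Ties break toward the lowest trial index; a trial whose objective
    raises is recorded as failed and never becomes the best.  Fully
    reproducible under ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    trials: list[Trial] = []
    for i in range(n_trials):
        t_seed = _trial_seed(seed, i)
        params = propose_candidate(trials, space, strategy=strategy, seed=t_seed)
        try:
            acc = float(objective(params))
            trials.append(Trial(i, params, acc, t_seed))
        except Exception as exc:  # noqa: BLE001 — failed trials are data
            trials.append(Trial(i, params, float("nan"), t_seed,
                                failed=True, error=str(exc)))
    ok = [t for t in trials if not t.failed]
    if not ok:
        raise RuntimeError("every trial failed")
    best = max(ok, key=lambda t: (t.val_accuracy, -t.trial_index))
    return SearchResult(trials=trials, best=best)


def fusion_objective(
    table: MemberOutputTable,
    params: tuple[float, float],
    val_split: float = 0.2,
    mode: str = "global",
    epochs_per_trial: int = 10,
    seed: int = 0,
) -> float:
    """Validation accuracy of the fused ensemble at one search point.

    The table is split (deterministically under ``seed``) into fit and
    validation parts.  In ``global`` mode the scalar weights (w1, 1−w1)
    are applied directly; in ``attention`` mode the attention matrix is
    trained for ``epochs_per_trial`` epochs at the trial's learning rate
    before validation accuracy is measured.
    """
    w1, lr = params
    n = table.n_samples
    if n == 0:
        raise ValueError("empty member-output table")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_split * n)))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    val_table = table.subset(val_idx)

    if mode == "global":
        fused = fuse_table(val_table, mode="global", weights=ScalarWeights.from_w1(w1))
    elif mode == "attention":
        fit_table = table.subset(fit_idx)
        params0 = AttentionParams.zeros(table.n_models, table.n_classes)
        fitted, _ = fit_attention(
            params0, fit_table, optimizer=AdagradConfig(lr=lr),
            epochs=epochs_per_trial, seed=seed,
        )
        fused = fuse_table(val_table, mode="attention", params=fitted)
    else:
        raise ValueError(f"unknown objective mode {mode!r}")
    return fused_accuracy(val_table, fused)
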