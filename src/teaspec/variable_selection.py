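"""Hybrid wavenumber selection: biPLS -> CARS -> SPA.

The cascade shrinks the spectrum in three stages, each consuming only the
variables the previous stage kept:

* **biPLS** (backward interval PLS) splits the grid into contiguous
  equal-width intervals and greedily eliminates the interval whose removal
  gives the lowest leave-one-out RMSECV, all the way down; the interval set
  with the lowest RMSECV anywhere along that elimination path is returned.
* **CARS** (competitive adaptive reweighted sampling) runs N Monte-Carlo
  sampling rounds. Each round fits PLS on a random sample subset, ranks
  variables by normalised absolute regression coefficient, keeps the top
  fraction dictated by an exponentially decreasing schedule (enforced
  selection), then resamples the kept set with weighted bootstrap draws so
  low-weight variables face competitive elimination (adaptive reweighted
  sampling). The round whose surviving set scores the lowest LOO RMSECV
  wins.
* **SPA** (successive projections algorithm) builds, from every possible
  starting column, a chain that repeatedly adds the column with the largest
  component orthogonal to the span of the columns already chosen, then picks
  the (start, chain-prefix) whose ordinary-least-squares model has the
  lowest LOO RMSECV. SPA subsets are built to be well conditioned, so plain
  multiple linear regression scores them.

All stochastic stages are reproducible from their seed; ties break toward
the lowest index / earliest step throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemometrics import loo_cv, fit_pls, pearson

__all__ = [
    "SelectionResult",
    "CARSConfig",
    "BiPLSConfig",
    "SPAConfig",
    "split_intervals",
    "bipls",
    "edf_ratio",
    "cars",
    "spa",
    "cascade",
]

logger = logging.getLogger("teaspec")


@dataclass
class SelectionResult:
    """Variables retained by one selector stage, with the RMSECV evidence."""

    stage: str  # {"bipls", "cars", "spa", "none"}
    selected_indices: np.ndarray   # indices into the matrix given to the stage
    selected_wavenumbers: np.ndarray
    rmsecv_trace: np.ndarray       # RMSECV per elimination/sampling step

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.selected_wavenumbers = np.asarray(self.selected_wavenumbers, dtype=float)
        self.rmsecv_trace = np.asarray(self.rmsecv_trace, dtype=float)
        if self.selected_indices.size != np.unique(self.selected_indices).size:
            raise ValueError("selected indices must be unique")
        if self.rmsecv_trace.size == 0:
            raise ValueError("rmsecv_trace must be nonempty")

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size

    def display_wavenumbers(self) -> np.ndarray:
        """Selected wavenumbers rounded to the nearest integer cm^-1."""
        return np.rint(self.selected_wavenumbers).astype(int)


@dataclass
class BiPLSConfig:
    n_intervals: int = 20
    max_components: int = 10


@dataclass
class CARSConfig:
    """Monte-Carlo sampling settings for CARS.

    The exponentially decreasing schedule r_i = a * exp(-k*i) is pinned by
    its boundary conditions r_1 = 1 (all variables eligible at the start)
    and r_N = 2/p (two variables survive the final round), giving
    a = exp(k) and k = ln(p/2)/(N - 1).
    """

    n_runs: int = 50
    calibration_fraction: float = 0.8
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("CARS needs at least 2 sampling runs")
        if not 0 < self.calibration_fraction <= 1:
            raise ValueError("calibration_fraction must be in (0, 1]")


@dataclass
class SPAConfig:
    max_vars: int = 25


def split_intervals(p: int, n_intervals: int) -> list:
    """Contiguous near-equal intervals; the remainder goes to leading ones."""
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals to eliminate from")
    if n_intervals > p:
        raise ValueError(f"cannot split {p} variables into {n_intervals} intervals")
    base, extra = divmod(p, n_intervals)
    sizes = [base + 1] * extra + [base] * (n_intervals - extra)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_intervals)]


def bipls(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    n_intervals: int = 20,
    max_components: int = 10,
) -> SelectionResult:
    """Backward interval PLS elimination.

    Greedily removes, at each round, the interval whose removal yields the
    lowest LOO RMSECV on the remainder, down to a single interval; returns
    the union of intervals at the step with the global-minimum RMSECV along
    that path (ties toward the earlier step, i.e. fewer removals).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    intervals = split_intervals(X.shape[1], n_intervals)
    surviving = list(range(n_intervals))

    def score(interval_ids) -> float:
        cols = np.concatenate([intervals[i] for i in interval_ids])
        return loo_cv(X[:, cols], y, max_components).rmsecv

    trace = [score(surviving)]
    best_rmsecv = trace[0]
    best_set = list(surviving)
    while len(surviving) > 1:
        candidates = [
            (score([j for j in surviving if j != i]), idx)
            for idx, i in enumerate(surviving)
        ]
        cand_rmsecv, drop_pos = min(candidates)  # ties -> lowest interval id
        del surviving[drop_pos]
        trace.append(cand_rmsecv)
        if cand_rmsecv < best_rmsecv:
            best_rmsecv = cand_rmsecv
            best_set = list(surviving)
        logger.debug(
            "bipls: %d intervals left, RMSECV=%.5g", len(surviving), cand_rmsecv
        )
    cols = np.concatenate([intervals[i] for i in sorted(best_set)])
    return SelectionResult("bipls", cols, np.asarray(grid)[cols], np.array(trace))


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Fraction of variables retained at CARS run ``i`` (1-based).

    r_i = a * exp(-k*i) with a = exp(k), k = ln(p/2)/(N-1), so that r_1 = 1
    and r_N = 2/p exactly.
    """
    if not 1 <= i <= n_runs:
        raise ValueError(f"run index must be in [1, {n_runs}], got {i}")
    if p < 2:
        raise ValueError(f"need at least 2 variables, got {p}")
    if n_runs < 2:
        raise ValueError("schedule needs at least 2 runs")
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(np.exp(k) * np.exp(-k * i))


def cars(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    config: CARSConfig,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling over ``config.n_runs`` rounds."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    n_cal = max(2, int(round(config.calibration_fraction * n)))
    eligible = np.arange(p)
    trace, sets = [], []
    for i in range(1, config.n_runs + 1):
        subset = np.sort(rng.choice(n, size=n_cal, replace=False))
        k_fit = min(config.max_components, n_cal - 1, eligible.size)
        model = fit_pls(X[np.ix_(subset, eligible)], y[subset], k_fit)
        w = np.abs(model.coefficients)
        total = w.sum()
        if total <= 0:  # uninformative fit: fall back to uniform weights
            w = np.full(eligible.size, 1.0 / eligible.size)
        else:
            w = w / total
        n_keep = min(int(np.ceil(p * edf_ratio(i, config.n_runs, p))), eligible.size)
        # enforced selection: keep the top-n_keep by weight (stable order)
        top = np.sort(np.argsort(-w, kind="stable")[:n_keep])
        w_top = w[top]
        w_top = w_top / w_top.sum()
        # adaptive reweighted sampling: p weighted draws with replacement
        # from the enforced set; survivors are the distinct draws, so the
        # retained count tracks the schedule while low-weight variables
        # still face competitive elimination
        drawn = rng.choice(top.size, size=p, replace=True, p=w_top)
        survivors = top[np.unique(drawn)]
        if survivors.size < 2:
            survivors = top  # keep the enforced set rather than collapse
        eligible = eligible[survivors]
        cv = loo_cv(X[:, eligible], y, min(config.max_components, eligible.size))
        trace.append(cv.rmsecv)
        sets.append(eligible.copy())
        logger.debug("cars run %d: %d vars, RMSECV=%.5g", i, eligible.size, cv.rmsecv)
    if not sets:
        raise ValueError("CARS produced no scorable run")
    best = int(np.argmin(trace))  # first minimum -> earlier run on ties
    cols = sets[best]
    return SelectionResult("cars", cols, np.asarray(grid)[cols], np.array(trace))


def _ols_loo_rmsecv(A: np.ndarray, y: np.ndarray) -> float:
    """Closed-form leave-one-out RMSECV of OLS with intercept (PRESS)."""
    n = A.shape[0]
    D = np.column_stack([np.ones(n), A])
    # pinv handles near-collinear chains; h_ii from the hat matrix
    pinv = np.linalg.pinv(D)
    resid = y - D @ (pinv @ y)
    h = np.einsum("ij,ji->i", D, pinv)
    denom = 1.0 - h
    denom = np.where(np.abs(denom) < 1e-10, np.nan, denom)
    loo = resid / denom
    if np.any(~np.isfinite(loo)):
        return float("inf")  # a leverage-one point: reject this subset
    return float(np.sqrt(np.mean(loo**2)))


def _projection_chain(X: np.ndarray, start: int, length: int) -> np.ndarray:
    """Column chain from ``start``: repeatedly add the candidate with the
    largest norm orthogonal to the span of the chosen columns."""
    n, p = X.shape
    R = X.copy()
    chain = [start]
    norm0 = np.linalg.norm(X[:, start])
    if norm0 > 0:
        qcur = X[:, start] / norm0
    else:
        qcur = np.zeros(n)
    mask = np.ones(p, dtype=bool)
    mask[start] = False
    for _ in range(length - 1):
        R = R - np.outer(qcur, qcur @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[~mask] = -1.0
        nxt = int(np.argmax(norms))  # argmax -> lowest index on ties
        if norms[nxt] <= 1e-12:
            break
        chain.append(nxt)
        mask[nxt] = False
        qcur = R[:, nxt] / norms[nxt]
    return np.array(chain, dtype=int)


def spa(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    max_vars: int = 25,
) -> SelectionResult:
    """Successive projections algorithm with exhaustive start search.

    For every start column a projection chain of up to ``max_vars`` columns
    is grown; each prefix is scored by the closed-form LOO RMSECV of an OLS
    model. The (start, prefix-length) with minimum RMSECV wins; ties prefer
    the shorter prefix, then the smaller start index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")
    max_vars = min(max_vars, n - 1, p)
    best = None  # (rmsecv, m, start, chain)
    for start in range(p):
        chain = _projection_chain(X, start, max_vars)
        for m in range(1, chain.size + 1):
            r = _ols_loo_rmsecv(X[:, chain[:m]], y)
            key = (r, m, start)
            if best is None or key < best[0]:
                best = (key, chain[:m].copy())
    (r_best, m_best, start_best), chain_best = best
    # trace: per-prefix RMSECV along the winning start's chain
    win_chain = _projection_chain(X, start_best, max_vars)
    trace = np.array(
        [_ols_loo_rmsecv(X[:, win_chain[:m]], y) for m in range(1, win_chain.size + 1)]
    )
    cols = np.sort(chain_best)
    logger.debug("spa: start=%d, m=%d, RMSECV=%.5g", start_best, m_best, r_best)
    return SelectionResult("spa", cols, np.asarray(grid)[cols], trace)


def cascade(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    bipls_cfg: BiPLSConfig | None = None,
    cars_cfg: CARSConfig | None = None,
    spa_cfg: SPAConfig | None = None,
) -> list:
    """Run the enabled stages in order; each consumes the survivors of the
    previous one. Indices in every result are in original-grid coordinates.

    Passing ``None`` for a stage disables it; with all stages disabled a
    single pass-through result keeps every variable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    current = np.arange(X.shape[1])
    results: list[SelectionResult] = []

    def remap(res: SelectionResult) -> SelectionResult:
        cols = current[res.selected_indices]
        return SelectionResult(res.stage, cols, grid[cols], res.rmsecv_trace)

    stages = []
    if bipls_cfg is not None:
        stages.append(("bipls", lambda M: bipls(
            M, y, grid[current], bipls_cfg.n_intervals, bipls_cfg.max_components)))
    if cars_cfg is not None:
        stages.append(("cars", lambda M: cars(M, y, grid[current], cars_cfg)))
    if spa_cfg is not None:
        stages.append(("spa", lambda M: spa(M, y, grid[current], spa_cfg.max_vars)))

    if not stages:
        return [SelectionResult("none", current, grid, np.array([
            loo_cv(X, y).rmsecv]))]

    for idx, (name, run) in enumerate(stages):
        res = remap(run(X[:, current]))
        results.append(res)
        current = res.selected_indices
        logger.info("%s kept %d variables", name, current.size)
        if current.size < 2 and idx < len(stages) - 1:
            warnings.warn(
                f"stage {name} kept {current.size} variable(s); "
                f"aborting remaining stages",
                stacklevel=2,
            )
            break
    return results
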