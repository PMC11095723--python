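"""Weighted nonlinear-least-squares calibration with multi-start search.

The objective is the inverse-variance weighted residual sum of squares

    LS(theta) = 1/2 * sum_cells w * (Zbar - z(theta))^2,   w = sigma^-2,

equal to the Gaussian negative log-likelihood up to an additive constant
(the 1/2 factor is kept package-wide, so information criteria computed
from ``loglik = -LS`` are consistent across models).

The search runs in log10 parameter coordinates over a bounded hypercube:
maxi-min Latin-hypercube starts, an Adam first stage from every start,
and bounded quasi-Newton (L-BFGS-B) refinement of the best stage-1
solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.spatial.distance import pdist, squareform

from .models import (
    OBSERVABLES,
    CandidateModel,
    CultureCondition,
    FixedConstants,
    IntegrationError,
    ParameterSet,
    simulate_conditions,
)
from .synthetic import TimeSeriesDataset

DEFAULT_BOUNDS = (1e-7, 1e7)

#: residual floor applied to replicate SDs so noiseless fixtures stay finite
SIGMA_FLOOR_FRAC = 1e-3
SIGMA_FLOOR_ABS = 1e-12

#: objective value returned when the simulation fails at a query point
PENALTY_LOSS = 1e12

#: default solver settings during fitting: looser tolerances than the
#: simulation API and a step cap so pathological parameter regions fail
#: fast (and are charged the penalty) instead of burning solver time
FIT_SOLVER_OPTIONS = {"rtol": 1e-6, "atol": 1e-8, "mxstep": 400}


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter bounds, searched on a log10 scale by default."""

    names: tuple[str, ...]
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()
    scale: str = "log10"

    def __post_init__(self) -> None:
        if not self.lower:
            object.__setattr__(self, "lower", (DEFAULT_BOUNDS[0],) * len(self.names))
        if not self.upper:
            object.__setattr__(self, "upper", (DEFAULT_BOUNDS[1],) * len(self.names))
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower and upper must have equal length")
        if self.scale not in ("log10", "linear"):
            raise ValueError("scale must be 'log10' or 'linear'")
        for nm, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"bounds for {nm} must satisfy lower < upper")
            if self.scale == "log10" and lo <= 0:
                raise ValueError(f"log10 scale requires positive bounds ({nm})")

    @property
    def dim(self) -> int:
        return len(self.names)

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if self.scale == "log10":
            return np.log10(lo), np.log10(hi)
        return lo, hi

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        return 10.0 ** x if self.scale == "log10" else np.asarray(x, float)

    def from_natural(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        return np.log10(theta) if self.scale == "log10" else theta

    @classmethod
    def for_model(cls, model: CandidateModel,
                  bounds: tuple[float, float] = DEFAULT_BOUNDS) -> "SearchSpace":
        names = model.free_parameter_names()
        return cls(names, (bounds[0],) * len(names), (bounds[1],) * len(names))


#: physically-motivated per-parameter bounds for reduced-budget searches:
#: rates are bounded by a ~10-minute doubling time (no mammalian cell
#: divides faster), per-cell consumption by media capacity over the
#: horizon, and half-saturation constants by +-3 decades around the
#: experimental concentration range.  Used by desk-scale fixtures; the
#: paper-scale default remains the full [1e-7, 1e7] hypercube.
PHYSICAL_BOUNDS = {
    "beta": (1e-7, 1e-3),
    "delta": (1e-8, 1e-3),
    "V_g": (1e-16, 1e-8),
    "cbar_g": (1e-3, 1e3),
    "K_o": (1e-4, 1e2),
    "K_g": (1e-3, 1e3),
    "K_l": (1e-3, 1e3),
}


def physical_search_space(model: CandidateModel) -> SearchSpace:
    """Search space with physically-plausible per-parameter bounds."""
    names = model.free_parameter_names()
    return SearchSpace(
        names,
        tuple(PHYSICAL_BOUNDS[n][0] for n in names),
        tuple(PHYSICAL_BOUNDS[n][1] for n in names),
    )


def search_space_for(
    model: CandidateModel,
    bounds: Mapping[str, Sequence[float]] | None = None,
) -> SearchSpace:
    """Search space from a per-parameter bounds mapping (config form);
    parameters not in the mapping get the default hypercube bounds."""
    if not bounds:
        return SearchSpace.for_model(model)
    names = model.free_parameter_names()
    lo, hi = [], []
    for n in names:
        b = bounds.get(n, DEFAULT_BOUNDS)
        lo.append(float(b[0]))
        hi.append(float(b[1]))
    return SearchSpace(names, tuple(lo), tuple(hi))


class NLSObjective:
    """Callable weighted-NLS loss for one model on one dataset split.

    Summary statistics, weights and index maps are precomputed once;
    each call costs a single stacked ODE solve.
    """

    def __init__(
        self,
        model: CandidateModel,
        consts: FixedConstants,
        dataset: TimeSeriesDataset,
        conditions: Mapping[str, CultureCondition],
        weight_mode: str = "inverse_variance",
        solver_options: dict | None = None,
        base_params: ParameterSet | None = None,
    ):
        if len(dataset) == 0:
            raise ValueError("dataset split is empty")
        if weight_mode not in ("inverse_variance", "unit"):
            raise ValueError("weight_mode must be 'inverse_variance' or 'unit'")
        self.model = model
        self.consts = consts
        self.solver_options = dict(FIT_SOLVER_OPTIONS)
        if solver_options:
            self.solver_options.update(solver_options)
        self.param_names = model.free_parameter_names()
        self.base_params = base_params or ParameterSet(
            beta=1.0, delta=0.0, V_g=0.0, cbar_g=1.0, K_o=1.0, K_g=1.0, K_l=1.0
        )

        summ = dataset.summaries
        cids = sorted(summ["condition_id"].unique())
        missing = [c for c in cids if c not in conditions]
        if missing:
            raise KeyError(f"no CultureCondition given for: {missing}")
        self.condition_ids = cids
        self.conditions = [conditions[c] for c in cids]
        self.times = np.unique(summ["time_h"].to_numpy(float))
        ci = pd.Categorical(summ["condition_id"], categories=cids).codes
        oi = pd.Categorical(summ["observable"], categories=OBSERVABLES).codes
        ti = np.searchsorted(self.times, summ["time_h"].to_numpy(float))
        self._idx = (np.asarray(ci), np.asarray(oi), np.asarray(ti))
        self.zbar = summ["mean"].to_numpy(float)
        sd = summ["sd"].to_numpy(float)
        if weight_mode == "unit":
            self.weights = np.ones_like(self.zbar)
        else:
            sigma = np.maximum.reduce(
                [sd, np.full_like(sd, SIGMA_FLOOR_ABS),
                 SIGMA_FLOOR_FRAC * np.abs(self.zbar)]
            )
            self.weights = sigma**-2
        self.n_points = self.zbar.size
        self.n_eval = 0

    def predict(self, params: ParameterSet) -> np.ndarray:
        sims = simulate_conditions(
            self.model, params, self.consts, self.conditions, self.times,
            self.solver_options,
        )
        return sims[self._idx]

    def _penalty(self, theta) -> float:
        # sloped, not flat: points the optimiser back toward the centre
        # of the (log-scale) hypercube instead of a zero-gradient plateau
        mag = np.linalg.norm(np.log10(np.abs(np.asarray(theta, float)) + 1e-300))
        return PENALTY_LOSS * (1.0 + 0.01 * mag)

    def __call__(self, theta: Sequence[float]) -> float:
        try:
            params = self.base_params.updated(self.param_names, theta)
        except ValueError:
            return self._penalty(theta)
        self.n_eval += 1
        try:
            z = self.predict(params)
        except (IntegrationError, ValueError):
            return self._penalty(theta)
        if not np.all(np.isfinite(z)):
            return self._penalty(theta)
        r = self.zbar - z
        return 0.5 * float(np.sum(self.weights * r * r))

    def residuals(self, theta: Sequence[float]) -> np.ndarray:
        """Weighted residual vector r with loss == sum(r**2)."""
        flat = np.sqrt(self._penalty(theta) / self.n_points)
        try:
            params = self.base_params.updated(self.param_names, theta)
            z = self.predict(params)
        except (IntegrationError, ValueError):
            return np.full(self.n_points, flat)
        if not np.all(np.isfinite(z)):
            return np.full(self.n_points, flat)
        self.n_eval += 1
        return np.sqrt(0.5 * self.weights) * (self.zbar - z)


def weighted_nls_objective(
    params: ParameterSet,
    model: CandidateModel,
    consts: FixedConstants,
    dataset_split: TimeSeriesDataset,
    conditions: Mapping[str, CultureCondition],
    weight_mode: str = "inverse_variance",
    solver_options: dict | None = None,
) -> float:
    """Evaluate the weighted-NLS loss at one parameter set."""
    obj = NLSObjective(
        model, consts, dataset_split, conditions, weight_mode, solver_options
    )
    return obj(params.to_array(obj.param_names))


def _maximin(points: np.ndarray) -> float:
    if len(points) < 2:
        return np.inf
    return float(pdist(points).min())


def _unit_lhs(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Centered Latin hypercube: one point per equal-probability bin."""
    centers = (np.arange(n) + 0.5) / n
    cols = [rng.permutation(centers) for _ in range(d)]
    return np.column_stack(cols)


def _maximin_improve(
    points: np.ndarray, rng: np.random.Generator, iters: int
) -> np.ndarray:
    """Greedy column-swap improvement of the maxi-min distance criterion.

    Swapping two points' values within a single column preserves the
    Latin-hypercube marginals, so the result is still an LHS; only swaps
    that improve the minimum pairwise distance are accepted.
    """
    n, d = points.shape
    if n < 3 or iters <= 0:
        return points
    dmat = squareform(pdist(points, "sqeuclidean"))
    np.fill_diagonal(dmat, np.inf)
    for _ in range(iters):
        cur_min = dmat.min()
        i = int(np.unravel_index(np.argmin(dmat), dmat.shape)[0])
        j = int(rng.integers(n))
        if j == i:
            continue
        col = int(rng.integers(d))
        pts = points.copy()
        pts[[i, j], col] = pts[[j, i], col]
        trial = dmat.copy()
        for k in (i, j):
            row = ((pts - pts[k]) ** 2).sum(axis=1)
            row[k] = np.inf
            trial[k, :] = row
            trial[:, k] = row
        if trial.min() > cur_min:
            points = pts
            dmat = trial
    return points


def lhs_starts(
    space: SearchSpace, n_points: int, seed: int = 0, maximin_iters: int = 100
) -> np.ndarray:
    """Maxi-min Latin-hypercube starting points, in natural units.

    Each one-dimensional projection occupies every equal-probability bin
    exactly once (on the search scale); a fixed budget of improvement
    swaps raises the minimum pairwise distance, never lowering it below
    the plain seeded draw.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    unit = _unit_lhs(n_points, space.dim, rng)
    unit = _maximin_improve(unit, rng, maximin_iters)
    lo, hi = space.internal_bounds()
    internal = lo + unit * (hi - lo)
    return space.to_natural(internal)


@dataclass
class FitResult:
    """Best calibrated parameters with the full multi-start archive."""

    theta_star: ParameterSet
    loss: float
    n_starts: int
    start_losses: np.ndarray
    converged: bool
    seed: int
    param_names: tuple[str, ...]
    model: CandidateModel
    space: SearchSpace | None = None
    archive: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return -self.loss

    def theta_array(self) -> np.ndarray:
        return self.theta_star.to_array(self.param_names)


DEFAULT_STAGE_OPTIONS = {
    "stage1_iters": 2000,   # Adam iterations per start
    "stage1_step": 0.05,    # Adam learning rate (log10 coordinates)
    "adam_beta1": 0.9,
    "adam_beta2": 0.999,
    "n_refine": 20,         # stage-1 solutions passed to L-BFGS-B
    "prescreen": None,      # optionally keep only the best-k starts by
                            # initial loss before running Adam at all
    "fd_step": 1e-4,        # forward-difference step (internal coords)
    "refine_maxiter": 200,
    "refine_min_sep": 0.5,  # min distance (internal coords) between the
                            # stage-1 solutions picked for refinement, so
                            # one wide attractor cannot monopolise stage 2
    "polish_n": 3,          # best refined solutions polished by TRF
    "polish_maxfev": 300,   # residual evaluations per polish
    # optimise log1p(loss) instead of the raw loss: the weighted-NLS
    # surface spans ~15 orders of magnitude and the compression keeps
    # finite-difference gradients informative far from the optimum
    # (monotone transform: argmin and the improvement guarantee are
    # unchanged; archived losses are always reported on the raw scale)
    "log_loss": True,
}


def _fd_grad(fun: Callable, x: np.ndarray, f0: float, h: float) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += h
        g[i] = (fun(xp) - f0) / h
    return g


def _adam(
    fun: Callable,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    iters: int,
    lr: float,
    b1: float,
    b2: float,
    h: float,
) -> tuple[np.ndarray, float]:
    x = x0.copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    f = fun(x)
    best_x, best_f = x.copy(), f
    for t in range(1, iters + 1):
        g = _fd_grad(fun, x, f, h)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        x = np.clip(x - lr * mhat / (np.sqrt(vhat) + 1e-8), lo, hi)
        f = fun(x)
        if f < best_f:
            best_x, best_f = x.copy(), f
    return best_x, best_f


def _diverse_best(
    xs: np.ndarray,
    fs: np.ndarray,
    active: np.ndarray,
    k: int,
    min_sep: float,
) -> np.ndarray:
    """Best-loss starts subject to a mutual minimum distance, so the
    refinement budget samples distinct local-optimum clusters."""
    order = active[np.argsort(fs[active])]
    picked: list[int] = []
    for i in order:
        if len(picked) == k:
            break
        if all(np.max(np.abs(xs[i] - xs[j])) >= min_sep for j in picked):
            picked.append(int(i))
    for i in order:  # fill up if the diversity constraint was too strict
        if len(picked) == k:
            break
        if i not in picked:
            picked.append(int(i))
    return np.asarray(picked, dtype=int)


def multistart_minimize(
    fun: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    n_starts: int,
    seed: int = 0,
    options: dict | None = None,
    starts: np.ndarray | None = None,
    residuals: Callable[[np.ndarray], np.ndarray] | None = None,
) -> dict:
    """Generic two-stage multi-start minimiser on a bounded box.

    Stage 1 runs Adam (finite-difference gradients) from every start
    (optionally only the ``prescreen`` best by initial loss); stage 2
    refines the best mutually-distant stage-1 solutions with L-BFGS-B.
    When a ``residuals`` callable is supplied (such that
    ``fun(x) == sum(residuals(x)**2)``), the best refined solutions get
    an improvement-only trust-region least-squares polish.  Fully
    deterministic under ``seed``.  Returns a dict with the best point,
    loss, and per-start archive.
    """
    opts = dict(DEFAULT_STAGE_OPTIONS)
    if options:
        opts.update(options)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    d = lower.size
    if starts is None:
        space = SearchSpace(
            tuple(f"x{i}" for i in range(d)),
            tuple(lower), tuple(upper), scale="linear",
        )
        starts = lhs_starts(space, n_starts, seed=seed)
    starts = np.atleast_2d(np.asarray(starts, float))
    n_starts = len(starts)

    use_log = bool(opts["log_loss"])
    work = (lambda x: float(np.log1p(fun(x)))) if use_log else fun
    raw = (lambda f: float(np.expm1(f))) if use_log else float

    init_losses = np.array([fun(x) for x in starts])
    order = np.argsort(init_losses)
    if opts["prescreen"] is not None:
        active = order[: int(opts["prescreen"])]
    else:
        active = np.arange(n_starts)

    stage1_x = starts.copy()
    stage1_f = init_losses.copy()
    for i in active:
        x, f = _adam(
            work, starts[i], lower, upper,
            opts["stage1_iters"], opts["stage1_step"],
            opts["adam_beta1"], opts["adam_beta2"], opts["fd_step"],
        )
        stage1_x[i], stage1_f[i] = x, raw(f)

    n_refine = min(int(opts["n_refine"]), len(active))
    refine_idx = _diverse_best(
        stage1_x, stage1_f, np.asarray(active), n_refine, opts["refine_min_sep"]
    )
    refined_f = np.full(n_starts, np.nan)
    refined_x = stage1_x.copy()
    best_x, best_f = None, np.inf
    converged = False
    for i in refine_idx:
        res = minimize(
            work, stage1_x[i], method="L-BFGS-B",
            bounds=list(zip(lower, upper)),
            options={"maxiter": opts["refine_maxiter"], "eps": opts["fd_step"]},
        )
        res_f = raw(res.fun)
        f = min(res_f, stage1_f[i])  # refinement never degrades
        x = res.x if res_f <= stage1_f[i] else stage1_x[i]
        refined_f[i] = f
        refined_x[i] = x
        if f < best_f:
            best_x, best_f = x, f
            converged = bool(res.success) or f <= stage1_f[i]

    if residuals is not None and len(refine_idx):
        # improvement-only Gauss-Newton polish in residual space; far
        # better conditioned than the scalar loss near an NLS optimum
        polish_idx = refine_idx[
            np.argsort(refined_f[refine_idx])[: int(opts["polish_n"])]
        ]
        for i in polish_idx:
            try:
                res = least_squares(
                    residuals, refined_x[i], bounds=(lower, upper),
                    method="trf", diff_step=opts["fd_step"],
                    max_nfev=int(opts["polish_maxfev"]),
                )
            except Exception:
                continue
            f = float(np.sum(res.fun**2))
            if f < refined_f[i]:
                refined_f[i] = f
                refined_x[i] = res.x
            if f < best_f:
                best_x, best_f, converged = res.x, f, True

    if best_x is None:  # no refinement requested: best stage-1 point
        i = int(np.argmin(stage1_f))
        best_x, best_f, converged = stage1_x[i], float(stage1_f[i]), True

    archive = pd.DataFrame(
        {
            "start": np.arange(n_starts),
            "initial_loss": init_losses,
            "stage1_loss": stage1_f,
            "refined_loss": refined_f,
        }
    )
    if not np.isfinite(best_f) or best_f >= PENALTY_LOSS:
        raise RuntimeError("all multi-start runs failed; see archive")
    return {
        "x": np.asarray(best_x, float),
        "loss": float(best_f),
        "archive": archive,
        "converged": converged,
        "n_starts": n_starts,
    }


def multistart_fit(
    model: CandidateModel,
    consts: FixedConstants,
    dataset_split: TimeSeriesDataset,
    conditions: Mapping[str, CultureCondition],
    space: SearchSpace | None = None,
    n_starts: int = 100,
    seed: int = 0,
    stage_options: dict | None = None,
    weight_mode: str = "inverse_variance",
    solver_options: dict | None = None,
) -> FitResult:
    """Calibrate one candidate model on a dataset split.

    Searches in log10 coordinates over ``space`` (default: the
    [1e-7, 1e7] hypercube on the model's free parameters).
    """
    space = space or SearchSpace.for_model(model)
    if tuple(space.names) != model.free_parameter_names():
        raise ValueError("search space names must match the model's free parameters")
    objective = NLSObjective(
        model, consts, dataset_split, conditions, weight_mode, solver_options
    )

    def fun(x: np.ndarray) -> float:
        return objective(space.to_natural(x))

    def residuals(x: np.ndarray) -> np.ndarray:
        return objective.residuals(space.to_natural(x))

    lo, hi = space.internal_bounds()
    opts = dict(stage_options or {})
    starts_nat = lhs_starts(space, n_starts, seed=seed)
    starts = space.from_natural(starts_nat)
    res = multistart_minimize(
        fun, lo, hi, n_starts, seed=seed, options=opts, starts=starts,
        residuals=residuals,
    )
    theta = space.to_natural(res["x"])
    params = objective.base_params.updated(space.names, theta)
    return FitResult(
        theta_star=params,
        loss=res["loss"],
        n_starts=res["n_starts"],
        start_losses=res["archive"]["stage1_loss"].to_numpy(),
        converged=res["converged"],
        seed=seed,
        param_names=tuple(space.names),
        model=model,
        space=space,
        archive=res["archive"],
        meta={"n_objective_evals": objective.n_eval},
    )


def planned_runs(n_starts: int, n_models: int) -> int:
    """Book-keeping: total stage-1 optimisation runs for a model family."""
    return int(n_starts) * int(n_models)
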