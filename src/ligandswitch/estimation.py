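"""Parameter estimation: multistart meta-evolutionary programming followed by
Nelder-Mead refinement, minimizing the sum of squared residuals between
densitometry time courses and model trajectories.

The search runs in log10 parameter space (rates span orders of magnitude, and
log space equalizes the mutation scale across coordinates).  Each restart is
an independent, seeded meta-EP run whose best individual seeds a Nelder-Mead
polish; the best of all restarts is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .receptor_model import (
    AFFINITY_RATIO,
    LigandSpec,
    ReceptorModelParams,
    initial_steady_state,
    readout,
    simulate,
)

__all__ = [
    "FitSeries",
    "FitDataset",
    "EstimationSettings",
    "EstimationResult",
    "EstimationFailure",
    "ModelObjective",
    "PENALTY",
    "objective",
    "meta_ep",
    "nelder_mead",
    "multistart_fit",
]

#: Objective value substituted when the model cannot be integrated at a trial
#: point; large but finite so the search stays totally ordered.
PENALTY = 1e12


class EstimationFailure(RuntimeError):
    """No restart produced an evaluable result."""


@dataclass(frozen=True)
class FitSeries:
    """One measured time course: a condition label, the stimulation applied,
    the receptor-pool scale of the cell state, the assay readout, and the
    observed (normalized) intensities."""

    condition: str
    ligand: LigandSpec
    r_scale: float
    readout_kind: str
    times: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "observed", np.asarray(self.observed, dtype=float))
        if self.times.size < 3:
            raise ValueError("each series needs >= 3 time points")
        if np.any(self.times < 0) or np.any(self.observed < 0):
            raise ValueError("times and intensities must be >= 0")
        if self.observed.shape != self.times.shape:
            raise ValueError("observed must match times")


@dataclass(frozen=True)
class FitDataset:
    """A collection of series fitted jointly.

    ``reference`` optionally names a (condition, time) point; when set, model
    predictions are divided by the predicted value there, matching data that
    were normalized to a reference band.  When None, data are compared on the
    model's absolute (dimensionless) scale.
    """

    series: tuple[FitSeries, ...]
    reference: tuple[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "series", tuple(self.series))
        if not self.series:
            raise ValueError("dataset must contain at least one series")
        if self.reference is not None:
            cond, t = self.reference
            ok = any(
                s.condition == cond and np.any(np.isclose(s.times, t))
                for s in self.series
            )
            if not ok:
                raise ValueError(f"reference point {self.reference} not in dataset")

    @property
    def total_sum_of_squares(self) -> float:
        return float(sum(np.sum(s.observed**2) for s in self.series))


@dataclass(frozen=True)
class EstimationSettings:
    """Hyper-parameters of the hybrid search.

    ``bounds`` are per-coordinate (low, high) boxes in log10 space.  Defaults
    follow common meta-EP practice; n_restarts defaults to 200 independent
    estimations, from which the minimum-objective model is kept.
    """

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 50
    generations: int = 100
    tournament_size: int = 10
    nm_max_iter: int = 1000
    nm_xtol: float = 1e-8
    nm_ftol: float = 1e-8
    n_restarts: int = 200
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "bounds", tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        )
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound needs low < high")
        for name in ("pop_size", "generations", "tournament_size",
                     "nm_max_iter", "n_restarts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of a search: the best point, its objective, and provenance."""

    x: np.ndarray
    objective: float
    restart_index: int = 0
    seed: int = 0
    n_evaluations: int = 0
    converged: bool = True
    params: ReceptorModelParams | None = None
    kd_egf: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if not self.objective >= 0:
            raise ValueError("objective must be >= 0")


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def objective(params: ReceptorModelParams, data: FitDataset) -> float:
    """Sum of squared residuals between observed series and model predictions.

    Each series is simulated from its own ligand-free steady state at its own
    r_scale.  If a reference point is declared, every prediction is divided by
    the predicted value at that point (relative-blot convention).  Integration
    failure returns :data:`PENALTY` instead of raising, so that a global
    search over a wide box never aborts.
    """
    try:
        preds = _predict(params, data)
    except Exception:
        return PENALTY
    sse = 0.0
    for s, pred in zip(data.series, preds):
        r = s.observed - pred
        sse += float(r @ r)
    if not np.isfinite(sse):
        return PENALTY
    return sse


def _predict(params: ReceptorModelParams, data: FitDataset) -> list[np.ndarray]:
    preds = []
    ref_value = None
    for s in data.series:
        p = replace(params, r_scale=s.r_scale)
        grid = s.times
        prepend = grid[0] != 0.0
        if prepend:
            grid = np.concatenate(([0.0], grid))
        traj = simulate(p, s.ligand, grid, initial_steady_state(p))
        y = readout(traj, s.readout_kind)
        if prepend:
            y = y[1:]
        preds.append(y)
        if data.reference is not None:
            cond, t = data.reference
            if s.condition == cond:
                idx = np.where(np.isclose(s.times, t))[0]
                if idx.size:
                    ref_value = y[idx[0]]
    if data.reference is not None:
        if ref_value is None or ref_value <= 0:
            raise ZeroDivisionError("reference prediction missing or non-positive")
        preds = [y / ref_value for y in preds]
    return preds


class ModelObjective:
    """Maps a log10 parameter vector onto :func:`objective`.

    ``free`` lists the coordinates being searched: any ReceptorModelParams
    rate name, or the special name ``"kd_egf"`` which sets the EGF
    dissociation constant (AREG's kd follows at 10x, the model's fixed
    affinity ratio).  Remaining rates stay at ``base``.
    """

    FIELDS = ("kon", "kp", "kdp", "ke0", "ke1", "kdpi", "kr", "kdeg", "kdegP", "vs")

    def __init__(self, data: FitDataset, base: ReceptorModelParams,
                 free: Sequence[str]):
        for name in free:
            if name != "kd_egf" and name not in self.FIELDS:
                raise ValueError(f"unknown free parameter {name!r}")
        self.data = data
        self.base = base
        self.free = tuple(free)

    def build_params(self, x) -> tuple[ReceptorModelParams, float | None]:
        values = {n: 10.0 ** xi for n, xi in zip(self.free, x)}
        kd_egf = values.pop("kd_egf", None)
        params = replace(self.base, **values) if values else self.base
        return params, kd_egf

    def dataset_for(self, kd_egf: float | None) -> FitDataset:
        if kd_egf is None:
            return self.data
        series = []
        for s in self.data.series:
            kd = kd_egf * (AFFINITY_RATIO if s.ligand.name == "AREG" else 1.0)
            lig = LigandSpec(s.ligand.name, s.ligand.concentration, kd)
            series.append(replace(s, ligand=lig))
        return FitDataset(series=tuple(series), reference=self.data.reference)

    def __call__(self, x) -> float:
        try:
            params, kd_egf = self.build_params(x)
            return objective(params, self.dataset_for(kd_egf))
        except Exception:
            return PENALTY


# --------------------------------------------------------------------------
# meta-evolutionary programming
# --------------------------------------------------------------------------

def meta_ep(
    fn: Callable[[np.ndarray], float],
    settings: EstimationSettings,
    seed: int,
) -> EstimationResult:
    """Classic self-adaptive ("meta") evolutionary programming.

    Each individual carries per-coordinate mutation step sizes sigma.  An
    offspring mutates the point with the parent's sigma, then the sigma
    itself log-normally with learning rates tau = 1/sqrt(2 sqrt(n)) and
    tau' = 1/sqrt(2 n).  Survival is (mu + mu) selection by q-round
    stochastic tournament over the joint parent/offspring pool.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in settings.bounds])
    hi = np.array([b[1] for b in settings.bounds])
    n = lo.size
    mu = settings.pop_size
    q = settings.tournament_size
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    tau_p = 1.0 / math.sqrt(2.0 * n)

    xs = rng.uniform(lo, hi, size=(mu, n))
    sigmas = np.full((mu, n), 0.1) * (hi - lo)
    fs = np.array([fn(x) for x in xs])
    n_eval = mu

    best_i = int(np.argmin(fs))
    best_x, best_f = xs[best_i].copy(), float(fs[best_i])

    for _ in range(settings.generations):
        child_x = xs + sigmas * rng.standard_normal((mu, n))
        np.clip(child_x, lo, hi, out=child_x)
        global_step = rng.standard_normal((mu, 1))
        child_s = sigmas * np.exp(tau_p * global_step
                                  + tau * rng.standard_normal((mu, n)))
        np.maximum(child_s, 1e-12, out=child_s)
        child_f = np.array([fn(x) for x in child_x])
        n_eval += mu

        pool_x = np.vstack([xs, child_x])
        pool_s = np.vstack([sigmas, child_s])
        pool_f = np.concatenate([fs, child_f])

        opponents = rng.integers(0, 2 * mu, size=(2 * mu, q))
        wins = (pool_f[:, None] <= pool_f[opponents]).sum(axis=1)
        # best wins first; ties broken by objective
        order = np.lexsort((pool_f, -wins))[:mu]
        xs, sigmas, fs = pool_x[order], pool_s[order], pool_f[order]

        i = int(np.argmin(fs))
        if fs[i] < best_f:
            best_x, best_f = xs[i].copy(), float(fs[i])

    return EstimationResult(x=best_x, objective=best_f, seed=seed,
                            n_evaluations=n_eval)


# --------------------------------------------------------------------------
# Nelder-Mead refinement
# --------------------------------------------------------------------------

def nelder_mead(
    fn: Callable[[np.ndarray], float],
    start,
    settings: EstimationSettings,
) -> EstimationResult:
    """Simplex refinement (reflection 1, expansion 2, contraction 0.5,
    shrink 0.5) from ``start``, bounded to the settings box.  The returned
    objective never exceeds the starting objective."""
    start = np.asarray(start, dtype=float)
    f0 = fn(start)
    res = minimize(
        fn,
        start,
        method="Nelder-Mead",
        bounds=settings.bounds,
        options={
            "maxiter": settings.nm_max_iter,
            "xatol": settings.nm_xtol,
            "fatol": settings.nm_ftol,
        },
    )
    n_eval = int(res.nfev) + 1
    if res.fun <= f0:
        x, f = np.asarray(res.x, dtype=float), float(res.fun)
    else:  # defensive; simplex should never regress
        x, f = start, float(f0)
    return EstimationResult(x=x, objective=f, n_evaluations=n_eval,
                            converged=bool(res.success))


# --------------------------------------------------------------------------
# multistart driver
# --------------------------------------------------------------------------

def multistart_fit(
    data: FitDataset,
    settings: EstimationSettings,
    base: ReceptorModelParams | None = None,
    free: Sequence[str] = ("kd_egf", "kp", "ke1"),
    fn: Callable[[np.ndarray], float] | None = None,
) -> EstimationResult:
    """Best of ``n_restarts`` independent meta-EP -> Nelder-Mead chains.

    Restart i is seeded ``settings.seed + i``, making the whole fit
    reproducible from (data, settings).  ``fn`` may override the objective
    callable (e.g. for benchmark functions); by default a
    :class:`ModelObjective` over ``free`` is built from ``data``.
    """
    if fn is None:
        if base is None:
            from .receptor_model import default_params

            base = default_params()
        model_obj = ModelObjective(data, base, free)
        fn = model_obj
    else:
        model_obj = None

    best: EstimationResult | None = None
    total_eval = 0
    for i in range(settings.n_restarts):
        restart_seed = settings.seed + i
        ep = meta_ep(fn, settings, seed=restart_seed)
        nm = nelder_mead(fn, ep.x, settings)
        total_eval += ep.n_evaluations + nm.n_evaluations
        if nm.objective >= PENALTY:
            continue
        if best is None or nm.objective < best.objective:
            best = replace(nm, restart_index=i, seed=restart_seed)
    if best is None:
        raise EstimationFailure("every restart returned the penalty objective")
    best = replace(best, n_evaluations=total_eval)
    if model_obj is not None:
        params, kd_egf = model_obj.build_params(best.x)
        best = replace(best, params=params, kd_egf=kd_egf)
    return best
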