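"""Weighted least-squares parameter estimation for the batch growth model.

The objective is the weighted sum of squared residuals

    SSE(theta) = sum_i sum_j ((c_ij - chat_ij(theta)) / W_j)^2

over all measured points of all species (biomass, sucrose, kno3), with one
weight W_j per species (default: the species' maximum observed value, which
scales residuals of very differently sized quantities — biomass ~20 g L^-1,
nitrate ~2 g L^-1 — to comparable magnitude). chat_ij comes from an RK4
batch simulation sampled exactly at the measurement times.

Minimization uses the Rosenbrock rotating-directions method (derivative
free; trial steps along an orthogonal direction set, expansion x3 on
success, reversal-contraction x(-0.5) on failure, Gram-Schmidt rotation of
the direction set after each stage), with box bounds enforced by
projection, wrapped in a seeded Latin-hypercube multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .kinetics import (
    CultureState,
    KineticParameters,
    ModelType,
    free_parameter_names,
)
from .simulate import simulate_batch

__all__ = [
    "SPECIES",
    "TimeCourseDataset",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "FitResult",
    "EstimationError",
    "objective",
    "rosenbrock_minimize",
    "fit_model",
    "estimate_mu_series",
]

SPECIES = ("biomass", "sucrose", "kno3")

# column of the simulated state corresponding to each species
_SPECIES_COL = {"biomass": 0, "sucrose": 1, "kno3": 2}


class EstimationError(RuntimeError):
    pass


@dataclass
class TimeCourseDataset:
    """Measured concentrations in long form with per-species weights.

    data : DataFrame with columns time_d, species, replicate, value
        (possibly replicated measurements; species from SPECIES).
    weights : W_j per species; defaults to each species' maximum
        observed value.
    """

    data: pd.DataFrame
    weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        required = {"time_d", "species", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        bad = set(self.data["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species {sorted(bad)}")
        if (self.data["value"] < 0).any():
            raise ValueError("negative concentrations in dataset")
        for sp, grp in self.data.groupby("species"):
            if grp["time_d"].nunique() < 2:
                raise ValueError(f"species {sp!r} has < 2 time points")
        self.data = self.data.sort_values(
            ["species", "time_d", "replicate"]
        ).reset_index(drop=True)
        if self.weights is None:
            self.weights = {
                sp: float(grp["value"].max())
                for sp, grp in self.data.groupby("species")
            }
        for sp, w in self.weights.items():
            if not (w > 0):
                raise ValueError(f"weight for {sp!r} must be > 0, got {w}")

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(sorted(self.data["species"].unique(),
                            key=SPECIES.index))

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_d"].unique())

    @property
    def n_points(self) -> int:
        """Total number of measured values (all species, all replicates)."""
        return len(self.data)

    def species_means(self, species: str) -> Tuple[np.ndarray, np.ndarray]:
        grp = (
            self.data[self.data["species"] == species]
            .groupby("time_d")["value"]
            .mean()
        )
        return grp.index.to_numpy(), grp.to_numpy()


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for estimation, one (lower, upper) pair per parameter."""

    lower: KineticParameters
    upper: KineticParameters

    def __post_init__(self) -> None:
        for name in free_parameter_names(ModelType.SIGMOID):
            lo = getattr(self.lower, name)
            hi = getattr(self.upper, name)
            if lo > hi:
                raise ValueError(f"lower > upper for {name}")
        # n1 too (not in SIGMOID free set ordering above it is; keep simple)

    def arrays(self, names: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self.lower, n) for n in names], dtype=float)
        hi = np.array([getattr(self.upper, n) for n in names], dtype=float)
        return lo, hi

    def contains(self, p: KineticParameters, names: Sequence[str]) -> bool:
        lo, hi = self.arrays(names)
        x = np.array([getattr(p, n) for n in names])
        return bool(np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12))


# Published estimation box for this culture (same box for every model type).
DEFAULT_BOUNDS = ParameterBounds(
    lower=KineticParameters(
        y_xs1=0.1, y_xs2=0.1, mu_max=0.1, k_s1=1e-3, k_s2=1e-3,
        m_s1=1e-7, m_s2=1e-7, s_m1=44.9, s_m2=2.0,
        n1=1e-3, n2=1e-3, n3=1e-3, n4=1e-3,
    ),
    upper=KineticParameters(
        y_xs1=1.0, y_xs2=10.0, mu_max=1.0, k_s1=44.9, k_s2=2.0,
        m_s1=0.1, m_s2=0.1, s_m1=200.0, s_m2=20.0,
        n1=5.0, n2=5.0, n3=5.0, n4=5.0,
    ),
)


@dataclass
class FitResult:
    """Outcome of a (multi-start) model fit."""

    params: KineticParameters
    model_type: ModelType
    objective: float
    n: int
    p: int
    residuals: pd.DataFrame
    n_restarts: int
    seed: Optional[int]
    converged: bool
    trace: List[float] = field(default_factory=list)

    @property
    def df(self) -> int:
        return self.n - self.p

    @property
    def variance(self) -> float:
        return self.objective / self.df


def _params_from_vector(
    x: np.ndarray, names: Sequence[str], template: KineticParameters
) -> KineticParameters:
    return replace(template, **{n: float(v) for n, v in zip(names, x)})


def predicted_curves(
    p: KineticParameters,
    model_type: ModelType,
    data: TimeCourseDataset,
    init: CultureState,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Model predictions chat at every measurement row of the dataset."""
    times = data.times
    t_eval = times[times > 0]
    traj = simulate_batch(p, model_type, init, float(times[-1]), dt,
                          t_eval=t_eval)
    lookup = {float(t): traj.states[i] for i, t in enumerate(traj.times)}
    pred = np.empty(len(data.data))
    for i, row in enumerate(data.data.itertuples(index=False)):
        pred[i] = lookup[float(row.time_d)][_SPECIES_COL[row.species]]
    out = data.data.copy()
    out["predicted"] = pred
    out["residual"] = out["value"] - out["predicted"]
    return out


def objective(
    p: KineticParameters,
    model_type: ModelType,
    data: TimeCourseDataset,
    init: CultureState,
    dt: float = 0.05,
) -> float:
    """Weighted SSE of the batch model against the dataset."""
    res = predicted_curves(p, model_type, data, init, dt)
    w = res["species"].map(data.weights).to_numpy(dtype=float)
    return float(np.sum((res["residual"].to_numpy() / w) ** 2))


def rosenbrock_minimize(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    *,
    init_step: float = 0.1,
    tol: float = 1e-9,
    max_evals: int = 5000,
    alpha: float = 3.0,
    beta: float = -0.5,
) -> Tuple[np.ndarray, float, List[float]]:
    """Rosenbrock's rotating-directions minimizer under box bounds.

    Trial points outside the box are projected onto it; a projected trial
    that does not move counts as a failed step. Steps start at
    ``init_step`` times the box width per coordinate (or |x0|+1 where the
    box is unbounded in practice). Terminates when every step length
    falls below ``tol`` (relative to the box width) or the evaluation
    budget is spent. Returns (x_best, f_best, best-so-far trace).
    """
    x0 = np.asarray(x0, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    ndim = x0.size
    if np.any(x0 < lower - 1e-12) or np.any(x0 > upper + 1e-12):
        raise ValueError("x0 must lie within the bounds")
    width = np.where(upper > lower, upper - lower, np.abs(x0) + 1.0)

    def clip(x: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(x, lower), upper)

    def safe_f(x: np.ndarray) -> float:
        v = f(x)
        return np.inf if not np.isfinite(v) else float(v)

    x = clip(x0.copy())
    fx = safe_f(x)
    evals = 1
    trace = [fx]
    directions = np.eye(ndim)
    steps = init_step * width.copy()
    lam = np.zeros(ndim)
    had_success = np.zeros(ndim, dtype=bool)
    had_failure = np.zeros(ndim, dtype=bool)

    while evals < max_evals:
        improved_any = False
        for i in range(ndim):
            trial = clip(x + steps[i] * directions[i])
            if np.allclose(trial, x, rtol=0.0, atol=1e-15):
                ft = np.inf  # projection pinned the move: a failure
            else:
                ft = safe_f(trial)
                evals += 1
            if ft <= fx:
                x, fx = trial, ft
                lam[i] += steps[i]
                steps[i] *= alpha
                had_success[i] = True
                improved_any = True
            else:
                steps[i] *= beta
                had_failure[i] = True
            trace.append(fx)
            if evals >= max_evals:
                break
        if np.all(had_success & had_failure):
            # stage complete: rotate the direction set (Gram-Schmidt on
            # the aggregate successful displacement and its complements)
            a = np.zeros((ndim, ndim))
            for i in range(ndim):
                a[i] = sum(lam[j] * directions[j] for j in range(i, ndim))
            new_dirs = []
            for i in range(ndim):
                v = a[i].copy()
                for d in new_dirs:
                    v -= (a[i] @ d) * d
                norm = np.linalg.norm(v)
                new_dirs.append(directions[i] if norm < 1e-14 else v / norm)
            directions = np.array(new_dirs)
            steps = init_step * width.copy()
            lam[:] = 0.0
            had_success[:] = False
            had_failure[:] = False
        if np.all(np.abs(steps) / width < tol) and not improved_any:
            break
    return x, fx, trace


def fit_model(
    model_type: ModelType,
    data: TimeCourseDataset,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    init: CultureState = CultureState(7.0, 45.6, 2.1, 1.2),
    *,
    n_restarts: int = 20,
    seed: int,
    dt: float = 0.05,
    max_evals: int = 4000,
    extra_starts: Sequence[KineticParameters] = (),
) -> FitResult:
    """Best weighted-SSE fit over seeded Latin-hypercube restarts.

    Free parameters are those of the model type (11/12/13); the fit is
    deterministic given the seed. ``extra_starts`` adds user-chosen start
    points (e.g. a literature parameter set) to the start list.
    """
    names = free_parameter_names(model_type)
    lo, hi = bounds.arrays(names)
    template = KineticParameters(
        y_xs1=1.0, y_xs2=1.0, mu_max=0.1, k_s1=1.0, k_s2=1.0,
        m_s1=0.0, m_s2=0.0, s_m1=100.0, s_m2=10.0,
    )

    def fvec(x: np.ndarray) -> float:
        try:
            return objective(
                _params_from_vector(x, names, template), model_type,
                data, init, dt,
            )
        except Exception:
            return np.inf

    starts: List[np.ndarray] = []
    for ep in extra_starts:
        starts.append(np.clip(
            np.array([getattr(ep, n) for n in names], dtype=float), lo, hi))
    if n_restarts > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        unit = sampler.random(n=n_restarts)
        starts.extend(lo + unit * (hi - lo))
    if not starts:
        raise EstimationError("no start points (n_restarts=0, no extras)")

    best: Optional[Tuple[np.ndarray, float, List[float]]] = None
    failures: List[str] = []
    for x0 in starts:
        try:
            res = rosenbrock_minimize(
                fvec, x0, lo, hi, max_evals=max_evals)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res[1] < best[1]:
            best = res
    if best is None or not np.isfinite(best[1]):
        raise EstimationError(
            f"all {len(starts)} restarts failed: {failures[:3]}")

    x_best, f_best, trace = best
    params = _params_from_vector(x_best, names, template)
    residuals = predicted_curves(params, model_type, data, init, dt)
    return FitResult(
        params=params,
        model_type=model_type,
        objective=f_best,
        n=data.n_points,
        p=len(names),
        residuals=residuals,
        n_restarts=n_restarts,
        seed=seed,
        converged=True,
        trace=trace,
    )


def estimate_mu_series(
    times: Sequence[float],
    biomass: Sequence[float],
    *,
    min_window: int = 4,
) -> float:
    """Specific growth rate from a biomass time series (d^-1).

    Slope of ln(x) versus t over the best-fitting exponential window:
    all contiguous windows of at least ``min_window`` points are scored
    by the R^2 of the linear fit, and the slope of the highest-R^2
    window is returned (ties go to the longer, then earlier, window).
    A constant series returns 0.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if t.size != x.size:
        raise ValueError("times and biomass must have equal length")
    if t.size < min_window:
        raise ValueError(f"need at least {min_window} points")
    if np.any(x <= 0):
        raise ValueError("biomass values must be positive")
    lx = np.log(x)
    if np.allclose(lx, lx[0]):
        return 0.0
    best = (-np.inf, 0, 0, 0.0)  # (r2, length, -start, slope)
    n = t.size
    for i in range(0, n - min_window + 1):
        for j in range(i + min_window, n + 1):
            tt, yy = t[i:j], lx[i:j]
            if yy.max() - yy.min() < 1e-8:
                continue  # flat stationary-phase window, not exponential
            slope, intercept = np.polyfit(tt, yy, 1)
            fitted = slope * tt + intercept
            ss_res = float(np.sum((yy - fitted) ** 2))
            ss_tot = float(np.sum((yy - yy.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot
            key = (r2, j - i, -i, slope)
            if key[:3] > best[:3]:
                best = key
    return float(best[3]) if np.isfinite(best[0]) else 0.0
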