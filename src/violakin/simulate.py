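"""Fixed-step classical RK4 integration of batch and fed-batch cultures.

The vector field is smooth except at the feed-window edges, so integration
is performed piecewise between "knots" (segment boundaries: t0, tf, the
feed start/end, and any requested output times). Every knot is landed on
exactly — a step never straddles the flow discontinuity, which preserves
fourth-order accuracy, and model predictions at measurement times need no
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, isfinite
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    CultureState,
    FeedStrategy,
    KineticParameters,
    ModelType,
    batch_rhs,
)

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate_rk4",
    "simulate_batch",
    "simulate_fedbatch",
    "TRAJECTORY_CSV_HEADER",
]

TRAJECTORY_CSV_HEADER = "time_d,biomass_gDW_L,sucrose_g_L,kno3_g_L,volume_L"

DEFAULT_DT = 0.01  # d

RHS = Callable[[float, tuple], tuple]


class IntegrationError(RuntimeError):
    """Raised when the vector field returns non-finite derivatives."""


@dataclass
class Trajectory:
    """Sampled culture time course.

    times is strictly increasing; states is the aligned (n, 4) array of
    (biomass, sucrose, KNO3, volume).
    """

    times: np.ndarray
    states: np.ndarray
    model_type: Optional[ModelType] = None
    params: Optional[KineticParameters] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must be (len(times), 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def biomass(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def sucrose(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def kno3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def volume(self) -> np.ndarray:
        return self.states[:, 3]

    def state_at(self, t: float) -> CultureState:
        """State at a sampled time t (must be on the output grid)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"t={t} not on the output grid")
        x, s1, s2, v = self.states[i]
        return CultureState(x=x, s1=s1, s2=s2, v=v)

    @property
    def final_state(self) -> CultureState:
        x, s1, s2, v = self.states[-1]
        return CultureState(x=x, s1=s1, s2=s2, v=v)

    def sample(self, times: Sequence[float]) -> "Trajectory":
        """Restrict to a subset of the output grid."""
        idx = [int(np.argmin(np.abs(self.times - t))) for t in times]
        return Trajectory(self.times[idx], self.states[idx],
                          self.model_type, self.params)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "biomass_gDW_L": self.biomass,
                "sucrose_g_L": self.sucrose,
                "kno3_g_L": self.kno3,
                "volume_L": self.volume,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rk4_segment(rhs: RHS, y: tuple, t0: float, t1: float, dt: float,
                 record: Optional[list] = None) -> tuple:
    """Integrate one smooth segment [t0, t1] with uniform steps <= dt."""
    n = max(1, ceil((t1 - t0) / dt - 1e-12))
    h = (t1 - t0) / n
    t = t0
    for _ in range(n):
        k1 = rhs(t, y)
        y2 = tuple(a + 0.5 * h * b for a, b in zip(y, k1))
        k2 = rhs(t + 0.5 * h, y2)
        y3 = tuple(a + 0.5 * h * b for a, b in zip(y, k2))
        k3 = rhs(t + 0.5 * h, y3)
        y4 = tuple(a + h * b for a, b in zip(y, k3))
        k4 = rhs(t + h, y4)
        if not all(isfinite(v) for v in k1 + k2 + k3 + k4):
            raise IntegrationError(
                f"non-finite derivative near t={t:.6g} (state {y})"
            )
        y = tuple(
            a + h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        )
        # non-negativity guard: concentrations clamp to 0 at depletion
        y = (max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0), y[3])
        t += h
        if record is not None:
            record.append((t, y))
    return y


def integrate_rk4(
    rhs: RHS,
    state0: CultureState,
    t0: float,
    tf: float,
    dt: float = DEFAULT_DT,
    *,
    t_eval: Optional[Sequence[float]] = None,
    breakpoints: Iterable[float] = (),
    model_type: Optional[ModelType] = None,
    params: Optional[KineticParameters] = None,
) -> Trajectory:
    """Classical fixed-step RK4 over [t0, tf].

    Parameters
    ----------
    rhs : callable(t, y) -> dy/dt over the 4-tuple (x, s1, s2, v).
    t_eval : output grid; default is every internal step. Requested times
        are landed on exactly (segment boundaries), not interpolated.
    breakpoints : additional times where the field is discontinuous
        (e.g. feed start/end); steps are aligned so none straddles them.
    """
    if not (tf > t0):
        raise ValueError("need tf > t0")
    if not (0 < dt <= tf - t0):
        raise ValueError("need 0 < dt <= tf - t0")
    knots = {t0, tf}
    knots.update(b for b in breakpoints if t0 < b < tf)
    te: Optional[list] = None
    if t_eval is not None:
        te = sorted(float(t) for t in t_eval)
        if te and (te[0] < t0 - 1e-12 or te[-1] > tf + 1e-12):
            raise ValueError("t_eval must lie within [t0, tf]")
        te = [min(max(t, t0), tf) for t in te]
        knots.update(te)
    knots = sorted(knots)

    y = state0.as_tuple()
    dense = t_eval is None
    out_t = [t0]
    out_y = [y]
    for a, b in zip(knots[:-1], knots[1:]):
        record: Optional[list] = [] if dense else None
        y = _rk4_segment(rhs, y, a, b, dt, record)
        if dense:
            for t_i, y_i in record:  # type: ignore[union-attr]
                out_t.append(t_i)
                out_y.append(y_i)
        else:
            out_t.append(b)
            out_y.append(y)
    traj = Trajectory(np.array(out_t), np.array(out_y), model_type, params)
    if te is not None:
        traj = traj.sample(te if te and abs(te[0] - t0) < 1e-12
                           else [t0] + te)
    return traj


def _clamped(y: tuple) -> CultureState:
    return CultureState(max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0), y[3])


def simulate_batch(
    p: KineticParameters,
    model_type: ModelType,
    init: CultureState,
    tf: float,
    dt: float = DEFAULT_DT,
    *,
    t_eval: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Batch culture trajectory over [0, tf] (constant volume)."""

    def rhs(t: float, y: tuple) -> tuple:
        # intermediate RK stages may dip infinitesimally below zero
        return batch_rhs(p, model_type, _clamped(y))

    return integrate_rk4(
        rhs, init, 0.0, tf, dt, t_eval=t_eval, model_type=model_type,
        params=p,
    )


def simulate_fedbatch(
    p: KineticParameters,
    model_type: ModelType,
    feed: FeedStrategy,
    init: Optional[CultureState] = None,
    dt: float = DEFAULT_DT,
    *,
    t_eval: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Batch phase then fed-batch over [0, feed.t_end].

    The initial state defaults to the optimized batch medium in the
    strategy's starting volume (inoculum 7 g DW L^-1, sucrose 45.6 g L^-1,
    KNO3 2.1 g L^-1). Integration restarts a step exactly at the feed
    start so the flow discontinuity never falls inside an RK4 step.
    """
    if init is None:
        init = CultureState(x=7.0, s1=45.6, s2=2.1, v=feed.v0)
    elif abs(init.v - feed.v0) > 1e-9:
        raise ValueError("init.v must equal feed.v0")

    # the two phases are integrated separately with phase-constant flow,
    # so no RK4 stage ever samples the wrong side of the discontinuity
    batch_phase = replace(feed, flow=0.0)
    feed_phase = feed

    def make_rhs(phase: FeedStrategy) -> RHS:
        def rhs(t: float, y: tuple) -> tuple:
            state = _clamped(y)
            if phase.flow == 0.0:
                dx, ds1, ds2, _ = batch_rhs(p, model_type, state)
                return (dx, ds1, ds2, 0.0)
            d = phase.flow / state.v
            dx, ds1, ds2, _ = batch_rhs(p, model_type, state)
            return (
                dx - d * state.x,
                ds1 + d * (phase.feed_s1 - state.s1),
                ds2 + d * (phase.feed_s2 - state.s2),
                phase.flow,
            )

        return rhs

    te = None if t_eval is None else sorted(float(t) for t in t_eval)
    segments = []
    if feed.t_feed_start > 0.0:
        segments.append((0.0, feed.t_feed_start, make_rhs(batch_phase)))
    segments.append((feed.t_feed_start, feed.t_end, make_rhs(feed_phase)))

    times_out = [0.0]
    states_out = [init.as_tuple()]
    state = init
    for a, b, rhs in segments:
        seg_eval = None
        if te is not None:
            seg_eval = [t for t in te if a < t <= b]
        traj = integrate_rk4(rhs, state, a, b, min(dt, b - a),
                             t_eval=seg_eval)
        times_out.extend(traj.times[1:])
        states_out.extend(map(tuple, traj.states[1:]))
        state = traj.final_state
    traj = Trajectory(np.array(times_out), np.array(states_out),
                      model_type, p)
    if te is not None:
        traj = traj.sample(te if te and te[0] == 0.0 else [0.0] + te)
    return traj
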