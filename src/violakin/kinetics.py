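"""Dual-substrate growth kernels with Luong-type substrate inhibition.

Specific growth rate of a plant cell suspension limited by a carbon source
(sucrose, ``s1``) and a nitrogen source (potassium nitrate, ``s2``):

    mu = mu_max * lim1(s1) * lim2(s2) * inh(s1; s_m1, n3) * inh(s2; s_m2, n4)

where each limitation term is either Monod ``s/(s + K)`` or sigmoid (Hill)
``s**n / (s**n + K**n)`` depending on the model type, and the inhibition
factor ``inh(s) = 1 - (s/s_m)**n`` drives growth to zero at the ceiling
concentration ``s_m``.

Units package-wide: time d, concentration g L^-1, volume L, flow L d^-1.
Biomass is g DW (dry weight) L^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from enum import Enum
from typing import Tuple

__all__ = [
    "ModelType",
    "KineticParameters",
    "CultureState",
    "FeedStrategy",
    "luong_factor",
    "monod_limitation",
    "sigmoid_limitation",
    "specific_growth_rate",
    "uptake_rates",
    "batch_rhs",
    "fedbatch_rhs",
    "free_parameter_names",
    "BATCH_FIT_MONOD",
    "BATCH_FIT_MONOD_SIGMOID",
    "BATCH_FIT_SIGMOID",
    "OPTIMIZED_BATCH_INITIAL_STATE",
]


class ModelType(str, Enum):
    """Which limitation kernel applies to each substrate.

    MONOD          : Monod on both substrates.
    MONOD_SIGMOID  : Monod on sucrose, sigmoid on nitrate (uses n2).
    SIGMOID        : sigmoid on both substrates (uses n1 and n2).

    All three carry the same two Luong inhibition factors (n3, n4).
    """

    MONOD = "monod"
    MONOD_SIGMOID = "monod_sigmoid"
    SIGMOID = "sigmoid"


@dataclass(frozen=True)
class KineticParameters:
    """The 13-parameter vector of the dual-substrate batch growth model.

    Attributes
    ----------
    y_xs1, y_xs2 : float
        Biomass yields, g DW per g sucrose / per g KNO3. Must be > 0.
    mu_max : float
        Maximum specific growth rate, d^-1.
    k_s1, k_s2 : float
        Half-saturation concentrations, g L^-1.
    m_s1, m_s2 : float
        Maintenance coefficients, g substrate (g DW)^-1 d^-1.
    s_m1, s_m2 : float
        Complete-inhibition ceilings, g L^-1. Must be > 0.
    n1, n2 : float
        Sigmoid (Hill) exponents for sucrose / nitrate limitation.
    n3, n4 : float
        Luong inhibition exponents for sucrose / nitrate.
    """

    y_xs1: float
    y_xs2: float
    mu_max: float
    k_s1: float
    k_s2: float
    m_s1: float
    m_s2: float
    s_m1: float
    s_m2: float
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0
    n4: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):  # also catches NaN
                raise ValueError(f"parameter {f.name}={v!r} must be >= 0")
        if self.y_xs1 <= 0 or self.y_xs2 <= 0:
            raise ValueError("yields y_xs1, y_xs2 must be > 0")
        if self.s_m1 <= 0 or self.s_m2 <= 0:
            raise ValueError("inhibition ceilings s_m1, s_m2 must be > 0")

    def with_(self, **kwargs: float) -> "KineticParameters":
        return replace(self, **kwargs)

    def free_names(self, model_type: ModelType) -> Tuple[str, ...]:
        return free_parameter_names(model_type)


_COMMON = (
    "y_xs1", "y_xs2", "mu_max", "k_s1", "k_s2",
    "m_s1", "m_s2", "s_m1", "s_m2", "n3", "n4",
)


def free_parameter_names(model_type: ModelType) -> Tuple[str, ...]:
    """Names of the parameters the given model type actually uses.

    MONOD has 11 free parameters (n1 and n2 are inert), MONOD_SIGMOID 12
    (adds n2) and SIGMOID 13 (adds n1 and n2).
    """
    if model_type is ModelType.MONOD:
        return _COMMON
    if model_type is ModelType.MONOD_SIGMOID:
        return _COMMON + ("n2",)
    if model_type is ModelType.SIGMOID:
        return _COMMON + ("n1", "n2")
    raise ValueError(f"unknown model type {model_type!r}")


@dataclass(frozen=True)
class CultureState:
    """Instantaneous broth state: biomass x (g DW L^-1), sucrose s1,
    potassium nitrate s2 (g L^-1) and broth volume v (L)."""

    x: float
    s1: float
    s2: float
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.s1 < 0 or self.s2 < 0:
            raise ValueError("concentrations must be >= 0")
        if not (self.v > 0):
            raise ValueError("broth volume must be > 0")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.x, self.s1, self.s2, self.v)


@dataclass(frozen=True)
class FeedStrategy:
    """Fed-batch control vector.

    The run starts as a batch in ``v0`` litres, feed flows at ``flow``
    L d^-1 between ``t_feed_start`` and ``t_end`` (the harvest time), and
    the feed bottle holds sucrose at ``feed_s1`` and KNO3 at ``feed_s2``
    g L^-1.
    """

    v0: float
    t_feed_start: float
    t_end: float
    flow: float
    feed_s1: float
    feed_s2: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_feed_start < self.t_end):
            raise ValueError("need 0 <= t_feed_start < t_end")
        if self.flow < 0:
            raise ValueError("flow must be >= 0")
        if not (self.v0 > 0):
            raise ValueError("v0 must be > 0")
        if self.feed_s1 < 0 or self.feed_s2 < 0:
            raise ValueError("feed concentrations must be >= 0")

    def flow_at(self, t: float) -> float:
        return self.flow if self.t_feed_start <= t <= self.t_end else 0.0


def luong_factor(s: float, s_m: float, n: float) -> float:
    """Luong-type substrate-inhibition factor, 1 - (s/s_m)**n on [0, 1].

    Equal to 1 with no substrate, falls to 0 at the ceiling s_m, and is
    clamped to exactly 0 for s >= s_m (growth fully inhibited past the
    ceiling; keeps fed-batch overshoot well-defined).
    """
    if s < 0:
        raise ValueError(f"substrate concentration s={s} must be >= 0")
    if not (s_m > 0):
        raise ValueError(f"inhibition ceiling s_m={s_m} must be > 0")
    if n < 0:
        raise ValueError(f"exponent n={n} must be >= 0")
    if s >= s_m:
        return 0.0
    f = 1.0 - (s / s_m) ** n
    return 0.0 if f < 0.0 else (1.0 if f > 1.0 else f)


def monod_limitation(s: float, k: float) -> float:
    if s <= 0.0:
        return 0.0
    return s / (s + k)


def sigmoid_limitation(s: float, k: float, n: float) -> float:
    if s <= 0.0:
        return 0.0
    sn = s ** n
    return sn / (sn + k ** n)


def specific_growth_rate(
    p: KineticParameters, model_type: ModelType, s1: float, s2: float
) -> float:
    """Specific growth rate mu (d^-1) at substrate levels (s1, s2).

    Product of the two limitation terms (Monod or sigmoid per model type)
    and the two Luong inhibition factors, scaled by mu_max. Always in
    [0, mu_max]; zero whenever either substrate is absent or at/above its
    inhibition ceiling.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("substrate concentrations must be >= 0")
    if model_type is ModelType.MONOD:
        lim1 = monod_limitation(s1, p.k_s1)
        lim2 = monod_limitation(s2, p.k_s2)
    elif model_type is ModelType.MONOD_SIGMOID:
        lim1 = monod_limitation(s1, p.k_s1)
        lim2 = sigmoid_limitation(s2, p.k_s2, p.n2)
    elif model_type is ModelType.SIGMOID:
        lim1 = sigmoid_limitation(s1, p.k_s1, p.n1)
        lim2 = sigmoid_limitation(s2, p.k_s2, p.n2)
    else:
        raise ValueError(f"unknown model type {model_type!r}")
    return (
        p.mu_max
        * lim1
        * lim2
        * luong_factor(s1, p.s_m1, p.n3)
        * luong_factor(s2, p.s_m2, p.n4)
    )


def uptake_rates(
    p: KineticParameters, mu: float, x: float
) -> Tuple[float, float]:
    """Volumetric substrate consumption rates (ds1/dt, ds2/dt), g L^-1 d^-1.

    dS/dt = -(mu / Y_X/S + m_S) * X for each substrate: growth-coupled
    consumption plus growth-independent maintenance. Both are <= 0.
    """
    if mu < 0 or x < 0:
        raise ValueError("mu and x must be >= 0")
    ds1 = -(mu / p.y_xs1 + p.m_s1) * x
    ds2 = -(mu / p.y_xs2 + p.m_s2) * x
    return ds1, ds2


def batch_rhs(
    p: KineticParameters, model_type: ModelType, state: CultureState
) -> Tuple[float, float, float, float]:
    """Batch vector field (dx/dt, ds1/dt, ds2/dt, dv/dt = 0).

    dX/dt = mu X; substrate uptake per `uptake_rates`, with consumption
    switched off once a substrate is depleted (non-negativity guard).
    """
    x, s1, s2 = state.x, state.s1, state.s2
    mu = specific_growth_rate(p, model_type, s1, s2)
    ds1, ds2 = uptake_rates(p, mu, x)
    if s1 <= 0.0:
        ds1 = 0.0
    if s2 <= 0.0:
        ds2 = 0.0
    return (mu * x, ds1, ds2, 0.0)


def fedbatch_rhs(
    p: KineticParameters,
    model_type: ModelType,
    state: CultureState,
    feed: FeedStrategy,
    t: float,
) -> Tuple[float, float, float, float]:
    """Fed-batch vector field with dilution rate D = F/V.

    Inside the feed window:
        dX/dt  = mu X - D X
        dS/dt  = -(mu/Y + m) X + D (S0 - S)
        dV/dt  = F
    Outside the window F = 0 and the field coincides with `batch_rhs`.
    """
    if not (state.v > 0):
        raise ValueError(f"broth volume must be > 0, got {state.v}")
    flow = feed.flow_at(t)
    dx, ds1, ds2, _ = batch_rhs(p, model_type, state)
    if flow == 0.0:
        return (dx, ds1, ds2, 0.0)
    d = flow / state.v
    return (
        dx - d * state.x,
        ds1 + d * (feed.feed_s1 - state.s1),
        ds2 + d * (feed.feed_s2 - state.s2),
        flow,
    )


# Published batch-fit parameter sets for the Viola odorata cell suspension
# (one row per model type), and the optimized batch starting medium:
# inoculum 7 g DW L^-1, sucrose 45.6 g L^-1, KNO3 2.1 g L^-1.
BATCH_FIT_MONOD = KineticParameters(
    y_xs1=0.51, y_xs2=7.86, mu_max=0.40, k_s1=29.93, k_s2=0.17,
    m_s1=5.08e-2, m_s2=1.95e-5, s_m1=85.93, s_m2=3.67, n3=3.68, n4=2.16,
)
BATCH_FIT_MONOD_SIGMOID = KineticParameters(
    y_xs1=0.50, y_xs2=7.71, mu_max=0.37, k_s1=14.16, k_s2=0.17,
    m_s1=0.06, m_s2=2.88e-4, s_m1=179.24, s_m2=16.14,
    n2=2.74, n3=0.60, n4=1.07,
)
BATCH_FIT_SIGMOID = KineticParameters(
    y_xs1=0.47, y_xs2=7.76, mu_max=0.37, k_s1=13.51, k_s2=0.01,
    m_s1=0.04, m_s2=2.34e-5, s_m1=155.00, s_m2=18.85,
    n1=4.07, n2=1.64, n3=0.37, n4=1.75,
)

OPTIMIZED_BATCH_INITIAL_STATE = CultureState(x=7.0, s1=45.6, s2=2.1, v=1.2)
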