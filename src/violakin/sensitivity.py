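"""Local parameter sensitivity of a model response by finite differences.

Absolute parameter sensitivity (APS) approximates df/dP by a central
difference; relative parameter sensitivity (RPS) is the dimensionless
elasticity (P/f) df/dP, which is invariant to the units of the response
and is used to rank parameters by influence.

The default response is the simulated batch biomass concentration at a
reference time (end of the batch, day 20).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List

from .kinetics import (
    CultureState,
    KineticParameters,
    ModelType,
    free_parameter_names,
)
from .simulate import simulate_batch

__all__ = [
    "SensitivityRecord",
    "absolute_sensitivity",
    "relative_sensitivity",
    "sensitivity_table",
    "biomass_response",
]


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    value: float
    aps: float
    rps: float
    rank: int = 0


def absolute_sensitivity(
    response: Callable[[KineticParameters], float],
    p: KineticParameters,
    name: str,
    rel_step: float = 0.01,
    *,
    abs_step: float = 0.0,
) -> float:
    """Central-difference df/dP for one parameter.

    The step is ``rel_step`` times the parameter value; for a parameter
    at zero an explicit ``abs_step`` must be supplied.
    """
    value = getattr(p, name)
    h = rel_step * value if value != 0 else abs_step
    if h == 0:
        raise ValueError(
            f"parameter {name} is 0; supply abs_step for the perturbation")
    try:
        f_plus = response(replace(p, **{name: value + h}))
        if value - h >= 0.0:
            f_minus = response(replace(p, **{name: value - h}))
            return (f_plus - f_minus) / (2.0 * h)
        # parameter pinned at the non-negativity boundary: one-sided step
        f_0 = response(p)
    except Exception as exc:
        raise RuntimeError(
            f"response evaluation failed while perturbing {name}: {exc}"
        ) from exc
    return (f_plus - f_0) / h


def relative_sensitivity(aps: float, p_value: float, f_value: float) -> float:
    """Elasticity (P/f) df/dP; dimensionless."""
    if f_value == 0:
        raise ValueError("response value is zero; RPS undefined")
    return p_value * aps / f_value


def biomass_response(
    model_type: ModelType,
    init: CultureState,
    t_ref: float = 20.0,
    dt: float = 0.01,
) -> Callable[[KineticParameters], float]:
    """Response functional: batch biomass concentration at t_ref."""

    def response(p: KineticParameters) -> float:
        traj = simulate_batch(p, model_type, init, t_ref, dt,
                              t_eval=[t_ref])
        return float(traj.biomass[-1])

    return response


def sensitivity_table(
    p: KineticParameters,
    model_type: ModelType,
    init: CultureState,
    t_ref: float = 20.0,
    rel_step: float = 0.01,
    dt: float = 0.01,
) -> List[SensitivityRecord]:
    """APS/RPS for every free parameter, ranked by |RPS| descending."""
    response = biomass_response(model_type, init, t_ref, dt)
    f0 = response(p)
    records = []
    for name in free_parameter_names(model_type):
        value = getattr(p, name)
        aps = absolute_sensitivity(response, p, name, rel_step,
                                   abs_step=rel_step if value == 0 else 0.0)
        rps = relative_sensitivity(aps, value, f0) if f0 != 0 else 0.0
        records.append(SensitivityRecord(name, value, aps, rps))
    records.sort(key=lambda r: abs(r.rps), reverse=True)
    return [replace(r, rank=i + 1) for i, r in enumerate(records)]
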