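"""F-test discrimination between rival fitted kinetic models.

Two procedures select among models fitted to the same time-course data:

* variance ratio: F = sigma^2_L / sigma^2_S, the larger model variance
  (SSE / (n - p)) over the smaller; the variances are statistically
  indistinguishable when F is below the upper-alpha F quantile, in which
  case the model with fewer parameters is preferred.
* nested SSE: F = ((SSE_A - SSE_B) / (p2 - p1)) / (SSE_B / (n - p2)) for
  a smaller model A inside a larger model B; the extra parameters are not
  justified when F is below the critical value.

A third screen rejects a fit whose estimated inhibition ceilings deviate
too far from the experimentally observed complete-inhibition
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Tuple

from scipy.stats import f as f_dist

__all__ = [
    "FitSummary",
    "DiscriminationResult",
    "ScreenResult",
    "model_variance",
    "critical_f",
    "f_test_variance",
    "f_test_nested",
    "screen_inhibition_ceiling",
]


class FitSummary(NamedTuple):
    """Minimal view of a fit for discrimination: SSE, data-point and
    parameter counts, and a label. Any FitResult-like object with
    .objective/.n/.p attributes is accepted where a FitSummary is."""

    objective: float
    n: int
    p: int
    label: str = ""


@dataclass(frozen=True)
class DiscriminationResult:
    method: str  # "variance-ratio" | "nested-SSE"
    f_statistic: float
    df: Tuple[int, int]
    critical_value: float
    alpha: float
    preferred_model: str
    decision_rule_text: str


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reasons: Tuple[str, ...]


def model_variance(sse: float, n: int, p: int) -> float:
    """Residual variance SSE / (n - p)."""
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    return sse / (n - p)


def critical_f(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return float(f_dist.ppf(1.0 - alpha, df1, df2))


def _label(fit, fallback: str) -> str:
    lab = getattr(fit, "label", "")
    if lab:
        return lab
    mt = getattr(fit, "model_type", None)
    return getattr(mt, "value", None) or fallback


def f_test_variance(fit_a, fit_b, alpha: float = 0.05) -> DiscriminationResult:
    """Variance-ratio F test between two fits of the same data.

    Symmetric in argument order: the larger variance always goes in the
    numerator (so F >= 1), with the numerator degrees of freedom taken
    from the larger-variance model. Unrounded variances feed the ratio.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("both fits must use the same data (equal n)")
    va = model_variance(fit_a.objective, fit_a.n, fit_a.p)
    vb = model_variance(fit_b.objective, fit_b.n, fit_b.p)
    la, lb = _label(fit_a, "model A"), _label(fit_b, "model B")
    if va >= vb:
        v_l, v_s = va, vb
        df = (fit_a.n - fit_a.p, fit_b.n - fit_b.p)
        large, small = (la, fit_a.p), (lb, fit_b.p)
    else:
        v_l, v_s = vb, va
        df = (fit_b.n - fit_b.p, fit_a.n - fit_a.p)
        large, small = (lb, fit_b.p), (la, fit_a.p)
    if v_s == 0.0:
        raise ValueError("smaller variance is zero; F ratio undefined")
    f_stat = v_l / v_s
    crit = critical_f(alpha, *df)
    if f_stat < crit:
        # indistinguishable variances: prefer the more parsimonious model
        preferred = min((small, large), key=lambda m: m[1])[0]
        rule = (
            f"F = {f_stat:.3f} < F_crit = {crit:.3f}: variances are "
            f"indistinguishable at alpha={alpha}; prefer the model with "
            f"fewer parameters ({preferred})."
        )
    else:
        preferred = small[0]
        rule = (
            f"F = {f_stat:.3f} >= F_crit = {crit:.3f}: the "
            f"smaller-variance model ({preferred}) fits significantly "
            f"better at alpha={alpha}."
        )
    return DiscriminationResult(
        method="variance-ratio",
        f_statistic=f_stat,
        df=df,
        critical_value=crit,
        alpha=alpha,
        preferred_model=preferred,
        decision_rule_text=rule,
    )


def f_test_nested(
    sse_a: float,
    sse_b: float,
    p1: int,
    p2: int,
    n: int,
    alpha: float = 0.05,
    *,
    label_a: str = "smaller model",
    label_b: str = "larger model",
) -> DiscriminationResult:
    """Nested-SSE F test: does the extra parameter of model B pay off?

    Model A (p1 parameters) is nested in model B (p2 > p1). The statistic
    compares the SSE drop per extra parameter against model B's residual
    variance, on (p2 - p1, n - p2) degrees of freedom.
    """
    if p2 <= p1:
        raise ValueError("need p2 > p1")
    if n <= p2:
        raise ValueError("need n > p2")
    if sse_a < 0 or sse_b < 0:
        raise ValueError("SSE values must be >= 0")
    if sse_b == 0:
        raise ValueError("sse_b is zero; F ratio undefined")
    df = (p2 - p1, n - p2)
    f_stat = ((sse_a - sse_b) / df[0]) / (sse_b / df[1])
    crit = critical_f(alpha, *df)
    if f_stat < crit:
        preferred = label_a
        rule = (
            f"F = {f_stat:.3f} < F_crit = {crit:.3f}: the extra "
            f"parameter(s) are not justified at alpha={alpha}; prefer "
            f"{label_a}."
        )
    else:
        preferred = label_b
        rule = (
            f"F = {f_stat:.3f} >= F_crit = {crit:.3f}: the richer model "
            f"({label_b}) is significantly better at alpha={alpha}."
        )
    return DiscriminationResult(
        method="nested-SSE",
        f_statistic=f_stat,
        df=df,
        critical_value=crit,
        alpha=alpha,
        preferred_model=preferred,
        decision_rule_text=rule,
    )


def screen_inhibition_ceiling(
    fit,
    observed_sm1: float,
    observed_sm2: float,
    rel_tol: float = 0.3,
) -> ScreenResult:
    """Plausibility screen on the fitted inhibition ceilings.

    Fails when a fitted ceiling deviates from the experimentally observed
    complete-inhibition concentration by more than ``rel_tol`` relative
    (e.g. a fitted sucrose ceiling of 85.93 g L^-1 against an observed
    140 g L^-1 fails at the default 30%).
    """
    if observed_sm1 <= 0 or observed_sm2 <= 0:
        raise ValueError("observed ceilings must be > 0")
    params = getattr(fit, "params", fit)
    reasons: List[str] = []
    for name, fitted, observed in (
        ("s_m1", params.s_m1, observed_sm1),
        ("s_m2", params.s_m2, observed_sm2),
    ):
        dev = abs(fitted - observed) / observed
        if dev > rel_tol:
            reasons.append(
                f"{name}: fitted {fitted:g} deviates {dev:.0%} from "
                f"observed {observed:g} (> {rel_tol:.0%})"
            )
    return ScreenResult(passed=not reasons, reasons=tuple(reasons))
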