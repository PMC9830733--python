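"""Probit (Lyman-type) NTCP for grade 2+ radiation pneumonitis, and
benefit-group classification.

The complication probability is driven by a single dose-function metric
(by default fV10, the percent of total lung function receiving >= 10 Gy):

    NTCP = Phi( (fV10 - TD50) / (m * TD50) )

with Phi the standard normal CDF, TD50 the metric value giving 50%
complication probability, and m the (dimensionless) slope.  The published
grade 2+ RP fit used here is fV10, m = 0.53, TD50 = 54.1 (fV10 on the
0-100% scale).  The probit form is the documented model choice; a logistic
alternative with the same midpoint/slope parametrization is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["NTCPParams", "BenefitLabel", "ntcp", "classify_benefit"]


@dataclass(frozen=True)
class NTCPParams:
    """Parameters of the dose-function NTCP model."""

    metric_name: str = "fV10"
    m: float = 0.53
    TD50: float = 54.1
    form: str = "probit"  # "probit" | "logit"

    def __post_init__(self) -> None:
        if self.m <= 0 or self.TD50 <= 0:
            raise ValueError("m and TD50 must be positive")
        if self.form not in ("probit", "logit"):
            raise ValueError(f"unknown NTCP form {self.form!r}")


@dataclass(frozen=True)
class BenefitLabel:
    """Benefit-group assignment of one patient."""

    group: str  # "benefit" | "non_benefit"
    basis: str | None  # functional strategy whose NTCP was lowest


def ntcp(metric_value, params: NTCPParams = NTCPParams()):
    """Complication probability (0-1) at a dose-function metric value.

    Strictly increasing in the metric; ntcp(TD50) = 0.5 exactly.  Accepts
    scalars or arrays.
    """
    value = np.asarray(metric_value, dtype=float)
    if np.any(value < 0):
        raise ValueError("metric value must be non-negative")
    t = (value - params.TD50) / (params.m * params.TD50)
    if params.form == "probit":
        p = norm.cdf(t)
    else:
        p = 1.0 / (1.0 + np.exp(-1.702 * t))  # logistic matched to the probit slope
    return float(p) if np.isscalar(metric_value) else p


def classify_benefit(
    ntcp_by_strategy: dict[str, float],
    functional_strategies: tuple[str, ...] | None = None,
) -> BenefitLabel:
    """Assign the benefit group from per-strategy NTCP values.

    A patient benefits iff the minimum NTCP over the functional strategies
    is strictly below the anatomical-plan NTCP (ties -> non-benefit);
    ``basis`` records the argmin strategy.  The strategy set compared can
    be restricted via ``functional_strategies``.
    """
    if "anatomical" not in ntcp_by_strategy:
        raise ValueError("anatomical strategy NTCP is required")
    if functional_strategies is None:
        functional_strategies = tuple(
            s for s in ntcp_by_strategy if s != "anatomical"
        )
    if not functional_strategies:
        raise ValueError("at least one functional strategy NTCP is required")
    missing = [s for s in functional_strategies if s not in ntcp_by_strategy]
    if missing:
        raise ValueError(f"missing NTCP for strategies {missing}")
    best = min(functional_strategies, key=lambda s: ntcp_by_strategy[s])
    if ntcp_by_strategy[best] < ntcp_by_strategy["anatomical"]:
        return BenefitLabel("benefit", best)
    return BenefitLabel("non_benefit", None)
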