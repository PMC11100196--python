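"""Supply side of the adoption system: GP workforce, income, and the income lookup.

The balancing loop works in three links: contractors determine how many GP
teams are needed (`gps_needed`); headcount dilutes the per-capita contract
income (`per_capita_income`); and income feeds the income-incentive (II)
multiplier through a monotone piecewise-linear lookup (`Lookup`,
`lookup_eval`).  Growth in the contractor stock therefore dampens its own
word-of-mouth driving force whenever the II switch is on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "GPWorkforceParams",
    "Lookup",
    "gps_needed",
    "per_capita_income",
    "lookup_eval",
]


@dataclass(frozen=True)
class Lookup:
    """Monotone piecewise-linear table function.

    System-dynamics style lookup: linear interpolation between knots,
    clamped to the endpoint values outside the knot range.  Knot abscissae
    must be strictly increasing and ordinates non-decreasing, so the
    evaluated function is non-decreasing everywhere.
    """

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        if len(self.x) < 2 or len(self.x) != len(self.y):
            raise ParameterError(
                "lookup needs at least 2 knots and matching x/y lengths; "
                f"got {len(self.x)} x and {len(self.y)} y"
            )
        if not all(np.isfinite(self.x)) or not all(np.isfinite(self.y)):
            raise ParameterError("lookup knots must be finite")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ParameterError("lookup x-knots must be strictly increasing")
        if any(b < a for a, b in zip(self.y, self.y[1:])):
            raise ParameterError("lookup y-knots must be non-decreasing")

    def __call__(self, x: float) -> float:
        # scalar fast path (hot loop of the simulator); endpoint clamping
        xs, ys = self.x, self.y
        if x <= xs[0]:
            return ys[0]
        if x >= xs[-1]:
            return ys[-1]
        i = bisect.bisect_right(xs, x) - 1
        frac = (x - xs[i]) / (xs[i + 1] - xs[i])
        return ys[i] + frac * (ys[i + 1] - ys[i])


def lookup_eval(table: Lookup, x: float) -> float:
    """Evaluate a monotone lookup at ``x`` (clamped linear interpolation)."""
    return table(x)


@dataclass(frozen=True)
class GPWorkforceParams:
    """Workforce and income constants of the supply loop.

    panel_size
        Contracts one GP team serves at nominal capacity (contracts/team).
    gp_adjust_time
        First-order adjustment time of the GP headcount toward the
        headcount needed (years).
    contract_fee
        Annual government subsidy paid into the team income pool per
        signed contract (currency/contract/year).
    gp_floor
        Minimum GP-team headcount kept on staff regardless of demand.
    base_income
        Non-contract annual income per GP team (currency/team/year).
    """

    panel_size: float = 800.0
    gp_adjust_time: float = 2.0
    contract_fee: float = 120.0
    gp_floor: float = 1.0
    base_income: float = 150_000.0

    def __post_init__(self):
        for name in ("panel_size", "gp_adjust_time", "contract_fee", "gp_floor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.base_income) or self.base_income < 0:
            raise ParameterError(
                f"base_income must be finite and >= 0, got {self.base_income}")


def gps_needed(C: float, params) -> float:
    """GP-team headcount needed to serve ``C`` contractors.

    Linear in the contractor stock (one team per ``panel_size`` contracts)
    with a floor so the headcount never drops below ``gp_floor``.
    """
    if C < 0:
        raise DomainError(f"contractor stock must be >= 0, got {C}")
    return max(params.gp_floor, C / params.panel_size)


def per_capita_income(C: float, gp_count: float, idr: float, params) -> float:
    """Annual per-capita income of a GP (currency/year).

    base_income plus the GP's share (the income distribution ratio ``idr``)
    of the contract subsidy pool, divided over the current headcount.
    Strictly decreasing in ``gp_count`` at fixed ``C`` — the dilution link
    of the balancing loop — and increasing in ``idr``.
    """
    if gp_count <= 0:
        raise DomainError(f"gp_count must be > 0, got {gp_count}")
    if C < 0:
        raise DomainError(f"contractor stock must be >= 0, got {C}")
    return params.base_income + params.contract_fee * C * idr / gp_count
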