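"""Parameter and scenario containers for the adoption model.

`Parameters` holds every rate constant, impact weight, lookup table and
structural constant of the extended Bass stock-and-flow system;
`ScenarioConfig` holds the six binary intervention switches (three
demand-side service contents, three supply-side incentives), the income
distribution ratio (IDR) and the intervention start year.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ParameterError
from .supply import GPWorkforceParams, Lookup

__all__ = ["Parameters", "ScenarioConfig", "DEFAULT_II_LOOKUP"]

#: Pre-calibration placeholder for the per-capita-income -> II-impact lookup;
#: a 5-knot monotone saturating curve on the plausible GP income range (CNY/yr).
DEFAULT_II_LOOKUP = Lookup(
    x=(150_000.0, 185_000.0, 215_000.0, 255_000.0, 290_000.0),
    y=(0.05, 0.20, 0.60, 0.95, 1.00),
)


@dataclass(frozen=True)
class Parameters:
    """All model constants.

    Rates and weights are per-year / dimensionless; the population may be a
    headcount or normalized to 1.0 (the model is scale-free in N except for
    workforce bookkeeping, which uses panel_size to convert contracts to
    GP-team headcount).
    """

    # population and diffusion core (default: ~10M young/middle-aged persons,
    # the scale of a Chinese megacity's occupational population)
    population: float = 1.0e7
    mobilization_rate: float = 0.01          # alpha, 1/year
    wom_base_coefficient: float = 0.3        # mu, 1/year
    base_attractiveness: float = 1.0         # beta0, attractiveness with all contents off
    w_hcs: float = 0.1
    w_wdp: float = 0.15
    w_hec: float = 0.15
    # driving force
    gamma_min: float = 1.0                   # "minimum driving force" scale
    drive_base: float = 1.0                  # g0, driving-force term with all incentives off
    w_et: float = 0.1
    w_jtp: float = 0.1
    ii_lookup: Lookup = DEFAULT_II_LOOKUP
    # collaborative distribution
    idr_gp_weight: float = 0.55              # w_delta in (0.5, 1): GP-share asymmetry
    reference_idr: float = 0.5               # IDR at which delta is normalized to 1
    delta_scale: float | None = None         # computed from reference_idr when None
    # workforce / income (supply loop)
    panel_size: float = 800.0
    gp_adjust_time: float = 6.0              # tau, years
    contract_fee: float = 120.0              # currency/contract/year
    gp_floor: float = 50.0
    base_income: float = 150_000.0
    # initial condition, timing, integration
    initial_contract_rate: float = 0.01      # CR0, fraction at year_start
    intervention_start_year: float = 2020.0
    # supply-side incentives (ET/JTP/II and the IDR policy) may be standing
    # policies rather than tied to the service-package launch; None means
    # they share intervention_start_year
    supply_start_year: float | None = None
    year_start: float = 2015.0
    year_end: float = 2030.0
    dt: float = 1.0 / 12.0                   # years per Euler step

    def __post_init__(self):
        self._validate_static()
        if self.delta_scale is None:
            raw = self._delta_raw(self.reference_idr)
            object.__setattr__(self, "delta_scale", 1.0 / raw)
        elif not (np.isfinite(self.delta_scale) and self.delta_scale > 0):
            raise ParameterError(f"delta_scale must be > 0, got {self.delta_scale}")

    def _delta_raw(self, idr: float) -> float:
        w = self.idr_gp_weight
        return w * math.sqrt(idr) + (1.0 - w) * math.sqrt(1.0 - idr)

    def _validate_static(self) -> None:
        def check(cond: bool, msg: str) -> None:
            if not cond:
                raise ParameterError(msg)

        p = self
        check(p.population > 0, f"population must be > 0, got {p.population}")
        check(0.0 <= p.mobilization_rate <= 1.0,
              f"mobilization_rate must be in [0, 1], got {p.mobilization_rate}")
        check(p.wom_base_coefficient >= 0,
              f"wom_base_coefficient must be >= 0, got {p.wom_base_coefficient}")
        for name in ("base_attractiveness", "w_hcs", "w_wdp", "w_hec",
                     "gamma_min", "drive_base", "w_et", "w_jtp"):
            check(getattr(p, name) >= 0, f"{name} must be >= 0, got {getattr(p, name)}")
        check(0.5 < p.idr_gp_weight < 1.0,
              f"idr_gp_weight must be in (0.5, 1.0), got {p.idr_gp_weight}")
        check(0.0 <= p.reference_idr <= 1.0,
              f"reference_idr must be in [0, 1], got {p.reference_idr}")
        check(0.0 <= p.initial_contract_rate < 1.0,
              f"initial_contract_rate must be in [0, 1), got {p.initial_contract_rate}")
        check(p.dt > 0, f"dt must be > 0, got {p.dt}")
        check(p.year_start < p.year_end,
              f"horizon must satisfy start < end, got [{p.year_start}, {p.year_end}]")
        for name in ("panel_size", "gp_adjust_time", "contract_fee", "gp_floor"):
            check(getattr(p, name) > 0, f"{name} must be > 0, got {getattr(p, name)}")
        check(p.base_income >= 0, f"base_income must be >= 0, got {p.base_income}")
        if not isinstance(p.ii_lookup, Lookup):
            raise ParameterError("ii_lookup must be a Lookup instance")

    @property
    def workforce(self) -> GPWorkforceParams:
        """Workforce constants as a standalone view."""
        return GPWorkforceParams(
            panel_size=self.panel_size,
            gp_adjust_time=self.gp_adjust_time,
            contract_fee=self.contract_fee,
            gp_floor=self.gp_floor,
            base_income=self.base_income,
        )

    def replace(self, **changes: Any) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        if changes.get("delta_scale", "unset") is None or (
            "idr_gp_weight" in changes or "reference_idr" in changes
        ) and "delta_scale" not in changes:
            changes.setdefault("delta_scale", None)
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ii_lookup"] = {"x": list(self.ii_lookup.x), "y": list(self.ii_lookup.y)}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        if "ii_lookup" in d and not isinstance(d["ii_lookup"], Lookup):
            table = d["ii_lookup"]
            try:
                d["ii_lookup"] = Lookup(x=tuple(table["x"]), y=tuple(table["y"]))
            except (KeyError, TypeError) as exc:
                raise ParameterError(f"malformed ii_lookup table: {table!r}") from exc
        return cls(**d)


@dataclass(frozen=True)
class ScenarioConfig:
    """One intervention scenario.

    hcs/wdp/hec are the demand-side service-package switches (health-care
    service, work-related disease prevention, health education &
    counseling); et/jtp/ii are the supply-side incentive switches
    (education & training, job-title promotion, income incentives).  idr is
    the GP's share of contract income; None means the reference IDR at
    which the collaborative-distribution multiplier equals 1.
    """

    hcs: int = 0
    wdp: int = 0
    hec: int = 0
    et: int = 0
    jtp: int = 0
    ii: int = 0
    idr: float | None = None
    intervention_start_year: float | None = None

    def __post_init__(self):
        for name in ("hcs", "wdp", "hec", "et", "jtp", "ii"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ParameterError(f"switch {name} must be 0 or 1, got {v!r}")
        if self.idr is not None and not 0.0 <= self.idr <= 1.0:
            raise ParameterError(f"idr must be in [0, 1], got {self.idr}")

    def effective_idr(self, params: Parameters) -> float:
        return params.reference_idr if self.idr is None else self.idr

    def start_year(self, params: Parameters) -> float:
        if self.intervention_start_year is not None:
            return self.intervention_start_year
        return params.intervention_start_year

    def supply_start_year_for(self, params: Parameters) -> float:
        """Activation year of the supply-side incentives and IDR policy."""
        if params.supply_start_year is not None:
            return params.supply_start_year
        return self.start_year(params)

    def replace(self, **changes: Any) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown scenario field(s): {sorted(unknown)}")
        return cls(**d)
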