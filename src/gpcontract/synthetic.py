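"""Synthetic stand-ins for unavailable inputs.

The historical 2015-2023 contract-rate series used for historicity testing
was published only as a figure, without printed values.  This module
generates a pseudo-historical series from the model itself — baseline
dynamics before the intervention year, the GP-service-package scenario
afterwards, mirroring the real introduction of GP building services in
2020 — plus additive Gaussian observation noise on the percent scale.  It
also draws randomized parameter vectors for calibration-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .calibration import _apply, _resolve_free
from .errors import ParameterError
from .model import contract_rate, simulate
from .params import Parameters, ScenarioConfig

__all__ = ["ObservedSeries", "generate_history", "random_parameters",
           "DEFAULT_HISTORY_YEARS", "DEFAULT_NOISE_SD"]

DEFAULT_HISTORY_YEARS = tuple(range(2015, 2024))
#: Observation noise, percentage points: large enough that a historicity
#: pass is informative, small enough that the generated series stays
#: monotone-increasing in expectation.
DEFAULT_NOISE_SD = 1.0


@dataclass(frozen=True)
class ObservedSeries:
    """An observed (or pseudo-observed) annual contract-rate series."""

    years: tuple[float, ...]
    rates: tuple[float, ...]          # percent
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "years", tuple(float(y) for y in self.years))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.years) != len(self.rates):
            raise ParameterError("years and rates must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ParameterError("years must be strictly increasing")
        if any(not 0.0 <= r <= 100.0 for r in self.rates):
            raise ParameterError("rates must be in [0, 100]")

    def __len__(self) -> int:
        return len(self.years)


def generate_history(params: Parameters, years=DEFAULT_HISTORY_YEARS,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     seed: int = 0) -> ObservedSeries:
    """Generate a pseudo-historical annual contract-rate series.

    Annual rates are read from the baseline simulation before the
    intervention start year and from the GP-service-package simulation from
    that year on (the two coincide before the start year by construction),
    then perturbed with independent Gaussian noise of standard deviation
    ``noise_sd`` percentage points, truncated to [0, 100].  Deterministic
    given ``seed``.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    baseline = simulate(params, ScenarioConfig())
    gpsp = simulate(params, ScenarioConfig(hcs=1, wdp=1, hec=1))
    start = params.intervention_start_year
    clean = [contract_rate(baseline if y < start else gpsp, y) for y in years]
    rng = np.random.default_rng(seed)
    noisy = np.clip(np.asarray(clean) + rng.normal(0.0, noise_sd, len(clean)),
                    0.0, 100.0) if noise_sd > 0 else np.asarray(clean)
    return ObservedSeries(
        years=tuple(years), rates=tuple(noisy),
        provenance={"seed": int(seed), "noise_sd": float(noise_sd),
                    "generator": "gpcontract.synthetic.generate_history",
                    "intervention_start_year": float(start)},
    )


def random_parameters(bounds: dict[str, tuple[float, float]], seed: int,
                      base_params: Parameters | None = None) -> Parameters:
    """Draw a random parameter vector, uniform per bounded name.

    Names follow the calibration convention (Parameters field names plus
    ``ii_y<k>`` for lookup knot ordinates); parameters without bounds keep
    their defaults.  Degenerate bounds pin a parameter exactly.
    Deterministic given ``seed``.
    """
    if base_params is None:
        base_params = Parameters()
    names = list(bounds)
    _resolve_free(base_params, names)
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo <= hi)):
        raise ParameterError("bounds must be finite with lower <= upper")
    rng = np.random.default_rng(seed)
    x = lo + rng.uniform(size=len(names)) * (hi - lo)
    params = _apply(base_params, names, x)
    if params is None:
        raise ParameterError(
            "drawn vector failed validation; tighten the bounds "
            f"(names={names})")
    return params
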