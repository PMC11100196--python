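"""Model validation: historicity testing and sensitivity analysis.

Historicity testing compares the simulated contract-rate trajectory with an
observed annual series (MAPE / RMSE against a stated pass threshold);
sensitivity analysis re-simulates under a one-at-a-time parameter sweep and
reports the spread of the horizon-end contract rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import _apply, _resolve_free
from .errors import DomainError, ParameterError
from .model import Trajectory, contract_rate, simulate
from .params import Parameters, ScenarioConfig
from .scenarios import build_catalog
from .synthetic import ObservedSeries

__all__ = ["FitReport", "SensitivityResult", "historicity_test",
           "sensitivity_sweep", "DEFAULT_MAPE_THRESHOLD"]

#: Default historicity pass threshold (mean absolute percentage error, %).
DEFAULT_MAPE_THRESHOLD = 5.0


@dataclass
class FitReport:
    """Fit of a simulated trajectory to an observed series."""

    mape: float                  # percent
    rmse: float                  # percentage points
    residuals: pd.DataFrame      # year, observed, simulated, residual
    threshold_mape: float
    passed: bool
    n_excluded: int = 0          # zero-valued observations excluded from MAPE


def historicity_test(traj: Trajectory, observed: ObservedSeries,
                     threshold_mape: float = DEFAULT_MAPE_THRESHOLD) -> FitReport:
    """Compare simulated contract rates with an observed annual series.

    MAPE = mean(|sim - obs| / obs) * 100 over observations with obs > 0
    (zero observations are excluded with a warning to avoid division by
    zero); RMSE is reported in percentage points over all observations.
    Passes iff MAPE <= ``threshold_mape``.  Metrics are invariant to the
    order of observations.
    """
    if len(observed) == 0:
        raise DomainError("observed series is empty")
    rows = []
    for year, obs in zip(observed.years, observed.rates):
        sim = contract_rate(traj, year)  # raises if outside horizon
        rows.append({"year": year, "observed": obs, "simulated": sim,
                     "residual": sim - obs})
    table = pd.DataFrame(rows)
    nonzero = table["observed"] > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} zero-valued observation(s) excluded from MAPE",
            stacklevel=2)
    if nonzero.any():
        mape = float((table.loc[nonzero, "residual"].abs()
                      / table.loc[nonzero, "observed"]).mean() * 100.0)
    else:
        mape = float("nan")
    rmse = float(np.sqrt((table["residual"] ** 2).mean()))
    passed = bool(mape <= threshold_mape)
    return FitReport(mape=mape, rmse=rmse, residuals=table,
                     threshold_mape=threshold_mape, passed=passed,
                     n_excluded=n_excluded)


@dataclass
class SensitivityResult:
    """One-at-a-time sweep of a single parameter."""

    parameter: str
    table: pd.DataFrame          # value, cr_2030_pct
    spread: float                # max - min, percentage points
    trajectories: dict[float, Trajectory]


def sensitivity_sweep(params: Parameters, parameter_name: str, values,
                      scenario: ScenarioConfig | None = None,
                      year: float | None = None) -> SensitivityResult:
    """Re-simulate with one parameter swept over ``values``, all else fixed.

    ``parameter_name`` may be any Parameters field, a lookup knot
    ``ii_y<k>``, or ``"idr"`` to sweep the scenario's income distribution
    ratio (the published sensitivity analysis).  Default scenario is the
    full intervention (all six switches on).
    """
    if scenario is None:
        scenario = build_catalog()["mixed7"]
    if year is None:
        year = params.year_end
    values = [float(v) for v in values]
    if not values:
        raise DomainError("values list must not be empty")
    if parameter_name != "idr":
        _resolve_free(params, [parameter_name])

    rows = []
    trajectories: dict[float, Trajectory] = {}
    for v in values:
        if parameter_name == "idr":
            traj = simulate(params, scenario.replace(idr=v))
        else:
            candidate = _apply(params, [parameter_name], np.array([v]))
            if candidate is None:
                raise ParameterError(
                    f"value {v} for {parameter_name!r} fails validation")
            traj = simulate(candidate, scenario)
        trajectories[v] = traj
        rows.append({"value": v, "cr_2030_pct": contract_rate(traj, year)})
    table = pd.DataFrame(rows)
    spread = float(table["cr_2030_pct"].max() - table["cr_2030_pct"].min())
    return SensitivityResult(parameter=parameter_name, table=table,
                             spread=spread, trajectories=trajectories)
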