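"""Stock-and-flow core of the extended Bass adoption model.

Two stocks partition the occupational population N: potential contractors P
and contractors C (no withdrawals, so C only grows and P + C = N at all
times).  Adoption flows through two channels:

* mobilization (external influence): ``alpha * P``;
* word-of-mouth (internal influence): ``beta * delta * gamma * mu * P * C / N``,

where beta is the demand-side attractiveness of the service package, gamma
the supply-side driving force of the GP teams, delta the collaborative
income-distribution multiplier and mu the baseline word-of-mouth
coefficient.  A third stock, the GP-team headcount, relaxes toward the
headcount needed and closes the supply-side balancing loop through
per-capita income.

Integration is explicit Euler at ``params.dt`` (default one month), the
system-dynamics convention; convergence is checked by dt-halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SimulationError
from .params import Parameters, ScenarioConfig
from .supply import gps_needed, lookup_eval, per_capita_income

__all__ = [
    "ModelState",
    "Trajectory",
    "attractiveness",
    "driving_force",
    "collaborative_effect",
    "adoption_from_mobilization",
    "adoption_from_wom",
    "step",
    "simulate",
    "contract_rate",
]

#: CSV column order for trajectory output.
TRAJECTORY_COLUMNS = [
    "time", "P", "C", "gp_count", "per_capita_income",
    "flow_mobilization", "flow_wom", "beta", "gamma", "delta",
    "contract_rate_pct",
]


@dataclass(frozen=True)
class ModelState:
    """The stocks at one instant."""

    time: float
    potential_contractors: float
    contractors: float
    gp_count: float

    def __post_init__(self):
        if self.potential_contractors < 0 or self.contractors < 0:
            raise DomainError(
                f"stocks must be non-negative at t={self.time}: "
                f"P={self.potential_contractors}, C={self.contractors}"
            )
        if self.gp_count <= 0:
            raise DomainError(f"gp_count must be > 0, got {self.gp_count}")


@dataclass
class Trajectory:
    """Time-indexed record of stocks, flows and multipliers.

    All arrays share the same length; ``contract_rate_pct`` is the
    prevalence 100*C/N, the quantity every scenario output reports.
    """

    time: np.ndarray
    P: np.ndarray
    C: np.ndarray
    gp_count: np.ndarray
    per_capita_income: np.ndarray
    flow_mobilization: np.ndarray
    flow_wom: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    contract_rate_pct: np.ndarray
    population: float
    cap_events: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRAJECTORY_COLUMNS})

    def contract_rate(self, year: float) -> float:
        return contract_rate(self, year)


def _step_gate(time: float, start_year: float) -> bool:
    """Interventions are step functions of calendar time."""
    return time >= start_year - 1e-9


def attractiveness(scenario: ScenarioConfig, params: Parameters,
                   time: float) -> float:
    """Demand-side attractiveness multiplier beta.

    Additive in the three package contents (HCS + WDP + HEC impacts) on top
    of the baseline attractiveness, each content contributing only once the
    intervention year is reached.
    """
    beta = params.base_attractiveness
    if _step_gate(time, scenario.start_year(params)):
        beta += (params.w_hcs * scenario.hcs
                 + params.w_wdp * scenario.wdp
                 + params.w_hec * scenario.hec)
    return beta


def driving_force(scenario: ScenarioConfig, per_capita_income_value: float,
                  params: Parameters, time: float | None = None) -> float:
    """Supply-side driving-force multiplier gamma.

    gamma = gamma_min * (g0 + ET impact + JTP impact + II impact), where the
    II impact is read from the monotone income lookup evaluated at the GPs'
    per-capita income.  ``time=None`` means the incentives are active.
    """
    if per_capita_income_value < 0:
        raise DomainError(
            f"per-capita income must be >= 0, got {per_capita_income_value}")
    inner = params.drive_base
    active = time is None or _step_gate(
        time, scenario.supply_start_year_for(params))
    if active:
        inner += params.w_et * scenario.et + params.w_jtp * scenario.jtp
        if scenario.ii:
            inner += lookup_eval(params.ii_lookup, per_capita_income_value)
    return params.gamma_min * inner


def collaborative_effect(idr: float, params: Parameters) -> float:
    """Collaborative-distribution multiplier delta(IDR).

    Asymmetric concave composite of the GP's and the other team members'
    shares, delta = scale * [w * sqrt(IDR) + (1-w) * sqrt(1-IDR)] with
    w = idr_gp_weight in (0.5, 1).  The unique interior maximum sits at
    w^2/(w^2 + (1-w)^2), between an IDR of 0.5 and 0.7 for w below ~0.604;
    the scale normalizes delta to 1 at the reference IDR so non-IDR
    scenarios are unaffected by the functional form.
    """
    if not 0.0 <= idr <= 1.0:
        raise DomainError(f"idr must be in [0, 1], got {idr}")
    return params.delta_scale * params._delta_raw(idr)


def adoption_from_mobilization(state: ModelState, params: Parameters) -> float:
    """External-influence adoption flow alpha * P (persons/year)."""
    return params.mobilization_rate * state.potential_contractors


def adoption_from_wom(state: ModelState, beta: float, gamma: float,
                      delta: float, params: Parameters) -> float:
    """Word-of-mouth adoption flow beta*delta*gamma*mu*P*C/N (persons/year)."""
    if params.population == 0:
        raise DomainError("population N must be nonzero")
    return (beta * delta * gamma * params.wom_base_coefficient
            * state.potential_contractors * state.contractors
            / params.population)


def _rates(state: ModelState, scenario: ScenarioConfig, params: Parameters
           ) -> dict[str, float]:
    """Multipliers and flows at the current state (no state change)."""
    t = state.time
    active_s = _step_gate(t, scenario.supply_start_year_for(params))
    idr_eff = scenario.effective_idr(params) if active_s else params.reference_idr
    beta = attractiveness(scenario, params, t)
    income = per_capita_income(state.contractors, state.gp_count, idr_eff, params)
    gamma = driving_force(scenario, income, params, time=t)
    delta = collaborative_effect(idr_eff, params)
    flow_mob = adoption_from_mobilization(state, params)
    flow_wom = adoption_from_wom(state, beta, gamma, delta, params)
    return {
        "beta": beta, "gamma": gamma, "delta": delta,
        "per_capita_income": income,
        "flow_mobilization": flow_mob, "flow_wom": flow_wom,
        "flow_total": flow_mob + flow_wom,
    }


def step(state: ModelState, scenario: ScenarioConfig, params: Parameters
         ) -> ModelState:
    """One explicit-Euler step of length ``params.dt``.

    The adoption flow is truncated so the potential pool never goes
    negative (C is capped at N); the GP headcount relaxes toward the
    headcount needed with time constant ``gp_adjust_time``.
    """
    dt = params.dt
    r = _rates(state, scenario, params)
    flow = min(r["flow_total"], state.potential_contractors / dt)
    new_c = min(state.contractors + dt * flow, params.population)
    new_p = max(params.population - new_c, 0.0)
    target = gps_needed(state.contractors, params)
    new_gp = state.gp_count + dt * (target - state.gp_count) / params.gp_adjust_time
    return ModelState(
        time=state.time + dt,
        potential_contractors=new_p,
        contractors=new_c,
        gp_count=new_gp,
    )


def simulate(params: Parameters, scenario: ScenarioConfig) -> Trajectory:
    """Integrate the system over the full horizon.

    Returns the trajectory at ``dt`` resolution, endpoints inclusive, with
    every multiplier recorded.  Deterministic: the model has no stochastic
    terms, so identical inputs give bit-identical trajectories.
    """
    dt = params.dt
    n_steps = int(round((params.year_end - params.year_start) / dt))
    if n_steps < 1:
        raise DomainError("horizon shorter than one integration step")
    n = n_steps + 1
    N = params.population

    time = params.year_start + dt * np.arange(n)
    cap_events: list[float] = []
    rec: dict[str, list[float]] = {name: []
                                   for name in TRAJECTORY_COLUMNS if name != "time"}

    c = params.initial_contract_rate * N
    p = N - c
    gp = max(params.gp_floor, c / params.panel_size)

    start_year = scenario.start_year(params)
    supply_start = scenario.supply_start_year_for(params)
    idr_on = scenario.effective_idr(params)
    delta_on = collaborative_effect(idr_on, params)
    delta_off = collaborative_effect(params.reference_idr, params)
    # hoisted constants (hot loop)
    mu = params.wom_base_coefficient
    alpha = params.mobilization_rate
    beta0 = params.base_attractiveness
    beta_boost = (params.w_hcs * scenario.hcs + params.w_wdp * scenario.wdp
                  + params.w_hec * scenario.hec)
    drive_fixed = (params.w_et * scenario.et + params.w_jtp * scenario.jtp)
    use_ii = bool(scenario.ii)
    lookup = params.ii_lookup
    gamma_min = params.gamma_min
    g0 = params.drive_base
    base_income = params.base_income
    fee = params.contract_fee
    idr_ref = params.reference_idr
    floor, panel = params.gp_floor, params.panel_size
    tau = params.gp_adjust_time
    gate = start_year - 1e-9
    gate_s = supply_start - 1e-9
    isfinite = math.isfinite
    (rec_p, rec_c, rec_gp, rec_inc, rec_fm, rec_fw, rec_beta, rec_gamma,
     rec_delta, rec_cr) = (rec["P"], rec["C"], rec["gp_count"],
                           rec["per_capita_income"], rec["flow_mobilization"],
                           rec["flow_wom"], rec["beta"], rec["gamma"],
                           rec["delta"], rec["contract_rate_pct"])

    t = params.year_start
    for k in range(n):
        beta = beta0 + beta_boost if t >= gate else beta0
        if t >= gate_s:
            delta = delta_on
            income = base_income + fee * c * idr_on / gp
            inner = g0 + drive_fixed
            if use_ii:
                inner += lookup(income)
        else:
            delta = delta_off
            income = base_income + fee * c * idr_ref / gp
            inner = g0
        gamma = gamma_min * inner
        flow_mob = alpha * p
        flow_wom = beta * delta * gamma * mu * p * c / N

        if not (isfinite(flow_mob) and isfinite(flow_wom)):
            raise SimulationError(
                f"non-finite adoption flow at t={t:.4f}", time=float(t))

        rec_p.append(p)
        rec_c.append(c)
        rec_gp.append(gp)
        rec_inc.append(income)
        rec_fm.append(flow_mob)
        rec_fw.append(flow_wom)
        rec_beta.append(beta)
        rec_gamma.append(gamma)
        rec_delta.append(delta)
        rec_cr.append(100.0 * c / N)

        if k < n_steps:
            flow = flow_mob + flow_wom
            if flow * dt > p:
                flow = p / dt
                cap_events.append(float(t))
            need = c / panel
            c = min(c + dt * flow, N)
            p = max(N - c, 0.0)
            gp = gp + dt * ((need if need > floor else floor) - gp) / tau
            t = time[k + 1]

    return Trajectory(time=time, population=N, cap_events=cap_events,
                      **{name: np.asarray(vals) for name, vals in rec.items()})


def contract_rate(traj: Trajectory, year: float) -> float:
    """Prevalence 100*C/N (percent) at the last recorded step with time <= year."""
    eps = 1e-9
    if year < traj.time[0] - eps or year > traj.time[-1] + eps:
        raise DomainError(
            f"year {year} outside simulated horizon "
            f"[{traj.time[0]}, {traj.time[-1]}]")
    idx = int(np.searchsorted(traj.time, year + eps, side="right")) - 1
    idx = max(idx, 0)
    return float(traj.contract_rate_pct[idx])
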