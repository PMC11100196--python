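# Methods

## Model

The package simulates uptake of general-practitioner (GP) contract
services in an occupational (young/middle-aged, 18–59) population as a
two-stock diffusion process with a workforce side-stock:

- **Stocks.** Potential contractors `P` and contractors `C` partition a
  closed population `N` (`P + C = N`); the GP-team headcount `G` is a third
  stock. Contracts are free and withdrawals are not modelled, so `C` is
  non-decreasing.
- **Flows.** Adoption has an external channel, GP-team mobilization
  `α·P`, and an internal word-of-mouth channel
  `β·δ·γ·μ·P·C/N`. This is a Bass diffusion structure in which the
  innovation coefficient is `α` and the imitation coefficient
  `q(t) = β(t)·δ·γ(t)·μ` is modulated by policy:
  - `β` — demand-side attractiveness: a baseline `β₀` plus additive
    impacts of the three service-package contents (health-care service HCS,
    work-related disease prevention WDP, health education & counseling
    HEC), active from the intervention year (2020) onward;
  - `γ` — supply-side driving force: `γ_min·(g₀ + ET + JTP + II)`, where
    education & training (ET) and job-title promotion (JTP) contribute
    constant impacts and income incentives (II) contribute through a
    monotone piecewise-linear lookup on the GPs' per-capita income;
  - `δ` — collaborative-distribution multiplier of the income
    distribution ratio (IDR, the GP's share of contract income), see below;
  - `μ` — constant baseline word-of-mouth coefficient.
- **Supply loop.** Headcount needed is `C/panel_size` (with a floor); `G`
  relaxes toward it with first-order time constant `τ`. Per-capita GP
  income is `base_income + fee·C·IDR/G`. Because `G` lags demand growth,
  income rises above its long-run level during fast diffusion and falls
  back as staffing catches up; through the II lookup this couples adoption
  speed back into the driving force (a reinforcing transient inside the
  balancing staffing loop).

### The δ(IDR) functional form

A literal `δ = IDR` cannot produce an interior optimum of the 2030
contract rate on the IDR policy grid, while the scenario outcomes clearly
have one (maximum at 0.5, with 0.7 ahead of 0.3). We therefore model the
collaborative effect as an asymmetric concave composite of the GP's and
the team's shares,

    δ(IDR) = scale · [w·√IDR + (1 − w)·√(1 − IDR)],   w ∈ (0.5, 1),

normalized (`scale`) so that δ = 1 at the reference IDR (0.5): non-IDR
scenarios are unaffected by the functional form. The maximizer is
`w²/(w² + (1 − w)²)`, which lies in (0.5, 0.7) for `w < ≈0.604` (and
δ(0.5) > δ(0.7) requires `w < ≈0.552`); the calibration bounds keep `w`
in (0.501, 0.545). With √-utilities the ratio
δ(0.5)/δ(0.7) is at most ≈1.022 (attained as w → 0.5), which bounds how
far the 0.5-vs-0.7 contrast can be driven by δ alone — a structural limit
discussed under *Known limitations*.

### Timing and readouts

All six intervention switches and the IDR policy activate as step
functions at the intervention start year (2020 by default; the observed
introduction of GP building services). Before that year the model runs at
baseline attractiveness/driving force and reference IDR. The reported
"contract rate" is always the prevalence `100·C/N` (percent); the
instantaneous adoption flow `α·P + β·δ·γ·μ·P·C/N` is recorded separately
in the trajectory (`flow_mobilization`, `flow_wom`). Scenario tables read
the prevalence at the end of the 2015–2030 horizon.

## Numerics

- **Integration**: explicit Euler with `dt = 1/12` year, the
  system-dynamics convention. The dt-halving check (1/12 → 1/24 changes
  the 2030 rate by < 0.1 pp under the reference calibration) and the two
  closed-form oracles (pure-mobilization exponential; constant-multiplier
  Bass) guard the integrator. Forward-Euler truncation peaks near the
  diffusion inflection at roughly `(p+q)²·dt/8` on the prevalence scale
  (~0.4 pp at Bass rates ≈0.33/yr), so oracle agreement is asserted at
  0.1% relative on horizon readouts and 0.5 pp sup-norm along the
  trajectory.
- **Flow cap**: the adoption flow is truncated so `P` never goes negative;
  cap events are recorded on the trajectory and logged.
- **Degenerate inputs**: `C = 0` silences word-of-mouth; `μ = 0` reduces
  the model to pure exponential mobilization; zero-valued observations are
  excluded from MAPE with a warning.

## Calibration

The exact parameter values behind the published scenario outcomes are not
available, so the model is calibrated by inverse simulation: one
parameter vector must jointly reproduce all printed 2030 outcomes (levels
and differences; `src/gpcontract/data/anchors.yaml`). `calibrate()`
minimizes the weighted sum of squared anchor residuals (percentage
points) with seeded Latin-hypercube screening, bounded least-squares
refinement (numeric Jacobian) and a Nelder–Mead polish; candidate lookup
tables are monotone-repaired (sorted abscissae, running-max ordinates)
rather than rejected, keeping the objective continuous. One-sided anchors
(`ge`/`le`) enter as hinge residuals.

The reference fit frees 19 quantities: `α`, `μ`, the 2015 initial rate
CR₀, the three demand impacts, the two non-income supply impacts, the
five lookup ordinates and four interior abscissae, the δ-weight `w`, and
the staffing time constant `τ`. Structural constants are fixed by
convention: `β₀ = g₀ = γ_min = 1` (their scales are absorbed by `μ` and
the impact weights), N = 10⁷ persons, panel size 800 contracts/team,
contract fee 120 currency units/contract/year, base GP income 150 000/yr,
GP floor 50 teams, horizon 2015–2030, intervention year 2020 (the
supply-side incentives can be given a different activation year through
`supply_start_year`; the reference keeps them at 2020). A
parameter-recovery test (anchors generated from known parameters; `α`,
`μ`, `β₀` recovered within 5%) guards identifiability before the
reference vector is accepted.

The fitted regime is mobilization-led: `α ≈ 0.033`/yr nearly accounts for
the no-intervention trajectory on its own, while the baseline
word-of-mouth coefficient is small (`μ ≈ 0.006`/yr) and the demand-side
contents multiply the word-of-mouth term strongly (attractiveness
impacts ≈ 4–5 each, so the full package raises `β` roughly fifteenfold).
Substantively this reads as: without a package tailored to them, working
adults sign mainly when their GP team recruits them directly, and
peer-to-peer spread is nearly dormant; the package is what switches the
imitation channel on. We probed the complementary regime (strong baseline
word-of-mouth, small `α`) extensively during calibration: it reproduces
the IDR-grid spacings but leaves the all-factor scenario several
percentage points short of its published gain, because the printed
single-combination outcomes then pin the supply impacts too low for any
admissible lookup to make up the difference.

### What the income lookup does

The calibrated lookup is a low plateau (II impact ≈ 0.10) with a sharp
rise at ≈ 206 k to a saturation level (≈ 0.69). Per-capita income under
the reference IDR of 0.5 sits just above the rise once diffusion is under
way, so every income-incentive scenario at IDR ≥ 0.5 operates at the
saturated impact — which is why IDR = 0.5 and IDR = 0.7 run almost in
parallel and the concave δ decides their ordering — while at IDR = 0.3
income stays in the 180–195 k band below the rise, cutting the driving
force by ≈ 0.6 and producing the large published penalty for a low GP
share. The knot positions are calibrated because these income bands
cannot be located a priori.

## Synthetic data

`generate_history` emulates the unpublished 2015–2023 annual contract-rate
statistics: annual prevalence readouts from the baseline model before 2020
and from the service-package scenario from 2020 on (mirroring the real
policy timeline), plus independent Gaussian observation noise, default
SD 1.0 pp, truncated to [0, 100]. The default noise level makes the
historicity demonstration non-trivial without hiding the trend. What the
generator does **not** emulate: reporting artifacts (rounding, revisions),
serially correlated measurement error, demographic drift of the
denominator, and any real shock to uptake (e.g. pandemic years). A passing
historicity test on this series therefore demonstrates internal
consistency of the pipeline and the fitting metric, not real-world
validity.

`random_parameters` draws uniform vectors inside stated bounds for
parameter-recovery experiments.

## Validation procedures

- **Historicity test**: MAPE and RMSE of simulated vs observed annual
  rates; default pass threshold MAPE ≤ 5% (the original analysis asserts
  "good agreement" without a numeric bar; 5% is our documented choice,
  configurable).
- **Sensitivity analysis**: one-at-a-time sweeps; the headline sweep is
  the IDR grid {0.1, 0.3, 0.5, 0.7, 0.9} under the full intervention,
  reported as the 2030 spread in percentage points.

## Design choices where the structure was open

- Demand- and supply-side impacts enter additively inside β and γ
  (matching the published variable table); the baselines β₀ and g₀ are
  additions — without them the no-intervention scenario could not diffuse
  at all.
- μ is a constant coefficient (the published equation calls it "the
  contract rate" while also multiplying by C/N; we read the C/N factor as
  the adopter-contact probability and μ as the per-contact adoption
  coefficient).
- Supply incentives are assumed off in the with-package comparison
  (mixed 7 being the all-on case), and the IDR sweep is run under the
  full intervention.
- The GP share of contract income equals the IDR; the lookup input is
  total income (base + contract share).
- Mixed 1–3 map to WDP/HEC/HCS (all incentives on) and mixed 4–6 to
  ET/JTP/II (all contents on), in that order.

## Known limitations

- The √-composite bounds δ(0.5)/δ(0.7) at ≈ 1.022 (attained as w → 0.5);
  multiplied by the model's top-end sensitivity (≈ 29 pp per unit of
  log-multiplier at the 75% level) this caps the reproducible 0.5-vs-0.7
  contract-rate gap at ≈ 0.6 pp, below the published ~2 pp. The shipped
  calibration has the correct ordering and argmax (0.5 ahead of 0.7,
  0.7 ahead of 0.9 and 0.3) but a 0.61 pp gap; see
  `data/reference_residuals.json`. Raising the gap requires either a more
  sharply peaked collaborative-effect function than the √-composite or an
  income channel that penalizes IDR = 0.7 relative to 0.5, which a
  monotone income lookup cannot do.
- The HEC-with-II level, the HEC-with-all-incentives level (mixed 2) and
  the all-contents-with-II level (mixed 6) share ≈ 1.4 pp of structural
  misfit that reweighting can only redistribute; in the shipped vector
  two of them sit 0.06–0.09 pp outside their anchor tolerances.
- With the default 1.0 pp observation noise and single-digit early
  prevalence, the synthetic-history MAPE is dominated by the earliest
  years (expected ≈ 8%), so the noisy historicity demonstration exceeds
  the 5% default threshold; the zero-noise closure is the meaningful
  pipeline check, and RMSE (≈ 1 pp) the more informative noisy metric.
- Parameter values are a calibrated stand-in for the unavailable original
  parameter table: they are jointly constrained by ~19 anchors but not
  individually identified; interpret magnitudes, not fourth decimals.
- No withdrawals, no demographic change, no GP recruitment pipeline:
  outside 2015–2030 or under churn the model is not meaningful.
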