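#!/usr/bin/env python
"""Produce the shipped reference calibration.

Runs `calibrate()` against the packaged anchor file from a staged initial
guess — the baseline level, the package level and the single-combination
levels are inverted one-dimensionally by bisection, which places the start
inside the mobilization-led regime that can satisfy the whole anchor set —
then polishes with a short deterministic chain of `calibrate()` restarts
from the incumbent optimum. The fitted vector and its residual report are
committed to `src/gpcontract/data/`.

Usage: python scripts/make_reference.py [seed] [maxiter]
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import yaml
from scipy.optimize import brentq

from gpcontract import Parameters
from gpcontract.calibration import calibrate, load_anchors
from gpcontract.model import contract_rate, simulate
from gpcontract.scenarios import build_catalog

DATA = Path(__file__).resolve().parent.parent / "src" / "gpcontract" / "data"

FREE = ["mobilization_rate", "wom_base_coefficient", "initial_contract_rate",
        "w_wdp", "w_hec", "w_hcs", "w_et", "w_jtp",
        "ii_y0", "ii_y1", "ii_y2", "ii_y3", "ii_y4",
        "ii_x1", "ii_x2", "ii_x3", "ii_x4",
        "idr_gp_weight", "gp_adjust_time"]

BOUNDS = {
    "mobilization_rate": (0.025, 0.0355),
    "wom_base_coefficient": (0.0005, 0.05),
    "initial_contract_rate": (0.004, 0.035),
    "w_wdp": (0.0, 10.0), "w_hec": (0.0, 10.0), "w_hcs": (0.0, 10.0),
    "w_et": (0.0, 2.0), "w_jtp": (0.0, 2.0),
    "ii_y0": (0.0, 1.5), "ii_y1": (0.0, 1.5), "ii_y2": (0.0, 2.5),
    "ii_y3": (0.0, 3.0), "ii_y4": (0.0, 3.0),
    "ii_x1": (165e3, 215e3), "ii_x2": (170e3, 225e3),
    "ii_x3": (175e3, 240e3), "ii_x4": (180e3, 260e3),
    "idr_gp_weight": (0.501, 0.545),
    "gp_adjust_time": (0.5, 2.5),
}


def staged_x0(alpha: float = 0.034, cr0: float = 0.02,
              tau: float = 1.0) -> dict[str, float]:
    """Initial guess from one-dimensional inversions of the level anchors."""
    cat = build_catalog()

    def cr(p, name):
        return contract_rate(simulate(p, cat[name]), 2030.0)

    base = Parameters(mobilization_rate=alpha, initial_contract_rate=cr0,
                      gp_adjust_time=tau, idr_gp_weight=0.51,
                      w_hcs=0, w_wdp=0, w_hec=0, w_et=0, w_jtp=0)
    mu = brentq(lambda m: cr(base.replace(wom_base_coefficient=m),
                             "baseline") - 42.3, 1e-6, 3.0, xtol=1e-13)
    p = base.replace(wom_base_coefficient=mu)

    def implied_multiplier(level):
        # post-intervention flow multiplier whose 2030 level matches `level`
        return brentq(lambda m: cr(p.replace(w_wdp=m - 1.0), "wdp_et") - level,
                      1.0, 5000.0, xtol=1e-13)

    a, b, c, d, s = [implied_multiplier(y)
                     for y in (48.3, 52.3, 52.5, 50.4, 57.8)]
    ell = (b + c + d) / (s + 2.0) - 1.0
    w_w = b / (1 + ell) - 1.0
    w_he = c / (1 + ell) - 1.0
    w_hc = d / (1 + ell) - 1.0
    w_et = max(a / (1 + w_w) - 1.0, 1e-4)
    # lookup: low plateau under the IDR=0.3 income band, saturation at the
    # level the idr>=0.5 scenarios occupy
    return {
        "mobilization_rate": alpha, "wom_base_coefficient": mu,
        "initial_contract_rate": cr0,
        "w_wdp": w_w, "w_hec": w_he, "w_hcs": w_hc,
        "w_et": w_et, "w_jtp": w_et,
        "ii_y0": 0.35 * ell, "ii_y1": 0.35 * ell, "ii_y2": 0.7 * ell,
        "ii_y3": ell, "ii_y4": ell + 0.02,
        "ii_x1": 186e3, "ii_x2": 191e3, "ii_x3": 196e3, "ii_x4": 215e3,
        "idr_gp_weight": 0.51, "gp_adjust_time": tau,
    }


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 61
    maxiter = int(sys.argv[2]) if len(sys.argv) > 2 else 2500
    anchors = load_anchors((DATA / "anchors.yaml").read_text())

    def as_x0(params: Parameters) -> dict[str, float]:
        x = {n: getattr(params, n) for n in FREE if not n.startswith("ii_")}
        x |= {f"ii_y{i}": y for i, y in enumerate(params.ii_lookup.y)}
        x |= {f"ii_x{i}": v for i, v in enumerate(params.ii_lookup.x) if i > 0}
        return x

    # deterministic polish chain: each round restarts from the incumbent
    result = calibrate(anchors, FREE, BOUNDS, seed=seed, n_init=80,
                       maxiter=maxiter, x0=staged_x0())
    for round_seed in (seed + 1, seed + 2, seed + 3):
        nxt = calibrate(anchors, FREE, BOUNDS, seed=round_seed, n_init=40,
                        maxiter=maxiter, x0=as_x0(result.params))
        if nxt.objective < result.objective:
            result = nxt

    print(result.residuals.to_string(index=False))
    print(f"objective={result.objective:.4f} feasible={result.feasible} "
          f"evaluations={result.n_evaluations}")

    params_doc = {"parameters": result.params.to_dict()}
    (DATA / "reference_params.yaml").write_text(
        "# Reference calibration produced by scripts/make_reference.py\n"
        f"# seed chain starting at {seed} objective={result.objective:.6f}\n"
        + yaml.safe_dump(params_doc, sort_keys=False))
    report = {
        "seed": seed,
        "objective": result.objective,
        "feasible": result.feasible,
        "n_evaluations": result.n_evaluations,
        "free_parameters": list(result.free),
        "residuals": result.residuals.to_dict(orient="records"),
    }
    (DATA / "reference_residuals.json").write_text(
        json.dumps(report, indent=2) + "\n")
    print(f"wrote {DATA / 'reference_params.yaml'}")


if __name__ == "__main__":
    main()
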