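#!/usr/bin/env python
"""Generalized-Born pair-transfer argument and rotational relaxation oracle.

Inverts the pair/single transfer ratio for the ion-pair spacing, shows the
ratio grows with separation (why a wide zwitterion buries at least as badly
as the bare cation), and validates the τ_r estimator on a rotor ensemble with
known 1/(2·D_r).  Writes results/born_rotation_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from permeate.born import pair_ratio, solve_pair_distance
from permeate.rotation import ensemble_acf, simulate_rotor_ensemble, tau_r

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    out = {}

    r_pair = solve_pair_distance(1.26, 1.80, 1.91)
    out["na_cl_spacing_A"] = r_pair
    print(f"Na+/Cl− transfer ratio 1.26 inverts to r = {r_pair:.2f} Å "
          f"(second solvation-shell minimum)")

    ratios = {r: pair_ratio(1.80, 1.91, r) for r in (float(f"{r_pair:.2f}"), 8.0, 12.0)}
    out["ratio_vs_separation"] = ratios
    print("pair/single ratio grows with separation: "
          + ", ".join(f"{r} Å → {v:.2f}" for r, v in ratios.items()))

    tau_true = 117.0
    u = simulate_rotor_ensemble(1.0 / (2 * tau_true), dt=0.5, n_steps=200_000,
                                n_rotors=16, seed=2015)
    c = ensemble_acf(u, max_lag=4000)
    tau, truncated = tau_r(c, 0.5)
    out["rotor"] = {"tau_true_ps": tau_true, "tau_hat_ps": tau,
                    "rel_error": abs(tau - tau_true) / tau_true,
                    "zero_crossing_found": truncated}
    print(f"rotor ensemble (16 × 100 ns): τ̂_r = {tau:.1f} ps vs 1/(2·D_r) = "
          f"{tau_true} ps ({out['rotor']['rel_error'] * 100:.1f}% off)")

    (ROOT / "born_rotation_summary.json").write_text(
        json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
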