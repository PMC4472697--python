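#!/usr/bin/env python
"""Estimate the PMF and D(z) from the steered fixtures and compare with truth.

Reads results/fixtures/ (run 01_simulate_fixtures.py first), applies the
forward-reverse and BD-FDT estimators with 0.2 Å bins and inverse-variance
run combination, and writes the recovered profiles plus an error summary to
results/.
"""

from pathlib import Path

import numpy as np

from permeate.core import read_profile, write_profile
from permeate.pipeline import analyze_trajectories
from permeate.steer_sim import read_trajectory

BASE = Path(__file__).resolve().parent.parent
ROOT = BASE / "results"
TRAJ = BASE / "scratch" / "fixtures"
DRIFT = (-4.5, 4.5)


def main() -> None:
    fixtures = ROOT / "fixtures"
    if not fixtures.exists() or not TRAJ.exists():
        raise SystemExit("run analysis/01_simulate_fixtures.py first")
    pmf_true = read_profile(fixtures / "true_pmf.tsv", role="pmf")
    diff_true = read_profile(fixtures / "true_diffusion.tsv", role="diffusion")

    slow = [read_trajectory(p) for p in sorted((TRAJ / "slow").glob("*.tsv"))]
    fast = [read_trajectory(p) for p in sorted((TRAJ / "fast").glob("*.tsv"))]

    lines = ["# estimator\tquantity\tmax_abs_err\tunits"]
    for est in ("fr", "bdfdt"):
        pmf, _, _, _ = analyze_trajectories(slow, reference_z=DRIFT[0],
                                            estimator=est)
        write_profile(pmf, ROOT / f"pmf_{est}.tsv")
        m = (pmf.z >= DRIFT[0]) & (pmf.z <= DRIFT[1])
        wt = np.interp(pmf.z[m], pmf_true.z, pmf_true.value) - \
            np.interp(DRIFT[0], pmf_true.z, pmf_true.value)
        err = np.abs(pmf.value[m] - wt).max()
        lines.append(f"{est}\tpmf\t{err:.4f}\tkcal/mol")
        print(f"{est.upper():6s} PMF: max |ŵ − w_true| = {err:.3f} kcal/mol "
              f"over the drift span (mean se {pmf.stderr[m].mean():.3f})")

    _, diff, _, _ = analyze_trajectories(fast, reference_z=DRIFT[0],
                                         estimator="fr")
    write_profile(diff, ROOT / "diffusion_fr.tsv")
    md = (diff.z >= DRIFT[0]) & (diff.z <= DRIFT[1])
    Dt = np.interp(diff.z[md], diff_true.z, diff_true.value)
    rel = (np.abs(diff.value[md] - Dt) / Dt).max()
    lines.append(f"fr\tdiffusion\t{rel:.4f}\trelative")
    print(f"D(z): max relative error = {rel * 100:.1f}% after 9-point smoothing "
          f"(3× true contrast, 20–60 Å²/ns)")

    (ROOT / "profile_recovery_summary.tsv").write_text("\n".join(lines) + "\n")
    print(f"profiles and summary → {ROOT}")


if __name__ == "__main__":
    main()
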