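#!/usr/bin/env python
"""Permeability coefficients through the inhomogeneous solubility-diffusion model.

Computes P for (a) the recovered double-well profiles against the closed-form
P of the true profiles, (b) the bundled one-leaflet small-solute presets at
both temperature variants with half-bilayer doubling, and (c) homogeneous
water-slab references.  Writes results/permeability_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from permeate.core import Profile1D, Thermo, read_profile
from permeate.permeability import homogeneous_p, isd_permeability
from permeate.presets import o2_like_profiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = {}

    # (a) recovery check on the double-well fixture
    pmf = read_profile(ROOT / "pmf_bdfdt.tsv", role="pmf")
    diff = read_profile(ROOT / "diffusion_fr.tsv", role="diffusion")
    pmf_true = read_profile(ROOT / "fixtures" / "true_pmf.tsv", role="pmf")
    diff_true = read_profile(ROOT / "fixtures" / "true_diffusion.tsv",
                             role="diffusion")
    th = Thermo(310.0)
    lo, hi = -4.3, 4.3
    mt = (pmf_true.z >= lo) & (pmf_true.z <= hi)
    P_true = isd_permeability(
        Profile1D(z=pmf_true.z[mt], value=pmf_true.value[mt],
                  stderr=np.zeros(mt.sum()), role="pmf"),
        Profile1D(z=diff_true.z[mt], value=diff_true.value[mt],
                  stderr=np.zeros(mt.sum()), role="diffusion"),
        th, n_resample=0).P
    mw = (pmf.z >= lo) & (pmf.z <= hi)
    md = (diff.z >= lo) & (diff.z <= hi)
    zz, ww = pmf.z[mw], pmf.value[mw]
    ww = ww - ww[np.abs(zz) >= 4.0].mean()
    res = isd_permeability(
        Profile1D(z=zz, value=ww, stderr=pmf.stderr[mw], role="pmf"),
        Profile1D(z=diff.z[md], value=diff.value[md], stderr=diff.stderr[md],
                  role="diffusion"), th, seed=2015)
    out["double_well"] = {"P_true_cm_s": P_true, "P_recovered_cm_s": res.P,
                          "se_cm_s": res.se,
                          "rel_error": abs(res.P - P_true) / P_true}
    print(f"double-well: P_true = {P_true:.2f} cm/s, recovered = "
          f"{res.P:.2f} ± {res.se:.2f} cm/s ({out['double_well']['rel_error']*100:.1f}% off)")

    # (b) one-leaflet presets, half-bilayer doubling
    for variant, T in (("cold", 323.0), ("hot", 350.0)):
        w, D = o2_like_profiles(variant)
        r = isd_permeability(w, D, Thermo(T), half_bilayer=True, n_resample=0)
        out[f"o2_like_{variant}"] = {"T_K": T, "P_cm_s": r.P}
        print(f"small-solute preset ({variant}, {T:.0f} K): P = {r.P:.0f} cm/s")
    print("the deeper hydrophobic well of the cold variant raises P despite "
          "identical headgroup barriers: P decreases with temperature")

    # (c) homogeneous slab references
    out["water_slab_like"] = {"P_cm_s": homogeneous_p(500.0, 60.8)}
    print(f"homogeneous 60.8 Å slab at D = 500 Å²/ns: P = "
          f"{out['water_slab_like']['P_cm_s']:.0f} cm/s")

    (ROOT / "permeability_summary.json").write_text(
        json.dumps(out, indent=2) + "\n")
    print(f"summary → {ROOT / 'permeability_summary.json'}")


if __name__ == "__main__":
    main()
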