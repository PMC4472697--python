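#!/usr/bin/env python
"""Generate the synthetic steered-trajectory fixtures used by the analyses.

Writes two six-run sets over the double-well landscape — a slow pull
(v_d = 0.15 Å/ns) whose work records feed the free-energy estimators and a
faster pull (v_d = 0.8 Å/ns) for the diffusion inversion — plus the analytic
true profiles, under results/fixtures/.
"""

import sys
from pathlib import Path

from permeate.core import Thermo, write_profile
from permeate.presets import (double_well_diffusion_protocol,
                              double_well_profiles, double_well_protocol)
from permeate.steer_sim import SimConfig, default_dt, generate_fixture_set

SEED = 2015
BASE = Path(__file__).resolve().parent.parent
OUT = BASE / "results" / "fixtures"
TRAJ = BASE / "scratch" / "fixtures"      # raw runs are large; kept as scratch


def main(seed: int = SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    thermo = Thermo(310.0)
    pmf_true, diff_true = double_well_profiles()
    write_profile(pmf_true, OUT / "true_pmf.tsv")
    write_profile(diff_true, OUT / "true_diffusion.tsv")

    for tag, proto, s in (("slow", double_well_protocol(), seed),
                          ("fast", double_well_diffusion_protocol(), seed + 1)):
        cfg = SimConfig(thermo=thermo, pmf_true=pmf_true, diff_true=diff_true,
                        dt=default_dt(proto), seed=s, duration=9.0 / proto.v_d)
        trajs = generate_fixture_set(cfg, proto, n_runs=6, base_seed=s,
                                     out_dir=TRAJ / tag)
        steps = sum(len(t.dW) for t in trajs)
        print(f"{tag} pull: v_d = {proto.v_d} Å/ns, v_av = {proto.v_av} Å/ns, "
              f"6 runs × {len(trajs[0].dW)} steps ({steps} total) → {TRAJ / tag}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
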