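"""Shared fixtures: synthetic steered-run sets over the double-well landscape.

The simulations are cheap (~0.2 s per six-run set) but shared session-wide so
every module sees the identical frozen data.
"""

from __future__ import annotations

import numpy as np
import pytest

from permeate.core import Thermo
from permeate.presets import (double_well_diffusion_protocol,
                              double_well_profiles, double_well_protocol)
from permeate.steer_sim import SimConfig, default_dt, generate_fixture_set

FIXTURE_SEED = 2015
DRIFT_RANGE = (-4.5, 4.5)   # span covered by the steady drift (z0 to z0 + v_d·T)


@pytest.fixture(scope="session")
def thermo():
    return Thermo(T=310.0)


@pytest.fixture(scope="session")
def dw_truth():
    """True (w, D) of the double-well landscape."""
    return double_well_profiles()


@pytest.fixture(scope="session")
def dw_trajectories(thermo, dw_truth):
    """Six slow OFR pulls (free-energy fixture), fixed seed."""
    pmf_true, diff_true = dw_truth
    proto = double_well_protocol()
    cfg = SimConfig(thermo=thermo, pmf_true=pmf_true, diff_true=diff_true,
                    dt=default_dt(proto), seed=FIXTURE_SEED,
                    duration=9.0 / proto.v_d)
    return generate_fixture_set(cfg, proto, n_runs=6, base_seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def dw_diffusion_trajectories(thermo, dw_truth):
    """Six faster OFR pulls (diffusion fixture), fixed seed."""
    pmf_true, diff_true = dw_truth
    proto = double_well_diffusion_protocol()
    cfg = SimConfig(thermo=thermo, pmf_true=pmf_true, diff_true=diff_true,
                    dt=default_dt(proto), seed=FIXTURE_SEED + 7,
                    duration=9.0 / proto.v_d)
    return generate_fixture_set(cfg, proto, n_runs=6, base_seed=FIXTURE_SEED + 7)


def true_pmf_on(z, pmf_true, reference_z):
    """True PMF interpolated to z and zeroed at reference_z."""
    w = np.interp(z, pmf_true.z, pmf_true.value)
    return w - np.interp(reference_z, pmf_true.z, pmf_true.value)
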