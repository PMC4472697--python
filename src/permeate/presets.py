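"""Analytic demo profiles and protocols for the synthetic steering engine.

These are smooth stand-ins (sums of Gaussians) that carry only scalar features
of real bilayer systems — barrier heights, well depths, bulk extents, typical
diffusion magnitudes — not digitized curves.  They serve as ground truth for
parameter-recovery tests and as ready-to-run pipeline demos.

* ``double_well`` — a compact two-well/central-barrier landscape with a 3×
  diffusion contrast; the standard recovery fixture.
* ``o2_like`` — one leaflet (bulk extent 30.4 Å, DPPC-like) with a hydrophobic
  central well and a small headgroup barrier; the "hot" variant's well is
  shallower by 2.5 k_B·T at 323 K.
* ``tyramine_like`` — full POPC-like profile (bulk extent 38.4 Å) for an
  uncharged species (6.7 kcal/mol central barrier) and a protonated one
  (21.0 kcal/mol), with bulk diffusion near 0.9×10⁻⁵ and 0.65×10⁻⁵ cm²/s.
"""

from __future__ import annotations

import numpy as np

from .core import KB_KCAL_MOL_K, Profile1D
from .steer_sim import SteeringProtocol, make_protocol

__all__ = [
    "double_well_profiles", "double_well_protocol",
    "o2_like_profiles", "tyramine_like_profiles", "tyramine_like_protocol",
]


def _gauss(z, center, width):
    return np.exp(-(((z - center) / width) ** 2))


def double_well_profiles(dz: float = 0.05) -> tuple[Profile1D, Profile1D]:
    """Two 1.2 kcal/mol wells at ±2 Å flanking a 2 kcal/mol central barrier.

    D(z) dips from 60 to 20 Å²/ns at the center (3× contrast).  Support
    [−8, 8] Å leaves room for the oscillation overshoot of the protocol.
    """
    z = np.arange(-8.0, 8.0 + dz / 2, dz)
    w = (2.0 * _gauss(z, 0.0, 1.0)
         - 1.2 * _gauss(z, -2.0, 1.2)
         - 1.2 * _gauss(z, 2.0, 1.2))
    D = 60.0 - 40.0 * _gauss(z, 0.0, 3.2)
    zeros = np.zeros_like(z)
    return (Profile1D(z=z, value=w, stderr=zeros, role="pmf"),
            Profile1D(z=z, value=D, stderr=zeros, role="diffusion"))


def double_well_protocol() -> SteeringProtocol:
    """Slow OFR pull for free-energy recovery: v_d = 0.15 Å/ns, A = 2.5 Å, n = 50.

    Free-energy accuracy is limited by the accumulated thermal work noise,
    whose per-bin standard deviation grows as √(k_B·T·⟨W_d⟩) ∝ √v_d; pulling
    slowly (total path length, and hence cost, is independent of v_d for an
    OFR sweep) keeps the integrated PMF error small over the 9 Å drift span.
    """
    return make_protocol(z0=-4.5, v_d=0.15, A=2.5, n=50)


def double_well_diffusion_protocol() -> SteeringProtocol:
    """Faster OFR pull for diffusion recovery: v_d = 0.8 Å/ns, A = 2.5 Å, n = 50.

    The dissipation→D(z) inversion needs per-bin ⟨W_d⟩ comfortably above its
    own standard error; at v_av = 80 Å/ns the per-bin dissipation spans
    ~0.16–0.49 kcal/mol over the 20–60 Å²/ns landscape while remaining in the
    linear (below-critical-speed) regime.
    """
    return make_protocol(z0=-4.5, v_d=0.8, A=2.5, n=50)


def o2_like_profiles(variant: str = "cold", dz: float = 0.1) -> tuple[Profile1D, Profile1D]:
    """One-leaflet small-nonpolar-solute profiles, bulk extent 30.4 Å.

    ``variant='cold'`` (323 K-like) has a hydrophobic well 2.5 k_B·T (at
    323 K) deeper than ``variant='hot'`` (350 K-like).
    """
    if variant not in ("cold", "hot"):
        raise ValueError("variant must be 'cold' or 'hot'")
    z = np.arange(0.0, 30.4 + dz / 2, dz)
    well_hot = 1.0                                   # kcal/mol
    well_cold = well_hot + 2.5 * KB_KCAL_MOL_K * 323.0
    depth = well_cold if variant == "cold" else well_hot
    w = -depth * _gauss(z, 0.0, 7.0) + 0.5 * _gauss(z, 20.0, 3.0)
    D = 400.0 + 100.0 * np.tanh((z - 15.0) / 5.0)    # ~300 core → 500 bulk, Å²/ns
    zeros = np.zeros_like(z)
    return (Profile1D(z=z, value=w, stderr=zeros, role="pmf"),
            Profile1D(z=z, value=D, stderr=zeros, role="diffusion"))


def tyramine_like_profiles(species: str = "neutral",
                           dz: float = 0.1) -> tuple[Profile1D, Profile1D]:
    """Full-bilayer weak-base profiles, bulk extent 38.4 Å.

    ``species='neutral'`` has a 6.7 kcal/mol central barrier; ``'protonated'``
    has 21.0 kcal/mol with a deeper interfacial well (headgroup association of
    the charged amine).
    """
    if species not in ("neutral", "protonated"):
        raise ValueError("species must be 'neutral' or 'protonated'")
    z = np.arange(-40.0, 40.0 + dz / 2, dz)
    az = np.abs(z)
    if species == "neutral":
        w = 6.7 * _gauss(z, 0.0, 9.0) - 0.8 * _gauss(az, 16.0, 4.0)
        D = 90.0 - 55.0 * _gauss(az, 12.0, 8.0)
    else:
        w = 21.0 * _gauss(z, 0.0, 8.0) - 1.5 * _gauss(az, 18.0, 4.0)
        D = 65.0 - 35.0 * _gauss(az, 10.0, 9.0)
    zeros = np.zeros_like(z)
    return (Profile1D(z=z, value=w, stderr=zeros, role="pmf"),
            Profile1D(z=z, value=D, stderr=zeros, role="diffusion"))


def tyramine_like_protocol() -> SteeringProtocol:
    """OFR pull across the full bilayer: v_d = 1 Å/ns, A = 2.5 Å, n = 50."""
    return make_protocol(z0=-37.0, v_d=1.0, A=2.5, n=50)
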