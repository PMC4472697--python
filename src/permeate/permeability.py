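"""The inhomogeneous solubility-diffusion (ISD) permeability integral.

The steady-state permeability of a symmetric membrane along its normal z is

    P = [ ∫_0^L dz e^{βw(z)} / D(z) ]⁻¹,

the reciprocal of the integrated local resistivity R(z) = e^{βw(z)}/D(z).
Profiles measured over one leaflet only are handled by doubling the total
resistance before inversion.  Uncertainty is by Monte-Carlo resampling of the
profile points, since the exponential makes first-order propagation
unreliable for barriers of several k_B·T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import A_PER_NS_TO_CM_PER_S, Profile1D, Thermo

__all__ = ["PermeabilityResult", "resistivity_profile", "isd_permeability", "homogeneous_p"]


@dataclass(frozen=True)
class PermeabilityResult:
    P: float            # cm/s
    se: float           # cm/s
    L: float            # integration width, Å
    half_bilayer: bool
    resistance: float   # total resistance, s/cm

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("permeability must be positive")


def resistivity_profile(w: Profile1D, D: Profile1D, thermo: Thermo) -> Profile1D:
    """Local resistivity R(z) = e^{βw(z)}/D(z) on the PMF's grid.

    D is linearly interpolated onto w's grid when the grids differ.  First-order
    uncertainty combines both inputs: (σ_R/R)² = (β·σ_w)² + (σ_D/D)².
    """
    if w.role != "pmf":
        raise ValueError("first profile must be a pmf")
    if D.role != "diffusion":
        raise ValueError("second profile must be a diffusion profile")
    if len(D) != len(w) or not np.allclose(D.z, w.z):
        # evaluate on the common support: trim w to D's range, interpolate D
        inside = (w.z >= D.z[0] - 1e-9) & (w.z <= D.z[-1] + 1e-9)
        if inside.sum() < 2:
            raise ValueError("profiles share fewer than 2 grid points of support")
        if not inside.all():
            w = Profile1D(z=w.z[inside], value=w.value[inside],
                          stderr=w.stderr[inside], role="pmf")
        D = D.interp_to(w.z)
    if np.any(D.value <= 0):
        raise ValueError("diffusion profile must be positive everywhere")
    beta = thermo.beta
    R = np.exp(beta * w.value) / D.value
    rel = np.sqrt((beta * w.stderr) ** 2 + (D.stderr / D.value) ** 2)
    return Profile1D(z=w.z.copy(), value=R, stderr=R * rel, role="resistivity")


def _trapz_resistance(z: np.ndarray, R: np.ndarray) -> float:
    return float(np.trapezoid(R, z))


def isd_permeability(w: Profile1D, D: Profile1D, thermo: Thermo,
                     half_bilayer: bool = False, n_resample: int = 10_000,
                     seed: int = 2015) -> PermeabilityResult:
    """Trapezoidal ISD permeability with Monte-Carlo uncertainty.

    Parameters
    ----------
    w, D : Profile1D
        PMF (referenced to 0 in bulk) and diffusion profile on a shared
        support; D is interpolated to w's grid if needed.
    half_bilayer : bool
        If True the profiles cover one leaflet and the total resistance is
        doubled before inversion.
    n_resample : int
        Gaussian resampling draws for the uncertainty (0 disables).
    """
    if len(w) < 2:
        raise ValueError("need at least 2 grid points to integrate")
    Rprof = resistivity_profile(w, D, thermo)
    if len(Rprof) != len(w) or not np.allclose(Rprof.z, w.z):
        w = w.interp_to(Rprof.z)          # w was trimmed to the common support
    Dg = D if (len(D) == len(w) and np.allclose(D.z, w.z)) else D.interp_to(w.z)
    res_native = _trapz_resistance(Rprof.z, Rprof.value)  # ns/Å
    factor = 2.0 if half_bilayer else 1.0
    P_native = 1.0 / (factor * res_native)                # Å/ns
    P = P_native * A_PER_NS_TO_CM_PER_S

    se = 0.0
    if n_resample:
        rng = np.random.default_rng(seed)
        wv = w.value + rng.normal(size=(n_resample, len(w))) * w.stderr
        Dv = Dg.value + rng.normal(size=(n_resample, len(w))) * Dg.stderr
        Dv = np.maximum(Dv, 1e-12)  # resampled D must stay positive
        Rv = np.exp(thermo.beta * wv) / Dv
        res_draws = np.trapezoid(Rv, w.z, axis=1) * factor
        P_draws = A_PER_NS_TO_CM_PER_S / res_draws
        se = float(np.std(P_draws))
    return PermeabilityResult(P=P, se=se, L=float(w.z[-1] - w.z[0]),
                              half_bilayer=half_bilayer, resistance=1.0 / P)


def homogeneous_p(D: float, L: float) -> float:
    """Permeability D/L of a homogeneous slab (D in Å²/ns, L in Å) in cm/s."""
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    return D / L * A_PER_NS_TO_CM_PER_S
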