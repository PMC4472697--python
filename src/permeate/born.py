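"""Generalized Born continuum-electrostatics transfer free energies.

For n charges moved from a medium of dielectric ε_w into one of dielectric ε_b,

    ΔG = ½·(1/ε_b − 1/ε_w)·( Σ_i q_i²/a_i + Σ_i Σ_{j≠i} q_i·q_j/r_ij ),

with Born radii a_i and pair separations r_ij.  For a ±q pair relative to the
single positive charge this reduces to the radius-and-spacing ratio

    ΔG_{+/−}/ΔG_+ = (a₊ + a₋)/a₋ − 2·a₊/r_{+/−},

which can be inverted for the mean interatomic spacing given a simulated or
measured ratio.  The ratio grows monotonically with r: screening between the
pair weakens as they separate, so a wider dipole costs more to bury.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["COULOMB_KCAL_A_MOL_E2", "BornChargeSet", "born_transfer_dG",
           "pair_ratio", "solve_pair_distance"]

#: Coulomb constant in kcal·Å/(mol·e²) — converts q²/r in (e²/Å) to kcal/mol.
COULOMB_KCAL_A_MOL_E2 = 332.0636


@dataclass
class BornChargeSet:
    """Charges (e), Born radii (Å), pair distances (Å) and the two dielectrics."""

    q: np.ndarray
    a: np.ndarray
    r: np.ndarray        # symmetric matrix; diagonal unused
    eps_w: float
    eps_b: float

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        n = self.q.size
        if self.a.size != n or self.r.shape != (n, n):
            raise ValueError("q, a must have length n and r must be n×n")
        if np.any(self.a <= 0):
            raise ValueError("Born radii must be positive")
        off = ~np.eye(n, dtype=bool)
        if n > 1 and np.any(self.r[off] <= 0):
            raise ValueError("pair distances must be positive")
        if self.eps_w < 1 or self.eps_b < 1:
            raise ValueError("dielectric constants must be >= 1")


def born_transfer_dG(charge_set: BornChargeSet,
                     coulomb: float = COULOMB_KCAL_A_MOL_E2) -> float:
    """Transfer free energy of the charge set between the two dielectrics.

    Returned in kcal/mol with the default Coulomb constant; pass ``coulomb=1``
    for the raw e²/Å scale (only ratios are dielectric-independent).
    """
    cs = charge_set
    prefactor = 0.5 * (1.0 / cs.eps_b - 1.0 / cs.eps_w)
    self_term = float(np.sum(cs.q ** 2 / cs.a))
    n = cs.q.size
    cross = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                cross += cs.q[i] * cs.q[j] / cs.r[i, j]
    return coulomb * prefactor * (self_term + cross)


def pair_ratio(a_plus: float, a_minus: float, r: float) -> float:
    """ΔG_{+/−}/ΔG_+ = (a₊ + a₋)/a₋ − 2·a₊/r for an equal-and-opposite pair."""
    if a_plus <= 0 or a_minus <= 0 or r <= 0:
        raise ValueError("radii and spacing must be positive")
    return (a_plus + a_minus) / a_minus - 2.0 * a_plus / r


def solve_pair_distance(ratio: float, a_plus: float, a_minus: float) -> float:
    """Invert the pair-to-single transfer ratio for the interatomic spacing.

    r = 2·a₊ / ((a₊ + a₋)/a₋ − ratio); a finite positive solution requires
    ratio < (a₊ + a₋)/a₋ (the r → ∞ limit of the ratio).
    """
    if a_plus <= 0 or a_minus <= 0:
        raise ValueError("radii must be positive")
    limit = (a_plus + a_minus) / a_minus
    denom = limit - ratio
    if denom <= 0:
        raise ValueError(f"no finite positive spacing: ratio must be < {limit:.6g}")
    return 2.0 * a_plus / denom
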