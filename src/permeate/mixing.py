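"""Multi-protonation-state permeability mixing.

A weak base (here the trace amine p-tyramine) crosses a bilayer as a mixture
of protonation states whose bulk populations follow Henderson-Hasselbalch.
Three approximations bracket the physics of interconversion during passage:

* slow interconversion — bulk populations are frozen; permeabilities add with
  their bulk fractions, P_slow = Σ f_i·P_i;
* fast interconversion — local equilibrium everywhere; the species act as
  resistors in parallel at every z, 1/P_fast = ∫ dz [Σ f_i e^{−βw_i(z)}·D_i(z)]⁻¹;
* minimum-resistance approximation (MRA) — at every z the species with the
  lower local resistivity (after offsetting each PMF by its bulk population
  penalty Δw(0) = 2.3·k_B·T·(pKa − pH)) carries the flux.

Because the uncharged species' bulk fraction enters exponentially while its
barrier is tens of k_B·T lower than the charged species', all three collapse
to nearly the same value in the tyramine regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

from .core import A_PER_NS_TO_CM_PER_S, Profile1D, Thermo
from .permeability import isd_permeability

__all__ = [
    "SpeciesState",
    "MixingSpec",
    "hh_fraction",
    "pmf_offset",
    "p_slow",
    "p_fast",
    "p_mra",
    "pka_sweep",
    "crossing_pka",
    "zwitterion_surface",
    "area_corrected_p",
]

_FRACTION_TOL = 1e-9


@dataclass
class SpeciesState:
    """One protonation state: bulk fraction plus either a permeability or profiles.

    ``offset`` is the bulk PMF offset Δw(0) in kcal/mol applied when comparing
    this species' profile against others (0 for the reference species).
    """

    label: str
    fraction: float
    P: float | None = None            # cm/s
    w: Profile1D | None = None
    D: Profile1D | None = None
    offset: float = 0.0

    def has_profiles(self) -> bool:
        return self.w is not None and self.D is not None

    def permeability(self, thermo: Thermo, half_bilayer: bool = False) -> float:
        """Species-own ISD permeability (cm/s), from P or from its profiles."""
        if self.P is not None:
            return self.P
        if not self.has_profiles():
            raise ValueError(f"species {self.label!r} supplies neither P nor (w, D)")
        return isd_permeability(self.w, self.D, thermo, half_bilayer=half_bilayer,
                                n_resample=0).P


@dataclass
class MixingSpec:
    """Species table plus the acid-base and experimental context for sweeps."""

    species: list
    pH: float
    thermo: Thermo
    pKa: float | None = None
    pKa1: float | None = None
    f_zw: float | None = None
    P_exp: float | None = None       # cm/s
    half_bilayer: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.pH < 14):
            raise ValueError("pH must lie in (0, 14)")
        if self.f_zw is not None and not (0 <= self.f_zw <= 1):
            raise ValueError("f_zw must lie in [0, 1]")


def _check_fractions(species) -> None:
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ValueError(f"species fractions must sum to 1, got {total!r}")


def hh_fraction(pKa: float, pH: float) -> float:
    """Henderson-Hasselbalch deprotonated fraction 1/(1 + 10^(pKa − pH))."""
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def pmf_offset(pKa: float, pH: float, thermo: Thermo) -> float:
    """Bulk PMF offset Δw(0) = 2.3·k_B·T·(pKa − pH) in kcal/mol.

    The free-energy penalty for a molecule to be found in the minority
    (deprotonated) state in bulk solution.
    """
    return 2.3 * thermo.kBT * (pKa - pH)


def p_slow(species) -> float:
    """Slow-interconversion mixture permeability Σ f_i·P_i (cm/s)."""
    _check_fractions(species)
    total = 0.0
    for s in species:
        if s.P is None:
            raise ValueError(f"species {s.label!r} has no permeability value")
        total += s.fraction * s.P
    return total


def _common_grid(species):
    grids = [s.w.z for s in species]
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    if hi <= lo:
        raise ValueError("species profiles have no common support")
    base = max(grids, key=len)
    return base[(base >= lo - 1e-12) & (base <= hi + 1e-12)]


def p_fast(species, thermo: Thermo, half_bilayer: bool = False) -> float:
    """Fast-interconversion (parallel-resistor) mixture permeability in cm/s.

    1/P = ∫ dz [Σ_i f_i e^{−βw_i(z)} D_i(z)]⁻¹ over the common grid.
    """
    _check_fractions(species)
    for s in species:
        if not s.has_profiles():
            raise ValueError(f"species {s.label!r} needs (w, D) profiles for the fast model")
    z = _common_grid(species)
    beta = thermo.beta
    conductivity = np.zeros_like(z)
    for s in species:
        wv = s.w.interp_to(z).value
        Dv = s.D.interp_to(z).value
        conductivity += s.fraction * np.exp(-beta * wv) * Dv
    res = float(np.trapezoid(1.0 / conductivity, z))
    if half_bilayer:
        res *= 2.0
    return A_PER_NS_TO_CM_PER_S / res


def p_mra(species, thermo: Thermo, half_bilayer: bool = False) -> float:
    """Minimum-resistance approximation permeability in cm/s.

    At each z the effective resistivity is min_i e^{β(w_i(z)+Δw_i(0))}/D_i(z):
    the species that is locally cheapest (after its bulk population offset)
    carries the flux, with no interconversion inside the membrane.
    """
    for s in species:
        if not s.has_profiles():
            raise ValueError(f"species {s.label!r} needs (w, D) profiles for the MRA")
    z = _common_grid(species)
    beta = thermo.beta
    per_species = []
    for s in species:
        wv = s.w.interp_to(z).value + s.offset
        Dv = s.D.interp_to(z).value
        per_species.append(np.exp(beta * wv) / Dv)
    R = np.min(np.vstack(per_species), axis=0)
    res = float(np.trapezoid(R, z))
    if half_bilayer:
        res *= 2.0
    return A_PER_NS_TO_CM_PER_S / res


def _two_state(spec: MixingSpec):
    """(deprotonated, protonated) pair convention: first species is uncharged."""
    if len(spec.species) != 2:
        raise ValueError("pKa sweep requires exactly two species (uncharged, protonated)")
    return spec.species[0], spec.species[1]


def pka_sweep(spec: MixingSpec, pKa_grid) -> dict:
    """Evaluate all three mixing approximations across a grid of amine pKa values.

    Species fractions are recomputed per grid point from Henderson-Hasselbalch
    at ``spec.pH``; the uncharged species' PMF offset is Δw(0).  Approximations
    requiring profiles are reported as NaN when only P values are supplied.
    """
    neutral, prot = _two_state(spec)
    pKa_grid = np.asarray(pKa_grid, dtype=float)
    th = spec.thermo
    P_n = neutral.permeability(th, spec.half_bilayer)
    P_p = prot.permeability(th, spec.half_bilayer)
    have_profiles = neutral.has_profiles() and prot.has_profiles()

    out = {"pKa": pKa_grid,
           "P_slow": np.empty_like(pKa_grid),
           "P_fast": np.full_like(pKa_grid, np.nan),
           "P_mra": np.full_like(pKa_grid, np.nan)}
    for i, pka in enumerate(pKa_grid):
        f_n = hh_fraction(pka, spec.pH)
        sp_n = SpeciesState(neutral.label, f_n, P=P_n, w=neutral.w, D=neutral.D,
                            offset=pmf_offset(pka, spec.pH, th))
        sp_p = SpeciesState(prot.label, 1.0 - f_n, P=P_p, w=prot.w, D=prot.D, offset=0.0)
        out["P_slow"][i] = p_slow([sp_n, sp_p])
        if have_profiles:
            out["P_fast"][i] = p_fast([sp_n, sp_p], th, spec.half_bilayer)
            out["P_mra"][i] = p_mra([sp_n, sp_p], th, spec.half_bilayer)
    return out


def crossing_pka(spec: MixingSpec, model: str = "slow",
                 bracket: tuple = (9.0, 13.0), tol: float = 1e-5) -> float:
    """pKa at which the chosen mixing model matches the experimental permeability.

    Bisection root of P_model(pKa) = P_exp on ``bracket``; raises if the
    difference does not change sign there.
    """
    if spec.P_exp is None:
        raise ValueError("MixingSpec.P_exp is required to locate a crossing")
    if model not in ("slow", "fast", "mra"):
        raise ValueError(f"unknown model {model!r}")

    def diff(pka: float) -> float:
        sweep = pka_sweep(spec, [pka])
        val = sweep[f"P_{model}"][0]
        if not np.isfinite(val):
            raise ValueError(f"model {model!r} not evaluable (profiles missing?)")
        return val - spec.P_exp

    lo, hi = bracket
    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo * d_hi > 0:
        raise ValueError(f"no sign change on [{lo}, {hi}]: "
                         f"ΔP({lo}) = {d_lo:.3e}, ΔP({hi}) = {d_hi:.3e}")
    return float(bisect(diff, lo, hi, xtol=tol))


def zwitterion_surface(spec: MixingSpec, pKa1_grid, f_zw_grid) -> dict:
    """Permeability surface over (pKa1, f_zw) with the P_exp contour.

    pKa1 is treated as a macrodissociation constant: the deprotonated pool
    f_d = 1/(1 + 10^(pKa1 − pH)) splits into uncharged (fraction f_d·(1−f_zw))
    and zwitterionic (f_d·f_zw) species.  The zwitterion is assigned the
    protonated species' permeability as an upper bound on its own.  P is the
    slow-interconversion model; the contour at P_exp is linearly interpolated
    (in log P) along pKa1 for each f_zw row.
    """
    neutral, prot = _two_state(spec)
    th = spec.thermo
    P_n = neutral.permeability(th, spec.half_bilayer)
    P_p = prot.permeability(th, spec.half_bilayer)
    pKa1_grid = np.asarray(pKa1_grid, dtype=float)
    f_zw_grid = np.asarray(f_zw_grid, dtype=float)
    if pKa1_grid.size == 0 or f_zw_grid.size == 0:
        raise ValueError("grids must be non-empty")

    f_d = 1.0 / (1.0 + 10.0 ** (pKa1_grid - spec.pH))          # deprotonated pool
    P = (f_d[:, None] * (1.0 - f_zw_grid[None, :]) * P_n
         + f_d[:, None] * f_zw_grid[None, :] * P_p             # zwitterion capped at P_p
         + (1.0 - f_d)[:, None] * P_p)

    contour = []
    if spec.P_exp is not None:
        logPe = np.log(spec.P_exp)
        for j, fz in enumerate(f_zw_grid):
            col = np.log(P[:, j])
            s = np.sign(col - logPe)
            idx = np.flatnonzero(s[:-1] * s[1:] <= 0)
            if idx.size:
                i = idx[0]
                t = (logPe - col[i]) / (col[i + 1] - col[i])
                contour.append((float(pKa1_grid[i] + t * (pKa1_grid[i + 1] - pKa1_grid[i])),
                                float(fz)))
    return {"pKa1": pKa1_grid, "f_zw": f_zw_grid, "P": P,
            "contour": np.array(contour) if contour else np.empty((0, 2))}


def area_corrected_p(P_measured: float, permeable_area_fraction: float) -> float:
    """Correct a measured permeability for partial permeable membrane area.

    When only a fraction of the membrane (e.g. the liquid-disordered phase of
    a phase-separated mixture) passes the permeant, the permeability through
    those regions is P_measured / fraction.
    """
    if not (0 < permeable_area_fraction <= 1):
        raise ValueError("permeable_area_fraction must lie in (0, 1]")
    return P_measured / permeable_area_fraction
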