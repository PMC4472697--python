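"""Units, physical constants, the shared 1-D profile container, and TSV/JSON I/O.

Internal unit system is Å, ns, kcal/mol, K throughout.  Conversion to the
reporting units of the permeability literature (cm/s for P, cm²/s for D) happens
only at output boundaries, through the exact constants in this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "KB_KCAL_MOL_K",
    "A2_PER_NS_TO_CM2_PER_S",
    "A_PER_NS_TO_CM_PER_S",
    "Thermo",
    "Profile1D",
    "PROFILE_ROLES",
    "read_profile",
    "write_profile",
    "boltzmann_g",
    "load_config",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_MOL_K = 1.987204e-3

#: 1 Å²/ns = 1e-16 cm² / 1e-9 s  (exact).
A2_PER_NS_TO_CM2_PER_S = 1e-7

#: 1 Å/ns = 1e-8 cm / 1e-9 s = 10 cm/s  (exact).
A_PER_NS_TO_CM_PER_S = 10.0

PROFILE_ROLES = ("pmf", "diffusion", "dissipation", "resistivity")

_ROLE_UNITS = {
    "pmf": "kcal/mol",
    "diffusion": "A^2/ns",
    "dissipation": "kcal/mol",
    "resistivity": "ns/A^2",
}


@dataclass(frozen=True)
class Thermo:
    """Temperature and derived thermodynamic factors.

    Parameters
    ----------
    T : float
        Absolute temperature in K.
    """

    T: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.T) or self.T <= 0:
            raise ValueError(f"temperature must be positive and finite, got {self.T}")

    @property
    def kB(self) -> float:
        return KB_KCAL_MOL_K

    @property
    def kBT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return KB_KCAL_MOL_K * self.T

    @property
    def beta(self) -> float:
        """Inverse thermal energy β = 1/(k_B·T) in mol/kcal."""
        return 1.0 / self.kBT


@dataclass
class Profile1D:
    """A gridded function of the bilayer-normal coordinate z with uncertainties.

    Used for the PMF w(z) (kcal/mol), the local diffusion coefficient D(z)
    (Å²/ns), accumulated dissipative work (kcal/mol) and the local resistivity
    e^{βw}/D (ns/Å²).  ``z`` must be strictly increasing; uniform spacing is
    allowed but not required.
    """

    z: np.ndarray
    value: np.ndarray
    stderr: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.role not in PROFILE_ROLES:
            raise ValueError(f"unknown profile role {self.role!r}; expected one of {PROFILE_ROLES}")
        if self.z.ndim != 1 or self.z.size == 0:
            raise ValueError("profile grid must be a non-empty 1-D array")
        if self.value.shape != self.z.shape or self.stderr.shape != self.z.shape:
            raise ValueError("value and stderr must match the z grid in length")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if np.any(self.stderr < 0):
            raise ValueError("stderr must be non-negative")
        if self.role == "diffusion" and np.any(self.value <= 0):
            raise ValueError("diffusion profile must be positive everywhere")

    def __len__(self) -> int:
        return self.z.size

    @property
    def units(self) -> str:
        return _ROLE_UNITS[self.role]

    def interp_to(self, z_new: np.ndarray) -> "Profile1D":
        """Linear interpolation of value and stderr onto a new grid (no extrapolation)."""
        z_new = np.asarray(z_new, dtype=float)
        if z_new.min() < self.z[0] - 1e-9 or z_new.max() > self.z[-1] + 1e-9:
            raise ValueError("interpolation target grid extends beyond profile support")
        v = np.interp(z_new, self.z, self.value)
        s = np.interp(z_new, self.z, self.stderr)
        return Profile1D(z=z_new, value=v, stderr=s, role=self.role)

    def shifted(self, offset: float) -> "Profile1D":
        return replace(self, value=self.value + offset)


def write_profile(profile: Profile1D, path: str | Path) -> None:
    """Write a profile as 3-column TSV at full float precision (17 sig. digits).

    The header comment records the role so that a round trip restores it.
    """
    if not isinstance(profile, Profile1D):
        raise TypeError("expected a Profile1D")
    path = Path(path)
    lines = [f"# role={profile.role} units={profile.units}",
             "# z_angstrom\tvalue\tstderr"]
    for zi, vi, si in zip(profile.z, profile.value, profile.stderr):
        lines.append(f"{zi:.17g}\t{vi:.17g}\t{si:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path, role: str | None = None) -> Profile1D:
    """Read the 3-column TSV profile dialect written by :func:`write_profile`.

    Parameters
    ----------
    path : path
        File with ``# role=...`` header and tab/space separated columns
        ``z_angstrom value stderr``.
    role : str, optional
        Expected role; overrides (and is checked against) the header when both
        are present.
    """
    path = Path(path)
    header_role = None
    z, v, s = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("role="):
                        header_role = tok[5:]
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                z.append(float(parts[0])); v.append(float(parts[1])); s.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed float: {exc}") from None
    use_role = role or header_role
    if use_role is None:
        raise ValueError(f"{path}: no role in header and none supplied")
    if role is not None and header_role is not None and role != header_role:
        raise ValueError(f"{path}: header role {header_role!r} does not match requested {role!r}")
    return Profile1D(z=np.array(z), value=np.array(v), stderr=np.array(s), role=use_role)


def boltzmann_g(w: Profile1D, thermo: Thermo) -> Profile1D:
    """Linear distribution function g(z) = exp(−β·w(z)) with delta-method errors.

    g(z) weights the local equilibrium occupancy along the bilayer normal; the
    first-order uncertainty is σ_g = β·g·σ_w.
    """
    if w.role != "pmf":
        raise ValueError(f"boltzmann_g expects a pmf profile, got role={w.role!r}")
    g = np.exp(-thermo.beta * w.value)
    sg = thermo.beta * g * w.stderr
    # g is dimensionless; it is carried on the pmf role as pmf-derived data
    return Profile1D(z=w.z.copy(), value=g, stderr=sg, role="pmf")


def load_config(path: str | Path) -> dict:
    """Load and minimally validate the run-configuration JSON.

    Recognised top-level keys: ``temperature_K`` (required for pipeline use),
    ``bin_width_A`` (default 0.2), ``smoothing_window`` (default 9),
    ``species``, ``protocol``, ``seed``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    cfg.setdefault("bin_width_A", 0.2)
    cfg.setdefault("smoothing_window", 9)
    if "temperature_K" in cfg:
        T = cfg["temperature_K"]
        if not isinstance(T, (int, float)) or T <= 0:
            raise ValueError(f"{path}: temperature_K must be a positive number")
    if cfg["bin_width_A"] <= 0:
        raise ValueError(f"{path}: bin_width_A must be positive")
    w = cfg["smoothing_window"]
    if not isinstance(w, int) or w < 1 or w % 2 == 0:
        raise ValueError(f"{path}: smoothing_window must be a positive odd integer")
    return cfg
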