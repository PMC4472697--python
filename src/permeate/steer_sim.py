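"""Synthetic steered-trajectory generator: constrained overdamped Langevin pulling.

The steered coordinate z is rigidly constrained to the oscillating
forward-reverse (OFR) path

    z_COM(t) = z0 + v_d·t + A·sin(ω·t),   ω = π·n·v_d/A,

over a user-specified true PMF w(z) and position-dependent diffusion profile
D(z).  At every step the applied (constraint) force is read off the force
balance of the overdamped dynamics,

    f_c = γ(z)·ż − F(z) − ξ,

with friction γ(z) = k_B·T/D(z), deterministic force F(z) = −dw/dz, and thermal
force ξ drawn fresh each step from a Gaussian of variance 2·γ(z)·k_B·T/Δt (γ at
the constrained position at step start).  The per-step work increment is
dW = f_c·Δz.  Under this model the forward-reverse identities hold exactly in
the mean: ⟨W_F⟩ − ΔF = ⟨W_d⟩ and d⟨W_d⟩/dz = k_B·T·v/D(z), with Gaussian work
of variance 2·k_B·T·⟨W_d⟩ — so every downstream estimator can be validated
against known ground truth.

Because z carries no free dynamics under the rigid constraint there is no
Itô/Stratonovich ambiguity and no spurious-drift correction; D(z) enters only
through γ(z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Profile1D, Thermo

__all__ = [
    "SteeringProtocol",
    "SimConfig",
    "WorkTrajectory",
    "make_protocol",
    "protocol_position",
    "protocol_velocity",
    "run_steered_trajectory",
    "generate_fixture_set",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class SteeringProtocol:
    """Parameters of the oscillating drift path z0 + v_d·t + A·sin(ωt)."""

    z0: float        # start position, Å
    v_d: float       # drift velocity, Å/ns
    A: float         # oscillation amplitude, Å
    n: float         # approximate per-oscillation sample count (frequency parameter)
    omega: float     # angular frequency, rad/ns
    v_av: float      # average oscillation speed 2·n·v_d, Å/ns
    v_c: float | None = None  # user-supplied critical-speed bound, Å/ns

    @property
    def v_max(self) -> float:
        """Peak protocol speed |ż| = v_d + A·ω."""
        return self.v_d + self.A * self.omega


def make_protocol(z0: float, v_d: float, A: float, n: float,
                  v_c: float | None = None) -> SteeringProtocol:
    """Build a steering protocol with ω = π·n·v_d/A and v_av = 2·n·v_d.

    ``A = 0`` is accepted as the degenerate pure-drift protocol (ω = 0,
    v_av = v_d): a constant-velocity pull with no oscillation.
    """
    if v_d <= 0 or A < 0:
        raise ValueError("v_d must be positive and A non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if A == 0.0:
        omega, v_av = 0.0, v_d
    else:
        omega = math.pi * n * v_d / A
        v_av = 2.0 * n * v_d
    if v_c is not None and v_av > v_c:
        raise ValueError(f"average oscillation speed {v_av} exceeds the critical speed {v_c}")
    return SteeringProtocol(z0=z0, v_d=v_d, A=A, n=n, omega=omega, v_av=v_av, v_c=v_c)


def protocol_position(protocol: SteeringProtocol, t):
    """Constrained position z_COM(t) = z0 + v_d·t + A·sin(ω·t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return protocol.z0 + protocol.v_d * t + protocol.A * np.sin(protocol.omega * t)


def protocol_velocity(protocol: SteeringProtocol, t):
    """Analytic path speed ż(t) = v_d + A·ω·cos(ω·t)."""
    t = np.asarray(t, dtype=float)
    return protocol.v_d + protocol.A * protocol.omega * np.cos(protocol.omega * t)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth profiles, time step and RNG seed for the synthetic engine."""

    thermo: Thermo
    pmf_true: Profile1D
    diff_true: Profile1D
    dt: float        # ns
    seed: int
    duration: float  # ns

    def __post_init__(self) -> None:
        if self.pmf_true.role != "pmf":
            raise ValueError("pmf_true must have role 'pmf'")
        if self.diff_true.role != "diffusion":
            raise ValueError("diff_true must have role 'diffusion'")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


def default_dt(protocol: SteeringProtocol, bin_width: float = 0.2) -> float:
    """Time step such that the peak step displacement is <= bin_width/4.

    Guarantees that the analysis resolves every bin crossing.
    """
    return bin_width / 4.0 / protocol.v_max


@dataclass
class WorkTrajectory:
    """Time series of constrained position, applied force and work increments.

    ``z[k]`` lies exactly on the protocol path; ``dW[k]`` is the work done over
    the step from ``t[k]`` to ``t[k+1]`` (length len(t) − 1).
    """

    t: np.ndarray
    z: np.ndarray
    f_applied: np.ndarray   # per-step force, kcal/(mol·Å), length len(t) − 1
    dW: np.ndarray          # per-step work increment, kcal/mol, length len(t) − 1
    run_id: str
    protocol: SteeringProtocol
    thermo: Thermo

    @property
    def total_work(self) -> float:
        return float(self.dW.sum())


def _stable_stream(seed: int, run_id: str) -> np.random.Generator:
    # run_id folded into the stream so that fixture sets are reproducible per run
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                 abs(hash_str(run_id)) % (2**31)])
    return np.random.default_rng(ss)


def hash_str(s: str) -> int:
    """Deterministic (process-independent) string hash for seed derivation."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def run_steered_trajectory(config: SimConfig, protocol: SteeringProtocol,
                           run_id: str = "run0") -> WorkTrajectory:
    """Simulate one constrained pull and record the applied-force work series."""
    n_steps = int(round(config.duration / config.dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one time step")
    t = np.arange(n_steps + 1) * config.dt
    z = protocol_position(protocol, t)

    zmin, zmax = z.min(), z.max()
    pmf, diff = config.pmf_true, config.diff_true
    lo = max(pmf.z[0], diff.z[0])
    hi = min(pmf.z[-1], diff.z[-1])
    if zmin < lo or zmax > hi:
        bad = t[np.argmax((z < lo) | (z > hi))]
        raise ValueError(
            f"protocol path leaves profile support [{lo}, {hi}] first at t = {bad:.6g} ns")

    force_spline = CubicSpline(pmf.z, pmf.value).derivative()  # dw/dz
    kBT = config.thermo.kBT
    gamma = kBT / np.interp(z[:-1], diff.z, diff.value)        # at step start

    dz = np.diff(z)
    zdot = dz / config.dt
    rng = _stable_stream(config.seed, run_id)
    xi = rng.normal(0.0, np.sqrt(2.0 * gamma * kBT / config.dt))
    F = -force_spline(z[:-1])                                  # −dw/dz
    f_c = gamma * zdot - F - xi
    dW = f_c * dz
    return WorkTrajectory(t=t, z=z, f_applied=f_c, dW=dW, run_id=run_id,
                          protocol=protocol, thermo=config.thermo)


def generate_fixture_set(config: SimConfig, protocol: SteeringProtocol,
                         n_runs: int, base_seed: int,
                         out_dir: str | Path | None = None) -> list[WorkTrajectory]:
    """Simulate ``n_runs`` independent pulls (multiple path sampling).

    Each run gets a distinct, reproducible stream derived from ``base_seed``.
    When ``out_dir`` is given, each trajectory is also written as TSV.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    trajs = []
    for i in range(n_runs):
        run_id = f"run{i:03d}"
        cfg = SimConfig(thermo=config.thermo, pmf_true=config.pmf_true,
                        diff_true=config.diff_true, dt=config.dt,
                        seed=base_seed, duration=config.duration)
        traj = run_steered_trajectory(cfg, protocol, run_id=run_id)
        trajs.append(traj)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for traj in trajs:
            write_trajectory(traj, out_dir / f"{traj.run_id}.tsv")
    return trajs


def write_trajectory(traj: WorkTrajectory, path: str | Path) -> None:
    """Trajectory TSV: header with run metadata, then t, z, f_applied, dW columns.

    Per-step rows carry the force and work of the step *starting* at that time;
    the final sample row has empty force/work fields.
    """
    p = traj.protocol
    lines = [
        f"# run_id={traj.run_id} T_K={traj.thermo.T:.17g} "
        f"protocol={p.z0:.17g},{p.v_d:.17g},{p.A:.17g},{p.n:.17g}",
        "# t_ns\tz_angstrom\tf_applied_kcal_mol_A\tdW_kcal_mol",
    ]
    for k in range(len(traj.dW)):
        lines.append(f"{traj.t[k]:.17g}\t{traj.z[k]:.17g}\t"
                     f"{traj.f_applied[k]:.17g}\t{traj.dW[k]:.17g}")
    lines.append(f"{traj.t[-1]:.17g}\t{traj.z[-1]:.17g}\t\t")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path) -> WorkTrajectory:
    """Read a trajectory TSV written by :func:`write_trajectory`."""
    path = Path(path)
    run_id, T, proto = "run", None, None
    t, z, f, dW = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("run_id="):
                        run_id = tok[7:]
                    elif tok.startswith("T_K="):
                        T = float(tok[4:])
                    elif tok.startswith("protocol="):
                        proto = [float(x) for x in tok[9:].split(",")]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            t.append(float(parts[0])); z.append(float(parts[1]))
            if parts[2].strip():
                f.append(float(parts[2])); dW.append(float(parts[3]))
    if T is None or proto is None:
        raise ValueError(f"{path}: missing T_K or protocol header")
    protocol = make_protocol(z0=proto[0], v_d=proto[1], A=proto[2], n=proto[3])
    return WorkTrajectory(t=np.array(t), z=np.array(z), f_applied=np.array(f),
                          dW=np.array(dW), run_id=run_id, protocol=protocol,
                          thermo=Thermo(T=T))
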