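"""Rotational autocorrelation and relaxation time of a molecular axis vector.

For a unit vector r̂ fixed in the molecular frame (e.g. the C1→C4 axis of a
phenol ring), the first-rank orientational correlation is

    c_r(t) = ⟨r̂(t)·r̂(0)⟩,

and the rotational relaxation time is its time integral, τ_r = ∫₀^∞ c_r dt,
truncated in practice at the first zero crossing of c_r (beyond which the
estimate is noise-dominated).  For free isotropic rotational diffusion with
coefficient D_r, c_r(t) = e^{−2·D_r·t} exactly, so τ_r = 1/(2·D_r) — the
closed form against which the synthetic generator here is validated.

τ_r sets how long a molecule takes to forget its orientation; starting
configurations separated by several τ_r are orientationally independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RotationTrace", "rotational_acf", "tau_r",
           "simulate_rotational_diffusion", "simulate_rotor_ensemble",
           "ensemble_acf"]


@dataclass
class RotationTrace:
    """Uniformly sampled unit-vector series with its ACF and relaxation time.

    ``truncated`` records whether the τ_r integral was stopped at a zero
    crossing of c_r (False means the window ran out first and the value is a
    lower bound).
    """

    t: np.ndarray            # ps
    u: np.ndarray            # (n, 3) unit vectors
    c_r: np.ndarray | None = None
    tau_r: float | None = None
    truncated: bool = True


def rotational_acf(u: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Lag-averaged orientational ACF c_r(k·Δt) = ⟨r̂(t+k·Δt)·r̂(t)⟩_t.

    Averages the dot product over all valid time origins at each lag, using an
    FFT per Cartesian component.  Non-unit input vectors are normalized with a
    warning.  c_r[0] = 1 exactly for unit input.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of vectors")
    n = u.shape[0]
    if n < 2:
        raise ValueError("need at least two frames")
    norms = np.linalg.norm(u, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        warnings.warn("non-unit vectors normalized before correlation", stacklevel=2)
        u = u / norms[:, None]
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)

    # sum_t u(t)·u(t+k) per component via FFT autocorrelation
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acf = np.zeros(max_lag + 1)
    for c in range(3):
        f = np.fft.rfft(u[:, c], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
        acf += ac
    counts = n - np.arange(max_lag + 1)
    return acf / counts


def tau_r(c_r: np.ndarray, dt: float) -> tuple[float, bool]:
    """Relaxation time: trapezoidal ∫c_r dt up to the first zero crossing.

    The crossing instant is located by linear interpolation between the last
    positive and first non-positive samples.  If c_r never crosses zero the
    full window is integrated and the result flagged (``truncated=False``).

    Returns ``(tau, truncated)`` with tau in the units of ``dt``.
    """
    c_r = np.asarray(c_r, dtype=float)
    if c_r.size == 0:
        raise ValueError("empty correlation series")
    if abs(c_r[0] - 1.0) > 1e-6:
        raise ValueError("c_r(0) must equal 1")
    neg = np.flatnonzero(c_r <= 0)
    if neg.size == 0:
        return float(np.trapezoid(c_r, dx=dt)), False
    k = int(neg[0])              # first non-positive sample; k >= 1 since c_r[0] = 1
    tau = float(np.trapezoid(c_r[:k], dx=dt))
    # triangle from the last positive sample to the interpolated zero
    c_prev, c_next = c_r[k - 1], c_r[k]
    if c_next < c_prev:
        t_frac = c_prev / (c_prev - c_next)   # in units of dt
        tau += 0.5 * c_prev * t_frac * dt
    return tau, True


def simulate_rotational_diffusion(D_r: float, dt: float, n_steps: int,
                                  seed: int) -> RotationTrace:
    """Isotropic rotational random walk of a unit vector on the sphere.

    Each step adds a Gaussian angular kick of variance 2·D_r·dt in the two
    directions perpendicular to the current orientation, then renormalizes.
    Requires D_r·dt ≤ 0.1 for the small-step discretization to be safe.
    """
    if D_r < 0 or dt <= 0 or n_steps < 1:
        raise ValueError("D_r must be >= 0, dt > 0, n_steps >= 1")
    if D_r * dt > 0.1:
        raise ValueError(f"D_r*dt = {D_r * dt:.3g} > 0.1: discretization unsafe")
    rng = np.random.default_rng(seed)
    u = np.empty((n_steps + 1, 3))
    u[0] = (0.0, 0.0, 1.0)
    if D_r == 0:
        u[:] = u[0]
    else:
        sigma = np.sqrt(2.0 * D_r * dt)
        kicks = rng.normal(0.0, sigma, size=(n_steps, 3))
        v = u[0].copy()
        for k in range(n_steps):
            g = kicks[k]
            g -= np.dot(g, v) * v          # tangent-plane component only
            v = v + g
            v /= np.linalg.norm(v)
            u[k + 1] = v
    t = np.arange(n_steps + 1) * dt
    return RotationTrace(t=t, u=u)


def simulate_rotor_ensemble(D_r: float, dt: float, n_steps: int,
                            n_rotors: int, seed: int) -> np.ndarray:
    """Independent rotational random walks, propagated together.

    Returns a (n_steps + 1, n_rotors, 3) array of unit vectors.  The per-step
    model is identical to :func:`simulate_rotational_diffusion`; rotors share
    no noise.  Ensemble averaging of the ACF tames the long-lag noise that a
    single trace accumulates near the zero crossing of c_r.
    """
    if D_r < 0 or dt <= 0 or n_steps < 1 or n_rotors < 1:
        raise ValueError("require D_r >= 0, dt > 0, n_steps >= 1, n_rotors >= 1")
    if D_r * dt > 0.1:
        raise ValueError(f"D_r*dt = {D_r * dt:.3g} > 0.1: discretization unsafe")
    rng = np.random.default_rng(seed)
    u = np.empty((n_steps + 1, n_rotors, 3))
    v = np.zeros((n_rotors, 3))
    v[:, 2] = 1.0
    u[0] = v
    if D_r == 0:
        u[:] = u[0]
        return u
    sigma = np.sqrt(2.0 * D_r * dt)
    for k in range(n_steps):
        g = rng.normal(0.0, sigma, size=(n_rotors, 3))
        g -= np.sum(g * v, axis=1, keepdims=True) * v
        v = v + g
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        u[k + 1] = v
    return u


def ensemble_acf(u: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Orientational ACF averaged over an ensemble of rotors.

    ``u`` is (n, m, 3) as returned by :func:`simulate_rotor_ensemble`.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 3 or u.shape[2] != 3:
        raise ValueError("expected an (n, m, 3) ensemble array")
    acfs = [rotational_acf(u[:, j, :], max_lag=max_lag) for j in range(u.shape[1])]
    return np.mean(acfs, axis=0)


def analyze_trace(trace: RotationTrace, max_lag: int | None = None) -> RotationTrace:
    """Fill in c_r and τ_r of a trace in place (and return it)."""
    trace.c_r = rotational_acf(trace.u, max_lag=max_lag)
    dt = float(trace.t[1] - trace.t[0])
    trace.tau_r, trace.truncated = tau_r(trace.c_r, dt)
    return trace
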