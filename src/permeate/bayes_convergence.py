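"""Sequential-Bayesian convergence diagnostic for per-bin work means.

As independent steered runs are added, the posterior over each bin's mean
reversible work sharpens.  Starting from a flat prior over a bounded grid of
candidate means and multiplying in one Gaussian likelihood per run (centered
on that run's bin value with that run's standard error), the posterior mode
μ_bin(N) after N runs traces how the best estimate settles.  The diagnostic is

    ⟨Δμ_bin⟩(N) = ⟨ |μ_bin(N) − μ_bin(N−1)| ⟩_bins,

averaged over a strided subset of bins (default every 5th bin, i.e. every
1 Å on a 0.2 Å grid), and its power-law decay ⟨Δμ_bin⟩ ∝ N^{−x}.  Independent
samples give x ≈ 1 (running-mean law); inputs that are themselves averages
over many correlated samples can converge faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BayesTrace", "sequential_posterior", "delta_mu_curve", "fit_power_law"]


@dataclass
class BayesTrace:
    """Posterior-mode history and the derived convergence curve."""

    mu: np.ndarray                    # (n_bins, N_runs) posterior modes
    delta_mu: np.ndarray              # (n_bins, N_runs−1) |μ(N) − μ(N−1)|
    avg_delta_mu: np.ndarray          # (N_runs−1,) bin-averaged curve
    exponent: float | None = None
    excluded: tuple = field(default_factory=tuple)


def sequential_posterior(samples: np.ndarray, stderr: np.ndarray,
                         grid_resolution: float = 1e-4,
                         grid_pad: float = 5.0) -> np.ndarray:
    """Posterior-mode sequence for one bin under a flat prior on a mean grid.

    Parameters
    ----------
    samples, stderr : arrays of length N ≥ 2
        Per-run bin values (kcal/mol) and their standard errors.
    grid_resolution : float
        Spacing of the candidate-mean grid in kcal/mol.
    grid_pad : float
        Grid extends ``grid_pad`` × max(stderr) beyond the sample range.

    Returns the mode after each update (length N).  With equal stderr the mode
    after N samples equals the running mean (conjugate-Gaussian closed form),
    up to grid resolution.
    """
    samples = np.asarray(samples, dtype=float)
    stderr = np.asarray(stderr, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples to track convergence")
    if samples.shape != stderr.shape:
        raise ValueError("samples and stderr must have equal length")
    if np.any(stderr <= 0):
        raise ValueError("standard errors must be strictly positive")

    pad = grid_pad * stderr.max()
    lo, hi = samples.min() - pad, samples.max() + pad
    n_grid = max(int(np.ceil((hi - lo) / grid_resolution)) + 1, 3)
    grid = np.linspace(lo, hi, n_grid)

    log_post = np.zeros_like(grid)     # flat prior
    modes = np.empty(samples.size)
    for k, (x, s) in enumerate(zip(samples, stderr)):
        log_post += -0.5 * ((grid - x) / s) ** 2
        modes[k] = grid[np.argmax(log_post)]
    return modes


def delta_mu_curve(traces: np.ndarray, bin_stride: int = 5) -> np.ndarray:
    """Bin-averaged |Δμ| per added sample over a strided bin subset.

    ``traces`` is (n_bins, N_runs) of posterior modes; the average at index
    N−2 is ⟨|μ_bin(N) − μ_bin(N−1)|⟩ over bins 0, stride, 2·stride, …
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 2:
        raise ValueError("traces must be (n_bins, N_runs) with N_runs >= 2")
    if bin_stride < 1:
        raise ValueError("bin_stride must be >= 1")
    subset = traces[::bin_stride]
    return np.mean(np.abs(np.diff(subset, axis=1)), axis=0)


def fit_power_law(curve: np.ndarray, exclude: tuple = ()) -> float:
    """Exponent x of ⟨Δμ_bin⟩(N) ∝ N^{−x} by log-log least squares.

    ``curve[k]`` corresponds to N = k + 2 (the first update is N = 2).
    ``exclude`` lists N values (not indices) to omit, e.g. a known outlier run.
    """
    curve = np.asarray(curve, dtype=float)
    N = np.arange(2, curve.size + 2)
    keep = ~np.isin(N, np.asarray(exclude, dtype=int))
    N, curve = N[keep], curve[keep]
    if curve.size < 3:
        raise ValueError("need at least three points after exclusion")
    if np.any(curve <= 0):
        raise ValueError("curve values must be positive for a log-log fit")
    slope, _ = np.polyfit(np.log(N), np.log(curve), 1)
    return float(-slope)


def convergence_trace(per_run_values: np.ndarray, per_run_stderr: np.ndarray,
                      bin_stride: int = 5, exclude: tuple = (),
                      grid_resolution: float = 1e-4) -> BayesTrace:
    """Full diagnostic: per-bin posterior modes → ⟨Δμ⟩ curve → power-law fit.

    ``per_run_values``/``per_run_stderr`` are (n_bins, N_runs).
    """
    vals = np.asarray(per_run_values, dtype=float)
    errs = np.asarray(per_run_stderr, dtype=float)
    if vals.shape != errs.shape or vals.ndim != 2:
        raise ValueError("per-run values and stderr must be matching 2-D arrays")
    mu = np.vstack([sequential_posterior(vals[b], errs[b], grid_resolution)
                    for b in range(vals.shape[0])])
    curve = delta_mu_curve(mu, bin_stride=bin_stride)
    exponent = None
    if curve.size >= 3 and np.all(curve > 0):
        exponent = fit_power_law(curve, exclude=exclude)
    return BayesTrace(mu=mu, delta_mu=np.abs(np.diff(mu, axis=1)),
                      avg_delta_mu=curve, exponent=exponent,
                      excluded=tuple(exclude))
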