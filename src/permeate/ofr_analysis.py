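"""From steered work trajectories to PMF and D(z) profiles.

The oscillating forward-reverse (OFR) protocol sweeps every spatial bin many
times in both directions.  Each full or partial crossing of a bin contributes
one work sample to that (bin, direction); the forward-reverse estimators

    ΔF_bin   = (⟨W_F⟩ − ⟨W_R⟩)/2
    ⟨W_d⟩_bin = (⟨W_F⟩ + ⟨W_R⟩)/2

or the Brownian-dynamics fluctuation-dissipation theorem (BD-FDT)

    ΔF_bin = −k_B·T · ln(⟨e^{−βW_F/2}⟩ / ⟨e^{−βW_R/2}⟩)

convert the per-bin samples to free-energy increments and dissipative work.
Multiple runs are combined per bin by inverse-variance weighting *before*
integration; the PMF is the cumulative integral taken from both ends with the
per-point uncertainty reported as the average of the two directional integral
uncertainties.  The dissipative work inverts to the local diffusion
coefficient through d⟨W_d⟩/dz = k_B·T·v/D(z), followed by a centered moving
average (default 9 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Profile1D, Thermo
from .steer_sim import WorkTrajectory, protocol_velocity

__all__ = [
    "BinWorkStats",
    "BinEstimates",
    "bin_work",
    "merge_stats",
    "fr_estimates",
    "bdfdt_estimate",
    "combine_runs",
    "integrate_pmf",
    "diffusion_profile",
    "autocorr_time",
]

#: Bins whose mean crossing speed falls below this fraction of the protocol's
#: average oscillation speed sit at protocol turning points, where the
#: dissipation→diffusion inversion is ill-conditioned; they are excluded from
#: D(z) (never from the PMF).
TURNING_POINT_SPEED_FRACTION = 0.05

#: Crossings shorter than this fraction of the bin width (fragments created
#: when a protocol turning point falls inside the bin) are kept in the sample
#: record for exact work bookkeeping but excluded from the per-bin means: a
#: fragment traverses only part of the bin and would bias both the free-energy
#: increment and the dissipation toward the sub-interval it covers.
MIN_CROSSING_FRACTION = 0.9


@dataclass
class BinWorkStats:
    """Per-bin forward/reverse work samples from one or more trajectories.

    Sample lists are ordered in time.  ``lengths_*`` hold the |Δz| actually
    traversed by each crossing (partial crossings at turning points traverse
    less than the bin width); ``speeds_*`` hold each crossing's |Δz|-weighted
    mean analytic path speed.
    """

    bin_edges: np.ndarray
    W_F_samples: list
    W_R_samples: list
    lengths_F: list
    lengths_R: list
    speeds_F: list
    speeds_R: list
    thermo: Thermo
    v_av: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        nf = np.array([len(w) for w in self.W_F_samples])
        nr = np.array([len(w) for w in self.W_R_samples])
        return nf, nr

    def complete(self, direction: str, b: int) -> np.ndarray:
        """Boolean mask of complete crossings (length ≥ 0.9 bin widths) in a bin."""
        lens = self.lengths_F[b] if direction == "F" else self.lengths_R[b]
        return np.asarray(lens) >= MIN_CROSSING_FRACTION * self.bin_width

    def complete_works(self, direction: str, b: int) -> np.ndarray:
        w = self.W_F_samples[b] if direction == "F" else self.W_R_samples[b]
        return np.asarray(w)[self.complete(direction, b)]

    def mean_crossing_speed(self) -> np.ndarray:
        """Per-bin length-weighted mean complete-crossing speed."""
        out = np.full(self.n_bins, np.nan)
        for b in range(self.n_bins):
            parts = []
            for d, speeds, lens in (("F", self.speeds_F[b], self.lengths_F[b]),
                                    ("R", self.speeds_R[b], self.lengths_R[b])):
                keep = self.complete(d, b)
                lens = np.asarray(lens)[keep]
                if lens.size and lens.sum() > 0:
                    parts.append(float(np.sum(np.asarray(speeds)[keep] * lens) / lens.sum()))
            if parts:
                out[b] = np.mean(parts)
        return out

    def mean_speed_length(self) -> np.ndarray:
        """Per-bin mean of (crossing speed × crossed length) over complete crossings.

        The dissipative work of one crossing is (k_B·T/D)·v̄_c·ℓ_c, so the
        quantity matching the per-crossing work mean is ⟨v̄_c·ℓ_c⟩ of the same
        crossing subset; for complete crossings it reduces to v̄·Δz.
        """
        out = np.full(self.n_bins, np.nan)
        for b in range(self.n_bins):
            parts = []
            for d, speeds, lens in (("F", self.speeds_F[b], self.lengths_F[b]),
                                    ("R", self.speeds_R[b], self.lengths_R[b])):
                keep = self.complete(d, b)
                if keep.any():
                    parts.append(float(np.mean(np.asarray(speeds)[keep]
                                               * np.asarray(lens)[keep])))
            if parts:
                out[b] = np.mean(parts)
        return out

    # plain and exponentiated per-bin averages -------------------------------

    def mean_WF(self) -> np.ndarray:
        return np.array([np.mean(w) if len(w) else np.nan for w in self.W_F_samples])

    def mean_WR(self) -> np.ndarray:
        return np.array([np.mean(w) if len(w) else np.nan for w in self.W_R_samples])

    def expavg_F(self) -> np.ndarray:
        b2 = self.thermo.beta / 2.0
        return np.array([np.mean(np.exp(-b2 * np.asarray(w))) if len(w) else np.nan
                         for w in self.W_F_samples])

    def expavg_R(self) -> np.ndarray:
        b2 = self.thermo.beta / 2.0
        return np.array([np.mean(np.exp(-b2 * np.asarray(w))) if len(w) else np.nan
                         for w in self.W_R_samples])


@dataclass
class BinEstimates:
    """Per-bin free-energy change and dissipative work with uncertainties."""

    bin_edges: np.ndarray
    dF: np.ndarray
    dF_se: np.ndarray
    Wd: np.ndarray
    Wd_se: np.ndarray
    method: str  # "FR" or "BDFDT"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = ~np.isfinite(self.dF)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by the initial-positive-sequence rule.

    Returns τ_int such that N_eff = N/(1 + 2·τ_int); zero for uncorrelated or
    short series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 0.0
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var == 0:
        return 0.0
    tau = 0.0
    for lag in range(1, n // 2):
        rho = np.dot(xc[:-lag], xc[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += rho
    return tau


def _se(x: np.ndarray) -> float:
    """Autocorrelation-corrected standard error of the mean of one sample series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return np.inf
    n_eff = n / (1.0 + 2.0 * autocorr_time(x))
    return float(np.std(x, ddof=1) / np.sqrt(n_eff))


def bin_work(traj: WorkTrajectory, bin_width: float = 0.2) -> BinWorkStats:
    """Assign every per-step work increment to a (bin, direction) crossing sample.

    Steps are split proportionally in z at bin edges, and a crossing closes
    whenever the particle leaves the bin or the discrete velocity changes sign
    (the increment spanning a turning point is split at the extremum at the
    sampling resolution).  Total work is conserved exactly: every increment
    lands in exactly one sample.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z, dW, dt = traj.z, traj.dW, traj.t[1] - traj.t[0]
    if z.size < 2:
        raise ValueError("trajectory too short to bin")
    dz = np.diff(z)
    if np.max(np.abs(dz)) > bin_width:
        raise ValueError("time step too coarse: a single step skips a whole bin")
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < bin_width:
        raise ValueError("trajectory covers less than one bin")

    e0 = np.floor(zmin / bin_width) * bin_width
    n_bins = int(np.ceil((zmax - e0) / bin_width - 1e-12))
    edges = e0 + np.arange(n_bins + 1) * bin_width

    z0s, z1s = z[:-1], z[1:]
    direction = np.where(dz >= 0, 1, -1)
    b0 = np.clip(np.floor((z0s - e0) / bin_width).astype(int), 0, n_bins - 1)
    b1 = np.clip(np.floor((z1s - e0) / bin_width).astype(int), 0, n_bins - 1)
    t_mid = traj.t[:-1] + 0.5 * dt
    speed = np.abs(protocol_velocity(traj.protocol, t_mid))

    crossing = b0 != b1
    counts = 1 + crossing.astype(int)
    pos = np.cumsum(counts) - counts
    total = int(counts.sum())

    p_bin = np.empty(total, dtype=int)
    p_dW = np.empty(total)
    p_len = np.empty(total)
    p_dir = np.repeat(direction, counts)
    p_sp = np.repeat(speed, counts)

    # first portion of every step
    frac = np.ones_like(dz)
    if crossing.any():
        edge_between = e0 + np.maximum(b0[crossing], b1[crossing]) * bin_width
        frac_c = (edge_between - z0s[crossing]) / dz[crossing]
        frac[crossing] = frac_c
    p_bin[pos] = b0
    p_dW[pos] = dW * frac
    p_len[pos] = np.abs(dz) * frac
    # second portion of crossing steps
    if crossing.any():
        second = pos[crossing] + 1
        p_bin[second] = b1[crossing]
        p_dW[second] = dW[crossing] * (1.0 - frac[crossing])
        p_len[second] = np.abs(dz[crossing]) * (1.0 - frac[crossing])

    # crossings: maximal runs of constant (bin, direction)
    if total == 0:
        raise ValueError("empty trajectory")
    boundary = np.flatnonzero((np.diff(p_bin) != 0) | (np.diff(p_dir) != 0)) + 1
    starts = np.concatenate(([0], boundary))
    W_s = np.add.reduceat(p_dW, starts)
    len_s = np.add.reduceat(p_len, starts)
    spl_s = np.add.reduceat(p_sp * p_len, starts)
    bin_s = p_bin[starts]
    dir_s = p_dir[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        v_s = np.where(len_s > 0, spl_s / np.where(len_s > 0, len_s, 1.0), p_sp[starts])

    keep = len_s > 0
    W_s, len_s, bin_s, dir_s, v_s = W_s[keep], len_s[keep], bin_s[keep], dir_s[keep], v_s[keep]

    WF = [[] for _ in range(n_bins)]
    WR = [[] for _ in range(n_bins)]
    LF = [[] for _ in range(n_bins)]
    LR = [[] for _ in range(n_bins)]
    SF = [[] for _ in range(n_bins)]
    SR = [[] for _ in range(n_bins)]
    for b, d, w, ln, v in zip(bin_s, dir_s, W_s, len_s, v_s):
        if d > 0:
            WF[b].append(w); LF[b].append(ln); SF[b].append(v)
        else:
            WR[b].append(w); LR[b].append(ln); SR[b].append(v)
    return BinWorkStats(bin_edges=edges,
                        W_F_samples=[np.array(x) for x in WF],
                        W_R_samples=[np.array(x) for x in WR],
                        lengths_F=[np.array(x) for x in LF],
                        lengths_R=[np.array(x) for x in LR],
                        speeds_F=[np.array(x) for x in SF],
                        speeds_R=[np.array(x) for x in SR],
                        thermo=traj.thermo, v_av=traj.protocol.v_av)


def merge_stats(stats_list: list[BinWorkStats]) -> BinWorkStats:
    """Pool per-bin samples of several runs (identical bin grids required)."""
    first = stats_list[0]
    for s in stats_list[1:]:
        if s.n_bins != first.n_bins or not np.allclose(s.bin_edges, first.bin_edges):
            raise ValueError("bin grids differ between runs")
    def cat(attr):
        return [np.concatenate([getattr(s, attr)[b] for s in stats_list])
                for b in range(first.n_bins)]
    return BinWorkStats(bin_edges=first.bin_edges.copy(),
                        W_F_samples=cat("W_F_samples"), W_R_samples=cat("W_R_samples"),
                        lengths_F=cat("lengths_F"), lengths_R=cat("lengths_R"),
                        speeds_F=cat("speeds_F"), speeds_R=cat("speeds_R"),
                        thermo=first.thermo, v_av=first.v_av)


def fr_estimates(stats: BinWorkStats, thermo: Thermo | None = None) -> BinEstimates:
    """Forward-reverse estimator: ΔF and ⟨W_d⟩ from plain directional means.

    Bins missing samples in either direction are flagged, never zeroed.
    """
    n = stats.n_bins
    dF = np.full(n, np.nan)
    dF_se = np.full(n, np.nan)
    Wd = np.full(n, np.nan)
    Wd_se = np.full(n, np.nan)
    for b in range(n):
        wf = stats.complete_works("F", b)
        wr = stats.complete_works("R", b)
        if len(wf) == 0 or len(wr) == 0:
            continue
        mF, mR = float(np.mean(wf)), float(np.mean(wr))
        sF, sR = _se(wf), _se(wr)
        dF[b] = 0.5 * (mF - mR)
        Wd[b] = 0.5 * (mF + mR)
        se = 0.5 * np.sqrt(sF ** 2 + sR ** 2)
        dF_se[b] = se
        Wd_se[b] = se
    return BinEstimates(bin_edges=stats.bin_edges.copy(), dF=dF, dF_se=dF_se,
                        Wd=Wd, Wd_se=Wd_se, method="FR")


def bdfdt_estimate(stats: BinWorkStats, thermo: Thermo | None = None) -> BinEstimates:
    """BD-FDT estimator: ΔF from Boltzmann-weighted half-work exponential averages.

    ΔF = −k_B·T·ln(⟨e^{−βW_F/2}⟩/⟨e^{−βW_R/2}⟩); the dissipative work is taken
    from the plain means as in the FR estimator (the BD-FDT only re-estimates
    the free energy).
    """
    th = thermo or stats.thermo
    kBT, b2 = th.kBT, th.beta / 2.0
    n = stats.n_bins
    dF = np.full(n, np.nan)
    dF_se = np.full(n, np.nan)
    Wd = np.full(n, np.nan)
    Wd_se = np.full(n, np.nan)
    for b in range(n):
        wf = stats.complete_works("F", b)
        wr = stats.complete_works("R", b)
        if len(wf) == 0 or len(wr) == 0:
            continue
        ef = np.exp(-b2 * wf)
        er = np.exp(-b2 * wr)
        mf, mr = float(np.mean(ef)), float(np.mean(er))
        if not (np.isfinite(mf) and np.isfinite(mr)) or mf <= 0 or mr <= 0:
            continue
        dF[b] = -kBT * np.log(mf / mr)
        dF_se[b] = kBT * np.sqrt((_se(ef) / mf) ** 2 + (_se(er) / mr) ** 2)
        mF, mR = float(np.mean(wf)), float(np.mean(wr))
        Wd[b] = 0.5 * (mF + mR)
        Wd_se[b] = 0.5 * np.sqrt(_se(wf) ** 2 + _se(wr) ** 2)
    return BinEstimates(bin_edges=stats.bin_edges.copy(), dF=dF, dF_se=dF_se,
                        Wd=Wd, Wd_se=Wd_se, method="BDFDT")


def combine_runs(per_run: list[BinEstimates]) -> BinEstimates:
    """Inverse-variance weighted per-bin combination of independent runs.

    Combination happens per bin, prior to any integration.  A bin missing in a
    run simply does not contribute there; a bin missing everywhere stays
    flagged.
    """
    if not per_run:
        raise ValueError("no runs to combine")
    first = per_run[0]
    for est in per_run[1:]:
        if est.bin_edges.shape != first.bin_edges.shape or \
                not np.allclose(est.bin_edges, first.bin_edges):
            raise ValueError("bin grids differ between runs")
        if est.method != first.method:
            raise ValueError("cannot combine estimates from different methods")

    def weighted(vals, ses):
        vals = np.asarray(vals)
        ses = np.asarray(ses)
        ok = np.isfinite(vals) & np.isfinite(ses) & (ses >= 0)
        w = np.zeros_like(ses)
        w[ok] = 1.0 / np.maximum(ses[ok], 1e-300) ** 2
        wsum = w.sum()
        if wsum == 0:
            return np.nan, np.nan
        return float(np.sum(w * np.where(ok, vals, 0.0)) / wsum), float(1.0 / np.sqrt(wsum))

    n = first.bin_edges.size - 1
    dF = np.full(n, np.nan)
    dF_se = np.full(n, np.nan)
    Wd = np.full(n, np.nan)
    Wd_se = np.full(n, np.nan)
    for b in range(n):
        dF[b], dF_se[b] = weighted([e.dF[b] for e in per_run], [e.dF_se[b] for e in per_run])
        Wd[b], Wd_se[b] = weighted([e.Wd[b] for e in per_run], [e.Wd_se[b] for e in per_run])
    return BinEstimates(bin_edges=first.bin_edges.copy(), dF=dF, dF_se=dF_se,
                        Wd=Wd, Wd_se=Wd_se, method=first.method)


def integrate_pmf(bins: BinEstimates, reference_z: float) -> Profile1D:
    """Bidirectional cumulative integration of per-bin ΔF to the PMF w(z).

    The left-to-right and right-to-left integrals of the same combined bin
    increments coincide pointwise; their uncertainties do not (each grows in
    its direction of integration), and the reported per-point uncertainty is
    the average of the two.  The profile lives on the bin edges and is shifted
    so that w(reference_z) = 0.
    """
    ok = np.isfinite(bins.dF)
    if not ok.any():
        raise ValueError("no usable bins")
    first, last = np.argmax(ok), len(ok) - 1 - np.argmax(ok[::-1])
    interior = np.arange(first, last + 1)
    gaps = interior[~ok[interior]]
    if gaps.size:
        centers = bins.bin_centers[gaps]
        raise ValueError(f"missing interior bins at z = {np.round(centers, 3).tolist()}")

    dF = bins.dF[first:last + 1]
    var = bins.dF_se[first:last + 1] ** 2
    edges = bins.bin_edges[first:last + 2]
    w = np.concatenate(([0.0], np.cumsum(dF)))
    se_left = np.sqrt(np.concatenate(([0.0], np.cumsum(var))))
    se_right = np.sqrt(np.concatenate((np.cumsum(var[::-1])[::-1], [0.0])))
    se = 0.5 * (se_left + se_right)

    if reference_z < edges[0] - 1e-9 or reference_z > edges[-1] + 1e-9:
        raise ValueError(f"reference z = {reference_z} outside PMF support "
                         f"[{edges[0]}, {edges[-1]}]")
    w0 = np.interp(reference_z, edges, w)
    return Profile1D(z=edges, value=w - w0, stderr=se, role="pmf")


def diffusion_profile(bins: BinEstimates, stats: BinWorkStats,
                      thermo: Thermo, window: int = 9) -> Profile1D:
    """Invert the per-bin dissipative work to D(z) with a 9-point moving average.

    The local relation d⟨W_d⟩/dz = k_B·T·v/D(z) gives, per complete crossing,
    ⟨W_d⟩ = k_B·T·⟨v̄_c·ℓ_c⟩/D.  The moving average (``window`` points, default
    9, shrinking symmetrically at the edges) is applied to the dissipation and
    its speed-length normalization *before* the reciprocal is taken:
    D = k_B·T·MA(⟨v̄_c·ℓ_c⟩)/MA(⟨W_d⟩).  Averaging first keeps the reciprocal
    well conditioned in weakly dissipating (high-D) bins, where inverting the
    raw per-bin ⟨W_d⟩ and then averaging would inflate D through the convexity
    of 1/x.  Bins touched only near protocol turning points (v̄ < 0.05·v_av)
    and bins with non-positive smoothed dissipation are flagged missing, not
    clipped, and are dropped from the output grid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if bins.bin_edges.shape != stats.bin_edges.shape or \
            not np.allclose(bins.bin_edges, stats.bin_edges):
        raise ValueError("estimates and stats are on different bin grids")
    vbar = stats.mean_crossing_speed()
    vlen = stats.mean_speed_length()
    valid = np.isfinite(bins.Wd) & np.isfinite(vlen) & np.isfinite(vbar) & \
        (vbar >= TURNING_POINT_SPEED_FRACTION * stats.v_av)

    half = window // 2
    n = stats.n_bins
    kBT = thermo.kBT
    D_sm = np.full(n, np.nan)
    se_sm = np.full(n, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = valid[lo:hi]
        wd = bins.Wd[lo:hi][sel]
        wd_se = bins.Wd_se[lo:hi][sel]
        vl = vlen[lo:hi][sel]
        wd_mean = wd.mean()
        if wd_mean <= 0:
            continue
        D_sm[i] = kBT * vl.mean() / wd_mean
        # windowed bins are independent estimates; first-order error on 1/MA(Wd)
        se_sm[i] = D_sm[i] * np.sqrt(np.sum(wd_se ** 2)) / (sel.sum() * wd_mean)
    keep = np.isfinite(D_sm) & (D_sm > 0)
    if not keep.any():
        raise ValueError("no bins survive the diffusion inversion")
    return Profile1D(z=stats.bin_centers[keep], value=D_sm[keep],
                     stderr=se_sm[keep], role="diffusion")
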