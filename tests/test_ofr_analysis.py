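"""Work binning, the FR and BD-FDT estimators, run combination and inversion.

The synthetic double-well fixtures provide exact ground truth: per-bin
free-energy increments from the true PMF spline, dissipation from
k_B·T·v/D(z), and Gaussian work fluctuations of variance 2·k_B·T·⟨W_d⟩.
"""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from permeate.core import Thermo
from permeate.ofr_analysis import (BinEstimates, BinWorkStats, autocorr_time,
                                   bdfdt_estimate, bin_work, combine_runs,
                                   diffusion_profile, fr_estimates,
                                   integrate_pmf, merge_stats)
from permeate.pipeline import analyze_trajectories
from permeate.steer_sim import (SimConfig, WorkTrajectory, make_protocol,
                                protocol_position)

from conftest import DRIFT_RANGE, true_pmf_on


def drift_trajectory(f_const=1.5, L=1.0, v=1.0, dt=1e-3, thermo=None):
    """Constant-force pure-drift trajectory for arithmetic checks."""
    th = thermo or Thermo(310.0)
    proto = make_protocol(z0=0.0, v_d=v, A=0.0, n=1)
    t = np.arange(int(round(L / v / dt)) + 1) * dt
    z = protocol_position(proto, t)
    f = np.full(t.size - 1, f_const)
    return WorkTrajectory(t=t, z=z, f_applied=f, dW=f * np.diff(z),
                          run_id="drift", protocol=proto, thermo=th)


class TestBinWork:
    def test_constant_force_single_pass_gives_f_times_binwidth(self):
        traj = drift_trajectory(f_const=1.5, L=1.0)
        stats = bin_work(traj, bin_width=0.2)
        for b in range(stats.n_bins):
            wf = stats.W_F_samples[b]
            if stats.complete("F", b).any():
                assert wf[stats.complete("F", b)][0] == pytest.approx(1.5 * 0.2)

    def test_pure_drift_has_no_reverse_samples(self):
        stats = bin_work(drift_trajectory(), bin_width=0.2)
        assert all(len(w) == 0 for w in stats.W_R_samples)

    def test_every_increment_lands_in_exactly_one_sample(self, dw_trajectories):
        traj = dw_trajectories[0]
        stats = bin_work(traj, bin_width=0.2)
        total_binned = sum(np.sum(w) for w in stats.W_F_samples) + \
            sum(np.sum(w) for w in stats.W_R_samples)
        assert total_binned == pytest.approx(traj.total_work, abs=1e-9)

    def test_forward_reverse_counts_balance_in_interior(self, dw_trajectories):
        stats = bin_work(dw_trajectories[0], bin_width=0.2)
        nf, nr = stats.counts()
        centers = stats.bin_centers
        interior = (centers > DRIFT_RANGE[0]) & (centers < DRIFT_RANGE[1])
        assert np.all(np.abs(nf[interior] - nr[interior]) <= 1)

    def test_ofr_sweep_collects_many_samples_per_interior_bin(self, dw_trajectories):
        stats = bin_work(dw_trajectories[0], bin_width=0.2)
        nf, nr = stats.counts()
        centers = stats.bin_centers
        core = (centers > -2.0) & (centers < 2.0)
        # one crossing per direction per oscillation dwelling on the bin: ~n
        assert nf[core].min() >= 30
        assert nr[core].min() >= 30

    def test_invalid_bin_width_rejected(self, dw_trajectories):
        with pytest.raises(ValueError):
            bin_work(dw_trajectories[0], bin_width=0.0)


class TestFREstimates:
    def test_arithmetic_of_forward_reverse_means(self):
        """⟨W_F⟩ = 3, ⟨W_R⟩ = −1 → ΔF = 2, ⟨W_d⟩ = 1."""
        edges = np.array([0.0, 0.2])
        stats = BinWorkStats(bin_edges=edges,
                             W_F_samples=[np.array([3.0, 3.0])],
                             W_R_samples=[np.array([-1.0, -1.0])],
                             lengths_F=[np.array([0.2, 0.2])],
                             lengths_R=[np.array([0.2, 0.2])],
                             speeds_F=[np.array([1.0, 1.0])],
                             speeds_R=[np.array([1.0, 1.0])],
                             thermo=Thermo(310.0), v_av=1.0)
        est = fr_estimates(stats)
        assert est.dF[0] == pytest.approx(2.0)
        assert est.Wd[0] == pytest.approx(1.0)

    def test_reversible_limit_has_zero_dissipation(self):
        edges = np.array([0.0, 0.2])
        stats = BinWorkStats(bin_edges=edges,
                             W_F_samples=[np.array([0.7, 0.7])],
                             W_R_samples=[np.array([-0.7, -0.7])],
                             lengths_F=[np.array([0.2, 0.2])],
                             lengths_R=[np.array([0.2, 0.2])],
                             speeds_F=[np.array([1.0, 1.0])],
                             speeds_R=[np.array([1.0, 1.0])],
                             thermo=Thermo(310.0), v_av=1.0)
        est = fr_estimates(stats)
        assert est.Wd[0] == pytest.approx(0.0, abs=1e-12)
        assert est.dF[0] == pytest.approx(0.7)

    def test_missing_direction_flagged_not_zeroed(self):
        stats = bin_work(drift_trajectory(), bin_width=0.2)  # no reverse samples
        est = fr_estimates(stats)
        assert np.all(~np.isfinite(est.dF))
        assert np.all(est.missing)

    def test_fr_identity_holds_per_bin(self, dw_trajectories):
        stats = bin_work(dw_trajectories[0], bin_width=0.2)
        est = fr_estimates(stats)
        for b in range(stats.n_bins):
            wf = stats.complete_works("F", b)
            wr = stats.complete_works("R", b)
            if len(wf) and len(wr):
                assert est.dF[b] + est.Wd[b] == pytest.approx(np.mean(wf), abs=1e-12)
                assert est.Wd[b] - est.dF[b] == pytest.approx(np.mean(wr), abs=1e-12)

    def test_per_bin_dF_matches_truth_within_2se(self, dw_trajectories, dw_truth):
        pmf_true, _ = dw_truth
        spl = CubicSpline(pmf_true.z, pmf_true.value)
        per_run = [fr_estimates(bin_work(t, 0.2)) for t in dw_trajectories]
        comb = combine_runs(per_run)
        dF_true = spl(comb.bin_edges[1:]) - spl(comb.bin_edges[:-1])
        centers = comb.bin_centers
        m = (centers > DRIFT_RANGE[0]) & (centers < DRIFT_RANGE[1])
        zscore = np.abs(comb.dF[m] - dF_true[m]) / comb.dF_se[m]
        # individual 2-se excursions happen; the bulk must be consistent
        assert np.mean(zscore < 2.0) > 0.9
        assert zscore.max() < 4.0


class TestBDFDT:
    def test_single_antisymmetric_samples_cancel_exactly(self, thermo):
        edges = np.array([0.0, 0.2])
        w = 0.9
        stats = BinWorkStats(bin_edges=edges,
                             W_F_samples=[np.array([w, w])],
                             W_R_samples=[np.array([-w, -w])],
                             lengths_F=[np.array([0.2, 0.2])],
                             lengths_R=[np.array([0.2, 0.2])],
                             speeds_F=[np.array([1.0, 1.0])],
                             speeds_R=[np.array([1.0, 1.0])],
                             thermo=thermo, v_av=1.0)
        est = bdfdt_estimate(stats)
        assert est.dF[0] == pytest.approx(w, abs=1e-12)

    def test_translation_covariance(self, thermo):
        """Shifting W_F by +c and W_R by −c shifts ΔF by exactly c."""
        rng = np.random.default_rng(8)
        wf = rng.normal(1.0, 0.3, 40)
        wr = rng.normal(-0.6, 0.3, 40)
        c = 0.35

        def est(wf, wr):
            stats = BinWorkStats(bin_edges=np.array([0.0, 0.2]),
                                 W_F_samples=[wf], W_R_samples=[wr],
                                 lengths_F=[np.full(wf.size, 0.2)],
                                 lengths_R=[np.full(wr.size, 0.2)],
                                 speeds_F=[np.ones(wf.size)],
                                 speeds_R=[np.ones(wr.size)],
                                 thermo=thermo, v_av=1.0)
            return bdfdt_estimate(stats).dF[0]

        assert est(wf + c, wr - c) == pytest.approx(est(wf, wr) + c, abs=1e-10)

    def test_agrees_with_fr_for_gaussian_work(self, thermo):
        """Gaussian work with Var = 2·k_B·T·⟨W_d⟩ satisfies both estimators."""
        rng = np.random.default_rng(12)
        dF_true, Wd = 0.4, 0.3
        sd = np.sqrt(2 * thermo.kBT * Wd)
        wf = rng.normal(dF_true + Wd, sd, 4000)
        wr = rng.normal(-dF_true + Wd, sd, 4000)
        stats = BinWorkStats(bin_edges=np.array([0.0, 0.2]),
                             W_F_samples=[wf], W_R_samples=[wr],
                             lengths_F=[np.full(wf.size, 0.2)],
                             lengths_R=[np.full(wr.size, 0.2)],
                             speeds_F=[np.ones(wf.size)],
                             speeds_R=[np.ones(wr.size)],
                             thermo=thermo, v_av=1.0)
        fr = fr_estimates(stats)
        bd = bdfdt_estimate(stats)
        comb_se = np.sqrt(fr.dF_se[0] ** 2 + bd.dF_se[0] ** 2)
        assert abs(bd.dF[0] - fr.dF[0]) < 2 * comb_se
        assert bd.dF[0] == pytest.approx(dF_true, abs=3 * bd.dF_se[0])


class TestCombineRuns:
    def _mk(self, dF, se):
        n = len(dF)
        edges = np.arange(n + 1) * 0.2
        dF = np.asarray(dF, float)
        se = np.asarray(se, float)
        return BinEstimates(bin_edges=edges, dF=dF, dF_se=se,
                            Wd=np.abs(dF), Wd_se=se, method="FR")

    def test_equal_errors_give_plain_average_and_root2_reduction(self):
        a = self._mk([1.0, 2.0], [0.2, 0.2])
        b = self._mk([3.0, 0.0], [0.2, 0.2])
        c = combine_runs([a, b])
        assert np.allclose(c.dF, [2.0, 1.0])
        assert np.allclose(c.dF_se, 0.2 / np.sqrt(2))

    def test_infinite_error_run_is_ignored(self):
        a = self._mk([1.0], [0.1])
        b = self._mk([99.0], [np.inf])
        c = combine_runs([a, b])
        assert c.dF[0] == pytest.approx(1.0)
        assert c.dF_se[0] == pytest.approx(0.1)

    def test_grid_mismatch_rejected(self):
        a = self._mk([1.0, 2.0], [0.1, 0.1])
        b = self._mk([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            combine_runs([a, b])

    def test_doubling_runs_shrinks_se_by_root2(self, dw_trajectories):
        per_run = [fr_estimates(bin_work(t, 0.2)) for t in dw_trajectories]
        se3 = np.nanmean(combine_runs(per_run[:3]).dF_se)
        se6 = np.nanmean(combine_runs(per_run).dF_se)
        assert se3 / se6 == pytest.approx(np.sqrt(2), rel=0.15)

    def test_reported_se_matches_run_scatter(self, dw_trajectories):
        """Calibration: per-run scatter is consistent with the claimed errors."""
        per_run = [fr_estimates(bin_work(t, 0.2)) for t in dw_trajectories]
        comb = combine_runs(per_run)
        centers = comb.bin_centers
        m = (centers > DRIFT_RANGE[0]) & (centers < DRIFT_RANGE[1])
        z2 = []
        for b in np.flatnonzero(m):
            vals = np.array([e.dF[b] for e in per_run])
            ses = np.array([e.dF_se[b] for e in per_run])
            ok = np.isfinite(vals)
            if ok.sum() == 6:
                z2.extend(((vals - comb.dF[b]) / ses)[ok] ** 2)
        assert 0.5 < np.mean(z2) < 1.8


class TestIntegratePMF:
    def test_constant_increment_integrates_to_linear_ramp(self):
        n = 10
        est = BinEstimates(bin_edges=np.arange(n + 1) * 0.2,
                           dF=np.full(n, 0.3), dF_se=np.full(n, 0.05),
                           Wd=np.zeros(n), Wd_se=np.zeros(n), method="FR")
        pmf = integrate_pmf(est, reference_z=0.0)
        assert np.allclose(pmf.value, 0.3 * np.arange(n + 1))

    def test_reference_shift(self):
        n = 4
        est = BinEstimates(bin_edges=np.arange(n + 1) * 1.0,
                           dF=np.ones(n), dF_se=np.full(n, 0.1),
                           Wd=np.zeros(n), Wd_se=np.zeros(n), method="FR")
        pmf = integrate_pmf(est, reference_z=2.0)
        assert pmf.value[2] == pytest.approx(0.0)

    def test_uncertainty_is_average_of_directional_integrals(self):
        n = 4
        est = BinEstimates(bin_edges=np.arange(n + 1) * 1.0,
                           dF=np.ones(n), dF_se=np.full(n, 0.1),
                           Wd=np.zeros(n), Wd_se=np.zeros(n), method="FR")
        pmf = integrate_pmf(est, reference_z=0.0)
        left = 0.1 * np.sqrt(np.arange(n + 1))
        right = 0.1 * np.sqrt(np.arange(n, -1, -1))
        assert np.allclose(pmf.stderr, 0.5 * (left + right))

    def test_missing_interior_bins_reported(self):
        n = 5
        dF = np.array([0.1, np.nan, 0.1, 0.1, 0.1])
        est = BinEstimates(bin_edges=np.arange(n + 1) * 1.0,
                           dF=dF, dF_se=np.full(n, 0.1),
                           Wd=np.zeros(n), Wd_se=np.zeros(n), method="FR")
        with pytest.raises(ValueError, match="missing interior"):
            integrate_pmf(est, reference_z=0.0)

    def test_recovers_true_double_well(self, dw_trajectories, dw_truth):
        pmf_true, _ = dw_truth
        for estimator in ("fr", "bdfdt"):
            pmf, _, _, _ = analyze_trajectories(dw_trajectories,
                                                reference_z=DRIFT_RANGE[0],
                                                estimator=estimator)
            m = (pmf.z >= DRIFT_RANGE[0]) & (pmf.z <= DRIFT_RANGE[1])
            wt = true_pmf_on(pmf.z[m], pmf_true, DRIFT_RANGE[0])
            assert np.abs(pmf.value[m] - wt).max() < 0.3


class TestDiffusionProfile:
    def test_exact_inversion_of_constant_dissipation(self, thermo):
        """Noiseless ⟨W_d⟩ = k_B·T·v̄·Δz/D0 in every bin inverts to exactly D0."""
        n, D0, v = 20, 7.0, 50.0
        dz = 0.2
        wd = thermo.kBT * v * dz / D0
        edges = np.arange(n + 1) * dz
        ones = [np.full(3, v) for _ in range(n)]
        lens = [np.full(3, dz) for _ in range(n)]
        stats = BinWorkStats(bin_edges=edges,
                             W_F_samples=[np.full(3, wd) for _ in range(n)],
                             W_R_samples=[np.full(3, wd) for _ in range(n)],
                             lengths_F=lens, lengths_R=[l.copy() for l in lens],
                             speeds_F=ones, speeds_R=[o.copy() for o in ones],
                             thermo=thermo, v_av=v)
        est = fr_estimates(stats)
        for window in (1, 9):
            prof = diffusion_profile(est, stats, thermo, window=window)
            assert np.allclose(prof.value, D0)

    def test_even_window_rejected(self, thermo, dw_diffusion_trajectories):
        stats = bin_work(dw_diffusion_trajectories[0], 0.2)
        est = fr_estimates(stats)
        with pytest.raises(ValueError):
            diffusion_profile(est, stats, thermo, window=4)

    def test_recovers_threefold_diffusion_contrast(self, thermo,
                                                   dw_diffusion_trajectories,
                                                   dw_truth):
        _, diff_true = dw_truth
        _, diff, _, _ = analyze_trajectories(dw_diffusion_trajectories,
                                             reference_z=DRIFT_RANGE[0],
                                             estimator="fr")
        m = (diff.z >= DRIFT_RANGE[0]) & (diff.z <= DRIFT_RANGE[1])
        Dt = np.interp(diff.z[m], diff_true.z, diff_true.value)
        rel = np.abs(diff.value[m] - Dt) / Dt
        assert rel.max() < 0.15


class TestAutocorrTime:
    def test_uncorrelated_series_has_negligible_tau(self):
        x = np.random.default_rng(5).normal(size=4000)
        assert autocorr_time(x) < 0.2

    def test_ar1_series_matches_closed_form(self):
        rng = np.random.default_rng(6)
        phi = 0.6
        x = np.empty(60_000)
        x[0] = 0.0
        eps = rng.normal(size=x.size)
        for k in range(1, x.size):
            x[k] = phi * x[k - 1] + eps[k]
        # for AR(1), tau_int = phi/(1−phi)
        assert autocorr_time(x) == pytest.approx(phi / (1 - phi), rel=0.2)


class TestEstimatorConsistency:
    def test_fr_and_bdfdt_pmfs_agree_within_2se(self, dw_trajectories):
        pmf_fr, _, _, _ = analyze_trajectories(dw_trajectories,
                                               reference_z=DRIFT_RANGE[0],
                                               estimator="fr")
        pmf_bd, _, _, _ = analyze_trajectories(dw_trajectories,
                                               reference_z=DRIFT_RANGE[0],
                                               estimator="bdfdt")
        assert np.allclose(pmf_fr.z, pmf_bd.z)
        comb_se = np.sqrt(pmf_fr.stderr ** 2 + pmf_bd.stderr ** 2)
        dev = np.abs(pmf_fr.value - pmf_bd.value)
        assert np.all(dev <= 2 * np.maximum(comb_se, 1e-12))

    def test_merge_stats_pools_samples(self, dw_trajectories):
        stats = [bin_work(t, 0.2) for t in dw_trajectories[:2]]
        pooled = merge_stats(stats)
        nf0, _ = stats[0].counts()
        nf1, _ = stats[1].counts()
        nfp, _ = pooled.counts()
        assert np.array_equal(nfp, nf0 + nf1)
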