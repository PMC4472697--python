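# Methods

## The model

The package treats passive membrane permeation in the inhomogeneous
solubility-diffusion (ISD) approximation: a solute crossing a bilayer of
width L experiences a potential of mean force w(z) and a local diffusion
coefficient D(z) along the membrane normal, and the steady-state permeability
is P = [∫ e^{βw(z)}/D(z) dz]⁻¹. The model assumes the lateral degrees of
freedom equilibrate fast relative to motion along z, that a 1-D Smoluchowski
description holds locally, and that the membrane is symmetric (profiles over
one leaflet are doubled in resistance before inversion).

Profiles come from nonequilibrium pulling. In the dynamic constraint protocol
the steered coordinate follows an oscillating drift path
z_COM(t) = z₀ + v_d·t + A·sin(ωt) with ω = π·n·v_d/A, so a single traversal
yields forward and reverse work samples in every spatial bin. Below the
critical speed the mean dissipated work is linear in the pulling speed,
d⟨W_d⟩/dz = k_B·T·v/D(z), which is what licenses both the forward-reverse
free-energy estimators and the dissipation→diffusion inversion.

## The synthetic engine and what it does (not) emulate

`steer_sim` integrates overdamped Langevin dynamics with the steered
coordinate rigidly constrained to the protocol path. The applied force is
read off the force balance f_c = γ(z)·ż − F(z) − ξ with γ(z) = k_B·T/D(z),
F = −dw/dz (derivative of a cubic-spline interpolant of the tabulated truth)
and thermal force ξ ~ N(0, 2γ(z)k_B·T/Δt), γ evaluated at the position at
step start. Because the coordinate has no free dynamics there is no
Itô/Stratonovich ambiguity and no spurious-drift term; work statistics are
exactly Gaussian with ⟨W⟩ = ΔF + ⟨W_d⟩ and Var(W) = 2k_B·T·⟨W_d⟩, so every
estimator downstream has a closed-form oracle.

What the generator deliberately does **not** emulate: lateral diffusion and
lipid-solute coupling, memory (non-Markovian friction), finite-stiffness
restraints, barostats/thermostats, or any chemistry. Passing recovery tests
therefore demonstrates the correctness of the estimators under the model in
which they are derived — not that a particular force field or sampling time
suffices for a real bilayer.

The default time step resolves a quarter bin at peak protocol speed
(Δt = bin_width/4/max|ż|), so no bin crossing is ever skipped.

## Binning and estimation conventions

* **Bins.** 0.2 Å spatial bins aligned to multiples of the width. Each
  per-step work increment is assigned to exactly one (bin, direction) by the
  sign of the displacement, split proportionally at bin edges; an increment
  spanning a velocity sign change is split at the extremum at sampling
  resolution. Total work is conserved exactly.
* **Complete crossings.** Fragments shorter than 0.9 bin widths (created when
  a protocol turning point falls inside a bin) stay in the sample record but
  are excluded from the per-bin means: a fragment samples only part of the
  bin and, because the path is shared by all runs, its bias does not average
  out. With fragments included, a deterministic per-bin bias of ~0.01
  kcal/mol (verified against a zero-noise trajectory) accumulated to ~0.1
  kcal/mol in the integrated PMF.
* **Estimators.** FR: ΔF = (⟨W_F⟩ − ⟨W_R⟩)/2, ⟨W_d⟩ = (⟨W_F⟩ + ⟨W_R⟩)/2.
  BD-FDT: ΔF = −k_B·T·ln(⟨e^{−βW_F/2}⟩/⟨e^{−βW_R/2}⟩) — the logarithm makes
  the estimator dimensionally consistent and reduces to the Gaussian-work
  result; dissipation always comes from the plain means.
* **Uncertainties.** Standard errors are autocorrelation-corrected per bin
  with N_eff = N/(1 + 2τ_int), τ_int by the initial-positive-sequence rule.
  Cross-bin correlations are not modelled; the run-scatter calibration test
  checks the resulting coverage empirically.
* **Run combination.** Runs are combined per bin by inverse-variance
  weighting *before* integration. The PMF is the cumulative sum of combined
  increments; the left-to-right and right-to-left integrals coincide in
  value, and the reported per-point uncertainty is the average of the two
  directional uncertainty profiles (conservative, flat error bars). The
  profile is zeroed at a user reference z.
* **Diffusion inversion.** Per bin, D = k_B·T·MA(⟨v̄_c·ℓ_c⟩)/MA(⟨W_d⟩): the
  9-point centered moving average (edges shrink symmetrically) is applied to
  the dissipation and its speed×length normalization *before* the
  reciprocal. Inverting raw per-bin ⟨W_d⟩ first and averaging afterwards
  inflates D in weakly dissipating bins by ≈(se/W_d)² through the convexity
  of 1/x; averaging first is the well-conditioned equivalent on smooth
  profiles. Crossing speeds v̄_c come from the analytic protocol derivative
  (the constraint makes ż exact), length-weighted within each crossing; the
  ⟨v̄_c·ℓ_c⟩ form equals v̄·Δz for complete crossings and stays unbiased for
  near-complete ones. Bins with mean crossing speed below 0.05·v_av
  (turning-point bins) or non-positive smoothed dissipation are flagged
  missing, never clipped, and are excluded from D(z) only — not from the PMF.

## Permeability and mixing

The resistivity R(z) = e^{βw}/D is integrated by the trapezoid rule on the
native grid (profiles are already binned and smoothed; higher-order rules add
nothing on noisy data). The P uncertainty is Monte-Carlo: profiles are
resampled pointwise from independent Gaussians with their standard errors
(10⁴ draws, fixed seed) and the standard deviation of the resampled P is
reported — the exponential makes the delta method unreliable for barriers of
several k_B·T. For symmetric full-bilayer profiles the estimated PMF is
anchored to the mean of its two bulk plateaus before the integral; one-sided
referencing doubles the barrier-error variance accumulated by the
integration.

Species mixing: slow interconversion P = Σ f_i·P_i; fast interconversion
1/P = ∫dz[Σ f_i e^{−βw_i}D_i]⁻¹ (local equilibrium, resistors in parallel);
minimum-resistance uses min_i e^{β(w_i+Δw_i(0))}/D_i pointwise. Bulk
fractions follow Henderson-Hasselbalch; the offset Δw(0) = 2.3·k_B·T·(pKa−pH)
uses the conventional 2.3 (≈ ln 10, so population identities hold to ~0.26%
per pKa unit). The zwitterion channel in the (pKa1, f_zw) surface is capped
at the protonated species' permeability, per the generalized-Born bound that
a dipole wider than the ion-pair minimum transfers at least as unfavourably
as the bare cation; the surface uses the slow model, which is closed-form in
the fractions and indistinguishable from the others in the
barrier-dominated regime.

## Rotational relaxation and convergence diagnostic

c_r(t) = ⟨r̂(t)·r̂(0)⟩ is lag-averaged over all origins (FFT per component);
τ_r integrates c_r by trapezoid to its first zero crossing (linearly
interpolated), falling back to the flagged full-window integral when no
crossing exists. The validation oracle is isotropic rotational diffusion
(first-rank decay e^{−2D_r t}, τ_r = 1/(2D_r)), simulated as a tangent-kick
random walk with per-step variance 2D_r·Δt per perpendicular direction and
renormalization (requires D_r·Δt ≤ 0.1; the scheme carries an O(D_r·Δt)
rate bias). Single-trace τ_r estimates at the 117 ps scale scatter 10–30%
over a 100 ns window because the zero-crossing truncation integrates long-lag
ACF noise; validation therefore ensemble-averages the ACF over 16 independent
rotors — the standard equivalent of averaging over molecules.

The convergence diagnostic updates, per bin, a flat prior over a candidate
mean grid (resolution 10⁻⁴ kcal/mol, span samples ± 5·max se) with one
Gaussian likelihood per run and records the posterior mode after each update;
with equal errors the mode is the running mean, and the final posterior is
order-invariant. ⟨Δμ_bin⟩(N), averaged over every fifth bin, is fit as
c·N^{−x} by log-log least squares with optional outlier exclusion. For iid
inputs the running-mean law gives |Δμ(N)| ∝ √(N/(N−1))/N, whose fitted
exponent approaches 1 from above as N grows; the iid control therefore uses
30 updates over 250 bins, where the fitted exponent sits near 1.05–1.12.

## Fixture design

The recovery fixture is a double-well landscape (2 kcal/mol central barrier,
1.2 kcal/mol wells at ±2 Å) with D(z) = 60 − 40·e^{−(z/3.2)²} Å²/ns (3×
contrast), steered over a 9 Å drift span with A = 2.5 Å, n = 50, six runs at
310 K. Two pulling speeds are bundled because the two recovery goals pull in
opposite directions: free-energy noise per bin grows as √(k_B·T·⟨W_d⟩) ∝ √v_d
(total path length, and hence cost, is independent of v_d), so the
free-energy fixture pulls at v_d = 0.15 Å/ns, while the diffusion inversion
needs ⟨W_d⟩ comfortably above its own standard error (relative error
∝ 1/√v_d), so the diffusion fixture pulls at v_d = 0.8 Å/ns. Both stay far
below any critical-speed scale. Recovery statements apply over the drift
span; the oscillation-overshoot wings beyond it are sampled only by slow,
fragmentary turning-point crossings and are reported but not guaranteed.
Problem sizes throughout (six runs of ~28 000 steps, 100 ns rotor ensembles,
10⁴ Monte-Carlo draws) were chosen so the statistical margins above hold
with room to spare at desk scale.

## Known limitations

* The uncertainty model corrects within-bin autocorrelation only; strongly
  correlated adjacent bins would make the reported PMF errors optimistic.
* The inverse-variance run combination uses estimated variances; with few
  crossings per run and bin, weight-estimation noise couples to the values
  (variance and dissipation are physically linked), biasing combined
  dissipation slightly low. This is visible only in sparsely sampled bins.
* Preset landscapes are smooth analytic stand-ins carrying scalar features
  (barrier heights, bulk extents, diffusion magnitudes) of real
  bilayer-permeant systems; they are not digitized curves, and quantities
  that depend on the true curve shapes cannot be reproduced from them.
* The mixing models take protonation-state populations as given; finite
  protonation/deprotonation kinetics (reaction-diffusion coupling) are out
  of scope.
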