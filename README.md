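# permeate

Membrane permeability coefficients from nonequilibrium steered trajectories.

Passive permeation of a solute across a lipid bilayer is governed, in the
inhomogeneous solubility-diffusion (ISD) picture, by two position-dependent
profiles along the bilayer normal z: the potential of mean force w(z) and the
local diffusion coefficient D(z) ≡ D_zz(z). The permeability coefficient is
the reciprocal of the integrated local resistivity,

    P = [ ∫₀ᴸ dz e^{βw(z)} / D(z) ]⁻¹ ,     β = 1/(k_B·T).

Both profiles can be harvested from a *single* class of steered simulations:
the oscillating forward-reverse (OFR) protocol drags the solute's z coordinate
rigidly along

    z_COM(t) = z₀ + v_d·t + A·sin(ωt),   ω = π·n·v_d/A,   v_av = 2·n·v_d,

so that every 0.2 Å bin is crossed many times in both directions. Per bin, the
forward-reverse estimators give the free-energy increment and the dissipated
work,

    ΔF = (⟨W_F⟩ − ⟨W_R⟩)/2,   ⟨W_d⟩ = (⟨W_F⟩ + ⟨W_R⟩)/2,

with the Boltzmann-weighted BD-FDT variant
ΔF = −k_B·T·ln(⟨e^{−βW_F/2}⟩/⟨e^{−βW_R/2}⟩) as the preferred free-energy
estimator; the dissipation inverts to the diffusion profile through
d⟨W_d⟩/dz = k_B·T·v/D(z). For weak bases that permeate as a mixture of
protonation states, the package composes species permeabilities under the
slow-interconversion, fast-interconversion (parallel-resistor) and
minimum-resistance approximations, with Henderson-Hasselbalch fractions and
the bulk PMF offset Δw(0) = 2.3·k_B·T·(pKa − pH). Supporting pieces cover the
generalized-Born pair-transfer argument, rotational relaxation times
τ_r = ∫c_r(t)dt, and a sequential-Bayesian convergence diagnostic for
multi-run averaging.

Because no public trajectory data accompany this class of steered-MD studies,
the package ships a constrained-Langevin engine (`permeate.steer_sim`) that
generates OFR work records over *known* w(z) and D(z), making every estimator
testable end to end — the identities ⟨W_F⟩ − ΔF = ⟨W_d⟩,
Var(W) = 2·k_B·T·⟨W_d⟩ and Eq-style dissipation linearity hold exactly in this
model. It is aimed at simulators who analyze steered bilayer-permeation runs
and want the full work-to-permeability route, with honest uncertainties, in
one tested toolchain.

## Worked example

Simulate six OFR pulls across a double-well landscape, estimate both
profiles, and compute the permeability:

```
$ permeate demo --kind double_well --out demo/
demo config → demo/double_well_config.json
$ permeate run --config demo/double_well_config.json --out demo/out
```

or, through the analysis drivers (which also compare against the known truth):

```
$ python analysis/01_simulate_fixtures.py
slow pull: v_d = 0.15 Å/ns, v_av = 15.0 Å/ns, 6 runs × 28454 steps ...
$ python analysis/02_estimate_profiles.py
FR     PMF: max |ŵ − w_true| = 0.072 kcal/mol over the drift span (mean se 0.086)
BDFDT  PMF: max |ŵ − w_true| = 0.097 kcal/mol over the drift span (mean se 0.087)
D(z): max relative error = 7.0% after 9-point smoothing (3× true contrast, 20–60 Å²/ns)
$ python analysis/03_permeability.py
double-well: P_true = 9.97 cm/s, recovered = 9.61 ± 0.50 cm/s (3.6% off)
```

The recovered PMF tracks the true 2 kcal/mol barrier and ±1.2 kcal/mol wells
to within a tenth of a kcal/mol, the smoothed D(z) resolves its threefold
contrast to a few percent, and the ISD integral of the recovered profiles
reproduces the closed-form permeability of the truth within its Monte-Carlo
uncertainty.

The mixing layer reproduces the weak-base arithmetic directly from printed
constants:

```
$ python analysis/04_pka_mixing.py
slow/fast/minimum-resistance sweeps over pKa 9–11.7 agree within 3.0% ...
simulated and measured permeabilities cross at amine pKa = 11.35
```

With species permeabilities of 2×10⁻³ cm/s (uncharged) and 9×10⁻¹⁴ cm/s
(protonated) and a measured P = 2.26×10⁻⁷ cm/s at pH 7.4, the
slow-interconversion mixture matches experiment at an amine pKa of 11.35 —
the uncharged species, though a ~10⁻⁴ minority in bulk, carries essentially
all of the flux.

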