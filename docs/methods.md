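# Methods

## Scope and model overview

`frlap` models excitation energy transfer (EET) in the helical nanotube
formed by far-red-light allophycocyanin (FRL-AP).  The model chain is:

1. a **geometric lattice** of point chromophore sites generated from the
   helical symmetry (7 protomers per 720° repeat, 72.6 Å rise; one α-PCB
   and one β-PCB per protomer);
2. **Förster theory** on that lattice — direction-specific spectral
   overlap integrals, geometric κ² factors, R⁻⁶ distance dependence —
   giving a first-order rate matrix over all sites;
3. **master-equation dynamics** (eigendecomposition of the generator
   augmented with decay/trap sinks), with analytic trap yields and mean
   first-passage times (MFPT) from linear solves, cross-checked by
   Gillespie kinetic Monte Carlo;
4. **global kinetic analysis** of time-resolved data — sequential (EADS)
   and parallel (DADS) schemes under Gaussian-IRF reconvolution with
   variable projection, and Poisson-weighted TCSPC reconvolution —
   applied to synthetic datasets generated in-package.

## Lattice geometry

Chromophores are point dipole sites on two coaxial cylinders: β-PCBs on
the inner cylinder (radius 20.5 Å), α-PCBs outside (30.76 Å).  Published
"edge-to-edge" distances are approximated by centre distances minus a
4.5 Å bilin half-extent per chromophore (configurable).  The free
placement parameters (α radius, β azimuthal/axial offsets) are solved by
least squares (`scripts/calibrate_placement.py --resolve`) against three
centre-distance targets:

| pair | target | rationale |
|---|---|---|
| β(i)–α(i+1) | 21 Å | closest pair: 12 Å edge-to-edge |
| α(i)–β(i) (intra-protomer) | 34 Å | terminal isolation ≈ 35 Å |
| β(i)–α(i+4) | 26 Å | contact with the helical level below |

With the β radius at 20.5 Å, a single 35 Å centre-distance cutoff then
reproduces the structural subunit contact topology exactly — each
interior α touches β at protomer offsets {0, −1, −4}, each β touches β at
{±1} and α at {0, +1, +4} — with a 1.8 Å margin between the contact shell
and the next-nearest shell.  The unpaired chromophore at each end (an
α-PCB at the pair-deficient end, a β-PCB at the other) sits ~34 Å from
every other site, matching the reported ~35 Å terminal isolation.

Coordinates are right-handed Cartesian with the helix axis along z,
protomer 0 at z = 0; handedness defaults to right and is configurable
(the mirror image preserves every distance).

## Transition dipoles and spectra

Transition dipole **orientations** follow a declared geometric
convention: each dipole is specified in its site's local cylindrical
frame by a pitch angle (out of the tangent plane, toward the axis) and a
tilt angle (from the tangent toward the radial direction), per subunit
class.  Defaults: α (4°, 22°), β (150°, 30°).

**Lineshapes** are sums of Gaussians in wavenumber: a main band plus an
optional vibronic shoulder (and an optional red tail, off by default);
emission is the mirror of the main band displaced to the emission peak,
area-normalised.  α-PCB: absorption 709 nm (σ = 170 cm⁻¹,
ε_max = 2.5×10⁵ M⁻¹cm⁻¹) with a weak vibronic wing (+1900 cm⁻¹,
amplitude 0.14, σ = 550 cm⁻¹) and emission at 714 nm.  β-PCB: broad
absorption at 621 nm (σ = 550 cm⁻¹, ε_max = 1.2×10⁵) with a vibronic
shoulder, emission at 665 nm.  The composite band maximum is re-centred
on the nominal peak so the declared peak positions hold exactly.

Two of these quantities deserve emphasis because they act as
**calibration parameters rather than measurements**:

* the **β emission position** is not observable in the intact complex
  (transfer outruns β fluorescence).  It controls the ratio of
  J(β→α) to J(α→α)/J(β→β) and therefore the speed of α↔α migration and
  terminal-PCB escape *relative to* the main pair transfer.  The default
  665 nm is chosen so the calibrated network reproduces the measured
  slow constants (below);
* the **dipole angles** control the κ² pattern across the recurring pair
  geometries.  The tangential-only convention (pitch = tilt = 0) cannot
  make κ² small for the α–α channels at offsets ±1, ±3 and ±4
  simultaneously, which leaves α-layer migration about an order of
  magnitude too fast regardless of every other parameter; the two-angle
  convention can, and the defaults were selected on the calibration
  anchors, not fitted to any acceptance threshold.

The α vibronic wing also fixes the direct-α excitation fraction when
pumping at 580 nm (~7% of the initial excitation, the declared
convention for the "small population of directly excited α-PCBs").

## Rate matrix and calibration

Pair rates use the point-dipole Förster expressions with the overlap
integral in M⁻¹cm⁻¹nm⁴ and R₀ in Å (R₀⁶ = 8.79×10⁻⁵ κ² n⁻⁴ Φ_D J);
medium defaults n = 1.33, Φ_D = 0.5, τ_D = 1.5 ns.  Because the absolute
in-situ dipole strengths are unknown, every transfer rate carries one
dimensionless global prefactor.  Calibration (deterministic, re-run at
model construction):

1. build the 26-site rate matrix of the 13-protomer tube with 889 ps
   excited-state decay on every site;
2. excite the 13 β sites uniformly, propagate, fit the total β population
   with three exponentials (slowest fixed at 889 ps);
3. root-find the prefactor so the fitted fast component equals the
   measured 517 fs transfer time (Brent's method on log prefactor;
   the solved default is ≈ 0.78, i.e. close to the raw Förster value).

The remaining anchors are then *predictions* of the calibrated network:
terminal-PCB transfer 31.3 ps (measured 35.9 ps; reference simulation
39.7 ps), fast:slow amplitude ratio 11.7 (reported 12:1), end-to-end
MFPT 687 ps (reported ~600–800 ps).

## Trap, efficiency and migration

The irreversible trap attaches to the **isolated terminal α-PCB** (the
end that would face the IsiX/PSI acceptor), with rate equal to the
fastest β→α pair rate; both are configurable and a ×0.1–×10 trap-rate
sweep is always reported.  Trap yield is computed analytically as
η = k_trap·(−K)⁻¹p₀ summed over trap sites; the 26-PCB figure uses
uniform β excitation, the 13-PCB figure restricts the calibrated network
to the α sites with uniform excitation.  MFPT is the summed expected
residence time on the transfer-only generator with the opposite-end
terminal pair absorbing; the decay-off variant is the headline (the
decay-on variant is exposed via `include_decay=True`).

**Known limitation.**  With the α-sub-network reading of the 13-PCB
model, the per-start-site trap yields of the two models interlock
(η from β(i) ≈ η from α(i+1)), so the 26- and 13-PCB efficiencies can
differ by at most ~5 percentage points — the model class reproduces the
*direction* of the published 26-vs-13 contrast (52.4% vs 56.5% with the
default calibration) but not its full magnitude (<50% vs ~65%).  The
trap-rate sweep is nearly flat because trapping is entry-limited rather
than capture-limited.

## Global analysis

Component time profiles are built analytically:
IRF⊗exponential = ½·exp(σ²/2τ² − t′/τ)·erfc(σ/(τ√2) − t′/(σ√2)),
evaluated through the scaled complement erfcx where the plain form would
overflow, so τ ≫ σ is stable.  Sequential-scheme profiles are Bateman
cascades of these; EADS and DADS are two representations of one model
matrix related by the exact linear transform DADS = Bᵀ·EADS, where B is
the cascade coefficient matrix (repeated lifetimes are rejected as
degenerate).  Lifetimes are optimised in log space by trust-region least
squares with amplitudes solved linearly per wavelength at every step
(variable projection); five seeded multistarts guard against local
minima.  Points within 100 fs of time zero are excluded by default
(coherent-artifact window), and the sub-IRF 20 fs component is fixed
during fitting — it is not identifiable under the 96 fs IRF.

TCSPC histograms are fit by the same reconvolution model with Poisson
weights 1/√max(count, 1) and a fitted time-zero and flat background;
channels with fewer than 10 counts are excluded because the Neyman
weighting is strongly biased for near-empty channels.  The reduced
chi-square of a correctly specified fit at 10⁴ peak counts scatters
around 1.0 with σ ≈ 0.055 per dataset.

## Synthetic data

The headline synthetic transient-absorption dataset emulates the
published measurement: a four-component sequential scheme with lifetimes
20 fs → 517 fs → 35.9 ps → 889 ps, Gaussian IRF of 96 fs FWHM, pump at
580 nm, probe 500–780 nm at 1 nm, a delay axis linear from −1 to 1 ps
(20 fs step) and logarithmic to 3.5 ns, and 1% additive Gaussian noise
(seed 1).  Component difference spectra are sums of nm-domain Gaussians:
β ground-state bleach/stimulated emission centred at 621 nm, α bleach at
705/709 nm (the small 3rd-to-4th component difference carries the
terminal-PCB transfer signature), a small direct-α bleach at time zero,
and a broad positive excited-state absorption band (~30% of the bleach)
for band-shape realism only.  TCSPC data are Poisson draws from the
reconvolution model (default 825 ps, 50 ps IRF FWHM, 10⁴ peak counts).

What the generator does *not* emulate: wavelength-dependent group
velocity dispersion, explicit coherent artifacts, pump scatter, detector
nonlinearity, and exciton annihilation.  Passing round-trip tests
therefore demonstrates correctness of the fitting machinery under the
model's own assumptions, not robustness to those instrument effects.

All random draws flow from one seeded generator per dataset and the seed
is recorded in the output metadata; identical seeds give byte-identical
files.

## Numerical choices

* Propagation: eigendecomposition of the augmented generator (sites +
  decay sink + trap sink, columns sum to zero, so mass balance holds to
  ~1e-12); scaled matrix-exponential stepping as fallback when the
  eigenvector condition number exceeds 1e10.
* Linear solves for η and MFPT; unreachable targets are flagged as
  infinite, not raised.
* Fit tolerances 1e-10 (function) / 1e-8 (parameters); multi-exponential
  initial lifetimes default to a log-spaced ladder over the data span.
* Kinetic Monte Carlo vectorises the jump chain over trajectories and
  reports a binomial standard error.
* Time grids default to 400 log-spaced points from 1 fs to 10 ns
  (350 points to 8 ns inside the calibration loop).
* Problem sizes used throughout the shipped analyses: 13 protomers
  (26 sites), 281 probe wavelengths × 221 delays, 650 TCSPC channels,
  10⁵ Monte-Carlo trajectories.
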