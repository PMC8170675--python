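# Methods

This note documents the models implemented in `dnallostery`, the
assumptions behind them, the choices made where the design was open, and
what the synthetic-data generators do and do not emulate.

## Photon-level smFRET burst analysis (`smfret`)

**Model.** A confocal two-channel photon record (channel 1 = acceptor,
channel 2 = donor) with pulsed interleaved excitation (PIE) is analysed at
the single-photon level.  Raw counts are corrected with five parameters:
relative detection efficiencies `gamma1 = 1`, `gamma2 = 1.12`, spectral
leakage `beta_DA = 0.050` (donor photons into the acceptor channel) and
`beta_AD = 0.0021` (the reverse), and the acceptor direct-excitation
probability `alpha = 0.049`.  Background-subtracted counts are multiplied
by the 2x2 matrix `(gamma1, -beta_DA; -beta_AD, gamma2)` and the
direct-excitation term `alpha (n'_D + n_A)` is removed from the acceptor.
Corrected counts are deliberately not clipped at zero: with noise they can
be slightly negative, and clipping would bias the efficiency histogram.

**Burst search.** A photon extends the current burst when its gap to the
previous photon is at most `gamma_channel * dt_max` (`dt_max = 100 us`); a
candidate burst is retained when its corrected photon sum exceeds 80.
Background rates start from the total photons per channel over the
measurement time, are re-estimated from photons outside retained bursts,
and the search iterates until the burst count is stable (at most 10
iterations; synthetic fixtures converge in 2-3).  Corrections, the burst
threshold and the background rates all refer to photons in the
donor-excitation PIE window (microtime 0-25 ns of a 50 ns period);
acceptor-excitation photons only enter the stoichiometry.  The microtime
window boundaries are a package choice — only the period and the
interleaving are physically fixed.

**Filters.** Acceptor photobleaching inside a transit skews the mean
arrival times: the burst asymmetry `alpha_DA = <t_D> - <t_A>` (raw channel
arrival times relative to the burst start) is compared against its
shot-noise standard deviation `sigma_DA = T/(2 sqrt 3) (1/n'_D +
1/n'_A)^1/2`, and bursts with `|alpha_DA| > sigma_DA` are removed.  Raw
times are used in the means because the shot-noise expression uses the
corrected counts only for the width.  The PIE stoichiometry `S = (n'_DD +
n'_DA)/(n'_DD + n'_DA + gamma_PIE n_AA)` with `gamma_PIE = 2.5`
(configurable) removes donor-only molecules at `S >= 0.8`.  No lower
S-bound is applied; acceptor-only molecules do not pass the
donor-excitation burst threshold in practice.  Note the two filters are
complementary: a bleach late in a transit trips the asymmetry test, an
early bleach leaves a symmetric, acceptor-dark burst that trips the
stoichiometry test instead.

**Histogram.** Efficiencies are histogrammed with 0.02-wide bins over
[-0.1, 1.1] (corrected E can leave [0, 1]).  For two-state binding data the
free and bound peak positions and widths are calibrated on ligand-free and
ligand-saturated reference histograms and then held fixed; only amplitudes
are fitted (non-negative linear least squares), and the bound fraction is
the numerically integrated area of the bound component over the total.
Log-normal peak shapes are available for populations near E = 0 or 1.

## Synthetic photon streams (`synthetic`)

The generator emulates molecules transiting a confocal volume: burst starts
are Poisson (default 20/s), photon counts per burst Poisson (mean 200),
arrival times uniform over a 1 ms transit, background uniform in time and
microtime (500/s per channel in the donor window).  Each double-labelled
burst draws its true efficiency from its population's Gaussian
(molecule-to-molecule spread), and the channel split applies the *forward*
of the correction model, so analysis with the same correction set recovers
the population mean.  Donor microtimes decay with `tau_D (1 - E)`;
donor-only molecules emit only donor-excitation photons with leakage-level
acceptor-channel counts.  Bleaching switches the acceptor off at a uniform
time within the transit.  Macrotimes and microtimes are quantised to the
32 ps recording grid.

Not emulated: diffusion kinetics (transit-time and brightness
distributions), detector dead time and afterpulsing, triplet blinking, and
interphoton correlations.  Passing tests therefore demonstrate the
correctness of the correction/search/filter chain, not robustness to those
instrument effects.

## Lifetime-efficiency analysis (`lifetime`)

For a Gaussian inter-dye distance distribution (mean `mu`, width `sigma`,
truncated at r > 0 and renormalised) the photon-weighted mean donor
lifetime is `<tau> = int tau(r)^2 P / int tau(r) P` and the mean efficiency
`<E> = int E(r) P / int P`, with `tau(r) = tau_D [1 + (R0/r)^6]^-1`.
Quadrature is adaptive with relative tolerance 1e-8 over `mu +/- 10
sigma`.  The width fit treats `mu` as an implicit per-point variable:
each observed `(mean E, mean lifetime)` peak position is projected
perpendicularly onto the fixed-`sigma` parametric curve (coordinates
normalised by `tau_D`), and the scalar `sigma` minimises the summed squared
projection distances.  At least three points are required.  The implied
per-dye cloud width assumes equal, isotropic donor and acceptor clouds:
`sigma_dye = sigma / sqrt 2`, reported rounded to two decimals.

## B-DNA FRET reference (`bdna`)

Dye positions on straight B-form DNA follow a helical lattice with axial
offset `L = 0.617 nm`, rise `0.338 nm/bp`, radial offsets `r_A = 1.177`,
`r_D = 1.247 nm`, twist `36 deg/bp` and angular offset `89.8 deg`.  The
midpoint efficiency `E_mp = R0^6/(R0^6 + R_DA^6)` (R0 = 5.4 nm) is mapped
to the linker-averaged mean efficiency by inverting the empirical cubic
`E_mp = 0.008 + 0.679 <E> + 1.470 <E>^2 - 1.141 <E>^3`, which is strictly
increasing on [0, 1]; the inverse uses bracketed root finding to 1e-12.
Base-pair separations are non-negative integers (labelled positions are
discrete).  `fit_r0` refits only the Forster distance with the lattice
fixed.  The comparison of this straight-helix reference with measured
efficiencies is qualitative: it assumes marginal DNA distance fluctuations
and linker motions slower than transfer.

## Binding thermodynamics (`binding`)

The two-box promoter carries four sites.  Sequential scheme: first ligand
with microscopic association constant `K` (any of 4 sites), second into the
same box with `sigma K`, third opens the other box with `J K`, fourth with
`J sigma K`.  Cross-box doubly bound states are excluded — the structural
protein-protein contact within a box makes box completion strictly
preferred.  The binding polynomial is `Q = 1 + 4s + 2 sigma s^2 + 4 J sigma
s^3 + J^2 sigma^2 s^4` (`s = Kx`) and the fully bound fraction its last
term over `Q`; an isolated box gives `f = sigma s^2/(1 + 2s + sigma s^2)`.
Free energies are in kBT with a 1 nM standard state for `K`; the reported
coupling energy is `-dg_J = ln J`.  These expressions hold for promoter
concentrations far below `1/K` (the measurements used ~30 pM), so free and
total ligand are identified and no depletion correction is applied.

**Global fitting.** Stage 1 fits all isolated-box isotherms with one global
`dg_sigma` and a local `dg_K` per box.  Stage 2 fixes `dg_sigma` and fits
the two-box isotherms with one `dg_K` and one `dg_J` per promoter label
(isotherms sharing a label, e.g. the two label positions of one promoter,
share both).  Both stages run from several starting values and keep the
best optimum; the sigma/K trade-off in stage 1 is shallow enough that a
single start occasionally lands in a secondary minimum.  Weights are
`1/f_err` when errors are provided.  Hill fits (`f = x^n/(K^n + x^n)`) are
performed in f-space with the midpoint parameterised logarithmically; the
Hill-plot transform is provided for display only.

**Occupancy statistic.** From a distribution `p(i)` of ligands per particle
(e.g. counted single-particle classes), the Hill coefficient is the
observed variance over the binomial variance at the same mean:
`n = (<i^2> - <i>^2)/(<i>(1 - <i>/N))`.  It is exactly 1 for binomial
distributions, 4 for two-point all-or-none distributions on 0/4, and
undefined at empty or full occupancy.

**Titration generator conditions.** Noise on the bound fraction is
additive Gaussian with SD 0.01, clipped to [0, 1] — the binomial standard
error of a fraction estimated from a few thousand bursts.  Titrations use
20 log-spaced concentrations centred on the construct's half-saturation
point (23-fold below to 23-fold above, `transition_grid`), matching how a
titration is designed in practice; a grid with long plateaus interacts with
the [0, 1] clipping to bias plateau points inward by a fraction of the
noise SD.  Two replicates per isotherm and two label-position isotherms per
two-box promoter mirror the replication of the measurements.  Under these
conditions the coupling free energy is recovered with a median error of
~3% (maximum ~10% over seeds) across the 1.9-5.8 kBT range; weak coupling
is intrinsically better determined than strong coupling, where the
isotherm shape saturates towards the all-or-none limit.

## Elastic coupling (`elastic`)

A protein that changes the local DNA bend by `alpha` at its site sets up
tension decaying over `xi = sqrt(kBT lp / f)`.  Two kinks separated by `ds`
cost `dE = 2 alpha^2 (lp/xi)(1 +/- exp(-ds/xi))` kBT (+ symmetric, -
antisymmetric); the helical period `lambda = 10.5 bp` interpolates between
the parities, giving `dg_J(ds) = 2 alpha^2 (lp/xi)(1 + sign * cos[2 pi (ds
+ ds0)/lambda] exp(-ds/xi))` and an analogous empirical form `n = a(b +
sign * cos * exp)` for Hill exponents.  Entropic contributions are omitted
(small compared to the enthalpic term).  Defaults: `lp = 40 nm`, `ds0 = 8
bp`, `kBT = 4.11 pN nm` (23 C), 0.34 nm/bp.

**Branch convention.** The expression is printed with `+cos`, appropriate
for proteins that introduce bends.  A bend-*relieving* protein swaps the
roles of the symmetric and antisymmetric arrangements, which is equivalent
to flipping the cosine sign; only that branch (`native_high`, the default)
reproduces couplings that decrease from one helical turn (8 bp) over two
turns (18 bp) to three (31 bp).  The literal printed sign remains available
via `branch="printed"`.

**Fitting protocol.** Sequential, mirroring how the two observables
constrain the model: Eq.-27-type fits of a Hill-exponent series determine
`(a, b, xi)`; the energy expression with `xi` fixed (default 14 bp) then
determines `alpha`.  Derived quantities: tension `f = kBT lp / xi^2` and
mean bend change `2 alpha / span` (default span 44 bp, box centre to box
centre).  The gel-screen periodicity is fitted with the empirical model
`c0 + c1 cos[2 pi (ds + ds0)/lambda] + c2 exp(-ds/c3)` after a coarse
phase scan; the phase is reported modulo the period.  Two phase values
coexist in the defaults: the gel fit yields ~7.2 bp while the model fits
use the rounded 8 bp; both are exposed, 8 bp is the default `ds0`.

## Curvature profiles (`curvature`)

Input is an ordered centerline point list (tracing centerlines out of
density maps is out of scope).  Points are smoothed with a cubic parametric
spline (configurable smoothing factor; 0 interpolates), resampled to
segments of `b = 0.34 nm` (1 bp) by inverting the cumulative arclength of a
dense evaluation, and the angle between successive segment vectors is
`arccos` of their normalised dot product, clamped to [-1, 1] against
rounding.  Group comparison aligns each profile on its midpoint, trims to
the shortest common support, and reports the mean per-segment difference in
degrees per bp.

## Two-state unfolding (`unfolding`)

The population-averaged Stokes radius is the cube root of the
volume-weighted sphere volume, `<R> = [3/(4 pi)(f v_f + (1-f) v_u)]^(1/3)`,
with logistic folded fraction `f = e^{-dG/RT}/(1 + e^{-dG/RT})`, linear
free energy `dG = m x + dG0` (folded minus unfolded; stable proteins have
`dG0 < 0`) and linearly expanding unfolded volume `v_u = m_u x + n_u`.
All five parameters are fitted simultaneously; initial guesses come from
the low-denaturant plateau (v_f), a linear fit of the top quarter (v_u
line) and the half-span crossing (midpoint).  Temperature is fixed at
298 K (`RT = 2.48 kJ/mol`) unless configured.  The synthetic generator
uses a folded radius of 2.0 nm and an unfolded radius growing from 3.4 to
4.2 nm over 0-6 M denaturant (realistic for a ~22 kDa protein), `m = 7
kJ/mol/M`, radius noise 0.02 nm and 31 points concentrated through the
transition; a fitted dG0 then carries a standard error of ~0.3 kJ/mol, and
recovery tests average three replicate curves.

## Dye clouds (`dyecloud`)

The accessible positions of a dye tethered through a seven-carbon chain are
enumerated with the rotational isomeric state model: the linker nitrogen
sits 132 pm from the base C8 atom, in-plane, at an N-C8-N9 angle of 123
deg; each backbone dihedral samples anti/gauche+/gauche- (3^7 = 2187
chains) with standard polyethylene geometry (0.153 nm bonds, 109.5 deg
angles) and a Boltzmann penalty of 2.1 kJ/mol per gauche rotamer (a
standard alkane value; configurable, as the underlying reference data are
not reproduced here).  Conformers whose chain carbons (beyond a
configurable exempt prefix of 0/1/4/7 atoms, reflecting how tightly the
low-resolution structural model should constrain the linker) or terminal
fluorophore sphere (radius 0.35 nm, configurable) overlap excluded-volume
atoms are discarded and the weights renormalised.  The FRET efficiency
between two clouds is the weighted double sum of the Forster expression
over all position pairs.  Orientation factors are not modelled (dynamic
averaging assumed).

## Numerical conventions

- Units: nm, ns, seconds for photon macrotimes, kBT for binding free
  energies, kJ/mol for unfolding, degrees at API boundaries (radians
  internally), bp for spacer lengths (0.34 nm/bp).
- Seeds: every generator takes an explicit seed and is deterministic given
  it; independent datasets derive distinct seeds.
- Ties at the burst-search threshold are retained (`<=`).
- Roots/inversions: bracketed root finding at 1e-12 (efficiency
  conversion); quadrature at 1e-8 relative (lifetime integrals).

## Problem sizes used in the tests

End-to-end photon tests use ~250 s of simulated measurement (~5000 bursts,
~1.5 M photons); calibration references use 60 s each.  Parameter-recovery
tests use 16-40 point series and 2 replicates.  These sizes put shot-noise
limits (e.g. +/-0.03 on a bound fraction at 5000 bursts) well inside the
asserted tolerances.

## Known limitations

- The burst generator's uniform-transit model understates burst-duration
  and brightness heterogeneity; retention fractions of the asymmetry filter
  on real data will differ.
- The KNF model fixes two ligands per box and forbids cross-box doubles;
  promoters with more than two boxes are out of scope.
- The elastic model is small-angle and enthalpy-only; it is a
  one-parameter-family description of the spacer dependence, not a full
  worm-like-chain boundary-value solution.
- Lifetime analysis uses peak positions, not photon-by-photon likelihoods.
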