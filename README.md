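# dnallostery

Analysis pipeline for DNA-mediated allosteric cooperativity in
transcription-factor/promoter binding, built around single-molecule FRET.
The motivating system is the competence regulator ComK of *Bacillus
subtilis*, which binds its promoters at two A-tract boxes (two ComK
molecules per box) separated by a spacer of 8-31 bp: occupying the first
box straightens the intrinsically curved DNA and changes the affinity of
the second box, a coupling transmitted through the double helix itself.
The package is aimed at single-molecule and DNA-biophysics groups who want
the full chain — photon records to coupling free energies — as tested,
scriptable building blocks, with synthetic-data generators for every stage
so the whole pipeline can be validated without any measured data.

## What it implements

- **`smfret`** — photon-level burst analysis with pulsed interleaved
  excitation: count corrections
  `(n_A, n'_D) = (γ₁, −β_DA; −β_AD, γ₂)(n₁−b₁T, n₂−b₂T)`,
  `n'_A = n_A − α(n'_D + n_A)`; inter-photon-time burst search with
  iterative background estimation; transfer efficiency
  `E = n'_A/(n'_A+n'_D)`, stoichiometry `S`, and the burst-asymmetry
  bleaching filter `|⟨t_D⟩−⟨t_A⟩| ≤ (T/2√3)(1/n'_D+1/n'_A)^½`;
  fixed-peak histogram fits for bound fractions.
- **`binding`** — sequential two-box binding model with binding polynomial
  `Q = 1 + 4s + 2σs² + 4Jσs³ + J²σ²s⁴` (`s = Kx`), intra-box factor σ,
  inter-box factor J, coupling free energy `−Δg_J = kBT ln J`; global
  two-stage fits; Hill fits; and the occupancy-distribution Hill statistic
  `n = Var(i)/(⟨i⟩(1−⟨i⟩/N))`.
- **`elastic`** — elastic-coupling model of force transmission:
  `Δg_J(Δs) = 2α²(l_p/ξ)(1 ± cos[2π(Δs+Δs₀)/λ] e^(−Δs/ξ))` with decay
  length `ξ = (kBT·l_p/f)^½`; spacer-series fits, derived tension and mean
  bend, and the cosine+exponential gel-periodicity fit.
- **`lifetime`** — donor lifetime vs. efficiency for a Gaussian distance
  distribution, distribution-width fits, dye-cloud width `σ_dye = σ/√2`.
- **`bdna`** — helical dye-lattice distance model for straight B-DNA and
  the empirical midpoint/mean efficiency conversion, with R₀ refits.
- **`curvature`** — per-segment (0.34 nm = 1 bp) bending-angle profiles of
  traced DNA centerlines and free-vs-bound class averages.
- **`unfolding`** — two-state stability fits on Stokes-radius denaturation
  curves, `⟨R⟩ = [3/(4π)(f v_f + (1−f)v_u)]^⅓`.
- **`dyecloud`** — rotational-isomeric-state enumeration of dye-linker
  conformers (3⁷ chains, clash filtering) and cloud-averaged FRET
  `E = ΣΣ p_i q_j R₀⁶/(R₀⁶+r_ij⁶)`.
- **`synthetic`** — generators that invert each analysis: PIE photon
  streams with two FRET subpopulations, donor-only molecules, background
  and acceptor bleaching; titrations; occupancy samples; spacer series;
  centerlines; denaturation curves.

See `docs/methods.md` for model details, parameter defaults and the
assumptions behind the generators.

## Worked example

Fit the elastic-coupling model to the measured inter-box coupling energies
of the three natural promoters (spacers 8, 18, 31 bp), then run the photon
pipeline on a synthetic two-population measurement:

```python
import dnallostery as dl

series = dl.SpacerSeries(ds=[8, 18, 31], y=[5.8, 4.5, 1.9], kind="energy")
fit = dl.fit_elastic(series, dl.ElasticModel(xi=14.0), fix_xi=True)
force, bend = dl.tension_and_bend(fit, span_bp=44.0)
print(f"bend angle per box: {fit.alpha_bend:.1f} +/- {fit.alpha_err:.1f} deg")
print(f"tension:            {force:.1f} pN")
print(f"mean bend change:   {bend:.2f} deg/bp")

truth = dl.FretPopulations(components=[(0.45, 0.03, 0.5), (0.63, 0.03, 0.5)])
stream = dl.simulate_photon_stream(truth, dl.SimulationConfig(seed=1, duration=60.0))
bursts, bg = dl.find_bursts(stream)
for b in bursts:
    dl.burst_metrics(b)
kept = dl.filter_bursts(bursts)
print(f"bursts found:       {len(bursts)}, retained after filters: {len(kept)}")
print(f"background (c1,c2): {bg[0]:.0f}, {bg[1]:.0f} photons/s")
```

Output:

```
bend angle per box: 25.3 +/- 2.0 deg
tension:            7.3 pN
mean bend change:   1.15 deg/bp
bursts found:       1172, retained after filters: 704
background (c1,c2): 497, 497 photons/s
```

The bend angle is the local curvature change a bound ComK pair imposes on
one box; the tension follows from the 14 bp decay length of the coupling;
the filters drop donor-only molecules and bursts with a mid-transit
acceptor bleach (the generator plants 10% donor-only and 5% bleached
bursts, plus shot-noise-level asymmetry rejections).

A command-line front end exposes each stage
(`dnallostery simulate-bursts | analyze-bursts | fit-isotherm |
fit-elastic | fit-lifetime | bdna-profile | hill-from-counts | curvature |
fit-unfolding | dye-fret`); every subcommand writes a JSON report carrying
the seed and a fingerprint of its configuration.

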