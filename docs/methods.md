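# Methods

This note documents the models and procedures pentaspec implements, the
parameters that matter, the synthetic-data generator and what it does and
does not emulate, and the numerical choices made where the design was open.

## Repeat design arithmetic

A WGGGW pentanucleotide repeated n times carries one GGG run per repeat.
G-runs are counted as *maximal* runs of consecutive G of length ≥ `min_len`
(default 3), scanning 5′→3′; maximality makes the runs non-overlapping.
Four consecutive G≥3 runs are grouped left-to-right into one potential
three-tetrad G4 unit, so an n-repeat WGGGW strand holds ⌊n/4⌋ units.  Unit
and tetrad concentrations follow directly: unit_conc = units × strand_conc
and tetrad_conc = 3 × unit_conc (three stacked tetrads per GGG-based unit;
runs longer than 3 still count three tetrads unless `min_len` is raised,
since all motifs of interest carry exactly G₃).  The 24/n µM scheme then
fixes 6 µM potential G4 units and 18 µM potential tetrads for every n that
is a multiple of 4, which is what makes spectroscopic amplitudes comparable
across repeat lengths.

Predicted species sizes are deliberately simple: a bimolecular duplex is
assumed full-register (two strands, n × motif-length bp); an intramolecular
hairpin pairs half the strand (⌊L/2⌋ bp); an intramolecular G4 involves the
whole strand (L nt).  Slipped/partial-register duplexes and interstrand G4
unit counting for multimolecular assemblies are not enumerated — the size
arithmetic supports gel-mobility reasoning, not structure prediction.

## Spectral containers and I/O

All data pass through two containers: `Spectrum` (signal vs wavelength at
one temperature; channel ABS in absorbance units or CD in raw instrument
mdeg) and `MeltingCurve` (absorbance vs temperature at one wavelength, one
ramp direction, one ramp rate).  CD values are kept as raw millidegrees; no
Δε calibration or concentration normalization is applied anywhere — the
comparability of spectra recorded at matched per-unit concentrations is the
caller's responsibility, mirroring how the underlying experiments are
designed.

The exchange format is one long-format CSV dialect (comma, dot decimal,
UTF-8, required header).  Floats are written with shortest-exact `repr`
formatting and parsed back with numpy's correctly-rounded reader, so
read∘write is the identity bit for bit (pandas' own numeric parser is not
round-trip exact and is used only to locate malformed cells for error
reporting).  Cross-spectrum arithmetic happens on a shared grid: the
intersection of wavelength ranges at a 1 nm step (typical spectrometer
export resolution), with linear interpolation and no extrapolation.

## Melting analysis

**Baseline correction.** The melting trace at an analytical wavelength
(295/273/260/245 nm) is corrected by pointwise subtraction of the trace at
335 nm, where nucleic acids do not absorb; the reference is interpolated
onto the curve's temperature grid when the grids differ by more than
0.1 °C.

**TDS.** The thermal difference spectrum is A(95 °C) − A(5 °C) on the
common grid.  The result is tagged with a NaN temperature sentinel.
Normalization to unit maximum absolute value is available but off by
default, so raw amplitudes (which carry concentration information under
the 24/n µM scheme) are preserved.

**Derivative and Tm.** dA/dT is computed by local polynomial least squares:
at each point a degree-2 polynomial is fitted to an 11-point window and
differentiated analytically, with one-sided shrunken windows at the ends.
This is the uneven-grid generalization of a Savitzky–Golay derivative and
is exact on polynomials up to the fit degree.  The window (11 points,
degree 2) preserves the derivative-extremum position on ramps sampled at
≤ 0.5 °C while suppressing point noise; the peak *amplitude* of dA/dT is
attenuated by a few percent, which is irrelevant here because only the
extremum position (Tm) and its sign are used.

Tm is the temperature of the global |dA/dT| extremum over interior points
(5 points excluded at each edge).  A transition is declared only when that
extremum exceeds `noise_k` (default 5) times a robust noise scale —
1.4826 × MAD of dA/dT over the coolest and hottest 10 % of points, where a
corrected trace should be flat.  This operational criterion is needed
because "no transition" is itself a reported outcome for some repeats.  The
transition amplitude is |median of the 5 lowest-T points − median of the 5
highest-T points| of the corrected trace; baselines are deliberately never
fitted, so no two-state or baseline-linearity assumption enters the
estimate.  The per-wavelength sign of the extremum is recorded, not
asserted a priori.

**Hysteresis.** Cooling and heating Tm are compared; the pair is flagged
hysteretic when they differ by more than `threshold_C` (default 1.0 °C, the
scale of instrument Tm repeatability), and the midpoint
(Tm·cooling + Tm·heating)/2 is reported for hysteretic pairs, where neither
branch alone estimates the equilibrium Tm.

**Signature classification.** A TDS or CD spectrum is assigned to a
structural class (parallel G4, antiparallel G4, hybrid G4, non-G4 duplex,
unstructured) by cosine similarity of mean-centered vectors against a
caller-supplied template library on the common 220–335 nm grid, accepting
the best label at score ≥ 0.80 and returning "unclassified" otherwise.
Mean-centering plus cosine makes the call invariant to signal offset and
scale; a zero spectrum scores 0 against everything.

## CD decomposition

With basis spectra CD_G4 and CD_non-G4 on a shared grid, the model is the
convex combination CD_calculated(f) = f·CD_non-G4 + (1 − f)·CD_G4 and the
objective SSR(f) = Σᵢ [CD_measured(λᵢ) − CD_calculated(f, λᵢ)]², an exact
quadratic in f.  The estimator evaluates SSR on the grid f = 0.1 … 0.9
(step 0.1, ties in the argmin broken toward smaller f for determinism) and
separately refines f as the closed-form least-squares solution of
(measured − CD_G4) against (CD_non-G4 − CD_G4), clamped to [0, 1]; the
refined value is also entered into the reported SSR profile, so the
profile's minimum equals the reported minimum SSR.  The SSR window defaults
to the full common grid (220–335 nm) and is configurable.  A basis whose
two spectra are numerically proportional (angle ≤ 1e−6 rad) is rejected as
ill-posed.

The decomposition assumes the measured spectrum and both bases are recorded
at the same per-G4-unit concentration and pathlength; no internal
renormalization is done.  Composite spectra of hypothetical m-unit
structures follow the same convention: Σ wⱼ·Sⱼ / Σ wⱼ, i.e. a per-unit
weighted mean, consistent with spectra recorded at equal potential-unit
concentration.

## Synthetic data

The generator supplies every input the pipeline consumes; it emulates the
*physics* of the measurements, not any particular instrument.

**Equilibrium melting.** A two-state transition with constant ΔH°, ΔS°
(van't Hoff; folding convention ΔH° < 0) and molecularity m ∈ {1, 2, 4}.
With K(T) = exp(−(ΔH° − T·ΔS°)/(R·T_K)), R = 1.987 cal mol⁻¹ K⁻¹,
T_K = T_C + 273.15, the folded fraction θ — defined per strand for all
molecularities, since that is what absorbance reports — satisfies
θ = K/(1+K) (m = 1), K = θ/(2·C_T·(1−θ)²) (m = 2, 2S⇌D), and
K = θ/(4·C_T³·(1−θ)⁴) (m = 4).  The higher-order relations are solved by
bisection on the monotone log-form residual to |Δθ| < 1e−13.  The midpoint
condition gives closed-form melting temperatures: Tm_K = ΔH°/ΔS° for m = 1,
and 1/Tm = (ΔS° − R·ln K_m)/ΔH° with K_m = 1/C_T (m = 2) or 2/C_T³ (m = 4)
— hence the concentration dependence of intermolecular Tm.  The observable
is A(T) = θ·b_f(T) + (1−θ)·b_u(T) with affine baselines, plus seeded
Gaussian noise (numpy `default_rng`; identical seeds give identical
curves).

**Kinetic ramps and hysteresis.** Finite kinetics use an Arrhenius folding
rate k_f(T) = A_f·exp(−Ea_f/(R·T_K)); the unfolding rate is always derived
by detailed balance, k_u(T) = k_f(T)/K(T), so the kinetic and thermodynamic
descriptions cannot disagree (for this reason the model stores only the
folding Arrhenius pair — an independently specified unfolding pair could
violate detailed balance).  The ODE is dθ/dt = k_f(1−θ) − k_u·θ (m = 1),
2k_f·C_T·(1−θ)² − k_u·θ (m = 2), 4k_f·C_T³·(1−θ)⁴ − k_u·θ (m = 4), with
T(t) linear per the ramp protocol and θ(0) the equilibrium value at the
start temperature.

Integration uses a fixed temperature step of ≥ 20 substeps per sampled
degree.  Each substep takes a classical RK4 step while |J|·dt < 1, where
J = ∂(dθ/dt)/∂θ is the local relaxation rate; where the kinetics are stiff
(far above Tm the derived unfolding rate grows as exp(−(Ea_f − ΔH°)/R·T),
reaching ~10³ min⁻¹ for a ~55 kcal/mol effective dissociation barrier, and
plain RK4 diverges at any practical step) the substep switches to the
exponential Rosenbrock–Euler update θ ← θ + expm1(J·dt)/J · F(θ), evaluated
at the substep's end temperature so that the fast-kinetics limit lands
exactly on the local equilibrium.  Against scipy's LSODA at rtol 1e−10 the
scheme agrees to ~1e−6 in θ on the preset ramps, and the ×10⁶-rate limit
reproduces the equilibrium curve to < 1e−5 in θ.

**Band spectra.** CD and TDS spectra are sums of Gaussian bands
(center, sd, amplitude) on a 220–335 nm grid.  Bundled presets place bands
at the field's fingerprints: parallel G4 CD +264/−245 nm, antiparallel G4
CD +295/−265 nm, non-G4 homopurine duplex CD +280/−258 nm, G4 TDS
+243/+273/−295 nm.  The 6 nm band widths keep each extremum at its nominal
center on a 1 nm grid despite band overlap.  Mixtures at known f are convex
combinations of two basis spectra plus seeded noise.

**Model presets.**  Thermodynamic and kinetic parameter values are fixture
conventions chosen once for qualitative regime matching — no calorimetric
or kinetic constants are available for these systems — and should not be
read as measurements:

| preset | regime | parameters |
|---|---|---|
| `intramolecular` | stable monomolecular G4, no hysteresis | ΔH° = −45 kcal/mol, Tm = 71 °C |
| `bimolecular_duplex` | fast two-strand duplex, concentration-dependent Tm | ΔH° = −60 kcal/mol, Tm = 55 °C at 3 µM |
| `slow_bimolecular_g4` | slow intermolecular G4, hysteretic | as above + k_off(Tm) = 0.05 min⁻¹, Ea_f = −15 kcal/mol |

The strongly anti-Arrhenius association (apparent Ea ≈ −15 kcal/mol, as for
nucleation-limited multistrand assembly) makes the slow preset hysteretic
at ordinary ramp rates — Tm(heating) − Tm(cooling) ≈ 16.5 °C at 2 °C/min
and ≈ 2 °C at 0.2 °C/min — while converging to the equilibrium curve at
0.02 °C/min and below.

**What the generator does not emulate.**  Instrument drift and lamp noise
structure (only white Gaussian noise), multi-intermediate (> 2-state)
transitions, wavelength-dependent baseline coupling, aggregation, and
sequence-dependent thermodynamics (no nearest-neighbor prediction).  Tests
passing on synthetic data therefore validate the *estimators* —
that Tm, f, TDS and hysteresis are recovered correctly when the data obey
the stated models — not the models' adequacy for any particular real
sample.

## Problem sizes and determinism

Default analyses use the standard ramp (95→5 °C, 0.5 °C sampling,
181 points per branch), 1 nm spectral grids of ~116 points, 100-replicate
Monte-Carlo sweeps for fraction recovery, and a 100-point random parameter
sweep for the thermodynamic consistency check; these sizes make every check
sharp while keeping the full suite and the acceptance script in the
seconds range.  All stochastic outputs are reproducible given
(seed, parameters); the CLI and the acceptance script funnel every source
of randomness through explicit integer seeds.

## Known limitations

- Two-basis unmixing only; ≥ 3-component decomposition with simplex
  constraints, and CONTIN/SELCON-style secondary-structure estimation, are
  out of scope.
- Tm is an operational derivative-extremum estimate: for intermolecular
  transitions it does not coincide exactly with the θ = 0.5 temperature
  (the dθ/dT extremum of a bimolecular transition is slightly displaced),
  and no ΔH° is extracted from melting curves.
- Signature classification is a nearest-template call with a fixed
  acceptance threshold (0.80 cosine); mixtures of classes score between
  templates and may come back "unclassified" rather than fractionated —
  quantitative apportioning is the decomposition module's job.
- The hairpin/duplex size arithmetic ignores loop penalties, bulges and
  register slippage.
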