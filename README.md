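# pentaspec

UV/CD spectroscopic analysis of G-quadruplex versus noncanonical-duplex
equilibria in short tandem pentanucleotide repeats, such as the
CANVAS-associated AGGGA (AAGGG-frame) repeat expansion motif and its WGGGW
relatives (W ∈ {A, T}).

Oligonucleotides of n = 4, 8, 12, 16 repeats of a WGGGW motif carry n
GGG runs, hence ⌊n/4⌋ potential three-tetrad G-quadruplex (G4) units.
Whether a given repeat folds into G4s, into a competing non-G4 duplex, or
into a mixture of both is read out spectroscopically, and this package
implements that readout as a tested, reusable pipeline:

- **Design arithmetic** (`pentaspec.repeats`): G-run counting, potential
  G4-unit and G-tetrad concentrations under the 24/n µM strand-concentration
  scheme (which holds 6 µM potential G4 units and 18 µM potential tetrads
  across n), and predicted species sizes (e.g. 40/60/80 bp full-register
  duplexes for n = 8/12/16 pentanucleotide repeats).
- **Melting analysis** (`pentaspec.melting`): baseline correction by
  subtracting the non-absorbing 335 nm trace, thermal difference spectra
  TDS(λ) = A₉₅°C(λ) − A₅°C(λ), melting temperature as the extremum of the
  smoothed first derivative dA/dT (no baseline fitting, no two-state
  assumption), hysteresis detection between cooling and heating branches
  with the midpoint Tm = (Tm·cooling + Tm·heating)/2, and template-based
  classification of TDS/CD signatures.
- **CD decomposition** (`pentaspec.decompose`): the measured CD spectrum of
  a mixed population is modelled as
  CD_calculated(f) = f·CD_non-G4 + (1 − f)·CD_G4; the non-G4 fraction f
  minimizes SSR(f) = Σᵢ [CD_measured(λᵢ) − CD_calculated(f, λᵢ)]², evaluated
  on the grid f = 0.1 … 0.9 and refined by the exact closed-form minimizer.
  Composite CD spectra of hypothetical m-unit structures are predicted as
  per-unit weighted means.
- **Synthetic data** (`pentaspec.simulate`): van't Hoff two-state melting
  for molecularities 1/2/4 (intramolecular, bimolecular, tetramolecular —
  intermolecular Tm rises with strand concentration), kinetic temperature
  ramps with Arrhenius folding/unfolding rates that reproduce
  ramp-rate-dependent hysteresis, Gaussian-band CD/TDS spectra of the
  canonical structural classes, and noisy two-basis mixtures at known f.

All spectra and melting traces travel as a single long-format CSV dialect
(`pentaspec.spectra`) with bit-exact read/write round trips.

## Worked example

Design the 8-repeat CANVAS motif at its 24/n µM concentration:

```sh
$ pentaspec design --motif AGGGA --n 8
sequence        AGGGA_x8
length_nt       40
g3_run_count    8
potential_g4_units      2
strand_conc_uM  3.0
unit_conc_uM    6.0
tetrad_conc_uM  18.0
```

Forty nucleotides hold eight GGG runs, i.e. two potential contiguous G4
units; at 3 µM strands that is 6 µM in potential G4 units and 18 µM in
potential G-tetrads — the scheme that makes TDS, melting and CD amplitudes
comparable across repeat lengths.

Generate a noisy synthetic CD spectrum that is 55% non-G4 duplex / 45%
parallel G4, then estimate the fraction back:

```sh
$ pentaspec simulate spectrum --preset parallel_G4_CD --out g4.csv
$ pentaspec simulate spectrum --preset non_G4_duplex_CD --out dx.csv
$ pentaspec simulate mixture --fraction 0.55 --noise-sd 0.2 --seed 11 --out mix.csv
$ pentaspec decompose --measured mix.csv --basis-g4 g4.csv --basis-non-g4 dx.csv --out decomp.json
```

The report (`decomp.json`) contains

```
f_grid_best  0.5
f_refined    0.5492
g4_fraction  0.4508
```

so the coarse f-grid picks 0.5 and the exact SSR minimizer recovers the
true non-G4 fraction 0.55 to within the noise (±0.007 at this noise level).

The same workflow runs from Python:

```python
import pentaspec as ps

model = ps.model_preset("slow_bimolecular_g4")
cool = ps.simulate_kinetic_ramp(model, ps.standard_protocol("cooling", 0.2))
heat = ps.simulate_kinetic_ramp(model, ps.standard_protocol("heating", 0.2))
h = ps.hysteresis(ps.estimate_tm(cool), ps.estimate_tm(heat))
print(h.hysteretic, h.midpoint_C)   # True 56.5
```

## Documentation

`docs/methods.md` describes the models, the estimation procedures, the
synthetic-data generator and its presets, numerical choices, and known
limitations.
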