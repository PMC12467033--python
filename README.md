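# enzybind

Quantitative analysis of small-molecule enzyme inhibition and binding, built
around the biophysical workflow used to characterize porphyrin inhibitors of
the digestive enzymes α-amylase and α-glucosidase (key targets for blunting
postprandial glucose release). Given plate-reader absorbances, kinetic
series, fluorescence titrations and FTIR spectra, the library computes every
stage of the characterization:

- **Activity** — inhibition rate `(1 − (A₁−A₂)/(A₃−A₄))·100`, MTT cell
  viability, IC50 by bracketing interpolation or 4-parameter-logistic fit,
  reversibility verdicts (velocity-vs-enzyme lines through the origin),
  temperature/pH stability profiles.
- **Inhibition kinetics** — apparent Km/Vmax per inhibitor level
  (Lineweaver–Burk `1/v = (Km/Vmax)(1/[S]) + 1/Vmax`, or direct nonlinear
  Michaelis–Menten), inhibition-type classification from Km/Vmax trends plus
  double-reciprocal intersection geometry, and the secondary-plot constants
  Ki (`slope = Km/Vmax·(1 + [I]/Ki)`) and Kis
  (`y-intercept = 1/Vmax·(1 + [I]/Kis)`), each as intercept/slope of an OLS
  line in [I].
- **Quenching and binding** — inner-filter correction
  `F_cor = F_obs·e^((A_ex+A_em)/2)`, Stern–Volmer fits
  `F₀/F = 1 + K_SV[Q]` (and the exponential variant for upward-curved
  plots), mechanism classification from K_SV(T) and `K_q = K_SV/τ₀` against
  the 2×10¹⁰ L/mol/s diffusion ceiling, and double-log binding analysis
  `log[(F₀−F)/F] = log K_a + n·log[Q]`.
- **Thermodynamics** — Van't Hoff regression
  `ln K_a = −ΔH⁰/(RT) + ΔS⁰/R`, `ΔG⁰ = −RT·ln K_a`, and binding-force
  classification from the (ΔH⁰, ΔS⁰) sign pattern.
- **Conformation** — synchronous-fluorescence RSFQ (`1 − F/F₀`) on the
  tyrosine (Δλ = 15 nm) and tryptophan (Δλ = 60 nm) channels, sub-grid peak
  shifts, residue-contribution comparison, and EEM peak picking with
  Rayleigh-scatter masking.
- **FTIR** — amide-I (1600–1700 cm⁻¹) windowing and baseline removal,
  Gaussian-sum deconvolution, and secondary-structure percentages by
  wavenumber-class assignment.

A synthetic-data module (`enzybind.simulate`) generates ground-truth data
for every stage — at zero noise each generator/analyser pair is an exact
inverse — and `enzybind.datasets` ships the published apparent-constant and
binding-constant tables for the six porphyrins (TAPP, THPP, TCPP,
Fe/Ni/Cu–TCPP) as desk-scale worked-example inputs.

## Worked example

```python
import enzybind as eb
from enzybind import datasets

fits = datasets.kinetic_fits("amy", "TAPP")      # apparent Km/Vmax vs [I]
print(eb.classify_inhibition(fits).inhibition_type)
print(eb.estimate_ki(fits).value, eb.estimate_kis(fits).value)

profile = eb.thermodynamic_profile(datasets.binding_pairs("glu", "THPP"))
print(profile.dh / 1000, profile.ds, profile.force)
```

prints

```
mixed
8.711648369531284 21.100633381268555
-97.14835377356519 -207.18790615672845 hbond_vdw
```

i.e. TAPP is a mixed-type amylase inhibitor with Ki ≈ 8.71 μg/mL (free
enzyme) and Kis ≈ 21.10 μg/mL (enzyme–substrate complex) — it binds the free
enzyme about 2.4× more tightly — while THPP binding to α-glucosidase is
enthalpy-driven (ΔH⁰ ≈ −97.1 kJ/mol, ΔS⁰ ≈ −207 J/mol/K), the signature of
hydrogen bonding and van der Waals contacts. The `examples/` directory
holds one narrative script per capability (kinetics, IC50, quenching,
thermodynamics, conformational spectra, FTIR).

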