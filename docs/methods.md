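# Methods

This note documents the models implemented in enzybind, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter when reproducing results.

## Models and procedures

**Activity arithmetic.** The inhibition rate is
`(1 − (A₁−A₂)/(A₃−A₄))·100` with A₁ the sample, A₂ the sample control
(enzyme replaced by buffer), A₃ the blank control and A₄ the reagent blank;
the function deliberately allows values below 0 or above 100 (activation,
over-quenched blanks) and only refuses A₃ = A₄. Cell viability is
`(A_s−A_b)/(A_c−A_b)·100`. Stability profiling is this same arithmetic
mapped over a temperature or pH grid plus a range/argmax summary — no
denaturation kinetics are modelled.

**IC50.** The default estimator interpolates linearly between the first
adjacent pair of points bracketing 50 % inhibition: it is assumption-free
and matches the common practice of reading IC50 off a locally linear
segment. The 4-parameter logistic
`y = bottom + (top−bottom)/(1+(IC50/c)^h)` is offered alongside and is the
right choice when the whole curve is trusted; on noiseless logistic data it
recovers the generating IC50 to better than 1e-6 relative, and under 2
percentage points of replicate noise its median error stays below 5 %.

**Inhibition kinetics.** Per inhibitor level the default fit is the
Lineweaver–Burk OLS of 1/v on 1/[S] (matching how such data are usually
reduced); direct nonlinear Michaelis–Menten fitting is available and agrees
to ≤1e-6 on clean data while being less noise-sensitive. Classification
uses two independent signals: (a) trends of apparent Km and Vmax over [I]
— Km "unchanged" means a relative spread ≤ 5 % (the default
`km_constancy_tol`, chosen because measured non-competitive systems show
~1 % spread while the weakest mixed system shows ~46 %); (b) the centroid of
all pairwise Lineweaver–Burk line intersections, with the same 5 % used to
decide whether the centroid lies on an axis (second quadrant ⇒ mixed,
negative x-axis ⇒ non-competitive, y-axis ⇒ competitive, parallel lines ⇒
uncompetitive). When both signals are defined and disagree, the verdict is
`ambiguous` with both signals attached — never a silent choice. One known
consequence: the α-glucosidase–THPP table (Km rising 15 %, intersection on
the x-axis) is reported ambiguous rather than forced into either label.

Ki and Kis come from the secondary regressions of LB slope and LB
intercept on [I]; both constants are the secondary line's own
intercept/slope ratio rather than any single measured point, which is what
reproduces the published constants (e.g. using the measured [I]=0 slope
instead does not). Regressions are unweighted OLS; recomputed constants
land within 1 % of the published Ki values and within 0.9 % for Kis.

**Quenching.** Inner-filter correction multiplies each point by
`e^((A_ex+A_em)/2)` and zeroes the stored absorbances, making the operation
idempotent; all points including the Q = 0 reference are corrected, so F₀
is the corrected reference. Stern–Volmer analysis fits both the linear
(`F₀/F = 1+K_SV[Q]`) and exponential (`F₀/F = e^(K_SV[Q])`) forms and keeps
the exponential one only when it improves the RSS of the ratio by more than
5 % (`min_improvement`) — a reproducible stand-in for the visual-curvature
judgement, tight enough not to fire on noise. The mechanism rule set:
K_SV strictly decreasing with temperature and every
`K_q = K_SV/τ₀ > 2×10¹⁰ L/mol/s` ⇒ static; the same with an exponential
model selected at any temperature ⇒ mixed-static-dominant; rising K_SV or
slow K_q ⇒ dynamic; anything else ⇒ indeterminate. τ₀ defaults to 1e-8 s
(the canonical biopolymer fluorescence lifetime), configurable. The
double-log fit uses base-10 logs; because the intercept is log₁₀K_a with
K_a in L/mol, quencher concentrations must be molar — the compound registry
(below) handles μg/mL → mol/L.

**Thermodynamics.** ΔH⁰ = −R·slope and ΔS⁰ = R·intercept of the OLS of
ln K_a on 1/T (the intercept route, not (ΔH−ΔG)/T, which does not reproduce
published entropies). ΔG⁰ is reported from −RT·ln K_a per temperature, with
ΔH⁰ − TΔS⁰ exposed as a consistency diagnostic; on exact Van't Hoff data
the two coincide. Force classification is strict-sign
(both > 0 hydrophobic; both < 0 hydrogen bond / van der Waals; ΔH < 0 < ΔS
electrostatic); magnitudes within `epsilon` (default 1e-6 J/mol) of zero
return `boundary` rather than a hard class, and the undefined pattern
ΔH > 0 > ΔS returns `out_of_ruleset`.

**Conformational spectroscopy.** RSFQ uses peak intensity (not integrated
area) — the conventional reading of synchronous-quenching plots. Peak
positions are localized by parabolic interpolation around the discrete
maximum so that sub-grid shifts on 2–4 nm instrument grids are resolvable;
the no-shift threshold defaults to one grid step. Residue dominance
compares the Trp (Δλ = 60 nm) and Tyr (Δλ = 15 nm) RSFQ series pointwise
with a 0.02 RSFQ tolerance and a simple-majority rule. EEM peak picking
masks first-order (|Em−Ex|) and second-order (|Em−2Ex|) Rayleigh ridges
within a 15 nm half-width, additionally discards maxima in cells adjacent
to the mask (ridge flanks masquerade as local maxima), and applies a
prominence floor of 5 % of the unmasked global maximum — standard EEM
practice where the source protocol is silent.

**FTIR.** The amide-I window is fixed at 1600–1700 cm⁻¹ with an
endpoint-line baseline (no rubber band); negative residuals are clipped
with a logged count. Sub-peaks are Gaussian — the dominant convention for
amide-I curve fitting. Seeding is either second-derivative minima
(Savitzky–Golay, window 9 points, order 3, both configurable) or the five
class-range midpoints; the bounded Gaussian-sum least-squares fit then
iteratively adds a component at the largest residual (up to 8 components)
until the RMS residual falls below 0.2 % of the band maximum, which is what
resolves bands overlapped more closely than the seeders can see. Class
ranges: β-sheet 1615–1637, antiparallel β-sheet 1638–1648, α-helix
1649–1660, β-turn 1661–1680, random coil 1681–1692 cm⁻¹; the 1 cm⁻¹ gaps
between printed ranges are closed so each gap belongs to the class below it
(each range keeps its own printed lower edge; assignment is deterministic
at every boundary). Centers outside 1615–1692 are excluded from the
percentage denominator with a warning.

**Units and the compound registry.** Inhibitor doses are μg/mL, substrate
mmol/L, quencher mol/L, temperatures K. Because binding constants are molar
while dosing is by mass, the registry carries molecular weights computed
from the molecular formulas of the six porphyrins (TAPP C₄₄H₃₄N₈, THPP
C₄₄H₃₀N₄O₄, TCPP C₄₈H₃₀N₄O₈, and the metalated forms modelled as neutral
M(II) chelates, M–TCPP = TCPP − 2H + M). The neutral-chelate choice (no
axial counter-ion) is the simplest structurally defensible one; users can
override any entry.

## Synthetic data: what it does and does not show

Each generator realizes the exact forward model its analysis stage
inverts: the four classical inhibition rate laws, `F = F₀/(1+K_SV Q)` or
`F = F₀/(1+K_a Qⁿ)` titrations with exact inner-filter attenuation, exact
Van't Hoff K_a(T), logistic dose-response, Gaussian synchronous/EEM/amide-I
spectra with known centers, shifts and class areas. Defaults mirror the
study conditions: substrate grid 2.5/5/7.5/10 mmol/L, temperatures
298/304/310 K, amide-I composition patterned on native α-amylase. Noise is
additive Gaussian with one `default_rng(seed)` stream per dataset, drawn in
row order; replicate noise magnitudes are not published, so the tests that
use noise state their sd explicitly (e.g. 2 % of full scale for the IC50
robustness check).

Passing the zero-noise inverse-pair suites therefore demonstrates
correctness of the estimators on their own model class, not robustness to
real-instrument effects: drift, photobleaching, scattering backgrounds,
non-Gaussian replicate error and model misspecification (e.g. Voigt-shaped
amide-I bands) are all outside the generators. The desk-scale checks
against the published constant tables are the complementary evidence that
the estimator conventions match how such data are actually reduced.

One internal consistency limit is worth knowing: published ΔH⁰/ΔS⁰ pairs
regenerate the published K_a(T) columns only to within the residuals of the
regression they came from (several percent at R² ≈ 0.98), so round-trip
tests through printed thermodynamic constants use a 10 % band while
round-trips through the package's own fits are exact to 1e-9.

## Numerical choices and degenerate inputs

All straight-line fits are unweighted OLS (`scipy.stats.linregress`);
nonlinear fits use `scipy.optimize.curve_fit`/`least_squares` with bounds
(centers confined to the amide-I window, positive Km/Vmax/IC50). Ties in
peak localization break toward shorter wavelength. Errors are specific:
division-by-zero blanks, unbracketed IC50, rank-deficient reversibility
lines, fluorescence enhancement where quenching is required, F ≥ F₀ points
listed by 1-based index in the double-log fit, non-positive secondary
slopes ("no inhibition signal"), and Kis requested for a non-competitive
classification. CSV loaders validate the declared schema, report 1-based
row indices, and reject empty tables explicitly. JSON reports are
deterministic (sorted keys, repr-round-trip floats): identical inputs give
byte-identical files.

## Known limitations

No global multi-curve fitting with shared parameters, substrate-depletion
or tight-binding corrections; no time-resolved lifetime analysis or FRET;
no heat-capacity (curved Van't Hoff) models; no PARAFAC for EEMs; no
Fourier self-deconvolution for FTIR. Published secondary-structure tables
are not numerically reproducible because the raw spectra are not public;
the FTIR stage is validated on synthetic mixtures (class areas recovered
within 3 % absolute) instead.
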