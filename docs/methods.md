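# Methods

This note documents the models, parameter choices, and numerical
conventions behind `poregibbs`, and what its synthetic-data tests do and do
not establish about field data.

## Thermodynamic core

**Reactions and data.** The two built-in catabolic reactions are
hydrogenotrophic methanogenesis (HCO3⁻ + 4 H2 + H⁺ → CH4 + 3 H2O) and
hydrogenotrophic sulfate reduction (SO4²⁻ + 4 H2 + H⁺ → HS⁻ + 4 H2O);
sulfate-coupled AOM is treated as reverse methanogenesis. Standard-state
Gibbs energies of formation and standard entropies at 25 °C / 1 atm for the
nine aqueous species are bundled in `src/poregibbs/data/species.csv`,
converted from the SUPCRT92 compilation (cal → kJ). Charge and C/H/O/S
balance of any user-defined reaction are verified at construction.

**Temperature correction.** ΔG°_r(T) = ΔG°_r(25 °C) − ΔS°_r·(T − 25 °C),
i.e. the reaction entropy is held constant. Over the package's validity
range (−2 to 40 °C) this differs from a full revised-HKF evaluation by well
under 1 kJ/mol, far below the natural variability of porewater activities;
the methanogenesis value at 24 °C is −229.98 kJ/mol, within 0.4 kJ/mol of
the −229.59 kJ/mol computed for the same conditions with the full
equation-of-state machinery. Pressure is treated as 1 atm throughout — the
sites this models are a few metres deep — and no pressure correction is
implemented.

A second reported anchor for this reaction, −238.98 kJ/mol at 28.5 °C, is
not consistent with any constant-entropy extrapolation of the 24 °C value
(our table gives ≈ −229.8 at 28.5 °C; the ~9 kJ/mol gap far exceeds any
plausible dΔG°/dT). Both anchors ship in `STANDARD_DG_ANCHORS` and
`gibbs_energy`/`depth_profile_gibbs` accept an explicit `dG_standard`, so
analyses tied to the 28.5 °C setting can use its reported value while the
table remains internally consistent.

**Activity model.** Charged species use the Helgeson B-dot extended
Debye-Hückel form, log₁₀ γ = −A z²√I/(1 + B å√I) + Ḃ I, with A(T) and B(T)
interpolated from the standard 0–40 °C table and Ḃ = 0.041 held constant
(its temperature dependence is negligible here). The ion-size parameter for
HCO3⁻, å = 3.787 Å (`HCO3_ION_SIZE_ANGSTROM`), was calibrated once so that
γ(−1, 0.7 M, 24 °C) = 0.661, the value reported for bicarbonate at these
conditions; the same parameterization then predicts 0.659 at 28.5 °C
against a reported 0.660, an independent check. Other ion sizes are
Kielland values (SO4²⁻ 4.0, CO3²⁻ 4.5, HS⁻ 3.5, H⁺ 9.0 Å). Dissolved CH4
and H2 are assigned γ = 1, water activity defaults to 1.0 (configurable via
the activities map), and a_H⁺ = 10^(−pH) with pH-scale differences (NBS vs
total) ignored.

**Carbonate speciation.** DIC fractions use pK1/pK2 from the Lueker et
al. (2000)-form seawater fit (total scale; nominal validity S 19–43) for
S > 0.5 ‰ and the Plummer & Busenberg (1982)-form freshwater constants
below; the `constants` argument accepts any `(T, S) → (pK1, pK2)` callable
or explicit pair, making the parameterization swappable. At pH 7.2, 24 °C,
35 ‰ the bicarbonate fraction of DIC is 0.942. The reported "ratio of
bicarbonate to carbon dioxide … 0.94" is implemented as this *fraction*:
the literal HCO3⁻:CO2 ratio at pH 7.2 is ≈ 20, so 0.94 can only describe
the fraction of DIC.

## Gas conversions

**Hydrogen.** Saturation under 1 atm pure H2 is modeled as
C(T,S) = C₂₅·exp[530·(1/T − 1/298.15) − k_s·S] μM. The van't Hoff slope
(530 K) is the standard Henry-law temperature dependence for H2; C₂₅ =
785.54 μM and k_s = 0.004640 ‰⁻¹ are solved exactly from the two site
anchors (671.8 μM at 24 °C/35 ‰; 704.9 μM at 28.5 °C/18.9 ‰). The solution
is physically sound — standard compilations give ≈ 780 μM for fresh water
at 25 °C and Setchenow coefficients of 0.004–0.005 ‰⁻¹ — so the
correlation interpolates sensibly across the package's validity range
(−2 to 40 °C, 0 to 40 ‰). Headspace ppm converts linearly:
C_aq = ppm·10⁻⁶·C_sat. No correction is applied for H2 re-equilibration
kinetics during vial incubation.

**Methane.** Aqueous CH4 is ideal-gas moles in the vial headspace,
n = (ppm·10⁻⁶ atm)·V_h/(R·T), divided by the porewater volume Φ·V_s of the
sediment plug and expressed in mM. The unit contract (mL in, mM out)
replaces any literal "×1000" factor. Dissolved residual CH4 in the killed
slurry at equilibration is neglected.

**DIC.** The measured CO2 mixing ratio is multiplied back through the
dilution chain (each step "a mL into b mL total" contributes b/a; a
"5 mL headspace : 135 mL zero air" dilution is read as 5 parts in 140),
converted to moles over the vial headspace, divided by the extraction
efficiency (default usage: 0.969, accepted as a given constant since the
vial geometry needed to derive it independently is not available), and
normalized by porewater mass at 1.025 g/mL. Vial headspace volume is a
required input with no default.

## Profiles, porosity, and cleaning

Porosity is Φ = w·ρ_sm/(ρ_sm·w + (1−w)·ρ_pw) with ρ_sm = 2.5 and ρ_pw =
1.025 g/cm³. Outlier cleaning applies two depth-dependent rules: in the
shallow window (default 0–33 cm) a value outside [Q1 − 1.5·IQR, Q3 +
1.5·IQR] — quartiles over a centered 5-point moving window ("n = 5" read as
the window length; a global-quartile variant is available via
`global_quartiles=True`) — is replaced by the mean of its three nearest
non-outlying values ("three adjacent" read as nearest-by-depth, since a
symmetric neighborhood of three is ambiguous); in the deep window (33–51
cm) a value strictly more than 3 standard deviations from the mean of the
surrounding window is replaced by that mean. Boundary cases use strict
inequalities — a value exactly on a fence is retained. Cleaning is
idempotent on the suite's fixtures. Depths are section midpoints in cm
below seafloor.

Core data round-trip through wide CSVs (`depth_cm`, variable columns,
optional `replicate`) with site metadata in a YAML sidecar.

## Energetics pipeline

The hydrogen profile defines the output grid (replicate triplicates
reduced by mean by default; median or independent handling available).
Other variables are matched by nearest depth within half the coarser
median grid spacing — profiles on offset grids align, single missing
depths do not silently borrow a neighbor. A missing DIC value is filled
with the mean of the depths immediately above and below, and the fill is
flagged in the result; unfillable gaps omit the depth. Classification
against an energy threshold ΔG_min (defaults −10 kJ/mol for
methanogenesis, −19.1 for sulfate reduction, both configurable to 0 to
express the no-minimum position) yields forward/reverse exergonic,
sub-threshold, or equilibrium states.

## Stoichiometric diagnostic

ΔDIC and ΔSO4 are computed against a reference horizon (a depth in the
profile, or a fixed overlying-water value); the fit regresses ΔDIC on
|ΔSO4| by OLS with free intercept (the source fits do not state whether
the intercept was forced; a zero-intercept option and a reduced-major-axis
estimator are provided since sulfate also carries error). Slopes below 1.5
classify as AOM-dominated, at or above 1.5 as OSR-dominated; an optional
band yields a "mixed" class. Departures from the integer stoichiometries
(organic-matter oxidation state, carbonate precipitation) are not modeled.

## Synthetic sites

The generator emulates the profile *shapes and moments* of the two site
archetypes; it is not a reaction-transport model. Sulfate is constant over
a bioirrigated plateau, declines linearly to zero at the depletion depth,
and carries Gaussian noise (sd 0.3 mM, floored at 0). DIC equals a
reference value plus the ground-truth slope times the *realized* sulfate
drawdown plus Gaussian noise, so the noiseless limit satisfies ΔDIC =
slope·|ΔSO4| exactly at every depth and the OLS estimate is unbiased.
Methane is linear (no net AOM; organic-rich template, deep value 1.4 mM
capped at 1.5 mM saturation) or concave-up (AOM; exponential tail
deep_value·e^{(z−z_dep)/λ} above the depletion depth with λ = 8 cm — a free
shape parameter — and a linear rise below). Hydrogen is drawn per zone
from a moment-matched lognormal (strictly positive, right-skewed;
truncated-normal available), with triplicate measurements jittered by a
2% relative sd — kept small so the between-depth moments match the
reported zone statistics, which already include measurement noise.

Template defaults are the reported site values wherever one exists:
organic-rich — 2 cm sections, sulfate 24 mM with a 12 cm plateau depleting
at 35 cm (reported range 30–40), slope 2.38 over the 12–40 cm window,
hydrogen zones 0–10 cm (mean 0.876 nM, variance 0.2285 nM²) and deeper
(mean 0.410 nM); organic-poor — 1 cm sections, sulfate 14 mM from the
surface depleting at 30 cm, slope 0.629 over 0–47 cm, hydrogen zones
0–15 cm (0.465 nM, 0.00081 nM²), 15–30 cm (transition, 1.0 nM, 0.203 nM²),
and below 30 cm (1.49 nM, 0.1936 nM²), with triplicates only above 47 cm.
Three choices had no reported value and are this package's own: the
organic-rich deep-zone hydrogen variance (0.04 nM²), the organic-poor
mid-zone mean (1.0 nM), and the synthetic sites' DIC reference values
(40 mM at the 12 cm reference horizon, 2 mM overlying water) — all chosen
once as field-plausible. The organic-poor sediment pH is likewise
unreported; the synthetic site uses 7.2, the one sediment pH measured in
this pair of settings. Reported variances are quoted in nM in their
source; this package reports nM².

**What passing tests show.** Parameter recovery (slopes, zone moments) and
the qualitative energetic structure are demonstrated on data *drawn from*
the template distributions; they validate the estimators and the pipeline
plumbing, not the field interpretation. Field features the generator
omits: depth-correlated noise, inter-core and seasonal variability,
diffusion-reaction coupling between profiles, carbonate precipitation, and
δ¹³C systematics.

**Near-equilibrium sign structure.** With the 28.5 °C standard-state
anchor, the below-depletion hydrogen mean (1.49 nM) sits almost exactly at
the methanogenesis equilibrium concentration for the accompanying methane
and DIC levels — the expected state of a hydrogen-buffered methanogenic
zone. A single core's deep-zone mean ΔG_r is therefore negative with high
but not unit probability, and the end-to-end sign-flip test asserts the
pattern on zone means across 25 seeded cores (upper 0–15 cm positive in
all, 30–40 cm negative in ≥ 20) rather than per depth at one seed. The
30–40 cm test window is the interval between the depletion depth and the
bottom of the reported methanogenesis-exergonic zone; deeper than that,
methane accumulation pushes the reaction back toward equilibrium and
neither direction is consistently exergonic — also the reported field
behavior.

## Proton-motive force

The per-proton translocation cost is F·|ΔΨ| + 2.303·RT·|ΔpH|: both
gradient components are taken as magnitudes of a gradient opposing proton
export, giving 14.43 kJ/mol H⁺ at 120 mV, ΔpH = −0.5, 25 °C, so a 10 kJ
budget moves 0.693 mol of protons. The defining expression mixes
per-proton and per-reaction terms ambiguously; the alternative "literal"
reading (budget = n·F·ΔΨ − 2.303·RT·ΔpH, giving 0.617 mol) is available
via `convention="literal"`. Neither reading reproduces the 0.63 mol quoted
in discussion of this thought experiment, so both auditable conventions
are shipped rather than a reverse-engineered constant. ATP yield is plain
division by the phosphorylation cost (10/60 ≈ 0.167 ≈ 0.17 mol ATP).

## Numerical conventions and limitations

- Zone membership and alignment windows are half-open [lower, upper);
  regression windows are closed [min, max].
- Welch's test uses `scipy.stats.ttest_ind(equal_var=False)`; the suite
  checks it against independently coded Welch formulas.
- OLS and its slope CI come from statsmodels; the RMA slope CI is the
  large-sample ratio approximation.
- Sulfide totals are treated as HS⁻ with γ(−1); H2S/HS⁻ partitioning is
  not modeled (mildly overstates the HS⁻ activity at pH < ~7.5, a ≤ 1–2
  kJ/mol effect on the sulfate-reduction ΔG_r).
- No Pitzer model, no pressure corrections, no redox speciation, no
  reaction-transport rates or power (energy-flux) calculations.
- Simulation sizes in the test and acceptance suites (200 cores for slope
  recovery, 500 for the Welch power property, 25 for the sign-flip
  pattern) were chosen so sampling error is small relative to the asserted
  margins while a full run stays in the seconds range.
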