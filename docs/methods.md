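# Methods

## Scope and intent

`ipdsim` implements the model-informed workflow used to develop in vivo
predictive dissolution (IPD) methods for immediate-release tablets of a
high-dose, poorly permeable drug: (1) biopharmaceutic screens and
constrained Weibull fitting of dissolution profiles, (2) a mechanistic
oral absorption/disposition simulation driven by the fitted release
curve, (3) noncompartmental scoring of predictions against plasma data,
and (4) virtual bioequivalence (VBE) campaigns. The default
parameterization describes acyclovir (BCS III/IV borderline: fraction
absorbed 10–30%, lowest biorelevant solubility 2.33 mg/mL at pH 5.8,
gastric solubility 3.6 mg/mL at pH 2.0, strengths 200–800 mg).

## Dissolution model

The release curve is the empirical Weibull function
`W(t) = Wmax(1 − exp(−(t − tlag)^β/α))`, which collapses to the
first-order model at `β = 1`, `tlag = 0`. The scale parameter multiplies
the *power of time* directly, so `α` carries units of min^β; the common
alternative `exp(−((t−tlag)/α')^β)` is the same family under
`α = α'^β` — fitted curves are identical, only the reported scale
differs. Fitting holds `tlag` (0 for IR tablets) and `Wmax` fixed and
estimates only `α, β`, which avoids overfitting 9-point profiles.
`Wmax` comes from the solubility cap `S·V·100/D`, truncated at 100%
when the dose fits in the vessel (e.g. 200 mg in 150 mL).

Numerical choices: ordinary least squares on replicate means (pooled
replicate points exposed as an option, identical on noise-free data);
trust-region reflective optimizer with bounds `α ∈ (10⁻⁹, 10⁶)`,
`β ∈ (0.1, 10)`; deterministic start `β = 1`, `α` from the observed time
to 63.2% of `Wmax` (linear interpolation, last sample time if the
profile never gets there); tolerances 10⁻¹⁵ so noise-free round trips
recover parameters to ~10⁻⁸ relative. An all-zero profile raises a
convergence error; observed means exceeding the fixed `Wmax` are
tolerated with a recorded warning (real profiles can overshoot the
theoretical cap within assay error).

## Gastrointestinal absorption model

An open compartmental absorption-transit chain — stomach, seven
small-intestinal segments, colon in series — stands in for proprietary
commercial ACAT implementations. All constants are exposed in
configuration; the topology is the only structural choice and follows
the literature-standard CAT layout (7 SI segments, first-order transit).

**Release and the solubility cap.** The "dispersed" dosage-form
semantics: undissolved formulation transits with luminal contents and
releases wherever it is, at the Weibull hazard
`h(t) = β(t−tlag)^(β−1)/α` applied to the releasable pool (dose ×
Wmax/100; the remainder never releases and simply transits). Released
mass in each segment partitions instantaneously between dissolved and
suspended-solid pools with dissolved = min(mass, S(pH)·V). This
equilibrium partition is the fast-kinetics limit of a first-order
redissolution model; we adopted it after finding that an explicit
two-pool relaxation at 10⁴/h produced identical plasma curves (Cmax
agreeing to 5 significant figures) at ~25× the integration cost, while
the equilibrium form enforces the cap exactly. The consequence matters
scientifically: for an 800 mg dose the dissolved luminal mass plateaus
at S·V per segment (540 mg in 150 mL of gastric medium), so release
beyond the cap only grows the suspended pool — the nonsink mechanism
that makes large-vessel (900 mL) dissolution inputs overpredict
exposure.

**Absorption and disposition.** Absorptive flux from each segment is
`Peff·A·(dissolved/V)` (stomach non-absorbing); central + one
peripheral compartment; renal elimination = filtration clearance +
saturable secretion `Σ Vmax·E·C/(Km + C)` (OAT2, MATE1). Hazard is
capped at 10⁴/h so near-instantaneous release (β < 1 at t → tlag⁺)
stays integrable; the cap corresponds to a release half-time of ~0.25 s
and is irrelevant for realistic tablets.

**Parameters (defaults, units, provenance).**

| parameter | default | note |
|---|---|---|
| Peff | 3.56×10⁻⁵ cm/s | MDCK-calibrated effective permeability |
| D_aq | 9.24×10⁻⁶ cm²/s | carried for provenance; unused by Weibull-driven release |
| solubility | 3.6 (pH 2.0), 2.33 (pH 5.8) mg/mL | linear in pH, clamped at table edges |
| gastric emptying t½ | 0.25 h | fasted |
| stomach / SI / colon fluid | 46 / 100 / 50 mL | static small fasted volumes |
| SI transit | 3.32 h total over 7 segments | standard CAT value |
| SI segment area | 8 cm² (colon 2 cm²) | *effective* area, see below |
| Vc, k12, k21 | 0.7 L/kg, 0.30/h, 0.25/h | two-compartment disposition |
| filtration CL | 6.4 L/h | ≈ fu·GFR |
| OAT2 / MATE1 Vmax | 0.12 / 0.024 mg/s/mg, E = 1 mg | Km 36 mg/L each |
| body weight | 68.2 kg | trial-population mean |

The absorptive areas are effective contact areas between the small
fluid pockets and mucosa, not anatomical areas; they were calibrated
once so that a fully dissolved low dose of a drug with this Peff
absorbs a 10–30% fraction (the reported physiological band for this
permeability class; the default gives fa ≈ 0.23 for a 200 mg solution)
and were not tuned further. The transporter Km is not publicly
reported; 36 mg/L keeps secretion effectively linear at therapeutic
plasma concentrations (< 2 mg/L) while preserving the saturable form,
and yields a total clearance of ≈ 21 L/h. Because disposition constants
are calibration defaults rather than published values, the simulator's
tests assert conservation laws, limiting cases and orderings — not
specific clinical concentrations.

**Numerics.** LSODA, rtol 10⁻⁸, atol 10⁻¹² × dose (dose-relative so
tracer-dose linearity checks hold), dense output interpolated to the
clinical sampling grid (0–24 h, 21 points). Internal state is mg and
hours; Peff converts from cm/s at the boundary; plasma output in ng/mL.
The right-hand side sums to zero by construction, so the mass ledger
(unreleased + dissolved + suspended + body + eliminated + fecal = dose)
closes to ~10⁻¹⁴ relative, asserted at 10⁻⁶ in tests.

## Noncompartmental analysis

Cmax/Tmax from the observed maximum (earliest grid time on ties);
AUC0–t by the linear-up/log-down trapezoid (log rule on declining
segments, exact for exponential decline on the sparse late grid; the
plain linear rule is exposed as `auc_method="linear"`); λz by
log-linear regression on the last 3 positive concentrations
(configurable), accepted only if the terminal window strictly declines;
AUC0–inf = AUC0–t + Clast/λz with the extrapolated fraction reported.
Profiles without a declining terminal phase get NaN AUC0–inf plus a
recorded warning rather than an exception. Non-positive concentrations
are treated as missing for λz purposes only.

## Virtual bioequivalence

The virtual population mirrors the clinical crossover cohort
biometrics (n = 42 male, 31.1 y, 168.7 cm, 68.2 kg). Variability is
propagated through Peff with median-preserving log-normal draws:
a between-subject draw per subject and fresh within-subject draws per
period, both at 35% CV by default (the within-subject CV observed for
this highly variable drug; the two knobs are independent because the
between/within decomposition is not otherwise identifiable). Subjects
are randomized 1:1 to TR/RT sequences. Each subject-period is a full
PBPK simulation followed by NCA.

Inference is the classical 2×2 crossover ANOVA on log metrics with
period, treatment and subject fixed effects (subject dummies absorb
sequence); the 90% CI of the back-transformed treatment ratio uses the
t distribution on n−2 residual degrees of freedom, and the
within-subject CV is `100·√(exp(MSE) − 1)`. A trial passes when the
CIs for Cmax and AUC0–inf (configurable; AUC0–t is also computed) lie
within 80.00–125.00%. A campaign runs 10 independent trials and passes
at a ≥ 80% trial pass rate. All randomness flows from one campaign
seed through a SeedSequence spawn per trial, so campaigns replay
exactly.

## Synthetic study conditions

The generators reproduce the study designs, not any measured dataset:
dissolution replicates (n = 3) on the 5–120 min sampling grid with 2%
multiplicative CV (typical UV-assay precision; optional additive
noise), and "observed" plasma profiles simulated from known true
parameters with 15% multiplicative residual error on the clinical grid
(typical bioanalytical + model residual scale for a highly variable
drug). What passing tests therefore show: the pipeline recovers known
ground truth under realistic noise, conserves mass, reproduces
limiting-case closed forms, and its BE machinery is calibrated
(self-vs-self campaigns pass; pass probability falls as the true GMR
departs from 100%). What they do not show: agreement with any specific
clinical dataset — the disposition defaults are calibration values, and
real formulations differ from Weibull curves in ways the generator does
not emulate (coning, disintegration bursts, pH-dependent excipient
effects).

## Known limitations

- Static luminal fluid volumes; no fluid secretion/absorption dynamics.
- No particle-size dissolution mechanics: release is entirely
  Weibull-driven, so the in vitro method must itself capture
  solubility-limited behavior (that is the point of the small-volume
  design).
- Alcohol-dehydrogenase metabolism is omitted (negligible for this
  drug); elimination is renal only.
- Colonic absorption uses a single well-mixed compartment with a small
  effective area; colonic pH solubility is clamped to the lowest table
  entry.
- The BE engine covers the standard 2×2 average-BE design only — no
  replicate designs, reference scaling, or dropouts.
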