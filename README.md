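# ipdsim

Tools for developing **in vivo predictive dissolution (IPD)** methods for
immediate-release tablets of poorly permeable, high-dose drugs —
acyclovir-style borderline BCS III/IV compounds — by coupling small-volume
in vitro dissolution data to a mechanistic oral-absorption model and
virtual bioequivalence (VBE) trials.

The problem: for a poorly permeable drug the gut wall provides no
"physiological sink", so whether a dose dissolves completely in the small
gastrointestinal fluid volume controls exposure. The Dose number
`Do = (D/V0)/S` flags this (Do > 1 means the dose cannot dissolve in a
250 mL glass of water), and in a dissolution vessel of volume `V` the
profile can only plateau at

```
Wmax = min(100, S · V · 100 / D)   [% of dose]
```

Dissolution curves are summarized by the constrained Weibull model

```
W(t) = Wmax · (1 − exp(−(t − tlag)^β / α))
```

with `Wmax` fixed from solubility and `tlag = 0` for IR tablets, so only
the scale `α` and shape `β` are fitted. The fitted curve drives a
9-compartment absorption-transit PBPK model (stomach, 7 small-intestinal
segments, colon; static small fluid volumes; per-segment solubility caps;
permeability-limited absorption `J = Peff·A·C`; two-compartment
disposition; renal filtration plus saturable OAT2/MATE1 secretion).
Predicted plasma profiles are scored against observations by
noncompartmental analysis (Cmax, Tmax, AUC0–t, AUC0–inf) and the percent
prediction error `PE = 100·(pred − obs)/obs`; competing products are
compared in simulated 2×2 crossover trials on a log-normal virtual
population (n = 42, Peff CV 35%), with the classical crossover ANOVA and
the 80–125% rule on the 90% CI of the geometric mean ratio, repeated over
10 trials with an 80% pass-rate decision threshold.

## Worked example

```python
import ipdsim as ip

# 800 mg tablet dissolved in a 135 mL mini-vessel, gastric solubility 3.6 mg/mL
wmax = ip.compute_wmax(ip.SolubilityContext(s=3.6, d=800, v=135))   # 60.75 %

# synthesize a noisy 3-replicate dissolution dataset and refit it
truth = ip.WeibullParams(alpha=30.0, beta=1.5, wmax=wmax)
scenario = ip.SyntheticScenario(true_params={"reference": truth}, seed=7)
profile = ip.make_dissolution_dataset(scenario)
fit = ip.fit_weibull(profile, wmax_fixed=wmax)
print(fit.params.alpha, fit.params.beta)      # 28.98, 1.476 (truth 30, 1.5)

# drive the PBPK model with the fitted release curve
model = ip.build_model()
result = ip.simulate_plasma(model, 800.0, fit.params)
metrics = ip.compute_nca(result.profile)
print(metrics.cmax, metrics.tmax)             # 384.5 ng/mL at 3.5 h
print(ip.fraction_absorbed(result))           # 0.088
```

The fitted `α`, `β` recover the generating values to within a few percent
at the default 2% assay noise. The simulated 800 mg profile peaks near
385 ng/mL with ~9% of the dose absorbed: the solubility cap holds the
dissolved luminal mass at ≈300 mg (never the full 800 mg), which is
exactly the nonsink behavior the small-volume dissolution method is
designed to reproduce. A campaign of ten self-vs-self crossover trials
(`ip.run_vbe_campaign(model, fit.params, fit.params, seed=1)`) passes
10/10 with GMRs near 100% and within-subject CVs of ~25–40%.

A CLI wraps the same pipeline: `ipdsim make-fixtures`,
`ipdsim fit-dissolution`, `ipdsim simulate-pk`, `ipdsim run-vbe`
(exit code 0 = pass, 2 = BE decision fail).

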