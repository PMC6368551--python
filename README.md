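# brineage

Analysis toolkit for MgCl₂-dominated ("athalassohaline") deep-sea brine
lakes, built around three linked questions about the Lake *Hephaestus*
system on the Mediterranean Ridge:

1. **How long has the brine been sitting on the sediment?**
   Pore waters beneath a newly ponded brine record its arrival: downward
   diffusion and advection of brine ions (Mg²⁺, Cl⁻) and the exchange of
   water isotopes (δD) imprint depth profiles whose shape depends on the
   contact time. `brineage` forward-models these profiles with the
   classical 1-D advection–diffusion solution and inverts them for the age.
2. **Where in the seawater–brine interface can life function?**
   The ~3-m halocline spans Mg²⁺ from ~70 mM (seawater) to 4,720 mM
   (brine). Samples are binned into the named interface fractions
   (UIF/MIF/LIF), mapped to water activity through a monotone calibration
   curve built from measured anchors, and classified against the
   recognized water-activity limit for cell division (a_w = 0.585) and the
   deepest observed active community (2,970 mM Mg²⁺).
3. **What does the dissolved organic matter look like?**
   Negative-mode FT-ICR-MS peak lists are assigned CHNOS molecular
   formulas by exhaustive bounded search at sub-ppm tolerance, then
   summarized as van Krevelen coordinates, compound-class counts and
   ratios (CHOS/CHO, CHNOS/CHNO), sulfur-count histograms and
   between-sample unique fractions.

A seeded synthetic-data module generates every input the pipeline needs
(pore-water profiles, haloclines, peak lists with ground truth), so the
whole analysis runs and is tested without any external data.

## The model

Tracer concentration `C(z, t)` at depth `z` below the sediment–water
interface obeys Fick's second law with advection,

    ∂C/∂t = D_s ∂²C/∂z² − V_s ∂C/∂z,

with the brine held at `C₀` at `z = 0` and background `C_bg` at depth.
On the dimensionless scale the closed-form (Ogata–Banks) solution is

    F(z,t) = ½ [ erfc((z − V_s t)/(2√(D_h t/R_d)))
               + exp(V_s z/D_h) · erfc((z + V_s t)/(2√(D_h t/R_d))) ],

with `D_h = D_s` for nonreactive tracers (`R_d = 1`); concentrations are
mapped affinely onto `[C_bg, C₀]`. The overflow-prone second term is
evaluated through the scaled complementary error function `erfcx`. The age
is the `t` minimizing the span-standardized residual sum of squares, found
by bounded scalar minimization over `log₁₀ t` with multiple starts;
uncertainty comes from a residual-resampling bootstrap. One Julian year is
3.15576 × 10⁷ s.

For the DOM stage, each peak's neutral mass is `m/z + 1.00727646677` u
([M−H]⁻), decomposed over bounded integer compositions CcHhNnOoSs filtered
by RDBE ≥ 0, even-electron (integer) RDBE, and H/C and O/C plausibility
ranges, ranked by |ppm error| with heteroatom parsimony as tie-break.

## Worked example

```python
from brineage import (TransportParams, preset_profile, fit_age,
                      bootstrap_age_ci, fit_activity_curve,
                      HEPHAESTUS_ANCHORS, make_interface_profile,
                      locate_threshold_depth)

# Mg2+ pore-water profile, synthesized from the published parameter set
params = TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=4720.0, Cbg=61.0)
profile = preset_profile("hephaestus_mg", seed=42)   # 2% IC noise

est = fit_age(profile, params)
lo, hi = bootstrap_age_ci(profile, params, n_boot=500, seed=42)
print(f"{est.t_seconds:.3e} s = {est.t_years:.0f} yr (95% CI {lo:.0f}-{hi:.0f})")
# 2.208e+10 s = 700 yr (95% CI 672-714)

curve = fit_activity_curve(HEPHAESTUS_ANCHORS)
halocline = make_interface_profile(shape="logistic", n=61)
print(f"a_w = 0.585 at {locate_threshold_depth(halocline, curve):.2f} m")
# a_w = 0.585 at 1.86 m
```

The fitted 2.21 × 10¹⁰ s is the sediment–brine contact time: this profile
was generated at the published timing of 2.2 × 10¹⁰ s (≈ 700 years), and
the inversion recovers it within the measurement noise. The threshold
depth says the recognized limit for cell division falls roughly midway
down a ~3-m sigmoidal halocline — only the upper half of the interface is
within the habitable water-activity window.

The same analyses are exposed on the command line:

```bash
brine-age run --demo --seed 1 --out report.json   # full synthetic pipeline
brine-age synth pore --preset hephaestus_mg --seed 5 --out mg.csv
brine-age fit --profile mg.csv --params params.yaml --boot 500 --seed 5
brine-age interface --profile iface.csv --threshold 0.585
brine-age dom assign --peaks peaks.csv --tol 0.2 --out assigned.csv
```

## Layout

| module | contents |
| --- | --- |
| `brineage.transport` | closed-form solution, parameter/profile types, unit helpers |
| `brineage.inversion` | age and single-parameter fits, bootstrap CI, age comparison |
| `brineage.habitability` | interface layers, activity curves, thresholds, classification |
| `brineage.domformula` | neutral-mass arithmetic, formula decomposition, class statistics |
| `brineage.synthetic` | seeded generators and published parameter presets |
| `brineage.io`, `brineage.pipeline`, `brineage.cli` | file formats, staged runs, `brine-age` CLI |
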