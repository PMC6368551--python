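# Methods

This note records the models, parameter choices and numerical decisions
behind `brineage`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Transport model

Pore-water tracers beneath a ponded brine are modelled by 1-D
advection–diffusion,

    ∂C/∂t = D_s ∂²C/∂z² − V_s ∂C/∂z,

with z in metres below the sediment–water interface (positive downward),
constant boundary value C₀ at z = 0 (the well-mixed brine column), and
uniform initial/background value C_bg. The closed-form Ogata–Banks
solution is evaluated on the dimensionless scale F ∈ [0, 1] and mapped
affinely onto [C_bg, C₀].

Assumptions: homogeneous sediment (one effective D_s already corrected for
tortuosity), constant V_s, no reaction (R_d = 1 by default; the R_d slot in
the formula is honoured if set > 1), no compaction, no temperature
dependence, semi-infinite domain. The affine background mapping is what
lets the identical solution fit ions relaxing downward to seawater values
and δD relaxing upward to the seawater isotopic composition; the brine
reservoir is assumed to hold both ion concentrations and isotope ratio
fixed at z = 0.

Key parameters (defaults bundled as presets):

| parameter | value | units | meaning |
| --- | --- | --- | --- |
| D_s (ions) | 2.4 × 10⁻¹⁰ | m² s⁻¹ | effective sediment diffusivity, Mg²⁺/Cl⁻ |
| D_s (δD) | 2.96 × 10⁻¹⁰ | m² s⁻¹ | ionic D_s rescaled by the free-water diffusivity ratio of water vs chloride (`scale_diffusivity`) |
| V_s | 9.51 × 10⁻¹¹ | m s⁻¹ | downward pore-water advection |
| C₀/C_bg (Mg) | 4720 / 61 | mmol kg⁻¹ | brine / Mediterranean seawater |
| C₀/C_bg (Cl) | 9120 / 630 | mmol kg⁻¹ | brine / seawater |
| C₀/C_bg (δD) | −16.5 / +5.1 | ‰ VSMOW | brine / seawater |
| 1 year | 3.15576 × 10⁷ | s | Julian year; reproduces the printed (seconds, years) pairings after rounding |

The deep background values for the ion curves and the δD endpoints are not
independently constrained by the profiles themselves; they are taken from
the published endmember compositions and are declared assumptions.

### Numerics

`exp(V_s z/D_h)·erfc(·)` overflows beyond roughly a metre at these
parameters; the implementation uses the identity
`exp(a)·erfc(b) = erfcx(b)·exp(a − b²)`, whose exponent is ≤ 0 for all
z ≥ 0, V_s ≥ 0, R_d ≥ 1, so the evaluation is overflow-free everywhere.
F is clipped to [0, 1] against rounding at the extremes. The closed form
was verified against an independent Crank–Nicolson solver of the PDE
(tests only): maximum deviation ~3 × 10⁻⁷ of the concentration span at the
bundled parameter set, far inside the 0.5 % acceptance band.

## Age inversion

The contact time t is the only routinely free parameter. The objective is
the sum of squared residuals with each tracer standardized by its span
|C₀ − C_bg|, so a joint Mg/Cl/δD fit weights a ~4,700 mmol kg⁻¹ gradient
and a ~22 ‰ gradient comparably. Minimization is bounded scalar search
over log₁₀ t (t spans decades; the log scale avoids bound-hugging),
multi-start on 3 log-spaced sub-intervals, `xatol` 1e-10 on log t, with
interval edges evaluated explicitly so a boundary optimum is returned
exactly. Optimizer failure from every start raises, never a silent
fallback.

`fit_free_parameter` mirrors the δD treatment (fit D_s at fixed t) and
generalizes to V_s and C₀. C₀ enters the model affinely and is solved in
closed form. Fitting t and D_s together is refused with an explicit
identifiability error: at small V_s they enter the solution almost solely
through the product D_s·t.

Uncertainty: residual-resampling bootstrap (depths are design points fixed
by coring, not random draws, so pairs resampling would be wrong),
percentile interval, widened if needed to contain the point estimate so
the interval invariant holds even for skewed replicate distributions.
Bootstrap refits use a single start seeded search over the same bounds —
the objective is smooth and unimodal near the optimum.

## Interface habitability

Layer binning uses the published Mg²⁺ ranges with both printed endpoints
inclusive: UIF 70–1,500, MIF 2,080–2,800, LIF 3,050–4,120 mM; the
unsampled intervals (1,500–2,080 and 2,800–3,050 mM) are reported as a
distinct GAP class rather than absorbed into a neighbour, below 70 mM is
SEAWATER, above 4,120 mM BRINE. The 4,120–4,720 mM fraction was never
analysed biologically, so a BRINE/LIF-adjacent "no community" call from
this package means unassessed, not demonstrated lifeless.

Water activity is interpolated from measured (MgCl₂ molarity, a_w) anchors
with a shape-preserving monotone cubic (PCHIP): exact at anchors, strictly
decreasing between them, no extrapolation beyond the anchored range.
Because a_w depends on the full ionic matrix (Na⁺ and SO₄²⁻ contents
differ between brine systems), anchors from different systems are refused
in a single curve; the bundled Hephaestus anchors are
(0.061 M, 0.980), (2.97 M, 0.653), (4.72 M, 0.395) — deliberately sparse,
three points being all that was measured along this gradient.

Threshold location interpolates a_w linearly in depth between samples and
agrees with a 1-mm dense-grid scan within one grid step (property-tested
on random sigmoidal haloclines). Habitability classification evaluates
both criteria independently and reports both flags; where both fail, the
observed-community limit (2,970 mM) takes precedence in the summary
status, since it is the direct observation.

## DOM formula assignment

Neutral mass = m/z + 1.00727646677 u ([M−H]⁻ only: standard for ESI(−)
DOM; no adducts or multiple charging). The decomposition enumerates the
full (C, N, O, S) count grid within bounds, solves H from the mass
residual (at sub-100-ppm tolerance below 1000 u only the nearest integer H
can match), and filters by |ppm| ≤ tolerance, RDBE ≥ 0, integer RDBE
(even-electron neutral molecules: H and N of equal parity), and H/C, O/C
ranges. Default bounds: C 1–60, H 1–120, N 0–3, O 0–40, S 0–3,
0.3 ≤ H/C ≤ 2.5, 0 ≤ O/C ≤ 1.2, tolerance 0.2 ppm — standard FT-ICR DOM
practice, with the tolerance leaving headroom over sub-100-ppb
calibration accuracy. Output is sorted by |ppm error|, ties broken by
fewer heteroatoms then lexicographic counts, so orderings are
reproducible. Grids implying more than 10⁷ candidates are refused with a
sizing diagnostic.

Class statistics: CHO/CHNO/CHOS/CHNOS require C, H, O > 0 (every class
name contains O); ratios are counted over unique formulas, not
intensity-weighted, matching count-based class panels. "Unique to either
sample" is the symmetric difference over the union — the only reading
that yields a single percentage for a two-sample comparison.

The printed DOM class ratios and unique-ion fractions of the real spectra
are not reproducible here (raw peak lists were never deposited) and are
treated as context, not targets.

## Synthetic data

Generators are pure functions of their arguments including the seed.

* Pore profiles: forward model plus noise at 17 depths spanning a 3.2-m
  core at 0.2-m resolution. Ion noise is 2 % relative (ion
  chromatography); δD noise is 0.5 ‰ absolute single-assay with the
  reported value taken as the mean of three replicate assays, matching the
  triplicate assay design of the isotope measurements. Both levels are
  declared assumptions — replicate variances were never published.
* Haloclines: linear or endpoint-renormalized logistic ramps, default
  70 → 4,720 mM over 3.0 m.
* Peak lists: exact [M−H]⁻ masses with multiplicative Gaussian ppm jitter
  (default 0.2 ppm) and lognormal intensities, returned with their ground
  truth. The random DOM panel used in recovery tests is restricted to
  neutral masses below 500 u, matching the small-molecule character of
  highly processed brine DOM; above ~500 u the CHNOS formula space is
  dense enough that unique top-ranked assignment at 1 ppm is not expected,
  for this package or any other.

What passing synthetic tests shows: the inversion recovers parameters it
generated under the stated noise, the numerics match independent oracles,
and the pipeline is deterministic under seeds. What it does not show:
that real pore waters obey the homogeneous 1-D model (bioturbation,
compaction, porosity gradients are not emulated), that real measurement
errors are Gaussian or independent, or that real DOM spectra are free of
isotopologue interferences and calibration drift.

## Problem sizes

Defaults were chosen so every analysis is interactive on one core: 17-point
profiles, 3-start fits, 200–1,000 bootstrap replicates, 50-replicate
coverage simulations, 100–300-formula recovery panels. The acceptance
script fits 5 replicate profiles per reported age and takes the median,
trading a few seconds of compute for insensitivity to any single noise
realization.

## Known limitations

* The age inversion assumes the transport parameters are known; errors in
  D_s or V_s propagate directly into t (they are not jointly identifiable
  from one profile).
* The background concentrations C_bg are fixed inputs; profiles that have
  not relaxed to a clean far-field value will bias the fit.
* The activity curve is an empirical interpolation over three anchors; its
  shape between anchors is smooth by construction, not by measurement.
* Formula assignment trusts a single-peak mass; no isotopologue
  verification or recalibration is performed.
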