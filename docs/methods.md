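# Methods

## Hydrodynamic model

The vessel is an unbaffled cylinder (diameter `D`, liquid height `H`,
working volume `V_L`) stirred by a centred flat-blade paddle (diameter
`d`, blade height `b`). The calculation chain is

```
Re = N d² / ν
N_p = A/Re + B [(10³ + 1.2 Re^0.66)/(10³ + 3.2 Re^0.66)]^p      (Nagata, unbaffled)
P = N_p N³ d⁵ ρ
ε = P / (V_L ρ)
τ_max = 5.33 ρ (ε ν)^½
λ_K = (ν³ / ε)^¼
ISF = 2πNd / (D − d)
```

with `A = 14 + (b/D)[670(d/D − 0.6)² + 185]`,
`B = 10^{1.3 − 4(b/D − 0.5)² − 1.14(d/D)}` and
`p = 1.1 + 4(b/D) − 2.5(d/D − 0.5)² − 7(b/D)⁴`. `N` is in rev/s; rpm is
converted once, at `AgitationCondition` construction. `τ_max` assumes the
peak dissipation model for particles smaller than the smallest eddies;
it is compared against a configurable threshold (default 0.092 Pa, the
literature value for hematopoietic stem cell proliferation) with a strict
inequality, so `τ_max == threshold` does not count as exceeding.

**Parameters.** Defaults describe the reference 100-ml system: `D` =
0.065 m, `d` = `D/2`, `H` = 0.46 `D`, `V_L` = 1×10⁻⁴ m³, water-like medium
(`ρ` = 1000 kg/m³, `ν` = 1×10⁻⁶ m²/s — adequate for basal media at
culture temperature). Blade height is rarely reported for such vessels;
the default `b/D` = 0.06 was fixed by a brute-force sweep of
`b/D ∈ [0.03, 0.15]` selecting the value whose Nagata power numbers best
match the reference pair (0.78, 0.69) at Re = 868/1764 — the sweep has a
unique minimizer at 0.06 (max deviation 0.0085). `K_l a` has no computed
source here (no correlation is adopted for surface-aerated vessels); it is
carried through reports only when supplied by the user.

**Geometry validation.** `V_L` must agree with `π(D/2)²H` within 5 %, and
`d < D` is enforced, which also makes `ISF` well defined. The
dimensionless identity `τ_max λ_K²/(ρν²)` is checked in the test suite by
recomputing it through two independent routes.

## Growth and metabolite kinetics

Balanced exponential growth `C_x(t) = C_x0 e^{μt}` is fitted as a straight
line in `ln C_x` vs `t` by ordinary least squares; `R²` is reported on the
log scale, consistent with the fitting objective. Log-linear fitting is
used rather than nonlinear least squares because the model is exactly
log-linear and the multiplicative (counting) error model makes the log
scale the natural one.

Metabolites obey `q_met C_x = dC_met/dt` with constant specific rate
`q_met` (g·cell⁻¹·h⁻¹). Against the exponential density this integrates in
closed form:

```
C(t) = C_base + s · q · C_x0 · 1000 · (e^{μt} − e^{μt_base})/μ
```

(`s` = −1 consumption, +1 production; the μ→0 limit is linear; the factor
1000 ml/l reconciles per-ml densities with per-l concentrations and is
applied in this one place). Predicted concentrations are floored at zero
with a warning, except during internal refits where the unclamped profile
is used.

**Medium exchanges.** A partial exchange at time τ replacing fraction `f`
with fresh medium at concentration `C_f` resets the concentration baseline
to `(1−f)·C(τ⁻) + f·C_f` while leaving cumulative consumption/production
continuous. For sampled data, `C(τ⁻)` at an event that falls between
samples is taken by linear interpolation of the observed concentrations;
measurements taken *at* an exchange time are read as pre-exchange values.
These two conventions are the package's accounting rules; with them, total
consumption is conserved no matter how many events subdivide a window (a
property-tested invariant).

**Estimators.** Interval rates use the arithmetic mean of the endpoint
densities as the interval-average density (matching discrete sampling);
the overall rate divides the exchange-corrected total change by the time
integral of the fitted exponential density. `q` is reported as a positive
magnitude with a consumption/production direction flag. The model `R²` is
computed between the closed-form profile at the estimated `q` and the
observations. The lactate:glucose ratio is exchange-corrected lactate
produced over glucose consumed in a window; it is undefined (an error)
when no net glucose is consumed.

Note the fitted μ and the observed fold expansion are reported
independently: an exponential fit over a week at μ ≈ 0.028 h⁻¹ implies a
far larger fold than densities that saturate late in culture, so the two
numbers need not be mutually consistent and are never forced to be.

## Morphology

Cells are segmented from grayscale images by global thresholding (Otsu's
histogram-bimodality criterion, overridable by a numeric threshold),
8-connected labelling, removal of border-touching regions, and a minimum
area of 50 px² to reject debris. Axis lengths come from second-order
central moments (ellipse-equivalent axes), not bounding boxes. Roundness
is `R_c = 4A/(π L_major²)`, the definition used by common image-analysis
software; for an ideal ellipse it equals the minor/major axis ratio. Raw
values can slightly exceed 1 through rasterization and are clamped to 1.
Circularity `4πA/P²` is measured as a secondary descriptor but never used
for classification. The round-cell frequency `f_r` counts `R_c` strictly
greater than the threshold (default 0.8). No splitting of touching cells
is attempted; inputs are assumed to be dispersed suspension-culture
fields.

## Synthetic data

The generator emulates a 7-day suspension run: seeding at 1×10⁵ cells/ml,
sampling on days 0/3/5/7, growth at μ = 0.028 h⁻¹ (low-shear condition;
0.022 h⁻¹ for high shear), lognormal counting noise with CV 0.1
(multiplicative, keeps counts positive), glucose starting and refreshed at
2.0 g/l with 50 % medium replacement on days 1/3/5, additive Gaussian
assay noise (σ = 0.05 g/l) floored at zero, and `q_glucose` =
3.1×10⁻¹² g·cell⁻¹·h⁻¹ — sized so about 60 % of the glucose supplied over
the week is consumed, keeping concentrations positive throughout.
`q_lactate` is 0.9·`q_glucose` (a lactate:glucose yield below 1, typical
of reasonably oxygenated dynamic cultures).

Images are rendered as non-overlapping constant-intensity ellipses (semi-
major 12–18 px, foreground 200, background 30, Gaussian pixel noise σ = 6,
contrast ≫ 5σ) placed by rejection sampling; axis ratios are drawn from a
round band (0.85–0.98) and a stretched band (0.40–0.70) that deliberately
exclude 0.75–0.85 so rasterization error cannot flip a cell's true class
at the 0.8 threshold, and exactly `round(n·f_true)` cells are round.
All randomness flows through numpy's PCG64 `default_rng`, with one spawned
stream per operation, so a fixed seed is reproducible across platforms.

What the generator does **not** emulate: growth-phase transitions
(lag/death), substrate limitation, shear-dependent death or apoptosis,
pH drift, overlapping or textured cells, and uneven illumination. Passing
tests therefore demonstrate correctness of the estimators under the stated
models, not robustness to every feature of real micrographs or assays.

## Numerical choices and limitations

- Problem sizes: replicated-recovery checks use 200 growth replicates and
  100 metabolite replicates at the default 4-point sampling, and one
  100-cell 1024×1024 image — enough for the Monte-Carlo means/medians to
  stabilise well inside the stated tolerances.
- The Nagata correlation is the only power-number model provided; baffled
  vessels and non-paddle impellers are out of scope, as are CFD and
  gas–liquid mass transfer.
- The mass-balance refit assumes a constant `q` over the whole run; real
  cultures show phase-dependent rates.
- Published reference tables for such systems can be internally
  inconsistent (e.g. a Reynolds-number pair not in the ratio of the
  agitation rates); this package always reports the self-consistent chain
  from the stated inputs and leaves reconciliation with any external table
  to the user.
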