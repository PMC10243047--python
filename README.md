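# bioshear

Quantitative analysis of hydrodynamic shear and its effects on suspension
cell expansion in small stirred-tank bioreactors.

Expanding hematopoietic-lineage cells ex vivo in a stirred vessel trades
mixing (needed for homogeneous nutrients and oxygen) against hydrodynamic
shear (which deforms and kills cells). `bioshear` is for bioprocess
engineers and cell-culture researchers who need to answer, from bench-scale
data: *what shear environment does my agitation rate create, how fast are
the cells growing and eating, and are they staying round?* It covers three
stages, each usable alone:

1. **Hydrodynamics** — for an unbaffled vessel with a flat-blade paddle:
   impeller Reynolds number `Re = N d²/ν`, power number `N_p` from Nagata's
   unbaffled-vessel correlation, power draw `P = N_p N³ d⁵ ρ`, specific
   energy dissipation `ε = P/(V_L ρ)`, maximum shear stress
   `τ_max = 5.33 ρ (εν)^½`, integrated shear factor `ISF = 2πNd/(D−d)`, and
   the Kolmogorov eddy length `λ_K = (ν³/ε)^¼`, with a comparison of
   `τ_max` against the 0.092 Pa threshold reported for hematopoietic stem
   cell proliferation.
2. **Kinetics** — log-linear fitting of exponential growth
   `C_x = C_x0 exp(μt)`, fold expansion, and specific metabolite rates from
   the batch mass balance `q_met C_x = dC_met/dt`, with correct accounting
   of partial medium exchanges (e.g. 50 % replacement on days 1/3/5) and
   the lactate:glucose yield ratio.
3. **Morphology** — segmentation of cells from grayscale micrographs,
   per-cell roundness `R_c = 4A/(π L_major²)` (equal to minor/major for an
   ellipse), and the round-cell frequency
   `f_r = #(R_c > 0.8) / n_cells`.

A synthetic-data module generates culture series, metabolite profiles and
cell images with known ground truth, so the whole pipeline is testable
without laboratory data.

## Worked example

The reference configuration is a 100-ml unbaffled vessel (D = 6.5 cm,
d = D/2, H = 0.46 D, water-like medium) agitated at 50 and 100 rpm:

```sh
bioshear hydro
```

```
Hydrodynamic parameters
                                                   50 rpm       100 rpm
Reynolds number, Re                                880.21       1760.42
Power number, N_p                                   0.770         0.693
Power, P (W)                                    1.616e-05     1.163e-04
Energy dissipated per unit mass, eps (W/kg)     1.616e-04     1.163e-03
Maximum shear stress, tau_max (Pa)                  0.068         0.182
Integrated shear factor, ISF (1/s)                  5.236        10.472
Size of smallest eddy, lambda_K (um)                280.5         171.2
K_l a (1/h)                                             -             -
tau_max > threshold                                 False          True
```

Reading the column for 50 rpm: the flow is transitional (Re ≈ 880), the
smallest turbulent eddies (~280 µm) are an order of magnitude larger than
a suspended cell, and the peak shear stress (0.068 Pa) stays below the
0.092 Pa damage threshold — a gentle environment. At 100 rpm the eddies
shrink and `τ_max` crosses the threshold, predicting morphological change
and impaired expansion.

The full pipeline on synthetic data compares a low-shear condition
(μ = 0.028 h⁻¹, 67 % round cells) with a high-shear one (μ = 0.022 h⁻¹,
41 % round):

```sh
bioshear all --seed 5 --out report
```

```
condition  mu_per_h  fold_expansion  q_glucose_g_per_cell_h  glucose_r_squared  lactate_glucose_ratio  f_r  n_cells
    50rpm  0.027883      106.545420            3.209164e-12            0.99417               0.842598 0.67      100
   100rpm  0.022172       41.482312            3.407734e-12            0.96846               0.757905 0.41      100
```

The fitted μ and measured round fraction recover the generator's ground
truth; the glucose mass-balance model explains > 96 % of the concentration
variance despite assay noise and three 50 % medium exchanges. Other
subcommands (`growth`, `metabolite`, `morph`, `simulate`) run the stages
individually on CSV/PNG inputs; every run writes a JSON manifest with
config snapshot, seed and file digests for exact reruns.

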