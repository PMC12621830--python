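# mqpi — multiparametric QPI drug-response analysis

`mqpi` analyzes time-lapse quantitative phase imaging (QPI) of cancer cells
under drug treatment. QPI measures the optical path length through a cell,
which is proportional to its dry (non-water) mass; imaging a 96-well plate
every 20 minutes for 48 hours yields a dry-mass trajectory for every cell,
and from those trajectories several independent response parameters per
drug. The package is aimed at functional precision-oncology work with
patient-derived material — organoid-derived 2D cultures and direct-from-thaw
patient samples — where single-cell resolution matters because samples are
small, heterogeneous, and often contaminated with non-tumor cells.

The pipeline, end to end:

1. **Phase retrieval** (`phase_reconstruction`). Four images under
   complementary half-circle LED illuminations are combined into two
   differential-phase-contrast (DPC) images and inverted to quantitative
   phase φ(x, y) by Tikhonov-regularized deconvolution with the weak-object
   transfer function (regularization β = 10⁻³, NA 0.25 by default).
2. **Segmentation and dry mass** (`cell_detection`). Cells are found by
   Sobel edge detection plus morphological processing; the mass of a cell
   is m = λ/(2πα) · Σ φ · A_pixel, with specific refractive increment
   α = 1.8×10⁻⁴ m³/kg.
3. **Tracking** (`tracking`). Cells are linked frame to frame by a globally
   optimal assignment on combined squared position and mass distance, with
   gates for births/deaths.
4. **Specific growth rate** (`growth_analysis`). Each track longer than 20
   frames is median-filtered (5 frames) and fitted with a least-squares
   line; SGR = slope / (fitted initial mass), in h⁻¹. Windowed variants
   (12 h windows every 2 h) resolve the time course. A mass threshold at
   the antimode of a bimodal initial-mass distribution filters out small
   non-growing contaminant cells in patient samples.
5. **Dose response** (`dose_response`). Mean SGR vs concentration C is
   fitted with the Hill model
   SGR(C) = E_max + (E₀ − E_max) / (1 + (C/EC₅₀)^HS),
   giving EC₅₀ and the depth of response DoR = (E₀ − E_max)/E₀ (DoR > 1
   means net mass loss at high dose). Lin's concordance coefficient and
   Welch/F tests are provided for comparisons.
6. **Response dynamics and heterogeneity** (`heterogeneity`). Treated and
   control windowed SGR distributions are compared with the Hellinger
   distance H ∈ [0, 1] (densities via Gaussian KDE, bandwidth 0.0025 h⁻¹);
   H(t) is fitted with a saturating exponential, and the time of response
   (ToR) is where the fit crosses a threshold calibrated as the maximum H
   between two on-plate vehicle-control groups. Responsive/non-responsive
   subpopulations are resolved by fitting each window's KDE with a sum of
   two Gaussians, warm-starting each window from the previous fit.

A synthetic-data generator (`synthetic_data`) produces seeded inputs at
every entry level — mass tracks, phase movies with ground-truth masks and
identities, and raw half-circle intensity stacks through the same forward
model the inverse uses — so the whole pipeline is testable without
microscope data.

## Worked example

Simulate a plate (two vehicle-control groups, one drug in a 6-point dose
curve in triplicate), then run the full analysis:

```python
from mqpi import PlateMap, RunConfig, WellSpec, run_pipeline

wells = {"A1": WellSpec(control_group="ctrlA"),
         "A2": WellSpec(control_group="ctrlB")}
for i, d in enumerate([0.003, 0.01, 0.0316, 0.1, 0.316, 1.0]):
    for rep in "abc":
        wells[f"B{i+1}{rep}"] = WellSpec(drug="vinblastine-like", dose=d)

cfg = RunConfig(
    entry="simulate", seed=81, plate_map=PlateMap(wells=wells), fix_hs=1.0,
    simulation={
        "population": {"n_cells": 80, "sgr_control": 0.02, "sgr_sd": 0.005,
                       "noise_sd_mass": 1.5, "linear_growth": True},
        "drugs": {"vinblastine-like": {"e0": 0.02, "emax": -0.012,
                                       "ec50": 0.1, "hs": 1.0,
                                       "response_delay_tau_h": 6.0}}})
summary = run_pipeline(cfg)
```

With this seed the run tracks 1600 cells and prints (via the summary dict):

```
EC50: 0.0941  DoR: 1.656  E0: 0.01992  Emax: -0.01306  R2: 0.9997
ToR threshold: 0.1260
  dose 0.003   ToR none
  dose 0.01    ToR 2.5 h
  dose 0.0316  ToR 0.8 h
  dose 0.1     ToR 0.4 h
  dose 0.316   ToR 0.3 h
  dose 1       ToR 0.2 h
```

Reading the numbers: the fitted EC₅₀ (0.094, generator truth 0.1,
concentration units are whatever the plate map uses) is the inflection of
the dose curve; DoR ≈ 1.66 > 1 says the high-dose plateau is net mass
*loss*, not merely growth arrest (E_max < 0). The lowest dose never
separates from control beyond the control-vs-control Hellinger threshold,
so its ToR is undefined (non-responsive); higher doses cross earlier —
the concentration-dependent onset the ToR statistic is designed to expose.

The same stages are available from the shell:

```sh
mqpi simulate --n-cells 200 --seed 1 -o tracks.csv
mqpi sgr tracks.csv -o sgr.csv
mqpi dose-response sgr.csv -o fits.json
mqpi run --config run.yaml --seed 1 -o out/
```

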