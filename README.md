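# qpiscreen

Multiparametric drug-response analysis for quantitative phase imaging
(QPI) drug screens. The package goes from raw differential phase contrast
(DPC) frames to single-cell dry-mass tracks, and from tracks to five
response parameters per drug/cell-line pair:

- **SGR** — specific growth rate, the mass-accumulation slope of a
  single-cell track normalized by its initial mass (h⁻¹); for
  proliferating cells SGR = ln 2 / t_doubling.
- **EC50** — the inflection point of a four-parameter Hill fit of mean
  SGR versus concentration,
  `SGR(C) = Emax + (E0 − Emax) / (1 + (C/EC50)^HS)`,
  accepted as a response only when it beats a flat line in an F-test at
  p < 0.01.
- **DoR** — depth of response, `(E0 − Emax)/E0`; ≤ 1 is cytostatic
  (growth slowed), > 1 cytotoxic (net mass loss).
- **ToR** — time of response: the Hellinger distance
  `H²(S,T) = ½ Σ (√sᵢ − √tᵢ)²` between treated and control single-cell
  SGR distributions is tracked over 24-h sliding windows, fitted by the
  saturating model `H(t) = a − b·e^{ct}`, and inverted at the
  control-vs-control threshold: `ToR = (1/c)·ln((a − H*)/b)`.
- **SD at EC50** — growth heterogeneity: the standard deviation of
  single-cell SGR at the tested concentration nearest the EC50.

It also includes the in-silico resistant-subpopulation mixing analysis
(normalized area under the precision–recall curve over a fixed SGR
threshold grid) and cross-assay concordance statistics (Pearson r, Lin's
concordance coefficient with a 10,000-resample bootstrap interval, and a
response/no-response confusion matrix) for validating against endpoint
viability assays.

The imaging front end implements the DPC model: four half-circle
illumination frames per time point, normalized opposing-pair differences
`(I₁−I₂)/(I₁+I₂)`, weak-object phase transfer functions computed from the
physical LED-array geometry, and Tikhonov-regularized deconvolution
(β = 10⁻³). Dry mass follows from integrated phase through the specific
refractive increment α = 1.8×10⁻⁴ m³/kg. Everything is testable without
instrument data through the built-in synthetic generators (bead phantoms,
cell-track populations, Hill-structured plates).

## Worked example

Simulate a 96-well-format screen of one drug (6-point dose response in
triplicate, 9 locations per well, 12 cells per location) whose true dose
response is cytostatic — E0 = 0.025 h⁻¹, Emax = 0.005 h⁻¹,
EC50 = 0.8 µM, HS = 1.2 — then run the track-to-dose-response pipeline:

```python
from qpiscreen import PlateLayout, generate_dose_response_tracks, doubling_time_from_sgr
from qpiscreen.pipeline import sgr_table, dose_response_table

layout = PlateLayout.default_screen(
    drugs=("fulvestrant",), concentrations_uM=(0.032, 0.16, 0.8, 4.0, 20.0),
    n_replicates=3,
)
tracks = generate_dose_response_tracks(
    e0=0.025, emax=0.005, ec50_uM=0.8, hs=1.2,
    layout=layout, n_cells_per_location=12, noise_cv=0.003, seed=11,
)
sgr_df, counts = sgr_table(tracks)
dr = dose_response_table(sgr_df, layout).iloc[0]
print(counts)
print(f"EC50 = {dr.ec50_uM:.3f} uM, E0 = {dr.e0:.4f} 1/h, Emax = {dr.emax:.4f} 1/h")
print(f"DoR = {dr.dor:.2f} ({'cytotoxic' if dr.cytotoxic else 'cytostatic'}), p = {dr.p_value:.2e}")
print(f"control doubling time = {doubling_time_from_sgr(dr.e0):.1f} h")
```

prints

```
{'input': 2268, 'accepted': 2033, 'mad_outlier_see': 133, 'mad_outlier_sgr_h': 91, 'low_mass': 11}
EC50 = 0.663 uM, E0 = 0.0247 1/h, Emax = 0.0051 1/h
DoR = 0.79 (cytostatic), p = 4.42e-03
control doubling time = 28.1 h
```

Reading the output: of 2268 generated tracks, 235 are rejected by the
standard filters (minimum 20 frames, minimum 110 pg mean mass, 3-MAD
outlier rules on fit quality s_y.x and on the normalized slope k). The
drug is called a responder (p < 0.01 against the flat model) with
DoR = 0.79 < 1, i.e. cytostatic — growth is slowed to about a fifth of
the control rate but mass is not lost. The asymptotes recover the
generating values closely; the fitted EC50 (0.66 µM vs the generating
0.8 µM) sits slightly low because the fit-quality trim preferentially
removes large, fast-growing cells — the regression residual scales with
cell mass — which nudges condition means downward (see
`docs/methods.md`).

A thin CLI mirrors the library stages:

```bash
qpi simulate --out tracks.csv --n-cells 200
qpi sgr --tracks tracks.csv --out sgr.csv --min-frames 20 --min-mass 110
qpi dose-response --sgr sgr.csv --layout plate.yaml --out dr.csv
qpi tor --tracks tracks.csv --layout plate.yaml --out tor.csv
qpi reconstruct --in frames/ --out phases/ --beta 1e-3
```

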