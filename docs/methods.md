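# Methods

This note documents the models, the numerical choices, and what the
synthetic fixtures do and do not emulate.

## DPC imaging model and phase retrieval

The imaging model is the linearized (weak-object) description of
differential phase contrast: each half-circle illumination pattern j
produces an intensity frame whose normalized contrast is linear in the
specimen phase through a transfer function H_j(u),

    I_j = background · (1 ± s_j),      FT(s_j) = H_j(u) · FT(φ).

The two opposing-pair differences g = (I₁ − I₂)/(I₁ + I₂) for the
vertical (90°) and horizontal (180°) axes are inverted jointly by
Tikhonov-regularized deconvolution

    φ = IFT[ Σ_j conj(H_j)·FT(g_j) / (Σ_j |H_j|² + β) ],   β = 10⁻³.

**Transfer functions.** H is computed from the physical source geometry:
an 8×8 LED board of 18 mm extent, 24 mm above the sample, split into
half-planes. Each LED is an extended emitter and is rasterized onto the
image frequency grid as a patch of half the LED pitch; the weak-object
transfer function is the source–pupil overlap correlation
H(u) = i·[G(u) − G(−u)], G(u) = Σ S(u′)P(u′)P(u′+u), evaluated by FFT
(the periodic correlation equals the linear one because the pupil support
fits twice inside the Nyquist cell at 0.54 µm pixels). With
NA_illum = 0.39 > NA_obj = 0.25 only bright-field LEDs — those inside the
pupil — contribute at first order; dark-field LEDs add background only,
so the actual transfer support ends at 2·NA_obj/λ. H is purely imaginary,
antisymmetric, zero at DC, and scaled to unit maximum magnitude so that
β = 10⁻³ has the same meaning at any image size.

Consequences worth knowing: the DC component of the phase is not
transferred (reconstructions are zero-mean) and the lowest spatial
frequencies are attenuated by the β term. The stated coherence parameter
of the instrument is the aperture ratio σ = NA_illum/NA_obj = 1.56; the
configuration derives it from the apertures rather than storing a second,
slightly inconsistent constant.

**Bead calibration.** A bead of radius r in a medium of index n_m adds
integrated phase (2π/λ)·Δn·V over its footprint, so
n = n_m + (λ/2π)·Σφ·A_pixel/V with V = (4/3)πr³. Because the regularized
inversion leaves a smooth shallow negative halo around compact objects
(the lost low-frequency content), the integral is taken over a disk of
1.2 bead radii after subtracting the median phase in a 2.5–3.5 radius
annulus. On simulated 5-µm polystyrene beads (n = 1.583 in n = 1.56
polymer) this recovers the index to ~0.07%, inside the 0.1% band the
physical calibration achieves; integrating without the local background
reference loses ~0.2%.

## Segmentation, background, mass

Cells are found by Sobel gradient magnitude (after σ = 1 px Gaussian
smoothing), Otsu threshold, morphological closing and hole filling; each
filled object is then tightened by an Otsu cut on its own phase values,
because the filled edge band alone overshoots the half-maximum footprint
severalfold. A distance-transform watershed optionally splits touching
cells (for single-cell lines).

Background correction removes a total-degree-8 polynomial fitted to
non-cell pixels only (coordinates rescaled to [−1,1]; the order falls
back automatically when background pixels are scarce), then subtracts a
rolling-ball background implemented as grayscale opening with a flat
disk (default radius 100 px) — structures narrower than the disk cannot
enter the background estimate — and finally re-centres the background
median at zero. Applying the correction twice changes a clean image by
well under 1% of its dynamic range; with strong pixel noise the repeated
degree-8 fit fluctuates at image corners (high leverage), which is why
the polynomial is fitted once per frame in the pipeline.

Mass integrates phase through the specific refractive increment:
m = (λ/2π)·Σφ·A_pixel/α with α = 1.8×10⁻⁴ m³/kg = 0.18 µm³/pg. Tracking
links objects frame to frame greedily on the combined cost
(Δpos/position_scale)² + (Δmass/mass_scale)², with position_scale twice
the median nearest-neighbour spacing and mass_scale the median object
mass of the frame; links costing more than 4 are refused, unmatched
objects open new tracks. Greedy lowest-cost-first with label tie-break
makes linking deterministic.

## SGR estimation and filtering

Track masses are median filtered (kernel 5, nearest-edge padding — zero
padding would corrupt the track ends), time-shifted to start at zero and
fitted by ordinary least squares; SGR = slope/intercept, the intercept is
the initial mass, and s_y.x = √(RSS/(n−2)) records fit quality. Tracks
shorter than 20 frames or lighter than 110 pg mean mass are rejected;
within each well a single-pass 3-MAD rule removes outliers in s_y.x and
in SGR (union of the two flags; with MAD = 0 only exact-median values
survive, so identical populations pass unchanged).

Two behaviours of this estimator matter for interpretation:

- On exponentially growing mass the linear slope/intercept ratio is
  biased *upward*, by roughly 0.55·g·W relative for rate g over a window
  of length W (≈ +30% at g = 0.02 h⁻¹, W = 24 h) — constant across
  windows, so temporal comparisons are unaffected.
- s_y.x scales with cell mass (both measurement noise and growth
  fluctuations are roughly proportional to size), so the 3-MAD trim on
  fit quality preferentially removes large, fast-growing cells and
  shifts condition means slightly downward (~2% relative in the
  synthetic screens). The same rule also censors strongly dying cells
  through the 110 pg mass floor, flattening the deep end of cytotoxic
  dose-response curves.

**Temporal windows.** Dynamics use overlapping 24-h windows centred on
imaging time points; a centre c is valid when [c − 12 h, c + 12 h) lies
inside the experiment, which yields exactly 144 windows for 72 h at
20-min spacing, grouped 8 adjacent windows per bin into 18 bins. Within
each window the same length/mass/MAD filters are re-applied and each
track is refitted from its in-window points. Bin summaries use the mean
SGR per track and a Gaussian KDE with Silverman bandwidth.

## Dose response

Mean SGR per condition is the mean over per-location means (SEM across
locations); the solvent control enters each drug's curve at a
pseudo-concentration of (lowest tested)/100 so the fit lives on a log10
axis. The four-parameter Hill model is fitted by bounded trust-region
least squares in log-concentration space with an analytic Jacobian,
multi-started over EC50 guesses spanning the tested range; HS is bounded
to [0.1, 10] and EC50 to [min/100, max·100]. The response call compares
the Hill and flat-line fits with
F = ((RSS_flat − RSS_hill)/3)/(RSS_hill/(n−4)) at p < 0.01. Because the
bounded nonlinear alternative cannot chase noise freely, the realized
false-response rate on flat-truth data sits below the nominal 1%
(≈ 0.3% in simulation) — the test is conservative, never anticonservative.
A numerically perfect Hill fit responds with p = 0 unless the flat fit is
equally perfect (exactly constant data), which is a non-response.

DoR = (E0 − Emax)/E0; DoR > 1 (equivalently Emax < 0) flags a cytotoxic
response. Heterogeneity uses identical machinery on per-condition SGR
standard deviations.

## Hellinger distance and time of response

Single-cell SGR values from the 24-h windows are turned into probability
distributions on a fixed grid of 10⁻⁴ h⁻¹ bins spanning [−0.3, 0.3] h⁻¹
(covering observed death rates; out-of-range values clip into edge bins
with a warning). Two constructors exist: the raw normalized histogram,
and a Silverman-bandwidth Gaussian KDE evaluated on the same grid. The
pipeline uses the KDE form: at realistic per-bin cell counts raw
histograms on a 10⁻⁴ grid are nearly disjoint and saturate the distance.

H(S,T) = √(½ Σ (√sᵢ − √tᵢ)²) ∈ [0, 1]. The response threshold H* is the
maximum distance between the plate's two control groups over time (the
two solvent controls in the default synthetic layout). Treated-vs-control
series are fitted by H(t) = a − b·e^{ct} (nonlinear least squares;
starts a = max H, b = a − H(0), c ∈ {−0.05, −0.02, −0.2} h⁻¹) and
inverted analytically: ToR = (1/c)·ln((a − H*)/b), natural logarithm.
No-response is declared when the plateau stays below the threshold
(a ≤ H*), the fit does not saturate (b ≤ 0), or the crossing falls
outside (0, duration]. The per-drug ToR reported "at EC50" is the ToR of
the smallest tested concentration strictly above the fitted EC50.

## Heterogeneity and in-silico mixing

SD at EC50 uses the tested concentration nearest the EC50 in log
distance. The mixing analysis spikes control cells into a treated
population so positives make up a target ratio
(round(ratio·n_treated/(1−ratio)), minimum 1; sampling without
replacement when the control pool allows), sweeps resistance thresholds
over a fixed grid (−0.1 to 0.15 h⁻¹ in 0.005 steps, strict SGR > θ), and
integrates precision over recall on the attainable frontier: ties in
recall keep the best precision and the recall→0 end is anchored at the
precision of the smallest positive recall, the usual PR-curve
convention — a perfectly separating grid then integrates to exactly 1.
Precision with no predictions is defined as the prevalence. The score is
normalized as (AUPRC − prevalence)/(1 − prevalence) so no-skill maps to
0; mixing repeats 100× per ratio (seeded) and the median normalized
AUPRC is reported together with the PR curve of the median repeat.

## Concordance statistics

Pearson r with the two-sided t-transform p-value; Lin's concordance
CCC = 2·cov(x,y)/(var x + var y + (mean x − mean y)²) with ddof = 1
moments (|CCC| ≤ |r| holds for any consistent choice); percentile
bootstrap over paired resamples (default 10,000; degenerate resamples
skipped and counted). EC50 concordance is intended on log10 scale, since
dose responses span decades. Response/no-response agreement is the
diagonal fraction of the 2×2 confusion matrix.

## Synthetic data: what it emulates, what it does not

The track generator draws per-cell SGR from a normal distribution and
grows mass at a constant rate dm/dt = SGR·m₀ (the constant
growth-rate picture of cells within a cell cycle; slope/intercept then
recovers the drawn SGR exactly), with optional exponential growth for
temporal-dynamics tests, an optional death switch to linear mass loss at
−0.217 h⁻¹ (floored at 5% of the death-onset mass), initial masses
~N(300, 80²) pg, 1% multiplicative mass noise, and 20-min sampling over
72 h. The plate generator places condition means on a ground-truth Hill
curve over a 96-well layout (5 drugs × 6 concentrations × 3 replicates
plus two triplicate solvent controls; 9 locations/well → 864 locations,
27 per condition).

Not emulated: cell division and lineage (tracks never split, so long
tracks are unrealistically monotone), segmentation/tracking errors
(dose-response tests enter at the track table), spatial crowding,
drug pharmacokinetics (condition means are stationary except in the
ToR fixtures), and instrument drift. Passing tests therefore validate
the estimators and their filtering rules against known ground truth,
not robustness to imaging artifacts.

## Problem sizes and numerical tolerances

Test fixtures use 64–384 px images, 3–9 beads, populations of 5–2000
tracks, 25–100 mixing repeats, and 300–1000 null simulations for
calibration of the F-test and Pearson null rates; these sizes make the
full suite run in a few minutes while keeping every statistical check
inside its stated binomial or SEM envelope. Imaginary residue after the
inverse FFT above 10⁻⁶ of the amplitude maximum triggers a warning;
curve fits cap at 600 function evaluations per start (Hill) and 10,000
(ToR); the ToR fit requires ≥ 4 time points; bootstrap intervals require
≥ 100 resamples.
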