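# Methods

This note records the models, conventions and numerical choices behind
`mqpi`, and what the synthetic-data tests do and do not establish about
real microscope data.

## Phase retrieval

Under the weak-object approximation, the normalized half-circle contrast
I_dpc = (I_a − I_b)/(I_a + I_b) is a linear filter of the specimen phase:
FT[I_dpc] = H(u)·FT[φ], with a purely imaginary, antisymmetric transfer
function H determined by the source and pupil geometry. H is evaluated
numerically on the discrete frequency grid as a zero-padded correlation of
the signed half-circle source with the circular pupil (padding avoids
cyclic aliasing, since H has support out to twice the pupil cutoff), and
normalized by the unsigned-source DC intensity so max |H| ≈ 0.4. The two
orthogonal axes are combined in one Tikhonov solve,

    φ̂ = IFT[ Σ_j conj(H_j)·FT[I_j] / (Σ_j |H_j|² + β) ],  β = 10⁻³,

with the DC component set to zero (DPC carries no information about the
absolute phase offset). Matched illumination/objective NA is assumed; the
default optics are NA 0.25, λ 525 nm, 0.6 µm pixels.

Consequences worth knowing:

- H → 0 toward DC, so very-low-frequency phase is unrecoverable at any β.
  The round-trip validation object is therefore band-passed to 0.35–0.9 of
  the pupil cutoff (`synthetic_data.bandlimited_phase`); on such objects
  the noiseless forward→inverse error is ≈1% relative L2.
- The synthetic forward model uses the same linear transfer functions, so
  the round trip validates the inversion algebra and regularization, not
  the physics of partially coherent image formation (a stated non-goal).
- Phases above ~1 rad violate the linear model; the forward model logs a
  warning. Real cells reach several radians — linearity error in real DPC
  data is not probed by these tests.

## Dry mass

m = λ/(2πα) · Σ_pixels φ · A_pixel, α = 1.8×10⁻⁴ m³/kg. With λ = 525 nm
and 0.6 µm pixels this is 0.167 pg per pixel·radian. The median phase of
non-cell pixels is subtracted before integration (on by default) so a DC
pedestal cannot bias mass; this choice is the package's own, as is the
convention that masks are integrated as-is without edge corrections.

## Segmentation

Sobel gradient magnitude → threshold (Otsu unless given) → dilation
(disk, 2 px) → hole filling → matched erosion → removal of objects under
50 px. The erosion after filling undoes the systematic boundary inflation
the dilation would otherwise leave (net effect: morphological closing of
the edge band before filling), so masks track the true boundary to ~±1 px.
Touching cells are deliberately not split (no watershed); clumps surface
as area outliers. On rendered uniform-disk cells, masks reach IoU ≈ 0.9
against ground truth and per-cell mass is recovered well within 3%.

## Tracking

Per frame pair, a globally optimal one-to-one assignment (Hungarian
algorithm on the Jaqaman-style augmented matrix) minimizes
c = w_s·‖Δxy‖² + w_m·(Δm)², with links gated at 15 µm displacement and 50%
relative mass jump. Default weights normalize each term to 1 at its gate,
and the non-link (birth/death) cost is 1.05, so any admissible link beats
leaving both endpoints unlinked. Optional single-frame gap closing is off
by default. Optimality is verified against brute-force enumeration for
small frames.

## Specific growth rate

Tracks strictly longer than 20 frames are median-filtered with a 5-frame
window that shrinks *symmetrically* at the ends (no padding; a linear
series passes through unchanged — the price is that a spike in the very
first or last frame cannot be suppressed). SGR is the least-squares slope
divided by the fitted line's value at the track's start time. Windowed
SGR (12 h windows centered every 2 h, cells present for less than half the
window excluded) uses the same normalization: the window fit extrapolated
to the track's start, which makes windowed and whole-track SGR identical
for constant-rate linear tracks. Window fits whose back-extrapolated
initial mass is not clearly positive (< 5% of the window's mean mass) are
excluded as unnormalizable.

A caveat the tests quantify: SGR-by-line-fit estimates the instantaneous
relative growth rate g of an exponentially growing cell only when g·T is
small. Over a full 48 h track at g = 0.02 h⁻¹ the estimator inflates g by
~1.9× and shifts a recovered EC₅₀ by ~50%. Dose-response recovery
validations therefore use the generator's linear-growth variant; the
exponential/linear mismatch itself is exercised in unit tests. For real
data this means EC₅₀ values are internally consistent but, at high growth
rates and long fit spans, not estimates of the underlying exponential-rate
dose curve.

## Dose response

Hill model SGR(C) = E_max + (E₀ − E_max)/(1 + (C/EC₅₀)^HS), with E₀ the
low-dose (growing) asymptote and E_max the high-dose asymptote; C = 0 is
evaluated analytically to E₀ so vehicle controls anchor the fit directly.
Fitting is nonlinear least squares over (E₀, E_max, log₁₀EC₅₀, HS), with
EC₅₀ bounded to [min dose/100, max dose×100], HS ∈ (0.05, 10], init from
the dose extremes, the geometric mid-dose, and HS = 1. HS can be fixed
(`fix_hs=1`) for the 3-parameter variant; at six or seven dose points the
free-HS fit roughly quadruples EC₅₀ variance, so the 3-parameter form is
the default choice in the packaged analyses. Replicate wells are pooled
into per-condition means, with across-well SEM retained and used as
weights (absolute_sigma) when available.

DoR = (E₀ − E_max)/E₀; DoR > 1 indicates net mass loss. A fit is flagged
degenerate when any of: non-convergence, EC₅₀ at its bounds,
se(log₁₀EC₅₀) > 0.3, span |E₀ − E_max| ≤ 4·se(span), R² < 0.85, or E₀ not
positive beyond 2·se(E₀) — the last because DoR and the normalized dose
curve are meaningless without a growing baseline, which is exactly the
failure mode of unfiltered contaminated samples.

Lin's concordance uses population (ddof = 0) variances:
ρ_c = 2·cov(x,y) / (var x + var y + (mean x − mean y)²).

## Time of response

Per window, treated and control SGR samples are smoothed with a fixed
Gaussian KDE (bandwidth 0.0025 h⁻¹, shared grid spanning the pooled
samples ±4 bandwidths) and compared with the Hellinger distance
H = sqrt(1 − ∫√(pq)). H(t) is fitted with H∞(1 − e^(−t/τ)) — zero-anchored,
no offset term, since H must grow from the control level and saturate at
≤1. The response threshold is the maximum H between two designated
on-plate control groups; ToR is the analytic crossing time of the fitted
curve, reported only when it falls within the observed window range
(a crossing extrapolated past the end of the assay is reported as
non-responsive rather than invented).

The threshold calibration depends on sampling-noise floors: H between two
finite samples is positive even for identical distributions, scaling like
sqrt(1/n_a + 1/n_b). The packaged study design therefore uses two
*single-well* control groups (~80 cells each) for the threshold and
compares each treated condition (pooled replicates, ~400 cells) against
the *full* vehicle pool, so the treated comparison's noise floor sits well
below the threshold. Under this design the false-call rate with treated ≡
control measured 0–1 per 100 seeded runs, while dose-dependent onset
delays (τ = 20, 10, 4 h across three doses) give strictly decreasing ToR.

## Subpopulation mixtures

Each window's KDE curve is fitted with
y = A·f·exp(−((x−μ_s)/σ_s)²) + A·(1−f)·exp(−((x−μ_n)/σ_n)²),
where s is the sensitive/responsive component, defined as the lower-SGR
one (components are relabeled after fitting if needed, f → 1−f). Note the
printed form: σ is √2 times the usual Gaussian standard deviation. The
first window initializes from the KDE amplitude and the overall median ±
SD/2; every later window warm-starts from the previous fit, and a failed
fit carries the previous parameters forward with a flag. When the two
means are closer than the average σ the fraction is flagged
unidentifiable. On 70/30 mixtures at 4σ separation (n = 2000) the
non-responsive fraction is recovered within ±0.01–0.05; a linearly
decaying fraction over 12 windows is tracked with mean error ≈0.015.

## Mass filtering of contaminated samples

Direct-from-thaw patient samples carry small non-growing (often dying)
non-tumor cells that dominate the population. The filter thresholds on
per-track initial mass; the automatic threshold is the antimode of a
two-Gaussian fit to the log₁₀ initial-mass KDE, with mode candidates from
peak detection (prominence ≥ 5% of the tallest peak) — a plain
median-based initialization collapses onto the dominant mode when
contamination is heavy. Unimodal distributions yield no suggestion, and a
manual threshold can always be passed.

The packaged contaminated-plate scenario emulates this setting: per well,
75–92% small cells (35 ± 10 pg, SGR −0.006 h⁻¹, drug-inert) against
tumor cells (280 ± 70 pg) on a Hill curve (E₀ 0.02, E_max −0.012, EC₅₀
0.1, HS 1), with a per-well batch offset N(0, 0.001 h⁻¹), five wells per
condition, 200 cells per well. The unfiltered bulk baseline is ~0 growth,
so the unfiltered fit is flagged degenerate (E₀ indistinguishable from
zero), while the filtered fit recovers EC₅₀ with median ≈7% error
(pre-registered spread over 33 seeds: max ≈19%).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
20-min cadence over 48 h; initial masses from (log)normal mixtures;
exponential (default) or exactly linear growth; Hill-mean dose effects
with exponential onset (1 − e^(−t/τ)); resistant and drug-inert
subpopulations; additive per-frame mass noise; bounded random-walk motion
(1 µm/frame step, 5 µm bound — small relative to cell size so tracking is
well-posed); uniform-disk or Gaussian-blob cells whose integrated phase
equals the scheduled mass exactly at render time. Placement enforces a
minimum separation and a margin of max radius + motion bound, so cells
never leave the field. All randomness flows through one seeded generator;
identical specs and seed give bit-identical outputs.

Not emulated: cell division and death events (off by default), mitotic
shape change, clumping and touching cells beyond incidental overlap,
illumination drift, focus error, partially coherent imaging physics, and
segmentation-confusing debris. Passing tests therefore demonstrate the
correctness of the measurement and statistics chain under the model's
assumptions, not robustness to every real-world imaging artifact.

## Problem sizes and determinism

The packaged validations use 50-cell/145-frame movies on 600² px fields,
256² round-trip objects, 100-replicate fit studies, 100-run null
calibrations, and plates of 16–35 wells at 80–200 cells per well — sizes
at which every statistic above is stable while a full test run stays in
the minutes range. Summaries are canonical JSON (sorted keys) stamped with
a SHA-256 hash of the config (minus the output directory), and a repeated
run with the same config and seed is byte-identical.
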