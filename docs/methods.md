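# Methods

## Signal model

A TCSPC acquisition delivers, per pixel, photon counts `h_k` in delay bins
of width Δ (collection 8 ps, analysis 128 ps after 16× rebinning) within
one laser repetition period T. The emission of a vesicle or pixel is
modelled as a two-component exponential mixture of free and protein-bound
NAD(P)H,

    I(t) ∝ f/τ_b · e^(−t/τ_b) + (1−f)/τ_f · e^(−t/τ_f),

where `f` is the *intensity* fraction of the bound component, so the
intensity-weighted mean lifetime is exactly `τ = f·τ_b + (1−f)·τ_f`.
Under periodic excitation the observed rate is the IRF-convolved decay
wrapped modulo T; with lifetimes up to 6 ns against a ~12 ns period the
wrap is never negligible and is always applied. Photon counts are Poisson.

## Phasor estimation and calibration

The discrete phasor uses bin centres and the amplitude correction
`(ωΔ/2)/sin(ωΔ/2)`. Two conventions make this estimator essentially exact
(≈1e-8 against the continuous transform) rather than merely approximate:

* **bin centres** supply the half-bin phase of rectangular binning, and the
  correction restores its amplitude attenuation;
* **the analysis window tiles the repetition period exactly.** The default
  time base is therefore 1536 × 8 ps = 96 × 128 ps = T = 12.288 ns
  (≈81.4 MHz). If the window falls short of the period, the untransformed
  tail biases the phasor (≈6e-3 in (g, s) at τ = 6 ns for a 12.288 ns
  window under a 12.5 ns period) — a bias no IRF calibration removes. The
  period is a configurable `TimeAxis` field for instruments where the two
  cannot be matched.

The IRF is removed in the frequency domain: `z_cal = z_meas / z_irf` with
`z = g + i·s`. Parametric Gaussian IRFs (default FWHM 250 ps, peak 0.6 ns —
a typical hybrid-detector response) use the analytic transform
`exp(−(ωσ)²/2)·exp(iωt₀)`; measured IRF histograms are transformed with the
same discrete estimator as the data so binning effects cancel. A reference
of known lifetime may substitute for an explicit IRF.

Lifetimes come from orthogonal projection onto the chord between the basis
phasors (default basis τ_free = 0.4 ns, τ_bound = 3.2 ns — the centres of
the literature free and NADH-dominated bound ranges; both configurable).
Off-chord phasors are clamped to [0, 1] in `f` with a flag rather than
rejected, so noisy dim vesicles stay in the sample. Phase
(`τ = s/(gω)`) and modulation (`τ = ω⁻¹√(1/(g²+s²) − 1)`) estimators are
kept as diagnostics only. The first harmonic is used throughout; higher
harmonics are supported but unused.

## Segmentation

The detector mirrors standard scale-space practice because no published
parameter set exists for this application; everything is configurable:

| parameter | default | role |
|---|---|---|
| background σ | 20 px | large-blur flattening of slow non-uniformity |
| scale ladder | 0.8 … 3.2 px, ratio √2 | sub-resolution EVs to small aggregates at 0.35 µm/px |
| threshold k | 3 | accept responses above k × (1.4826 × MAD of the flattened image) |
| min separation | 4 px | greedy suppression, larger response wins |
| mask radius | √2 × σ | LoG zero-crossing radius |

Local maxima are strict over all 26 neighbours in (row, col, scale);
equal-valued plateaus that dominate their entire surrounding yield exactly
one detection at their earliest raster voxel, which keeps the detector
deterministic. All convolutions pad reflectively. Merged aggregates are
not split (no watershed); a detected "single EV" may be a small cluster.

## Per-EV and per-pixel analysis

Pixels of one vesicle are pooled (summed) into one decay before the phasor
transform; pooling conserves photons exactly. Vesicles with fewer than 300
pooled photons (configurable) are dropped — below this the phasor variance
makes τ uninformative. The mean background decay, estimated per field from
the unmasked pixels and scaled by the vesicle's pixel count, is subtracted
from each pooled decay before the transform (on by default): a flat
dark/stray background otherwise drags dim-vesicle phasors toward the origin
and biases τ upward by ~0.04 ns at a 5000-photon budget. Cell fields are
bright enough for per-pixel estimation (minimum 100 photons/pixel,
configurable); invalid pixels are NaN in the lifetime map and excluded from
statistics. No phasor-space smoothing is applied by default; an optional
3×3 median filter on (g, s) exists behind a flag for very dim data.

Population histograms use 0.1 ns bins over [0.2, 6.0] ns and an unweighted
least-squares Gaussian fit initialised at the sample moments; fewer than 20
values or zero spread raise an error directing the caller to the direct
sample moments. Group statistics operate on per-EV (or per-pixel) lifetime
lists, not on fitted parameters, preserving n for the degrees of freedom;
the t-test is pooled-variance by default (Welch behind a flag) and multiple
comparisons default to Tukey–Kramer (Bonferroni behind a flag).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on:
sparse sub-resolution emitters (2-D Gaussian footprints, σ 0.7–2.0 px)
against a dark field; per-vesicle expected photons drawn log-uniform from
500–20 000 (single-EV signal is genuinely low; real per-EV counts are
unpublished, so the budget is an explicit assumption); a uniform Poisson
dark/stray background of 5 expected counts/pixel over the window; lifetime
populations drawn from Gaussians truncated to [0.2, 6.0] ns and clamped
into the basis interval (<0.3 % of draws for every population used); cell
phantoms as disk-shaped cytosol with an elliptical nucleus and granular
mitochondria, each pixel drawing its own lifetime. Expectation curves are
computed from the exponentially-modified-Gaussian CDF summed over wrap
periods, so bin integrals are exact; a fixed seed gives byte-identical
output, with per-FOV substreams spawned deterministically.

It does **not** model diffraction (the footprint is a free Gaussian, not a
PSF), detector afterpulsing or pile-up, cell motion during accumulation,
autofluorescent background structure, or vesicle aggregation. Passing the
recovery benchmarks therefore demonstrates that the *pipeline* is unbiased
and correctly calibrated under its own assumptions — not that those
assumptions exhaust real instrument data.

## Benchmark problem sizes

Desk-scale runs keep full statistical fidelity while staying fast: per-EV
recovery uses 200 vesicles per repeat spread over eight 180 × 180 px fields
(vesicle density per area comparable to dozens per full 512 px field),
≥ 5000 photons per vesicle, three independent repeats whose Gaussian-fit
parameters are averaged; compartment recovery uses one 160 × 160 px
three-cell phantom at 5000 photons/pixel. The blank-field false-positive
control runs at the full default 512 × 512 geometry. At these sizes the
dominant uncertainty in a recovered population mean is the sampling noise
of the 200 drawn lifetimes (SE ≈ σ/√200 ≈ 0.02 ns per repeat), not
estimator noise.

## Numerical choices and degenerate inputs

* Exponentially-modified-Gaussian CDF evaluated via `erfcx` for u ≥ 0 and
  plain `erfc` with a decaying exponent otherwise — stable over the full
  time range without overflow.
* Gaussian-fit convergence tolerances 1e-8; fit failures raise with
  initialisation diagnostics rather than returning silently.
* Zero-total decays, absent mask labels, empty scale lists, non-integer or
  negative counts, and metadata mismatches all raise immediately with the
  offending field named.
* MAD-based noise: an all-zero flattened image yields σ_noise = 0, in which
  case any strictly positive response is accepted.
* Ties: plateau maxima resolve to the earliest raster voxel; equidistant
  mask pixels go to the lower label id.

## Known limitations

* The two-component basis is an approximation; NAD(P)H in real samples is
  multi-exponential, and the projected τ is a basis-dependent summary.
* Segmentation counts aggregates as single vesicles.
* The background subtraction assumes a spatially uniform background decay.
* Population SDs recovered from low-photon vesicles include an estimator
  noise floor (≈0.05 ns at 3000 pooled photons) added in quadrature to the
  true population spread.
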