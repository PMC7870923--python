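# evflim

Phasor-based NAD(P)H fluorescence-lifetime (FLIM) analysis of **single
extracellular vesicles (EVs)**, with a matching synthetic-data generator for
end-to-end validation.

EVs are cell-derived membrane particles that carry, among much else, the
metabolic cofactors NADH and NADPH ("NAD(P)H"). Free NAD(P)H fluoresces with
a short lifetime (~0.3–0.8 ns) and protein-bound NAD(P)H with a long one
(~1.5–6 ns), so the mean fluorescence lifetime of a vesicle reports on its
free/bound balance — a label-free metabolic readout at single-EV
resolution. This package implements the computational side of that
measurement for time-correlated single-photon-counting (TCSPC) image
stacks: vesicle segmentation, per-vesicle lifetime estimation, population
statistics, and group comparisons. It is written for microscopists and
image-analysis developers working with low-photon TCSPC data.

## Method

Each pixel of a field of view holds a histogram of photon arrival delays
`h_k` on bin centres `t_k`. Its **phasor** at the angular repetition
frequency ω = 2π/T is

```
g = Σ h_k cos(ω t_k) / Σ h_k ,   s = Σ h_k sin(ω t_k) / Σ h_k
```

with a finite-bin amplitude correction `(ωΔ/2)/sin(ωΔ/2)`. A
single-exponential decay of lifetime τ lies on the universal semicircle at
`g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`. The instrument response is removed
by complex division (frequency-domain deconvolution), after which a
free/bound mixture falls on the chord between the two component phasors.
Orthogonal projection onto that chord gives the bound intensity fraction
`f`, and the reported mean lifetime is

```
τ = f·τ_bound + (1 − f)·τ_free          (default basis 0.4 / 3.2 ns)
```

Vesicles are found in the intensity image by a five-stage blob detector:
background flattening (subtract a large Gaussian blur), scale-normalised
Laplacian-of-Gaussian filtering at a √2-spaced scale ladder, strict 3-D
local-maximum detection across (row, col, scale), thresholding against a
robust MAD noise estimate, and disk-mask synthesis at the LoG zero-crossing
radius. Because single vesicles yield few photons, all pixels of a vesicle
are pooled into one decay before the phasor transform. Per-sample lifetime
histograms are summarised by Gaussian fits (mean ± SD), and groups are
compared with Student's t-tests, one-way ANOVA, Tukey–Kramer multiple
comparisons, and ordinary least-squares regression.

The `simulate` module generates the same kind of data with known ground
truth: sparse Gaussian-footprint vesicles with Poisson photon noise,
two-component decays convolved with the IRF and wrapped around the laser
period, Gaussian lifetime populations, multi-compartment cell phantoms
(nuclei / mitochondria / cytosol), and blank negative controls.

## Worked example

```python
import numpy as np
from evflim import (SimulationConfig, render_ev_sample, analyze_fov,
                    fit_gaussian_histogram, default_irf)

config = SimulationConfig(fov_shape=(180, 180), n_evs=25, seed=0,
                          population=(1.33, 0.31), photon_budget=(5000, 20000))
irf = default_irf()
taus = []
for stack, truths in render_ev_sample(config, n_fovs=8):
    records = analyze_fov(stack, irf)
    taus.extend(r.tau_ns for r in records)

fit = fit_gaussian_histogram(np.asarray(taus))
print(f"analyzed {len(taus)} vesicles")
print(f"fitted lifetime population: {fit.mean_ns:.2f} +/- {fit.sd_ns:.2f} ns")
```

prints

```
analyzed 200 vesicles
fitted lifetime population: 1.33 +/- 0.33 ns
```

Two hundred vesicles were simulated with true lifetimes drawn from a
Gaussian population of 1.33 ± 0.31 ns; every one was re-detected by the
blob pipeline, and the Gaussian fitted to the recovered per-vesicle
lifetime histogram reproduces the generating population (the small excess
in the SD is the residual phasor shot noise at this photon budget).

The same workflows are available from the shell via the `evflim` console
script (`simulate-evs`, `simulate-cells`, `simulate-blank`, `segment`,
`analyze`, `analyze-cells`, `compare`, `render`); every run writes its
effective `config.yaml` next to its outputs.

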