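# braggsieve

Background/Bragg-signal separation for 2D diffraction frames: weighted
azimuthal statistics, iterative sigma clipping, lossy sparsification of
detector images, and an SNR-based Bragg peak finder with a frame veto.

## Who this is for

Serial-crystallography and single-crystal diffraction pipelines face a
bandwidth problem: modern pixel detectors produce thousands of multi-megapixel
frames per second, most of whose pixels carry only smooth, isotropic
background scattering.  If the background of each Debye–Scherrer ring can be
estimated robustly — mean μ_r and standard deviation σ_r per radial bin —
then a frame can be reduced to (a) the few pixels that rise above
μ_r + n·σ_r (the candidate Bragg signal) plus (b) the 1D background profile,
and everything else can be regenerated on demand.  The same statistics drive
a peak finder whose per-frame peak count serves as a live veto for empty
frames.  `braggsieve` implements that stack as a tested NumPy library with a
thin command-line interface, exercised entirely on synthetic data with known
ground truth.

## The statistics at the core

Every pixel *i* carries a signal (dark-subtracted counts) and a
normalization norm_i (flat field × solid angle × polarization × efficiency ×
flux).  With intensity v_i = signal_i / norm_i and weight ω_i = c_i·norm_i,
each radial bin is summarized by the sums

    Ω = Σ ω_i,   Ω₂ = Σ ω_i²,   V = Σ ω_i v_i,   VV = Σ ω_i (v_i − V/Ω)²

giving the weighted mean μ = V/Ω and the ring ("azimuthal") variance
σ² = VV/Ω.  The sums update in a single streaming pass and two partial sums
merge exactly via

    VV_AB = VV_A + VV_B + (Ω_A Ω_B / Ω_AB)(μ_A − μ_B)²,

so whole-frame reductions parallelize over pixel blocks.  Sigma clipping
iteratively discards pixels with |v_i − μ_r| > n·σ_r; the cutoff n is either
fixed or adapted to the ring population N through a Chauvenet-style
criterion t(N) = √(2 ln(N/√(2π))) (≈2.7 at N=100, ≈3.5 at N=1000).  Clipping
always measures deviations against the ring spread: Poisson errors would put
both pixels of a {1, 199} ring at ~10σ and empty it, whereas the ring spread
puts each at exactly 1σ.  After the ensemble is trimmed, the *hybrid* model
reports Poisson uncertainties computed from the ring mean.

Sparsification keeps pixels above μ_r + n·σ_r — an upper-tail fraction
Q(n) of a normal background (16% at 1σ, 2.3% at 2σ, 0.13% at 3σ) — for a
theoretical compression of 1/(2·Q(n)): ≈22× at 2σ.  Densification restores
the kept pixels bit-exactly and redraws the rest from the stored profile,
noiseless or with matched Gaussian/Poisson noise.  The peak finder registers
a pixel as a peak apex when it exceeds min_snr ring sigmas, is the strict
maximum of its square patch, and enough patch pixels pass the SNR condition;
a frame passes the veto when its peak count reaches a threshold.

## Worked example

```python
import numpy as np
from braggsieve import (DetectorGeometry, SimulationSpec, generate, preprocess,
    build_radius_map, build_bin_assignment, sigma_clip, ClipConfig, pick_pixels,
    find_peaks, PeakFinderConfig, veto, theoretical_compression_ratio)

geom = DetectorGeometry(n_rows=512, n_cols=512,
                        beam_center_row=255.5, beam_center_col=255.5)
stack = generate(SimulationSpec(geometry=geom, n_frames=1, n_peaks=50, seed=1))
frame = preprocess(stack.frames[0], mask=stack.mask)
bins = build_bin_assignment(build_radius_map(geom), stack.mask, n_bins=96)

clip = sigma_clip(frame, bins, ClipConfig(snr_cutoff="auto", error_model="hybrid"))
sparse = pick_pixels(frame, clip, 2.0, geom)
peaks = find_peaks(frame, clip, PeakFinderConfig(patch_size=5, min_snr=5, min_pixels=4))
```

This prints, via the obvious f-strings:

```
clip iterations (max over bins): 5
background at r=100 px: mean=178.89  std=13.37  truth=178.70
retained pixels: 7570 / 262144 (2.89%)
theoretical compression at 2 sigma: 22.0x
peaks found: 50 (50 injected); frame kept at veto threshold 20: True
first peak: centroid=(22.32, 255.32) intensity=1705 sigma=47.0
```

The clipped ring mean lands on the injected background (178.89 vs 178.70,
well inside one standard error); the retained fraction (2.89%) sits slightly
above the pure-noise 2.275% because the frame really does contain 50 peaks
plus their tails; and all 50 injected peaks are found with sub-pixel
centroids and no false positives.

The same pipeline is available from the shell:

```sh
braggsieve simulate --out stack.h5 --size 512 --frames 10 --peaks 50 --seed 1
braggsieve sparsify stack.h5 sparse.h5 --bins 96 --snr auto --snr-pick 2
braggsieve densify sparse.h5 restored.h5 --noise gaussian --seed 2
braggsieve peakfind stack.h5 peaks.cxi --min-snr 5 --veto-min-peaks 20
```

## Documentation

`docs/methods.md` describes the statistical model, the error models and
their failure modes, the synthetic-data generator, and the numerical and
design choices in detail.
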