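# Methods

## Problem setting

A diffraction frame from a macromolecular or powder sample decomposes into a
smooth, isotropic background (amorphous/solvent scattering) plus sparse,
sharp Bragg peaks and occasional shadowed or defective pixels.  All pixels
at the same distance r from the beam center see, after anisotropy
corrections, the same background flux, so the ring population is the natural
statistical ensemble: its central tendency estimates the background and its
spread the background noise, provided the Bragg outliers are removed.
Everything in this package is built on that single idea.

## Pixel model and corrections

The corrected intensity of pixel i is

    v_i = (I_raw,i − I_dark,i) / (F_i · Ω_i · P_i · A_i · I0)

with flat field F, solid angle Ω, polarization P, apparent efficiency A and
incoming flux I0.  The numerator ("signal") and denominator ("norm") are
kept separate throughout: ring averages are computed as summed signal over
summed normalization, which is both numerically convenient and makes the
weighting explicit.  Correction arrays are accepted as precomputed inputs;
the cos³(2θ) solid-angle and 1 − pf·(sin 2θ cos φ)² polarization helpers
shipped here are textbook conveniences for synthetic work, not calibrated
models.

Two per-pixel noise models are supported.  The Poisson model sets
σ_i² = max(signal_i, floor) with floor = 1 ADU² — counting statistics, with
the floor giving empty pixels a nonzero uncertainty, since λ = 0 is never
exactly true of a physical detector — plus an optional per-pixel dark-noise
variance added in quadrature.  The fixed model takes an arbitrary
user-supplied variance map for detectors whose noise is not Poissonian.

## Ring statistics

With weights ω_i = c_i·norm_i (c_i = 1 here: pixels are never split between
bins, fractional-area splitting blurs the signal and is out of scope), each
bin carries four sums: Ω = Σω, Ω₂ = Σω², V = Σωv, VV = Σω(v − V/Ω)².
The weighted mean is V/Ω.  Three uncertainty models are derived from them:

* **azimuthal** — the observed ring spread: std² = VV/Ω (weighted
  population variance) and sem² = VV·Ω₂/Ω³.  For unit weights these reduce
  exactly to the population standard deviation and std/√N, which is the
  binding contract; the weighted sem uses the Kish effective sample size
  N_eff = Ω²/Ω₂ so that sem = std/√N_eff.
* **poisson** — propagation of the per-pixel variances:
  sem² = Σc_i²σ_i²/Ω², std = sem·√N_eff.  The coefficient is squared in the
  numerator so that uncertainties scale with the pixel fraction considered.
* **hybrid** — Poisson propagation with the ring-mean-based rate
  σ_i² = max(μ_r·norm_i, floor), i.e. counting statistics of the *ensemble*
  rather than of each pixel.  This is the reporting model used after
  clipping, when the ensemble has been trimmed to its mono-modal background
  core.

The choice of the population form VV/Ω (rather than a frequency-weights
unbiased form) is anchored to the bimodal two-pixel ring {1, 199}: its mean
is 100 and each pixel must sit at exactly one azimuthal sigma (std = 99),
while Poisson statistics would place both at ~10σ.  That discrepancy is not
academic — clipping bimodal rings with Poisson errors empties them entirely,
which is the failure mode that motivates the azimuthal model.

### Single-pass accumulation and merging

The four sums update in one streaming pass per pixel
(VV += ω(v − μ_old)(v − μ_new), zero for the first element) and two partial
accumulators A, B over disjoint pixel sets merge exactly:

    VV_AB = VV_A + VV_B + (Ω_A Ω_B / Ω_AB)(μ_A − μ_B)².

The cross term is evaluated from the two means, not from raw V differences,
to avoid catastrophic cancellation when one side is tiny; all arithmetic is
double precision.  The test suite verifies equivalence with the textbook
two-pass formulas to 1e−10 relative error over a thousand random weighted
sets under arbitrary merge orders, so block-parallel reductions are safe.
The whole-frame path (`profile_from_frame`) is a vectorized bincount
implementation of the same sums.

## Sigma clipping

Per bin, iteratively: estimate (μ_r, σ_r) under the clipping error model —
always the azimuthal spread, unless the pure Poisson model is explicitly
requested — and discard pixels with |v_i − μ_r| strictly greater than
n·σ_r; ties at exactly n·σ_r are retained.  Clipping is two-sided: positive
outliers are Bragg peaks, negative ones shadows.  A bin exits the loop as
soon as an iteration discards nothing; `max_iter` (default 5) is a safety
cap, and a handful of iterations is typical on well-behaved frames (the
suite asserts ≤ 10).  Bins that lose every pixel are flagged invalid and
reported with a warning, never an exception, because a silent zero
background would corrupt every consumer downstream.

The automatic cutoff is a Chauvenet-style criterion: accept losing about one
genuine sample per ring, giving t(N) = √(2 ln(N/√(2π))), monotonically
increasing from ≈2.7 at N = 100 to ≈3.5 at N = 1000.  N is the *current*
inlier count, re-evaluated per bin and per iteration as the ensemble
shrinks; ensembles below N = 3 (where t leaves the real axis) are clamped
to N = 3.

## Sparsification and densification

A pixel is retained when unmasked and v_i > μ_r + n·σ_r.  Pixels in invalid
bins are always retained — losing signal is worse than losing compression.
Values are stored as float32 of the corrected intensity (bit-exact round
trip; whether to store raw or corrected values is a free choice and
corrected is the one that makes densified frames directly consumable).
For an exactly normal background the retained fraction is the upper tail
Q(n) — 16%, 2.3%, 0.13% at n = 1, 2, 3 — and with two numbers stored per
retained pixel the theoretical compression ratio is 1/(2·Q(n)) ≈ 22× at 2σ,
≥ 6.4× already at 1.5σ.  The container is HDF5 following the NeXus
convention: CSR-style concatenated indices/values with a frame pointer,
per-frame background curves, and the geometry provenance (shape, beam
center, pixel pitch, radius-map hash).  Datasets are written uncompressed;
any lossless HDF5 codec may be layered on without changing the layout.

Densification rebuilds the radius map from the stored geometry, assigns
each pixel its bin, and fills background pixels with μ_r (noiseless), with
μ_r + N(0, σ_r) draws (for software that performs its own noise analysis),
or with Poisson(μ_r) draws; rings with negative mean fall back to Gaussian
with a warning.  Masked and out-of-range pixels get the sentinel −1 —
shaded regions cannot be reconstructed and must stay masked downstream.
Retained pixels are restored last, bit-exactly.  Output is deterministic
given (sparse frame, noise mode, seed).  Gaussian output is left
untruncated unless integer output is requested, in which case it is rounded
and clipped at zero.

One property of the scheme worth knowing: a densified frame carries the
background's upper tail *twice* — the redrawn Gaussian background includes
its own > nσ tail, and the original tail pixels are restored on top — so
re-clipping a densified frame biases the ring mean high by ≈ φ(n)·σ_r
(φ the standard normal density: ~0.05σ at n = 2, negligible at n = 3).
Re-sparsifying at n = 2 therefore re-selects only ~88% of the original
pixels (borderline ones fall under the slightly raised threshold), while at
n = 3 the round trip is stable at ~99%.  The suite pins both behaviours.

## Peak finding and veto

Candidates are pixels with (v_i − μ_r)/σ_r ≥ min_snr, using the post-clip
hybrid σ_r of the pixel's own ring; because σ is measured *along* the ring,
a steep radial background does not inflate the noise estimate the way a
square-neighborhood variance does, preserving sensitivity near the beam
center where ring curvature is strong (the suite demonstrates this against
a square-window baseline oracle).  A candidate is an apex iff it is the
strict maximum of its patch (ties broken by smallest row-major index — the
choice is arbitrary but must be deterministic), and is registered iff at
least min_pixels patch pixels (apex included) meet the SNR condition;
defaults follow the common practice of 4 pixels in a 5×5 patch.  The
centroid is the intensity-weighted mean position over qualifying pixels
with background-subtracted weights clamped at zero; the summed
background-subtracted intensity and the quadrature sum of the ring sigmas
are recorded with it.  Overlapping peaks are reported separately, never
merged.  An optional σ floor supports nearly noise-free synthetic rings.

Peak lists are written as CXI-convention HDF5 tables (nPeaks plus
fixed-width rows padded to max_peaks; X = column, Y = row, 0-based), with a
few extra datasets (per-peak sigma, pixel count, apex position) so the
round trip is lossless.  The veto keeps a frame iff its peak count reaches
a threshold; at a threshold of 20 a frame with 19 peaks is discarded and
one with 20 is kept.

## Synthetic data

The generator emulates the data regime above: an isotropic background
B(r) = constant + broad radial Gaussians (default: floor 50 ADU, a
forward-scattering lobe of 150 ADU with width 0.45·r_max, and a diffuse
ring of 60 ADU at 0.55·r_max — a typical amorphous curve shape at one ADU
per photon), Poisson counting noise, and 2D-Gaussian peaks (σ = 1.2 px)
whose apex amplitude is drawn as a multiple (uniform in [10, 30]) of the
local background noise √B(r).  Peaks are rejection-placed at least 16 px
apart and 8 px from borders and masked pixels; the mask is a random salt of
defective pixels plus an optional dead-row strip.  All randomness flows
from one seed; generation is bit-reproducible, and the exact background
function and peak table are returned as ground truth.

What it does not model: structure factors, mosaicity or any physical
diffraction intensity distribution; detector gain stages, saturation or
charge sharing; anisotropic backgrounds (which the ring model cannot
handle by construction).  Passing tests therefore demonstrate the
statistical machinery — unbiased background recovery, correct tail
fractions, peak localization — under the model's own assumptions, not
performance on any particular real detector.

## Problem sizes and test design

Unit tests run on 64²–256² frames.  The end-to-end statistical checks use:
one 2048² standard-normal frame (500 bins) for the empirical keep fraction;
a 256² frame with 24 bins for the densification round trip — the per-bin
mean/std comparison at 3× sampling error is repeated across every bin, so
the bin count is sized to keep the expected number of >3σ chance excursions
near 0.1; and a 100-frame stack of 512² frames with 50 peaks each (96 bins)
for background/peak recovery, a size chosen to keep a full run on one CPU
within a coffee break while leaving thousands of peaks and bins to score.
Background-recovery assertions use the study peak density (50 peaks per
512² frame): at several times that density the sub-threshold tails of peaks
left inside rings measurably bias the clipped background, which is a real
property of the method, not a test artifact.

## Known limitations

* Equal-width radius bins only; q or 2θ binning is available as a
  conversion helper but not as a binning axis.
* Flat orthogonal detector geometry (no tilts, no multi-module layouts).
* Backgrounds that vary strongly *within* a bin (very narrow rings, e.g.
  ice rings, or under-resolved gradients) inflate the azimuthal σ and can
  make clipping fire on genuine background; bins must be chosen fine enough
  to resolve the background's radial structure, but coarse enough to keep
  ring populations statistically useful.
* The aggressive-threshold densification bias described above: below n ≈ 2
  the restored frames are statistically slightly brighter than the
  originals in the tail region.
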