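"""Iterative sigma clipping of radial bins.

Each radial bin starts from all of its unmasked pixels and repeatedly
discards the pixels whose corrected intensity deviates from the current ring
mean by strictly more than ``n`` ring standard deviations (positive outliers
are Bragg peaks, negative ones shadows or defective pixels).  The loop for a
bin exits as soon as an iteration discards nothing, so a generous iteration
cap costs nothing; a handful of iterations is typical.

The cutoff ``n`` is either fixed or adapted to the shrinking ensemble size
with a Chauvenet-style criterion, t(N) = sqrt(2 ln(N / sqrt(2 pi))): the
threshold at which, for an N-sample normal ensemble, about one sample is
expected beyond it.  It grows from ~2.7 at N=100 to ~3.5 at N=1000.

Error models: clipping itself always measures deviations against the ring
spread (azimuthal model) unless the pure Poisson model is explicitly
requested -- Poisson errors wildly overstate the significance of bimodal
rings and can empty them (see :mod:`braggsieve.azstats`).  What varies is
the *reporting* model of the returned profile: ``"hybrid"`` clips with the
azimuthal spread, then quotes Poisson uncertainties computed from the ring
mean of the trimmed, mono-modal ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .azstats import ERROR_MODELS, RadialProfile, profile_from_frame
from .geometry import BinAssignment
from .preprocess import PreprocessedFrame

__all__ = ["ClipConfig", "ClipResult", "chauvenet_cutoff", "sigma_clip"]

#: Smallest ensemble size at which the adaptive cutoff is evaluated; below
#: it t(N) would leave the real axis (N < sqrt(2 pi) ~ 2.5).
_MIN_CHAUVENET_N = 3


def chauvenet_cutoff(n_pixels):
    """Adaptive clipping threshold t(N) = sqrt(2 ln(N / sqrt(2 pi))).

    Monotonically increasing in N; ensembles smaller than 3 are clamped to
    N=3.  Accepts scalars or arrays.
    """
    n = np.maximum(np.asarray(n_pixels, dtype=np.float64), _MIN_CHAUVENET_N)
    t = np.sqrt(2.0 * np.log(n / np.sqrt(2.0 * np.pi)))
    if np.isscalar(n_pixels):
        return float(t)
    return t


@dataclass
class ClipConfig:
    """Sigma-clipping parameters.

    ``snr_cutoff`` is the rejection threshold in sigma units, or ``"auto"``
    for the Chauvenet-variant cutoff recomputed per bin and per iteration as
    the ensemble shrinks.  ``error_model`` selects the *reporting* model of
    the final profile (clipping uses the azimuthal spread except under the
    pure ``"poisson"`` model).
    """

    snr_cutoff: float | str = "auto"
    max_iter: int = 5
    error_model: str = "hybrid"
    variance_floor: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.snr_cutoff, str):
            if self.snr_cutoff != "auto":
                raise ValueError("snr_cutoff must be a positive number or 'auto'")
        elif self.snr_cutoff <= 0:
            raise ValueError("snr_cutoff must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(
                f"unknown error model {self.error_model!r}; choose from {ERROR_MODELS}"
            )


@dataclass
class ClipResult:
    """Outcome of sigma clipping one frame.

    ``profile`` carries the post-clip background statistics under the
    configured reporting model; ``inlier_mask`` marks the retained pixels;
    ``iterations_used`` counts, per bin, the clip iterations executed before
    that bin converged.
    """

    profile: RadialProfile
    inlier_mask: np.ndarray
    iterations_used: np.ndarray
    bins: BinAssignment = field(repr=False)
    config: ClipConfig = field(repr=False)


def sigma_clip(
    frame: PreprocessedFrame,
    bins: BinAssignment,
    config: ClipConfig | None = None,
) -> ClipResult:
    """Iteratively clip outliers in every radial bin of a frame.

    Returns a :class:`ClipResult`; bins that end up with no inlier at all
    (possible only under the pure Poisson model on pathological input) are
    flagged invalid in the profile and reported with a warning rather than
    raising.
    """
    if config is None:
        config = ClipConfig()
    if bins.shape != frame.shape:
        raise ValueError("bin assignment shape does not match frame")

    clip_model = "poisson" if config.error_model == "poisson" else "azimuthal"
    auto = config.snr_cutoff == "auto"

    inlier = (bins.pixel_bin >= 0) & ~frame.mask
    pb = bins.pixel_bin
    n_bins = bins.n_bins
    iterations_used = np.zeros(n_bins, dtype=np.int64)
    counts0 = np.bincount(pb[inlier], minlength=n_bins)
    active = counts0 > 0
    had_pixels = active.copy()

    for _ in range(config.max_iter):
        prof = profile_from_frame(
            frame,
            bins,
            error_model=clip_model,
            inlier_mask=inlier,
            variance_floor=config.variance_floor,
        )
        if auto:
            thresh = chauvenet_cutoff(np.maximum(prof.count, 1))
        else:
            thresh = np.full(n_bins, float(config.snr_cutoff))

        iterations_used[active] += 1

        # Rejection (strict: ties at exactly n*sigma are retained), applied
        # only within still-active bins.
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_pb = np.maximum(pb, 0)
            dev = np.abs(frame.signal / frame.norm - prof.mean[safe_pb])
            limit = thresh[safe_pb] * prof.std[safe_pb]
            reject = inlier & active[safe_pb] & (dev > limit)

        if not reject.any():
            break
        inlier &= ~reject
        changed = np.zeros(n_bins, dtype=bool)
        changed[np.unique(pb[reject])] = True
        active &= changed
        if not active.any():
            break

    profile = profile_from_frame(
        frame,
        bins,
        error_model=config.error_model,
        inlier_mask=inlier,
        variance_floor=config.variance_floor,
    )
    emptied = had_pixels & ~profile.valid
    if emptied.any():
        warnings.warn(
            f"sigma clipping emptied {int(emptied.sum())} bin(s); "
            "they are flagged invalid in the profile",
            RuntimeWarning,
            stacklevel=2,
        )
    return ClipResult(
        profile=profile,
        inlier_mask=inlier,
        iterations_used=iterations_used,
        bins=bins,
        config=config,
    )
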