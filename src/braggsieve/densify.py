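"""Reconstruction of dense frames from their sparse representation.

Retained pixels are restored bit-exactly; every other unmasked pixel is
synthesized from the stored per-ring background -- either the plain ring
mean (noiseless, preferred by integration programs that do their own
smoothing) or the mean plus matched noise (Gaussian with the stored ring
sigma, or Poisson draws at the ring mean) for programs that perform their
own noise analysis on the background.  Masked regions cannot be
reconstructed and are set to the sentinel value -1, as is any pixel whose
radius falls outside the stored binning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import DetectorGeometry, build_radius_map
from .sparsify import SparseFrame

__all__ = ["MASK_SENTINEL", "NOISE_MODES", "densify"]

MASK_SENTINEL = -1.0
NOISE_MODES = ("none", "gaussian", "poisson")


def _bin_index(sparse: SparseFrame) -> np.ndarray:
    """Per-pixel bin index rebuilt from the stored geometry; -1 if unknown."""
    geom = DetectorGeometry(
        n_rows=sparse.shape[0],
        n_cols=sparse.shape[1],
        beam_center_row=sparse.beam_center[0],
        beam_center_col=sparse.beam_center[1],
        pixel_size=sparse.pixel_size,
    )
    r = build_radius_map(geom)
    edges = sparse.bin_edges
    n_bins = edges.size - 1
    idx = np.searchsorted(edges, r, side="right") - 1
    # last bin is closed; radii beyond the outer edge are unknown
    idx[r == edges[-1]] = n_bins - 1
    idx[(r > edges[-1]) | (idx < 0)] = -1
    return idx.astype(np.int64)


def densify(
    sparse: SparseFrame,
    noise: str = "none",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    integer_output: bool = False,
) -> np.ndarray:
    """Rebuild one dense frame from a :class:`SparseFrame`.

    Parameters
    ----------
    sparse
        The sparse frame to densify.
    noise
        ``"none"`` (ring means), ``"gaussian"`` (means + N(0, sigma_r)) or
        ``"poisson"`` (Poisson draws at the ring mean; rings with a negative
        mean fall back to Gaussian with a warning).
    seed, rng
        Source of randomness for the noisy modes; given the same sparse
        frame, mode and seed the output is bit-reproducible.
    integer_output
        Round the result and clip the background at zero, returning int32
        (count-like output); the float output is left untruncated.

    Returns
    -------
    numpy.ndarray
        Dense float32 frame (or int32 with ``integer_output``); masked and
        unknown-bin pixels hold the sentinel -1.
    """
    if noise not in NOISE_MODES:
        raise ValueError(f"unknown noise mode {noise!r}; choose from {NOISE_MODES}")
    if rng is None:
        rng = np.random.default_rng(seed)

    idx = _bin_index(sparse)
    mean = sparse.background_mean
    std = sparse.background_std
    known = (idx >= 0) & np.isfinite(mean[np.maximum(idx, 0)])
    safe = np.maximum(idx, 0)

    out = np.full(sparse.shape, MASK_SENTINEL, dtype=np.float64)
    out[known] = mean[safe[known]]

    if noise == "gaussian":
        out[known] += std[safe[known]] * rng.standard_normal(int(known.sum()))
    elif noise == "poisson":
        neg = known & (mean[safe] < 0)
        pos = known & ~neg
        out[pos] = rng.poisson(mean[safe[pos]]).astype(np.float64)
        if neg.any():
            warnings.warn(
                "negative ring mean under poisson noise; falling back to "
                f"gaussian for {int(neg.sum())} pixel(s)",
                RuntimeWarning,
                stacklevel=2,
            )
            out[neg] += std[safe[neg]] * rng.standard_normal(int(neg.sum()))

    if sparse.mask is not None:
        out[sparse.mask] = MASK_SENTINEL

    out32 = out.astype(np.float32)
    # restore retained pixels last, bit-exact
    out32.ravel()[sparse.pixel_indices] = sparse.pixel_values

    if integer_output:
        res = np.rint(out32)
        sentinel = out32 == MASK_SENTINEL
        res[~sentinel] = np.maximum(res[~sentinel], 0.0)
        res[sentinel] = MASK_SENTINEL
        return res.astype(np.int32)
    return out32
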