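"""SNR-based Bragg peak finding on the clipped background, plus the veto.

A pixel is a peak candidate when its background-subtracted corrected
intensity exceeds ``min_snr`` ring standard deviations.  A candidate is an
apex when it is the strict maximum of its square patch (ties broken by the
smallest row-major index), and it is registered as a peak when at least
``min_pixels`` pixels of the patch (apex included) meet the SNR condition.
For each registered peak the background-subtracted intensity-weighted
centroid, the summed background-subtracted intensity and its propagated
deviation are recorded.

Because the background sigma is measured *along the ring* of each pixel, a
steep radial background does not inflate the noise estimate the way a square
neighborhood variance does, which preserves sensitivity close to the beam
center where ring curvature is strong.

Peak lists are written to HDF5 following the CXI peak-list convention
(fixed-width rows padded to ``max_peaks``, ``nPeaks`` giving the valid
count; X is the column coordinate, Y the row, 0-based), readable by standard
serial-crystallography indexing pipelines.  The frame-level veto simply
keeps a frame when its peak count reaches a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import maximum_filter

from .clipping import ClipResult
from .preprocess import PreprocessedFrame

__all__ = [
    "PeakFinderConfig",
    "Peak",
    "PeakList",
    "find_peaks",
    "veto",
    "write_cxi",
    "read_cxi",
]


@dataclass
class PeakFinderConfig:
    """Peak-picker parameters.

    ``patch_size`` is the odd side of the square local neighborhood (3 or 5
    typical); ``min_pixels`` the number of patch pixels, apex included, that
    must meet the SNR condition; ``sigma_floor`` a lower bound on the ring
    sigma used in the SNR (useful for nearly noise-free synthetic rings).
    """

    patch_size: int = 5
    min_snr: float = 3.0
    min_pixels: int = 4
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if not 1 <= self.min_pixels <= self.patch_size**2:
            raise ValueError("min_pixels must be between 1 and patch_size**2")
        if self.min_snr <= 0:
            raise ValueError("min_snr must be positive")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be non-negative")


@dataclass
class Peak:
    """One registered peak of a frame."""

    centroid_row: float
    centroid_col: float
    total_intensity: float
    sigma: float
    n_pixels: int
    apex_row: int
    apex_col: int


@dataclass
class PeakList:
    """Peaks of one frame."""

    frame_id: int
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


def find_peaks(
    frame: PreprocessedFrame,
    clip: ClipResult,
    config: PeakFinderConfig | None = None,
    frame_id: int = 0,
) -> PeakList:
    """Locate Bragg peaks of one frame on top of its clipped background."""
    if config is None:
        config = PeakFinderConfig()
    prof = clip.profile
    bins = clip.bins
    if bins.shape != frame.shape:
        raise ValueError("clip result does not match frame shape")

    pb = bins.pixel_bin
    safe_pb = np.maximum(pb, 0)
    valid = ~frame.mask & (pb >= 0) & prof.valid[safe_pb]

    with np.errstate(invalid="ignore", divide="ignore"):
        v = frame.signal / frame.norm
        bsub = v - prof.mean[safe_pb]  # background-subtracted intensity
        sigma = np.maximum(prof.std[safe_pb], config.sigma_floor)
        snr = bsub / np.maximum(sigma, np.finfo(np.float64).tiny)
    bsub = np.where(valid, bsub, -np.inf)
    snr = np.where(valid, snr, -np.inf)

    candidate = snr >= config.min_snr
    if not candidate.any():
        return PeakList(frame_id=frame_id)

    local_max = maximum_filter(bsub, size=config.patch_size, mode="constant", cval=-np.inf)
    apex_mask = candidate & (bsub == local_max)

    half = config.patch_size // 2
    n_rows, n_cols = frame.shape
    peaks: list[Peak] = []
    for r, c in zip(*np.nonzero(apex_mask)):
        r0, r1 = max(r - half, 0), min(r + half + 1, n_rows)
        c0, c1 = max(c - half, 0), min(c + half + 1, n_cols)
        patch_b = bsub[r0:r1, c0:c1]
        # strict maximum with first-index tie-break: drop this apex if an
        # equal value occurs earlier in row-major order within the patch
        ties = np.nonzero(patch_b == bsub[r, c])
        tie_flat = (ties[0] + r0) * n_cols + (ties[1] + c0)
        if tie_flat.min() != r * n_cols + c:
            continue

        qual = snr[r0:r1, c0:c1] >= config.min_snr
        nq = int(qual.sum())
        if nq < config.min_pixels:
            continue

        weights = np.clip(patch_b, 0.0, None) * qual
        wsum = float(weights.sum())
        rows_idx, cols_idx = np.mgrid[r0:r1, c0:c1]
        if wsum > 0:
            cen_r = float((weights * rows_idx).sum() / wsum)
            cen_c = float((weights * cols_idx).sum() / wsum)
        else:  # all qualifying intensities clamped to zero: fall back to apex
            cen_r, cen_c = float(r), float(c)
        total = float(patch_b[qual].sum())
        sig = float(np.sqrt((sigma[r0:r1, c0:c1][qual] ** 2).sum()))
        peaks.append(
            Peak(
                centroid_row=cen_r,
                centroid_col=cen_c,
                total_intensity=total,
                sigma=sig,
                n_pixels=nq,
                apex_row=int(r),
                apex_col=int(c),
            )
        )
    return PeakList(frame_id=frame_id, peaks=peaks)


def veto(peaklist: PeakList, min_peaks: int) -> bool:
    """Keep-decision of the frame veto: keep iff the peak count reaches
    ``min_peaks`` (a threshold of 0 keeps everything)."""
    if min_peaks < 0:
        raise ValueError("min_peaks must be >= 0")
    return len(peaklist) >= min_peaks


_CXI_GROUP = "entry_1/result_1"


def write_cxi(peaklists, path, max_peaks: int | None = None) -> None:
    """Write peak lists as CXI-convention padded tables.

    Datasets under ``/entry_1/result_1``: ``nPeaks``, ``peakXPosRaw`` (column
    coordinate), ``peakYPosRaw`` (row), ``peakTotalIntensity``, ``peakSNR``,
    plus ``peakSigma``, ``peakNPixels``, ``peakApexX``, ``peakApexY`` and
    ``frame_id`` so that the round trip is exact.  Rows are padded with
    zeros up to ``max_peaks`` (default: the longest list, at least 1).
    """
    peaklists = list(peaklists)
    n_frames = len(peaklists)
    if max_peaks is None:
        max_peaks = max((len(p) for p in peaklists), default=0)
    max_peaks = max(int(max_peaks), 1)
    if any(len(p) > max_peaks for p in peaklists):
        raise ValueError("a peak list exceeds max_peaks")

    shape = (n_frames, max_peaks)
    npeaks = np.zeros(n_frames, dtype=np.int64)
    fid = np.zeros(n_frames, dtype=np.int64)
    x = np.zeros(shape)
    y = np.zeros(shape)
    intensity = np.zeros(shape)
    snr = np.zeros(shape)
    sig = np.zeros(shape)
    npix = np.zeros(shape, dtype=np.int64)
    apex_x = np.zeros(shape, dtype=np.int64)
    apex_y = np.zeros(shape, dtype=np.int64)
    for i, pl in enumerate(peaklists):
        npeaks[i] = len(pl)
        fid[i] = pl.frame_id
        for j, p in enumerate(pl.peaks):
            x[i, j] = p.centroid_col
            y[i, j] = p.centroid_row
            intensity[i, j] = p.total_intensity
            sig[i, j] = p.sigma
            snr[i, j] = p.total_intensity / p.sigma if p.sigma > 0 else 0.0
            npix[i, j] = p.n_pixels
            apex_x[i, j] = p.apex_col
            apex_y[i, j] = p.apex_row

    with h5py.File(path, "w") as h5:
        grp = h5.create_group(_CXI_GROUP)
        grp.create_dataset("nPeaks", data=npeaks)
        grp.create_dataset("frame_id", data=fid)
        grp.create_dataset("peakXPosRaw", data=x)
        grp.create_dataset("peakYPosRaw", data=y)
        grp.create_dataset("peakTotalIntensity", data=intensity)
        grp.create_dataset("peakSNR", data=snr)
        grp.create_dataset("peakSigma", data=sig)
        grp.create_dataset("peakNPixels", data=npix)
        grp.create_dataset("peakApexX", data=apex_x)
        grp.create_dataset("peakApexY", data=apex_y)


def read_cxi(path) -> list[PeakList]:
    """Read a CXI peak-list file written by :func:`write_cxi`."""
    with h5py.File(path, "r") as h5:
        grp = h5.get(_CXI_GROUP)
        if grp is None:
            raise ValueError(f"malformed CXI file: missing group {_CXI_GROUP!r}")
        npeaks = grp["nPeaks"][()]
        fid = grp["frame_id"][()]
        x = grp["peakXPosRaw"][()]
        y = grp["peakYPosRaw"][()]
        intensity = grp["peakTotalIntensity"][()]
        sig = grp["peakSigma"][()]
        npix = grp["peakNPixels"][()]
        apex_x = grp["peakApexX"][()]
        apex_y = grp["peakApexY"][()]

    lists = []
    for i in range(npeaks.size):
        peaks = [
            Peak(
                centroid_row=float(y[i, j]),
                centroid_col=float(x[i, j]),
                total_intensity=float(intensity[i, j]),
                sigma=float(sig[i, j]),
                n_pixels=int(npix[i, j]),
                apex_row=int(apex_y[i, j]),
                apex_col=int(apex_x[i, j]),
            )
            for j in range(int(npeaks[i]))
        ]
        lists.append(PeakList(frame_id=int(fid[i]), peaks=peaks))
    return lists
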