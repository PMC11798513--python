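"""Seeded generator of synthetic diffraction frames with ground truth.

The generator emulates the data regime the separation stack is built for: a
smooth, isotropic radial background (a constant plus broad radial Gaussians,
in ADU with one ADU per photon), Poisson counting noise, sparse 2D-Gaussian
Bragg peaks whose apex amplitude is expressed in units of the local
background noise sqrt(B(r)), and masked gaps (a random salt of defective
pixels plus an optional dead-row strip).  Every random choice flows from a
single :class:`numpy.random.Generator` seed, so generation is
bit-reproducible, and the exact injected background and peak table are
returned as ground truth for parameter-recovery tests.

It deliberately does *not* model structure factors, mosaicity, detector
gain stages or anisotropic backgrounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .geometry import DetectorGeometry, build_radius_map

__all__ = [
    "RadialBackground",
    "SimulationSpec",
    "TruePeak",
    "SyntheticStack",
    "default_background",
    "generate",
    "write_dense_stack",
    "read_dense_stack",
    "write_truth_manifest",
]


@dataclass(frozen=True)
class RadialBackground:
    """Isotropic background B(r) = constant + sum of radial Gaussians.

    ``gaussians`` is a tuple of (amplitude ADU, center, width) triples in
    radius units.  Must be non-negative everywhere (amplitudes >= 0).
    """

    constant: float = 50.0
    gaussians: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.constant < 0 or any(a < 0 or s <= 0 for a, _, s in self.gaussians):
            raise ValueError("background must be non-negative with positive widths")

    def __call__(self, r):
        r = np.asarray(r, dtype=np.float64)
        out = np.full(r.shape, self.constant)
        for amp, center, width in self.gaussians:
            out += amp * np.exp(-0.5 * ((r - center) / width) ** 2)
        return out


def default_background(r_max: float) -> RadialBackground:
    """Smooth two-lobe background scaled to a detector of outer radius r_max.

    A bright forward-scattering lobe plus a broad diffuse ring at ~0.55 r_max
    over a constant floor -- the shape of a typical amorphous scattering
    curve, with amplitudes large enough that Poisson noise is a few ADU.
    """
    return RadialBackground(
        constant=50.0,
        gaussians=((150.0, 0.0, 0.45 * r_max), (60.0, 0.55 * r_max, 0.12 * r_max)),
    )


@dataclass
class SimulationSpec:
    """Conditions of one synthetic acquisition.

    ``peak_snr_range`` bounds the apex amplitude in units of the local
    background noise; peaks are kept ``min_separation`` pixels apart and
    ``border_margin`` pixels away from edges and masked pixels.
    """

    geometry: DetectorGeometry
    background: RadialBackground | None = None
    n_frames: int = 1
    n_peaks: int = 50
    peak_sigma_px: float = 1.2
    peak_snr_range: tuple[float, float] = (10.0, 30.0)
    mask_fraction: float = 0.002
    gap_rows: tuple[int, int] | None = None
    min_separation: float = 16.0
    border_margin: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_peaks < 0:
            raise ValueError("n_frames must be >= 1 and n_peaks >= 0")
        if self.peak_sigma_px <= 0:
            raise ValueError("peak_sigma_px must be positive")
        lo, hi = self.peak_snr_range
        if lo <= 0 or hi < lo:
            raise ValueError("peak_snr_range must be 0 < lo <= hi")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TruePeak:
    """Ground truth of one injected peak."""

    row: float
    col: float
    amplitude: float  # apex amplitude in ADU
    snr: float  # apex amplitude / sqrt(local background)
    sigma_px: float


@dataclass
class SyntheticStack:
    """Generated frames plus everything needed to score a recovery run."""

    frames: np.ndarray  # (n_frames, n_rows, n_cols) float64 counts
    mask: np.ndarray  # (n_rows, n_cols) bool, shared by all frames
    background_map: np.ndarray  # noiseless analytic background per pixel
    background: RadialBackground
    peaks: list[list[TruePeak]]  # per frame
    spec: SimulationSpec = field(repr=False)

    def background_at(self, r):
        """Analytic background level at radius r (e.g. at bin centers)."""
        return self.background(r)


def _build_mask(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(spec.geometry.shape, dtype=bool)
    if spec.mask_fraction > 0:
        mask |= rng.random(mask.shape) < spec.mask_fraction
    if spec.gap_rows is not None:
        lo, hi = spec.gap_rows
        mask[lo:hi, :] = True
    return mask


def _place_peaks(spec: SimulationSpec, mask: np.ndarray, rng: np.random.Generator):
    """Rejection-sample peak centers respecting spacing, borders and mask."""
    n_rows, n_cols = spec.geometry.shape
    m = spec.border_margin
    placed: list[tuple[float, float]] = []
    tries = 0
    max_tries = 200 * max(spec.n_peaks, 1)
    while len(placed) < spec.n_peaks:
        if tries >= max_tries:
            raise ValueError(
                "could not place peaks under the spacing constraints; "
                "reduce n_peaks or min_separation"
            )
        tries += 1
        row = rng.uniform(m, n_rows - 1 - m)
        col = rng.uniform(m, n_cols - 1 - m)
        if any(np.hypot(row - r, col - c) < spec.min_separation for r, c in placed):
            continue
        ri, ci = int(round(row)), int(round(col))
        r0, r1 = max(ri - 2, 0), min(ri + 3, n_rows)
        c0, c1 = max(ci - 2, 0), min(ci + 3, n_cols)
        if mask[r0:r1, c0:c1].any():
            continue
        placed.append((row, col))
    return placed


def generate(spec: SimulationSpec) -> SyntheticStack:
    """Generate a frame stack according to ``spec``.

    Each frame is an independent Poisson draw of the analytic background
    plus that frame's injected Gaussian peaks; peak placements are redrawn
    per frame.
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    radius = build_radius_map(geom)
    background = spec.background
    if background is None:
        background = default_background(float(radius.max()))
    background_map = background(radius)
    if np.any(background_map < 0):
        raise ValueError("background must be non-negative everywhere")
    mask = _build_mask(spec, rng)

    n_rows, n_cols = geom.shape
    frames = np.empty((spec.n_frames, n_rows, n_cols))
    all_peaks: list[list[TruePeak]] = []
    for k in range(spec.n_frames):
        lam = background_map.copy()
        truths: list[TruePeak] = []
        for row, col in _place_peaks(spec, mask, rng):
            snr = rng.uniform(*spec.peak_snr_range)
            local_bg = background(float(np.hypot(row - geom.beam_center_row,
                                                 col - geom.beam_center_col)
                                        * geom.pixel_size))
            amp = snr * np.sqrt(local_bg)
            s = spec.peak_sigma_px
            w = int(np.ceil(4 * s))
            r0, r1 = max(int(row) - w, 0), min(int(row) + w + 1, n_rows)
            c0, c1 = max(int(col) - w, 0), min(int(col) + w + 1, n_cols)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            lam[r0:r1, c0:c1] += amp * np.exp(
                -0.5 * (((rr - row) ** 2 + (cc - col) ** 2) / s**2)
            )
            truths.append(
                TruePeak(row=row, col=col, amplitude=float(amp),
                         snr=float(snr), sigma_px=s)
            )
        frames[k] = rng.poisson(lam)
        all_peaks.append(truths)

    return SyntheticStack(
        frames=frames,
        mask=mask,
        background_map=background_map,
        background=background,
        peaks=all_peaks,
        spec=spec,
    )


def write_dense_stack(path, frames: np.ndarray, mask: np.ndarray | None = None) -> None:
    """Write a dense frame stack to HDF5 (``/entry/data/data`` + optional
    ``/entry/mask``)."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    with h5py.File(path, "w") as h5:
        entry = h5.create_group("entry")
        entry.attrs["NX_class"] = "NXentry"
        data = entry.create_group("data")
        data.attrs["NX_class"] = "NXdata"
        data.create_dataset("data", data=frames.astype(np.float32))
        if mask is not None:
            entry.create_dataset("mask", data=np.asarray(mask).astype(np.uint8))


def read_dense_stack(path):
    """Read a dense stack written by :func:`write_dense_stack`.

    Returns ``(frames, mask_or_None)``.
    """
    with h5py.File(path, "r") as h5:
        data = h5.get("entry/data/data")
        if data is None:
            raise ValueError("malformed dense stack: missing dataset 'entry/data/data'")
        frames = data[()].astype(np.float64)
        mask = h5.get("entry/mask")
        mask = mask[()].astype(bool) if mask is not None else None
    return frames, mask


def write_truth_manifest(path, stack: SyntheticStack) -> None:
    """Write the ground-truth peak table and background parameters as JSON."""
    doc = {
        "background": {
            "constant": stack.background.constant,
            "gaussians": [list(g) for g in stack.background.gaussians],
        },
        "n_frames": int(stack.frames.shape[0]),
        "peaks": [
            [
                {"row": p.row, "col": p.col, "amplitude": p.amplitude,
                 "snr": p.snr, "sigma_px": p.sigma_px}
                for p in frame_peaks
            ]
            for frame_peaks in stack.peaks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
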