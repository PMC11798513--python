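"""Detector geometry and radial binning.

The whole signal-separation stack works on rings of constant distance to the
beam center (Debye-Scherrer rings).  This module builds the per-pixel radius
map and the sparse pixel->bin assignment that every azimuthal statistic
consumes.  Pixels are never split between bins: each unmasked, in-range pixel
contributes to exactly one radial bin with coefficient 1, which keeps the
mapping a plain integer lookup instead of a sparse matrix with fractional
areas (fractional-area splitting blurs the signal and is deliberately not
supported).

Conventions (fixed once, since detector literature varies):

* pixel coordinates are 0-based and a pixel's *center* sits at integer
  ``(row, col)``;
* radial bins are half-open ``[lo, hi)`` with the last bin closed;
* masked or out-of-range pixels carry the sentinel bin index ``MASKED_BIN``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MASKED_BIN",
    "DetectorGeometry",
    "BinAssignment",
    "build_radius_map",
    "build_bin_assignment",
    "radius_to_twotheta",
    "radius_to_q",
    "load_geometry",
]

#: Sentinel bin index for masked / out-of-range pixels.
MASKED_BIN = -1


@dataclass(frozen=True)
class DetectorGeometry:
    """Fixed experimental geometry of a flat, orthogonal detector.

    Parameters
    ----------
    n_rows, n_cols
        Detector size in pixels.
    beam_center_row, beam_center_col
        Direct-beam position in fractional pixel coordinates.  It may lie
        outside the frame (common for off-centered detectors).
    pixel_size
        Pixel pitch in metres.  Use 1.0 to work in pixel units.
    sample_detector_distance
        Optional sample-detector distance in metres, only needed for the
        2theta / q conversion helpers.
    wavelength
        Optional wavelength in Angstrom, only needed for q conversion.
    """

    n_rows: int
    n_cols: int
    beam_center_row: float
    beam_center_col: float
    pixel_size: float = 1.0
    sample_detector_distance: float | None = None
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one row and one column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def build_radius_map(geometry: DetectorGeometry) -> np.ndarray:
    """Distance of every pixel center from the beam center.

    Returns an ``(n_rows, n_cols)`` float64 array in the units of
    ``pixel_size`` (metres, or pixels when ``pixel_size == 1``).
    """
    rows = (np.arange(geometry.n_rows, dtype=np.float64) - geometry.beam_center_row)
    cols = (np.arange(geometry.n_cols, dtype=np.float64) - geometry.beam_center_col)
    r = np.hypot(rows[:, None], cols[None, :])
    r *= geometry.pixel_size
    return r


def radius_to_twotheta(radius, geometry: DetectorGeometry):
    """Scattering angle 2theta (rad) for a radius on the detector face."""
    if geometry.sample_detector_distance is None:
        raise ValueError("sample_detector_distance is required for 2theta conversion")
    return np.arctan2(radius, geometry.sample_detector_distance)


def radius_to_q(radius, geometry: DetectorGeometry):
    """Scattering-vector modulus q = 4*pi*sin(theta)/lambda in 1/Angstrom."""
    if geometry.wavelength is None:
        raise ValueError("wavelength is required for q conversion")
    tth = radius_to_twotheta(radius, geometry)
    return 4.0 * np.pi * np.sin(0.5 * tth) / geometry.wavelength


@dataclass(frozen=True)
class BinAssignment:
    """Sparse pixel -> radial-bin mapping.

    ``pixel_bin`` holds, for every pixel, the index of the single bin it
    contributes to (or :data:`MASKED_BIN`).  ``coefficients`` are the
    contribution fractions c_i; without pixel splitting they are 1.0 for
    every assigned pixel and 0.0 for sentinel pixels.
    """

    n_bins: int
    bin_edges: np.ndarray  # (n_bins + 1,), strictly increasing
    pixel_bin: np.ndarray  # (n_rows, n_cols) int32, MASKED_BIN sentinel
    coefficients: np.ndarray  # (n_rows, n_cols) float64 in {0} U (0, 1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_bin.shape

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_counts(self) -> np.ndarray:
        """Number of assigned pixels per bin."""
        valid = self.pixel_bin >= 0
        return np.bincount(self.pixel_bin[valid], minlength=self.n_bins)


def build_bin_assignment(
    radius_map: np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = 500,
) -> BinAssignment:
    """Assign every unmasked pixel to one of ``n_bins`` equal-width radial bins.

    Bins span ``[0, max radius over unmasked pixels]``; intervals are
    half-open with the last bin closed, so the outermost pixel lands in the
    last bin rather than falling off the histogram.

    Raises
    ------
    ValueError
        If ``n_bins < 1``, shapes disagree, or every pixel is masked.
    """
    radius_map = np.asarray(radius_map, dtype=np.float64)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mask is None:
        mask = np.zeros(radius_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != radius_map.shape:
        raise ValueError("mask shape does not match radius map")
    valid = ~mask
    if not valid.any():
        raise ValueError("all pixels are masked; cannot build a bin assignment")

    rmax = float(radius_map[valid].max())
    if rmax <= 0.0:
        # Degenerate single-point geometry: one bin of unit width.
        rmax = 1.0
    edges = np.linspace(0.0, rmax, n_bins + 1)
    width = rmax / n_bins

    idx = np.floor_divide(radius_map, width).astype(np.int32)
    np.clip(idx, 0, n_bins - 1, out=idx)  # closes the last bin
    pixel_bin = np.where(valid, idx, np.int32(MASKED_BIN))
    coefficients = np.where(valid, 1.0, 0.0)
    return BinAssignment(
        n_bins=n_bins,
        bin_edges=edges,
        pixel_bin=pixel_bin,
        coefficients=coefficients,
    )


def load_geometry(path: str | Path) -> DetectorGeometry:
    """Read a :class:`DetectorGeometry` from a JSON, TOML or YAML config file.

    The file must contain the field names of :class:`DetectorGeometry` at the
    top level (unknown keys are rejected to catch typos).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yml", ".yaml"}:
        import yaml

        data = yaml.safe_load(text)
    elif path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    allowed = set(DetectorGeometry.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown geometry fields: {sorted(unknown)}")
    return DetectorGeometry(**data)
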