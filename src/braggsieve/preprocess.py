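"""Pixel-wise corrections: dark subtraction and normalization.

The corrected intensity of a pixel is ``(I_raw - I_dark) / (F * O * P * A * I0)``
with F the flat field, O the solid angle, P the polarization factor, A the
apparent detector efficiency and I0 the incoming flux.  Downstream statistics
never form that quotient eagerly: they carry the numerator (``signal``) and
denominator (``norm``) separately so that ring averages can be computed as
"summed signal over summed normalization" with full control of the weights.

Two detector noise models are supported:

* ``"poisson"`` -- counting statistics, sigma_i^2 = max(signal_i, floor),
  optionally plus a per-pixel dark-noise variance added in quadrature;
* ``"fixed"`` -- a user-supplied per-pixel variance map, for detectors whose
  noise is not Poissonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry, build_radius_map, radius_to_twotheta

__all__ = [
    "CorrectionSet",
    "PreprocessedFrame",
    "preprocess",
    "solid_angle_map",
    "polarization_map",
]

NOISE_MODELS = ("poisson", "fixed")


@dataclass
class CorrectionSet:
    """Per-pixel correction arrays; any component may be omitted.

    Omitted normalization terms count as 1, an omitted dark as 0.
    ``dark_variance`` is the per-pixel variance of the dark signal, added in
    quadrature to the Poisson term under the ``"poisson"`` noise model.
    """

    dark: np.ndarray | None = None
    flat: np.ndarray | None = None
    solid_angle: np.ndarray | None = None
    polarization: np.ndarray | None = None
    efficiency: np.ndarray | None = None
    dark_variance: np.ndarray | None = None
    flux: float = 1.0

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValueError("flux must be positive")


@dataclass
class PreprocessedFrame:
    """Signal/normalization decomposition of one detector frame.

    ``signal`` is raw minus dark (ADU), ``norm`` the product of all
    normalization corrections times the flux, ``variance`` the per-pixel
    variance of ``signal`` under the chosen noise model.  ``intensity``
    (signal/norm) is the corrected pixel value used everywhere downstream.
    """

    signal: np.ndarray
    norm: np.ndarray
    variance: np.ndarray
    mask: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.signal.shape

    @property
    def intensity(self) -> np.ndarray:
        """Corrected intensity signal/norm; masked pixels are NaN."""
        out = np.full(self.signal.shape, np.nan)
        valid = ~self.mask
        np.divide(self.signal, self.norm, out=out, where=valid)
        return out


def _as_array(arr, shape, name) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != shape:
        raise ValueError(f"{name} shape {arr.shape} does not match frame {shape}")
    return arr


def preprocess(
    raw: np.ndarray,
    corrections: CorrectionSet | None = None,
    mask: np.ndarray | None = None,
    noise_model: str = "poisson",
    variance_floor: float = 1.0,
    variance_map: np.ndarray | None = None,
) -> PreprocessedFrame:
    """Apply dark subtraction and normalization corrections to a raw frame.

    Parameters
    ----------
    raw
        Raw detector frame (ADU).
    corrections
        Optional :class:`CorrectionSet`; ``None`` means identity corrections.
    mask
        Boolean array, ``True`` for pixels to exclude from all statistics.
    noise_model
        ``"poisson"`` or ``"fixed"`` (see module docstring).
    variance_floor
        Lower bound (ADU^2) of the Poisson variance so that empty pixels keep
        a nonzero uncertainty.
    variance_map
        Required per-pixel variance array for the ``"fixed"`` model.

    Raises
    ------
    ValueError
        On shape mismatch, a non-positive normalization on an unmasked pixel,
        or a missing variance map for the fixed model.
    """
    raw = np.asarray(raw, dtype=np.float64)
    shape = raw.shape
    if corrections is None:
        corrections = CorrectionSet()
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
    mask = _as_array(mask, shape, "mask").astype(bool)
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise_model!r}; choose from {NOISE_MODELS}")

    if corrections.dark is not None:
        signal = raw - _as_array(corrections.dark, shape, "dark")
    else:
        signal = raw.copy()

    norm = np.full(shape, float(corrections.flux))
    for name in ("flat", "solid_angle", "polarization", "efficiency"):
        comp = getattr(corrections, name)
        if comp is not None:
            norm *= _as_array(comp, shape, name)
    if np.any(norm[~mask] <= 0):
        raise ValueError("normalization is non-positive on an unmasked pixel")

    if noise_model == "poisson":
        variance = np.maximum(signal, variance_floor)
        if corrections.dark_variance is not None:
            variance = variance + _as_array(corrections.dark_variance, shape, "dark_variance")
    else:
        if variance_map is None:
            raise ValueError("variance_map is required for the fixed noise model")
        variance = _as_array(variance_map, shape, "variance_map")
    if np.any(variance[~mask] < 0):
        raise ValueError("variance must be non-negative on unmasked pixels")

    return PreprocessedFrame(signal=signal, norm=norm, variance=variance, mask=mask)


def solid_angle_map(geometry: DetectorGeometry) -> np.ndarray:
    """Relative solid angle of each pixel, cos^3(2theta) flat-detector form.

    Convenience helper: beamlines normally supply a calibrated array; this
    textbook approximation (pixel area fixed, distance and obliquity growing
    with radius) is good enough for synthetic studies.
    """
    r = build_radius_map(geometry)
    tth = radius_to_twotheta(r, geometry)
    return np.cos(tth) ** 3


def polarization_map(geometry: DetectorGeometry, polarization_factor: float = 0.99) -> np.ndarray:
    """Polarization correction P = 1 - pf * (sin(2theta) * cos(phi))^2.

    Convenience helper for a horizontally polarized beam (phi measured from
    the horizontal detector axis); supply a calibrated array for real data.
    """
    rows = np.arange(geometry.n_rows, dtype=np.float64) - geometry.beam_center_row
    cols = np.arange(geometry.n_cols, dtype=np.float64) - geometry.beam_center_col
    phi = np.arctan2(rows[:, None], cols[None, :])
    r = build_radius_map(geometry)
    tth = radius_to_twotheta(r, geometry)
    return 1.0 - polarization_factor * (np.sin(tth) * np.cos(phi)) ** 2
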