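"""Weighted azimuthal statistics with mergeable single-pass accumulators.

Every radial bin pools the corrected intensities v_i = signal_i / norm_i of
its pixels with weights omega_i = c_i * norm_i.  The bin is summarized by
four sums,

    Omega  = sum omega_i           (sum of weights)
    Omega2 = sum omega_i^2
    V      = sum omega_i * v_i     (= sum c_i * signal_i)
    VV     = sum omega_i * (v_i - V/Omega)^2

from which the weighted mean is ``V/Omega`` and the weighted population
variance ``VV/Omega``.  The sums can be formed in one streaming pass
(:func:`accumulate`) and partial sums over disjoint pixel subsets can be
combined exactly (:func:`merge`), which is what makes block-parallel
reductions possible.  :func:`profile_from_frame` is the vectorized whole-frame
path.

Three error models are offered for the per-bin uncertainty:

``"azimuthal"``
    The spread of intensities along the ring: std^2 = VV/Omega and
    sem^2 = VV * Omega2 / Omega^3.  For unit weights these reduce exactly to
    the population standard deviation and std/sqrt(N).
``"poisson"``
    Propagation of the per-pixel counting variances:
    sem^2 = sum c_i^2 sigma_i^2 / Omega^2 and std = sem * sqrt(N_eff) with
    the Kish effective sample size N_eff = Omega^2 / Omega2.
``"hybrid"``
    Poisson propagation with the ring-mean-based rate lambda_i =
    max(mean_r * norm_i, floor); this is the reporting model used after the
    ensemble has been trimmed to its background mode by sigma clipping.

Why two pixel-level error models at all: for a two-pixel ring {1, 199} the
mean is 100; Poisson statistics put each pixel ~10 sigma away (sqrt(100)=10)
whereas the observed ring spread puts each at exactly 1 sigma (std=99).
Clipping with Poisson errors would therefore empty every ring that carries a
strong Bragg peak on a weak background; clipping must use the azimuthal
spread.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import BinAssignment
from .preprocess import PreprocessedFrame

__all__ = [
    "ERROR_MODELS",
    "WeightedAccumulator",
    "RadialProfile",
    "accumulate",
    "merge",
    "profile_from_frame",
]

ERROR_MODELS = ("poisson", "azimuthal", "hybrid")


@dataclass(frozen=True)
class WeightedAccumulator:
    """Partial weighted statistics (Omega, Omega2, V, VV) of one bin.

    The all-zero accumulator is the identity element of :func:`merge`.
    All arithmetic is double precision.
    """

    omega: float = 0.0
    omega2: float = 0.0
    V: float = 0.0
    VV: float = 0.0
    count: int = 0

    @property
    def mean(self) -> float:
        if self.count == 0:
            raise ValueError("mean of an empty accumulator")
        return self.V / self.omega

    @property
    def variance(self) -> float:
        """Weighted population variance VV/Omega."""
        if self.count == 0:
            raise ValueError("variance of an empty accumulator")
        return max(self.VV, 0.0) / self.omega

    @classmethod
    def from_values(cls, values, weights=None) -> "WeightedAccumulator":
        """Build an accumulator from arrays in one vectorized two-pass sweep."""
        v = np.asarray(values, dtype=np.float64).ravel()
        w = (
            np.ones_like(v)
            if weights is None
            else np.asarray(weights, dtype=np.float64).ravel()
        )
        if v.size == 0:
            return cls()
        omega = float(w.sum())
        mean = float((w * v).sum() / omega)
        return cls(
            omega=omega,
            omega2=float((w * w).sum()),
            V=float((w * v).sum()),
            VV=float((w * (v - mean) ** 2).sum()),
            count=int(v.size),
        )


def accumulate(acc: WeightedAccumulator, v: float, omega: float) -> WeightedAccumulator:
    """Streaming update of an accumulator with one weighted intensity.

    Uses the incremental recurrence
    ``VV += omega * (v - mean_old) * (v - mean_new)``, which is exact in
    exact arithmetic and numerically well behaved; the first element leaves
    VV at zero.
    """
    if omega <= 0:
        raise ValueError("weight must be positive")
    if acc.count == 0:
        return WeightedAccumulator(
            omega=omega, omega2=omega * omega, V=omega * v, VV=0.0, count=1
        )
    mean_old = acc.V / acc.omega
    new_omega = acc.omega + omega
    new_V = acc.V + omega * v
    mean_new = new_V / new_omega
    new_VV = acc.VV + omega * (v - mean_old) * (v - mean_new)
    return WeightedAccumulator(
        omega=new_omega,
        omega2=acc.omega2 + omega * omega,
        V=new_V,
        VV=new_VV,
        count=acc.count + 1,
    )


def merge(a: WeightedAccumulator, b: WeightedAccumulator) -> WeightedAccumulator:
    """Exact union of two partial accumulators over disjoint pixel sets.

    ``VV_AB = VV_A + VV_B + Omega_A*Omega_B/Omega_AB * (mean_A - mean_B)^2``.
    The cross term is evaluated from the two means rather than from
    V_A/V_B differences directly, which avoids the cancellation that makes
    the naive form unstable when V_A or V_B is very small; everything is kept
    in double precision.
    """
    if a.count == 0:
        return replace(b)
    if b.count == 0:
        return replace(a)
    omega = a.omega + b.omega
    delta = a.V / a.omega - b.V / b.omega
    vv = a.VV + b.VV + (a.omega * b.omega / omega) * delta * delta
    return WeightedAccumulator(
        omega=omega,
        omega2=a.omega2 + b.omega2,
        V=a.V + b.V,
        VV=vv,
        count=a.count + b.count,
    )


@dataclass
class RadialProfile:
    """Per-bin radius, weighted mean, pixel-level std, sem and retained count.

    Bins that received no pixel are flagged invalid (``valid`` False, NaN
    statistics) instead of being zero-filled: a silent zero background would
    corrupt every consumer downstream.
    """

    bin_radius: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    sem: np.ndarray
    count: np.ndarray
    error_model: str
    valid: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_radius.size

    def to_text(self, path) -> None:
        """Write the profile as 3-column text (radius, mean, std)."""
        np.savetxt(
            path,
            np.column_stack([self.bin_radius, self.mean, self.std]),
            header="radius mean std",
        )


def _bin_sums(frame: PreprocessedFrame, bins: BinAssignment, select: np.ndarray):
    """Raw per-bin sums (Omega, Omega2, V, VV, count) over selected pixels."""
    b = bins.pixel_bin[select]
    c = bins.coefficients[select]
    norm = frame.norm[select]
    v = frame.signal[select] / norm
    w = c * norm
    n = bins.n_bins
    omega = np.bincount(b, weights=w, minlength=n)
    omega2 = np.bincount(b, weights=w * w, minlength=n)
    V = np.bincount(b, weights=w * v, minlength=n)
    count = np.bincount(b, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = V / omega
    dev = v - mean[b]
    VV = np.bincount(b, weights=w * dev * dev, minlength=n)
    return omega, omega2, V, VV, count, mean, b, c, v


def profile_from_frame(
    frame: PreprocessedFrame,
    bins: BinAssignment,
    error_model: str = "azimuthal",
    inlier_mask: np.ndarray | None = None,
    variance_floor: float = 1.0,
) -> RadialProfile:
    """Weighted azimuthal mean and uncertainties of one frame.

    Parameters
    ----------
    frame
        Preprocessed frame (signal/norm/variance/mask).
    bins
        Pixel->bin assignment matching the frame shape.
    error_model
        One of :data:`ERROR_MODELS`; see module docstring.
    inlier_mask
        Optional boolean array restricting the statistics to a pixel subset
        (used by sigma clipping); ``None`` keeps all unmasked pixels.
    variance_floor
        Floor (ADU^2) of the mean-based rate under the hybrid model.
    """
    if error_model not in ERROR_MODELS:
        raise ValueError(f"unknown error model {error_model!r}; choose from {ERROR_MODELS}")
    if bins.shape != frame.shape:
        raise ValueError("bin assignment shape does not match frame")
    select = (bins.pixel_bin >= 0) & ~frame.mask
    if inlier_mask is not None:
        select = select & inlier_mask

    n = bins.n_bins
    if not select.any():
        nan = np.full(n, np.nan)
        return RadialProfile(
            bin_radius=bins.bin_centers,
            mean=nan.copy(),
            std=nan.copy(),
            sem=nan.copy(),
            count=np.zeros(n, dtype=np.int64),
            error_model=error_model,
            valid=np.zeros(n, dtype=bool),
        )

    omega, omega2, V, VV, count, mean, b, c, v = _bin_sums(frame, bins, select)
    ok = count > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        if error_model == "azimuthal":
            std = np.sqrt(np.maximum(VV, 0.0) / omega)
            sem = np.sqrt(np.maximum(VV, 0.0) * omega2 / omega**3)
        else:
            if error_model == "poisson":
                sigma2 = frame.variance[select]
            else:  # hybrid: mean-based Poisson rate on the (trimmed) ensemble
                norm = frame.norm[select]
                sigma2 = np.maximum(mean[b] * norm, variance_floor)
            sem2 = np.bincount(b, weights=c * c * sigma2, minlength=n) / omega**2
            n_eff = omega**2 / omega2
            sem = np.sqrt(sem2)
            std = sem * np.sqrt(n_eff)

    mean = np.where(ok, mean, np.nan)
    std = np.where(ok, std, np.nan)
    sem = np.where(ok, sem, np.nan)
    return RadialProfile(
        bin_radius=bins.bin_centers,
        mean=mean,
        std=std,
        sem=sem,
        count=count.astype(np.int64),
        error_model=error_model,
        valid=ok,
    )
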