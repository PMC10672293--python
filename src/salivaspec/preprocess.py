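"""Spectral preprocessing: fingerprint truncation, Savitzky-Golay second
derivative, unit-vector normalisation, training-mean centring.

The chain runs in a fixed order on replicate-averaged raw absorbance::

    truncate_region -> sg_derivative -> vector_normalise -> centring

The second derivative (9-point window, 2nd-order polynomial) removes
baseline offsets and linear drifts while smoothing noise; vector
normalisation removes multiplicative effects (sample thickness, scatter,
concentration); mean-centring statistics are learned on training rows only
and applied to held-out rows, so external validation stays blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "CentreModel",
    "truncate_region",
    "sg_derivative",
    "vector_normalise",
    "fit_centre",
    "apply_centre",
    "preprocess",
]

#: fingerprint region analysed throughout, cm^-1
FINGERPRINT = (900.0, 1800.0)


@dataclass(frozen=True)
class PreprocessConfig:
    region: tuple[float, float] = FINGERPRINT
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 2
    norm: str = "unit_vector"
    centre: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must not exceed sg_polyorder")
        if self.norm != "unit_vector":
            raise ValueError(f"unknown normalisation {self.norm!r}")
        if self.region[0] >= self.region[1]:
            raise ValueError("region must be (low, high) with low < high")


def truncate_region(
    ds: SpectralDataset, region: tuple[float, float] = FINGERPRINT
) -> SpectralDataset:
    """Retain axis points inside the closed interval ``region`` (cm^-1)."""
    lo, hi = min(region), max(region)
    mask = (ds.axis.values >= lo) & (ds.axis.values <= hi)
    if mask.sum() < 2:
        raise ValueError(f"region {region} retains fewer than two axis points")
    axis = WavenumberAxis(ds.axis.values[mask])
    return ds.with_intensities(ds.intensities[:, mask], axis=axis)


def sg_derivative(
    ds: SpectralDataset, window: int = 9, polyorder: int = 2, deriv: int = 2
) -> SpectralDataset:
    """Savitzky-Golay smoothed derivative along the wavenumber axis.

    Each row is convolved with the least-squares local-polynomial derivative
    filter.  The derivative is taken with respect to wavenumber (scaled by
    the grid spacing), so for ``deriv=2`` the output carries units of
    absorbance * cm^2.  The
    ``(window - 1) / 2`` points at each edge, where the window is
    incomplete, are dropped rather than extrapolated.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    if ds.n_points < window:
        raise ValueError("fewer axis points than the filter window")
    spacing = ds.axis.values[1] - ds.axis.values[0]  # negative: axis descends
    out = savgol_filter(
        ds.intensities, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=spacing, axis=1,
    )
    half = (window - 1) // 2
    sl = slice(half, ds.n_points - half)
    axis = WavenumberAxis(ds.axis.values[sl])
    return ds.with_intensities(out[:, sl], axis=axis)


def vector_normalise(ds: SpectralDataset) -> SpectralDataset:
    """Scale each row to unit Euclidean norm over the retained region."""
    norms = np.linalg.norm(ds.intensities, axis=1)
    if np.any(norms == 0):
        raise ValueError("cannot vector-normalise an all-zero spectrum")
    return ds.with_intensities(ds.intensities / norms[:, None])


@dataclass(frozen=True)
class CentreModel:
    """Column means learned from training rows only."""

    axis: WavenumberAxis
    mean_spectrum: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.mean_spectrum).shape != (self.axis.n_points,):
            raise ValueError("mean_spectrum length must match the axis")


def fit_centre(ds: SpectralDataset) -> CentreModel:
    if ds.n_rows < 1:
        raise ValueError("need at least one training row to fit the centre")
    return CentreModel(ds.axis, ds.intensities.mean(axis=0))


def apply_centre(model: CentreModel, ds: SpectralDataset) -> SpectralDataset:
    if model.axis != ds.axis:
        raise ValueError("centre model and dataset axes differ")
    return ds.with_intensities(ds.intensities - model.mean_spectrum)


def preprocess(
    ds: SpectralDataset, config: PreprocessConfig = PreprocessConfig()
) -> SpectralDataset:
    """Run truncate -> SG derivative -> vector normalisation once.

    Centring is deliberately excluded: its statistics must come from the
    training split (see :func:`fit_centre` / :func:`apply_centre`).  The
    chain marks its output and refuses to run twice — a second pass would
    differentiate an already-differentiated spectrum.
    """
    if ds.flags.get("preprocessed"):
        raise ValueError("dataset is already preprocessed; the chain is not idempotent")
    out = truncate_region(ds, config.region)
    out = sg_derivative(out, config.sg_window, config.sg_polyorder, config.sg_deriv)
    out = vector_normalise(out)
    out.flags["preprocessed"] = True
    return out
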