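"""Seeded two-class synthetic saliva-swab cohort generator.

The clinical spectra behind the screening study are not public, so every
downstream stage is exercised on simulated cohorts that reproduce the
*statistical structure* the analysis relies on:

* severe class imbalance (tens of cancer-positive samples against hundreds
  of controls), three replicate measurements per sample;
* class-mean differences concentrated in the fingerprint region, planted as
  signed amplitude offsets on Gaussian bands at the study's reported
  discriminating wavenumbers;
* a *narrower* positive class: within-class band-amplitude jitter is scaled
  down for positives, giving them strictly smaller total variance — the
  asymmetry that motivates quadratic (per-class covariance) discriminants;
* nuisance structure that the preprocessing chain must remove: random
  polynomial baseline drift, multiplicative gain (scatter), additive white
  noise, and an optional constant swab-background spectrum.

Band amplitudes/widths and effect sizes are not reported by the study
("small differences" only); the defaults here are calibrated once so that
the standard PCA-QDA pipeline lands in the reported performance regime, and
are documented in the methods note.  They are a stated world, not fitted
estimates of the real effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, WavenumberAxis, default_axis

__all__ = [
    "BandSpec",
    "CohortConfig",
    "default_band_library",
    "scaffold_bands",
    "rayon_swab_background",
    "simulate_cohort",
    "planted_truth",
    "lung_default_config",
    "prostate_default_config",
]


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorbance band.

    ``class_delta`` is the signed amplitude offset applied to the positive
    (cancer) class; positive delta means higher absorbance in cancer.
    """

    centre: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # absorbance units
    class_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")


# calibrated defaults for the planted discriminating bands
_MARKER_AMPLITUDE = 0.030
_MARKER_DELTA = 0.006
# width rule: bands with a same-table neighbour within 13 cm^-1 are kept
# narrow so the 9-point SG derivative can resolve them; isolated bands are
# broader.  A few hand overrides keep crowded triplets resolvable.
_WIDTH_TIGHT = 4.2
_WIDTH_ISOLATED = 5.5
_WIDTH_OVERRIDES = {
    "lung": {1480.0: 4.6, 1094.0: 5.0, 1078.0: 4.6},
    "prostate": {},
}


def _band_widths(wavenumbers: list[float], endpoint: str) -> list[float]:
    widths = []
    for w in wavenumbers:
        others = [abs(w - x) for x in wavenumbers if x != w]
        tight = others and min(others) <= 13.0
        widths.append(_WIDTH_TIGHT if tight else _WIDTH_ISOLATED)
    for i, w in enumerate(wavenumbers):
        if w in _WIDTH_OVERRIDES.get(endpoint, {}):
            widths[i] = _WIDTH_OVERRIDES[endpoint][w]
    return widths


def _band_table(endpoint: str) -> pd.DataFrame:
    if endpoint not in ("lung", "prostate"):
        raise ValueError(f"unknown endpoint {endpoint!r}; use 'lung' or 'prostate'")
    with resources.files("salivaspec.data").joinpath(f"bands_{endpoint}.csv").open() as fh:
        return pd.read_csv(fh)


def default_band_library(endpoint: str) -> list[BandSpec]:
    """Discriminating bands for one screening endpoint, plus scaffolding.

    Returns one :class:`BandSpec` per reported discriminating wavenumber of
    the chosen endpoint (delta sign following the reported absorbance
    direction: up = higher in the cancer class), followed by broad generic
    biofluid scaffolding bands (amide I ~1650, amide II ~1545, phosphate
    ~1240 and ~1086 cm^-1) that carry no class difference.
    """
    table = _band_table(endpoint)
    centres = [float(w) for w in table["wavenumber"]]
    widths = _band_widths(centres, endpoint)
    bands = [
        BandSpec(
            centre=c,
            width=w,
            amplitude=_MARKER_AMPLITUDE,
            class_delta=_MARKER_DELTA if d == "up" else -_MARKER_DELTA,
        )
        for c, w, d in zip(centres, widths, table["direction"])
    ]
    return bands + scaffold_bands()


def scaffold_bands() -> list[BandSpec]:
    """Broad class-neutral bands shared by every saliva spectrum.

    Amide I / amide II protein backbone bands, the two phosphate bands, a
    carbohydrate shoulder, and the broad O-H/N-H stretch centred ~3300
    cm^-1 that dominates raw biofluid spectra outside the fingerprint.
    """
    return [
        BandSpec(3300.0, 180.0, 0.60),
        BandSpec(2930.0, 35.0, 0.12),
        BandSpec(1650.0, 30.0, 0.55),
        BandSpec(1545.0, 28.0, 0.35),
        BandSpec(1400.0, 30.0, 0.15),
        BandSpec(1240.0, 28.0, 0.18),
        BandSpec(1086.0, 30.0, 0.20),
        BandSpec(1045.0, 28.0, 0.16),
    ]


def rayon_swab_background(axis: WavenumberAxis) -> np.ndarray:
    """Constant background of a rayon (regenerated cellulose) swab tip.

    Cellulose C-O/C-C skeletal bands near 1160, 1060 and 1020 cm^-1 plus the
    broad hydroxyl stretch; identical for every measurement, so it shifts
    class means equally and should be inert to classification.
    """
    cellulose = [
        BandSpec(3350.0, 160.0, 0.05),
        BandSpec(1160.0, 10.0, 0.02),
        BandSpec(1060.0, 12.0, 0.03),
        BandSpec(1020.0, 10.0, 0.025),
        BandSpec(895.0, 8.0, 0.01),
    ]
    return _evaluate_bands(axis.values, cellulose)


def _evaluate_bands(values: np.ndarray, bands: list[BandSpec]) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((values - b.centre) / b.width) ** 2)
    return out


@dataclass
class CohortConfig:
    """Stated world for one simulated screening cohort.

    Defaults mirror the lung-cancer cohort after outlier removal: 31
    positives vs 948 controls, three replicate spectra per sample, on the
    full 1798-point instrument axis.
    """

    n_positive: int = 31
    n_control: int = 948
    replicates_per_sample: int = 3
    bands: list[BandSpec] = field(default_factory=lambda: default_band_library("lung"))
    #: within-class band-amplitude jitter (relative SD) for controls
    jitter_sd: float = 0.10
    #: multiplier (<1) shrinking positive-class jitter — the narrower profile
    positive_variance_scale: float = 0.5
    baseline_order: int = 2
    baseline_amp: float = 0.01
    gain_sd: float = 0.02
    noise_sd: float = 0.001
    #: fixed spectrum added to every measurement; None disables
    swab_background: np.ndarray | None = None
    add_swab_background: bool = True
    seed: int = 0
    axis: WavenumberAxis = field(default_factory=default_axis)

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_control < 0:
            raise ValueError("class counts must be non-negative")
        if not (0.0 < self.positive_variance_scale <= 1.0):
            raise ValueError("positive_variance_scale must lie in (0, 1]")
        if self.noise_sd < 0 or self.gain_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least one replicate per sample")
        lo, hi = self.axis.values.min(), self.axis.values.max()
        for b in self.bands:
            if not (lo <= b.centre <= hi):
                raise ValueError(f"band centre {b.centre} outside axis range")


def lung_default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Lung-endpoint default cohort (31 positives / 948 controls)."""
    params = dict(
        n_positive=31, n_control=948, bands=default_band_library("lung"), seed=seed
    )
    params.update(overrides)
    return CohortConfig(**params)


def prostate_default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Prostate-endpoint default cohort (17 positives / 570 controls)."""
    params = dict(
        n_positive=17, n_control=570, bands=default_band_library("prostate"), seed=seed
    )
    params.update(overrides)
    return CohortConfig(**params)


def simulate_cohort(config: CohortConfig) -> SpectralDataset:
    """Draw one cohort; bit-identical for a given config (seed included).

    Each measurement is built as::

        gain * sum_i A_si * G(nu; centre_i, width_i) + baseline + swab + noise

    where the per-sample band amplitude ``A_si = amplitude_i +
    class_delta_i * 1[positive] + jitter`` is shared by that sample's
    replicates, ``gain = 1 + N(0, gain_sd)`` and the polynomial baseline are
    drawn per measurement.
    """
    rng = np.random.default_rng(config.seed)
    nu = config.axis.values
    n_points = nu.size
    reps = config.replicates_per_sample

    swab = config.swab_background
    if swab is None and config.add_swab_background:
        swab = rayon_swab_background(config.axis)
    if swab is not None and np.asarray(swab).shape != (n_points,):
        raise ValueError("swab_background length must match the axis")

    # precompute band shape matrix: n_bands x n_points
    shapes = np.stack(
        [np.exp(-0.5 * ((nu - b.centre) / b.width) ** 2) for b in config.bands]
    )
    base_amp = np.array([b.amplitude for b in config.bands])
    delta = np.array([b.class_delta for b in config.bands])

    sample_ids, labels_per_sample = [], []
    for i in range(config.n_positive):
        sample_ids.append(f"P{i:04d}")
        labels_per_sample.append("positive")
    for i in range(config.n_control):
        sample_ids.append(f"C{i:04d}")
        labels_per_sample.append("control")

    n_samples = len(sample_ids)
    rows = np.empty((n_samples * reps, n_points))
    meta_sample, meta_rep, meta_label = [], [], []
    # scale nu to [-1, 1] for a well-conditioned baseline polynomial
    nu_scaled = (nu - nu.mean()) / (np.ptp(nu) / 2 if np.ptp(nu) > 0 else 1.0)

    r = 0
    for s in range(n_samples):
        positive = labels_per_sample[s] == "positive"
        scale = config.positive_variance_scale if positive else 1.0
        amp = base_amp + (delta if positive else 0.0)
        amp = amp * (1.0 + scale * config.jitter_sd * rng.standard_normal(len(amp)))
        clean = amp @ shapes
        for rep in range(1, reps + 1):
            gain = 1.0 + config.gain_sd * rng.standard_normal()
            coeffs = config.baseline_amp * rng.standard_normal(config.baseline_order + 1)
            baseline = np.polynomial.polynomial.polyval(nu_scaled, coeffs)
            row = gain * clean + baseline
            if swab is not None:
                row = row + swab
            if config.noise_sd > 0:
                row = row + config.noise_sd * rng.standard_normal(n_points)
            rows[r] = row
            meta_sample.append(sample_ids[s])
            meta_rep.append(rep)
            meta_label.append(labels_per_sample[s])
            r += 1

    meta = pd.DataFrame(
        {
            "sample_id": meta_sample,
            "replicate_id": pd.array(meta_rep, dtype="Int64"),
            "label": meta_label,
        }
    )
    return SpectralDataset(config.axis, rows, meta)


def planted_truth(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth marker table the markers module must recover.

    One row per band with nonzero ``class_delta``: columns ``wavenumber``
    and ``direction`` (``up`` = higher absorbance in the positive class),
    sorted descending by wavenumber.
    """
    rows = [
        {"wavenumber": b.centre, "direction": "up" if b.class_delta > 0 else "down"}
        for b in config.bands
        if b.class_delta != 0.0
    ]
    out = pd.DataFrame(rows, columns=["wavenumber", "direction"])
    return out.sort_values("wavenumber", ascending=False).reset_index(drop=True)
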