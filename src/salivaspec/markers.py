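"""Spectral-marker extraction: discriminating wavenumbers from PCA loadings
and the difference-between-mean (DBM) spectrum, with direction arrows and
tentative vibrational band assignments.

Candidate markers are local maxima of the summed absolute PC loadings whose
preprocessed-domain DBM magnitude lies in the upper tail — wavenumbers that
both drive the retained variance and actually differ between classes.  The
direction call (higher/lower absorbance in the cancer class) is made on the
*raw*-domain DBM: the second derivative inverts peak signs, so derivative-
domain signs would not describe absorbance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .chemometrics import PCAModel
from .dataset import WavenumberAxis

__all__ = [
    "AssignmentLibrary",
    "load_assignments",
    "dbm_spectrum",
    "total_loading",
    "extract_markers",
    "assign_bands",
]

MARKER_COLUMNS = ["wavenumber", "direction", "loading_weight", "dbm_value", "assignment"]


@dataclass(frozen=True)
class AssignmentLibrary:
    """Wavenumber -> tentative vibrational assignment lookup."""

    endpoint: str
    entries: pd.DataFrame  # columns: wavenumber, assignment

    def __post_init__(self) -> None:
        if self.entries["wavenumber"].duplicated().any():
            raise ValueError("assignment library has duplicate wavenumbers")


def load_assignments(endpoint: str) -> AssignmentLibrary:
    """Packaged assignment library for one endpoint (lung or prostate)."""
    if endpoint not in ("lung", "prostate"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    with resources.files("salivaspec.data").joinpath(f"bands_{endpoint}.csv").open() as fh:
        table = pd.read_csv(fh)
    return AssignmentLibrary(endpoint, table[["wavenumber", "assignment"]].copy())


def dbm_spectrum(class_a_rows: np.ndarray, class_b_rows: np.ndarray) -> np.ndarray:
    """Difference between mean spectra: ``mean(a) - mean(b)``.

    Call with (positive rows, control rows) so that a positive value means
    higher intensity in the cancer class.
    """
    a = np.atleast_2d(np.asarray(class_a_rows, dtype=float))
    b = np.atleast_2d(np.asarray(class_b_rows, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("class matrices are on different axes")
    return a.mean(axis=0) - b.mean(axis=0)


def total_loading(model: PCAModel) -> np.ndarray:
    """Element-wise sum of the K retained loading vectors ('TOTAL' trace)."""
    return model.loadings.sum(axis=1)


def extract_markers(
    axis: WavenumberAxis,
    loading: np.ndarray,
    dbm_pre: np.ndarray,
    raw_axis: WavenumberAxis | None = None,
    dbm_raw: np.ndarray | None = None,
    top_quantile: float = 0.9,
    min_separation: float = 8.0,
    max_markers: int = 20,
) -> pd.DataFrame:
    """Pick discriminating wavenumbers from summed-loading-magnitude peaks.

    ``loading`` is either the full ``n_points x K`` loadings matrix — in
    which case the peak surface is the summed absolute loading
    ``sum_k |l_k|`` (the marker weight) — or an already-summed 1-D trace,
    used as ``|trace|``.  The matrix form is preferred: the signed TOTAL
    trace lets loading lobes of opposite sign cancel, which makes peak
    positions twitchy under resampling.

    Local maxima of the surface whose ``|dbm_pre|`` lies in the top
    ``1 - top_quantile`` tail are kept, thinned so no two markers are
    closer than ``min_separation`` cm^-1 (stronger peak wins), and
    capped at ``max_markers``.  The direction arrow is the sign of
    ``dbm_raw`` at the nearest raw-axis point (``up`` = higher absorbance
    in the positive class); when no raw DBM is supplied, the sign of the
    preprocessed DBM is used with inverted polarity (2nd-derivative peaks
    point down).

    Scale-invariant in both inputs: the threshold is a quantile of
    ``|dbm_pre|`` and peak locations ignore overall magnitude.
    """
    loading = np.asarray(loading, dtype=float)
    dbm_pre = np.asarray(dbm_pre, dtype=float)
    if loading.ndim == 2:
        if loading.shape[0] != axis.n_points:
            raise ValueError("loadings matrix must have one row per axis point")
        abs_total = np.abs(loading).sum(axis=1)
    elif loading.shape == (axis.n_points,):
        abs_total = np.abs(loading)
    else:
        raise ValueError("loading must be a 1-D trace or n_points x K matrix")
    if dbm_pre.shape != (axis.n_points,):
        raise ValueError("dbm_pre must live on the given axis")
    if not np.any(abs_total > 0) or not np.any(np.abs(dbm_pre) > 0):
        return pd.DataFrame(columns=MARKER_COLUMNS)

    peaks = argrelextrema(abs_total, np.greater_equal, order=1)[0]
    # drop plateau duplicates and flat-zero artefacts
    peaks = peaks[abs_total[peaks] > 0]
    threshold = np.quantile(np.abs(dbm_pre), top_quantile)
    # a marker's DBM magnitude is taken over +-2 grid points: loading and
    # DBM extrema of the same band can sit one point apart on a noisy grid
    n = dbm_pre.size
    local_dbm = np.array(
        [np.max(np.abs(dbm_pre[max(0, p - 2) : min(n, p + 3)])) for p in peaks]
    )
    peaks = peaks[local_dbm >= threshold]
    if peaks.size == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)

    # greedy thinning: strongest |total| first, enforce min separation
    order = peaks[np.argsort(abs_total[peaks])[::-1]]
    kept: list[int] = []
    for p in order:
        wn = axis.values[p]
        if all(abs(wn - axis.values[q]) >= min_separation for q in kept):
            kept.append(int(p))
        if len(kept) == max_markers:
            break

    rows = []
    for p in kept:
        wn = float(axis.values[p])
        if dbm_raw is not None:
            look_axis = raw_axis if raw_axis is not None else axis
            arr = np.asarray(dbm_raw, dtype=float)
            j = look_axis.index_of(wn)
            # read the band against its local background: centre (+-2 pts)
            # minus a surrounding annulus, so broad baseline offsets in the
            # raw DBM cannot flip the direction of a narrow band
            centre = arr[max(0, j - 2) : j + 3].mean()
            ring = np.r_[arr[max(0, j - 12) : max(0, j - 5)], arr[j + 6 : j + 13]]
            raw_val = float(centre - (ring.mean() if ring.size else 0.0))
        else:
            raw_val = -float(dbm_pre[p])
        rows.append(
            {
                "wavenumber": wn,
                "direction": "up" if raw_val > 0 else "down",
                "loading_weight": float(abs_total[p]),
                "dbm_value": float(dbm_pre[p]),
                "assignment": None,
            }
        )
    out = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return out.sort_values("wavenumber", ascending=False).reset_index(drop=True)


def assign_bands(
    table: pd.DataFrame, lib: AssignmentLibrary, tolerance: float = 4.0
) -> pd.DataFrame:
    """Attach the nearest library assignment within ``tolerance`` cm^-1.

    The default tolerance (~2 grid steps at 1.86 cm^-1 resolution) leaves
    markers with no nearby library entry unassigned.
    """
    out = table.copy()
    lib_wn = lib.entries["wavenumber"].to_numpy(dtype=float)
    lib_text = lib.entries["assignment"].to_numpy()
    assigned = []
    for wn in out["wavenumber"]:
        if lib_wn.size == 0:
            assigned.append(None)
            continue
        j = int(np.argmin(np.abs(lib_wn - wn)))
        assigned.append(lib_text[j] if abs(lib_wn[j] - wn) <= tolerance else None)
    out["assignment"] = assigned
    return out
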