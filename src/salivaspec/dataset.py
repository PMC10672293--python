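"""Spectral dataset container and CSV I/O.

A cohort of ATR-FTIR absorbance spectra lives in a :class:`SpectralDataset`:
an ``n_rows x n_points`` intensity matrix on a shared wavenumber axis, with
per-row sample/replicate/class metadata.  The axis is always stored in
descending wavenumber order (4000 -> 650 cm^-1), the orientation mid-IR
spectrometers export and plots use; readers normalise either file order to it.

Canonical on-disk form is a pair of CSV files:

* spectra: first column ``row_id``, then one numeric-header column per
  wavenumber;
* metadata: columns ``row_id, sample_id, replicate_id, label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: controlled vocabulary for class labels
LABELS = ("positive", "control", "unknown")

#: default acquisition grid: 1798 points spanning 4000 -> 650 cm^-1
DEFAULT_N_POINTS = 1798
DEFAULT_RANGE = (650.0, 4000.0)


def default_axis() -> "WavenumberAxis":
    """The full-range instrument axis: 1798 points, 4000 -> 650 cm^-1."""
    values = np.linspace(DEFAULT_RANGE[1], DEFAULT_RANGE[0], DEFAULT_N_POINTS)
    return WavenumberAxis(values)


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform, strictly descending wavenumber grid (cm^-1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two points")
        steps = np.diff(values)
        if not np.all(steps < 0):
            raise ValueError("wavenumber axis must be strictly descending")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("wavenumber axis must be uniformly spaced")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def nominal_resolution(self) -> float:
        """Absolute spacing between adjacent grid points (cm^-1)."""
        return float(abs(self.values[1] - self.values[0]))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )


@dataclass
class SpectralDataset:
    """Absorbance spectra plus per-row sample metadata.

    ``meta`` has one row per spectrum with columns ``sample_id``,
    ``replicate_id`` (nullable integer) and ``label`` (one of
    ``positive | control | unknown``).
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.axis.n_points:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} columns "
                f"but the axis has {self.axis.n_points} points"
            )
        required = {"sample_id", "replicate_id", "label"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError(
                f"metadata has {len(self.meta)} rows but intensity matrix "
                f"has {self.intensities.shape[0]}"
            )
        bad = set(self.meta["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; allowed: {LABELS}")
        # a sample must carry one label only
        per_sample = self.meta.groupby("sample_id")["label"].nunique()
        if (per_sample > 1).any():
            offender = per_sample[per_sample > 1].index[0]
            raise ValueError(f"sample {offender!r} carries conflicting labels")
        key = self.meta[["sample_id", "replicate_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (sample_id, replicate_id) pair: "
                f"({dup['sample_id']!r}, {dup['replicate_id']!r})"
            )
        self.meta = self.meta.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.n_points

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def rows_for(self, label: str) -> np.ndarray:
        """Intensity rows whose class label equals ``label``."""
        return self.intensities[self.labels == label]

    def subset(self, row_indices: np.ndarray | list) -> "SpectralDataset":
        idx = np.asarray(row_indices)
        return SpectralDataset(
            axis=self.axis,
            intensities=self.intensities[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            flags=dict(self.flags),
        )

    def subset_samples(self, sample_ids) -> "SpectralDataset":
        wanted = set(sample_ids)
        mask = self.meta["sample_id"].isin(wanted).to_numpy()
        return self.subset(np.nonzero(mask)[0])

    def with_intensities(
        self, intensities: np.ndarray, axis: WavenumberAxis | None = None
    ) -> "SpectralDataset":
        return SpectralDataset(
            axis=axis if axis is not None else self.axis,
            intensities=intensities,
            meta=self.meta.copy(),
            flags=dict(self.flags),
        )


# ----------------------------------------------------------------------
# operations


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Collapse replicate spectra to one arithmetic-mean spectrum per sample.

    Measurement replicates (three per swab in the acquisition protocol) are
    averaged on the raw absorbance scale, before any preprocessing.  Samples
    with a single replicate pass through unchanged; ``replicate_id`` is
    cleared in the result.  The output keeps samples in order of first
    appearance, so the operation is invariant to replicate row order.
    """
    order = ds.meta["sample_id"].drop_duplicates().tolist()
    groups = ds.meta.groupby("sample_id", sort=False).indices
    rows = np.empty((len(order), ds.n_points))
    labels = []
    for i, sid in enumerate(order):
        idx = groups[sid]
        block = ds.intensities[idx]
        # identical replicates pass through bit-exactly
        if len(idx) == 1 or not np.any(block != block[0]):
            rows[i] = block[0]
        else:
            rows[i] = block.mean(axis=0)
        labels.append(ds.meta["label"].iloc[idx[0]])
    meta = pd.DataFrame(
        {
            "sample_id": order,
            "replicate_id": pd.array([pd.NA] * len(order), dtype="Int64"),
            "label": labels,
        }
    )
    return SpectralDataset(ds.axis, rows, meta, flags=dict(ds.flags))


def read_dataset(spectra_path, metadata_path) -> SpectralDataset:
    """Read a spectra/metadata CSV pair into a :class:`SpectralDataset`.

    The spectra header must be numeric wavenumbers (any monotone order); the
    axis is normalised to descending with matrix columns reordered to match.
    Metadata rows are joined on ``row_id`` and must cover exactly the same
    rows as the spectra file.
    """
    spectra = pd.read_csv(spectra_path)
    if spectra.shape[1] < 2:
        raise ValueError("spectra CSV must have a row-id column plus wavenumbers")
    header = spectra.columns[1:]
    try:
        wavenumbers = header.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric wavenumber header cell: {exc}") from exc
    matrix = spectra.iloc[:, 1:].to_numpy(dtype=float)
    # normalise orientation to descending
    if wavenumbers.size >= 2 and wavenumbers[0] < wavenumbers[-1]:
        wavenumbers = wavenumbers[::-1]
        matrix = matrix[:, ::-1]
    axis = WavenumberAxis(wavenumbers)

    meta = pd.read_csv(metadata_path)
    required = {"row_id", "sample_id", "replicate_id", "label"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if len(meta) != len(spectra):
        raise ValueError(
            f"row-count mismatch: spectra file has {len(spectra)} rows, "
            f"metadata file has {len(meta)} rows"
        )
    row_ids = spectra.iloc[:, 0]
    meta = meta.set_index("row_id").reindex(row_ids)
    if meta["sample_id"].isna().any():
        raise ValueError("metadata row_id values do not match the spectra file")
    meta = meta.reset_index(drop=True)
    meta["replicate_id"] = pd.array(meta["replicate_id"], dtype="Int64")
    meta["label"] = meta["label"].map(_canonical_label)
    return SpectralDataset(axis, matrix, meta[["sample_id", "replicate_id", "label"]])


def write_dataset(ds: SpectralDataset, spectra_path, metadata_path) -> None:
    """Write the canonical wide-CSV pair; inverse of :func:`read_dataset`."""
    row_ids = [f"r{i}" for i in range(ds.n_rows)]
    spectra = pd.DataFrame(
        ds.intensities, columns=[format(float(v), ".17g") for v in ds.axis.values]
    )
    spectra.insert(0, "row_id", row_ids)
    spectra.to_csv(spectra_path, index=False)
    meta = ds.meta.copy()
    meta.insert(0, "row_id", row_ids)
    meta.to_csv(metadata_path, index=False)


_LABEL_ALIASES = {
    "positive": "positive",
    "cancer": "positive",
    "case": "positive",
    "control": "control",
    "other": "control",
    "benign": "control",
    "unknown": "unknown",
    "blind": "unknown",
}


def _canonical_label(raw) -> str:
    try:
        return _LABEL_ALIASES[str(raw).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown class label {raw!r}; expected one of {sorted(_LABEL_ALIASES)}"
        ) from None
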