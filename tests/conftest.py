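import numpy as np
import pandas as pd
import pytest

from salivaspec.dataset import SpectralDataset, WavenumberAxis, default_axis
from salivaspec.synth import BandSpec, CohortConfig


@pytest.fixture(scope="session")
def full_axis() -> WavenumberAxis:
    return default_axis()


@pytest.fixture
def small_axis() -> WavenumberAxis:
    """A short descending axis for cheap unit tests."""
    return WavenumberAxis(np.linspace(1800.0, 900.0, 100))


def make_dataset(axis, intensities, sample_ids, replicate_ids=None, labels=None):
    n = len(sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "replicate_id": pd.array(
                replicate_ids if replicate_ids is not None else [pd.NA] * n,
                dtype="Int64",
            ),
            "label": labels if labels is not None else ["control"] * n,
        }
    )
    return SpectralDataset(axis, np.asarray(intensities, dtype=float), meta)


@pytest.fixture
def tiny_cohort_config(full_axis) -> CohortConfig:
    """A small, fast cohort with two well-separated planted bands."""
    bands = [
        BandSpec(1650.0, 25.0, 0.5),
        BandSpec(1550.0, 20.0, 0.3),
        BandSpec(1400.0, 6.0, 0.05, class_delta=0.01),
        BandSpec(1100.0, 6.0, 0.05, class_delta=-0.01),
    ]
    return CohortConfig(
        n_positive=6, n_control=12, replicates_per_sample=3, bands=bands, seed=42
    )
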