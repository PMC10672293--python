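"""Simulate a saliva-swab screening cohort and write it as a CSV pair.

Builds the default lung-endpoint cohort — 31 cancer-positive and 948 control
samples, three replicate spectra per swab on the 1798-point 4000-650 cm^-1
grid — and shows the on-disk format every other stage consumes.
"""

import tempfile
from pathlib import Path

import numpy as np

from salivaspec import (
    lung_default_config,
    planted_truth,
    read_dataset,
    simulate_cohort,
    write_dataset,
)

cfg = lung_default_config(seed=7)
ds = simulate_cohort(cfg)
print(f"cohort: {ds.n_rows} spectra ({cfg.n_positive} positive + "
      f"{cfg.n_control} control samples x {cfg.replicates_per_sample} replicates)")
print(f"axis:   {ds.n_points} points, {ds.axis.values[0]:.0f} -> "
      f"{ds.axis.values[-1]:.0f} cm^-1 "
      f"({ds.axis.nominal_resolution:.2f} cm^-1 per step)")

out = Path(tempfile.mkdtemp())
write_dataset(ds, out / "spectra.csv", out / "metadata.csv")
back = read_dataset(out / "spectra.csv", out / "metadata.csv")
print(f"round trip: max |difference| = "
      f"{np.max(np.abs(back.intensities - ds.intensities)):.2e}  (CSV is lossless)")

truth = planted_truth(cfg)
print(f"\nplanted truth: {len(truth)} discriminating bands "
      f"(these are what marker extraction must find)")
print(truth.head(6).to_string(index=False))
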