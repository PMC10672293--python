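"""Which wavenumbers carry the class difference, and what do they mean?

The marker table combines two views: summed-|loading| peaks of the
train-fitted PCA (wavenumbers driving retained variance) gated by the
difference-between-mean (DBM) spectrum (wavenumbers that actually separate
the classes).  Directions come from the raw-domain DBM: 'up' = higher
absorbance in the cancer class.  Tentative vibrational assignments are
attached from the packaged band library.
"""

import numpy as np

from salivaspec import RunConfig, lung_default_config, planted_truth, run_pipeline

cfg = RunConfig(cohort=lung_default_config(seed=7), seed=7, n_components=8)
report = run_pipeline(cfg)

table = report.markers.copy()
table["wavenumber"] = table["wavenumber"].round(1)
print(table[["wavenumber", "direction", "assignment"]].to_string(index=False))

truth = planted_truth(cfg.cohort)
hits = sum(
    1 for wn in truth.wavenumber if np.abs(table.wavenumber - wn).min() <= 4.0
)
print(f"\nrecovered {hits}/{len(truth)} planted bands within +-4 cm^-1 "
      f"({100 * hits / len(truth):.0f}%)")
print("-> bands closer together than ~13 cm^-1 merge under the 9-point SG "
      "derivative, which caps recovery below 100%")
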