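"""Hotelling T2 / Q-residual outlier screening and the Kennard-Stone split.

A PCA model of the preprocessed cohort yields two distances per sample:
T2 (within the model subspace) and Q (residual off it).  A sample is
discarded only when it exceeds both 95% control limits.  The retained
cohort is then split 70/30 per class by the deterministic Kennard-Stone
max-min-distance rule, which picks a training set that spans the spectral
space instead of a random draw.
"""

import numpy as np

from salivaspec import (
    average_replicates,
    fit_pca,
    hotelling_q_outliers,
    kennard_stone_split,
    lung_default_config,
    preprocess,
    select_k,
    simulate_cohort,
)

pre = preprocess(average_replicates(simulate_cohort(lung_default_config(seed=7))))
X = pre.intensities - pre.intensities.mean(axis=0)
k = select_k(X, strategy="explained_variance_threshold", threshold=0.95)
model = fit_pca(X, k)
report = hotelling_q_outliers(model, X, alpha=0.95)
print(f"outlier PCA: {k} PCs; limits T2={report.t2_limit:.1f}, Q={report.q_limit:.2e}")
print(f"flagged {report.flags.sum()} of {pre.n_rows} samples "
      "(must exceed BOTH limits)")

kept = pre.subset(np.nonzero(~report.flags)[0])
split = kennard_stone_split(kept, fraction=0.70)
train = kept.subset_samples(split.train_ids)
test = kept.subset_samples(split.test_ids)
for name, part in (("train", train), ("test", test)):
    pos = int(np.sum(part.labels == "positive"))
    print(f"{name}: {part.n_rows} samples ({pos} positive, {part.n_rows - pos} control)")
print("-> 22/664 train split of a 31/948 cohort reproduces round(0.70 x n) per class")
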