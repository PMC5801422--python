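"""Standard measure M vs bootstrap-robust measure M_robust on one dataset.

Scores a small synthetic time course with the cosinor detector under
quantile normalization, then prints both measures for a few rhythmic and
flat genes.  M_robust = E_hat - RMSE_hat discounts genes whose measure is
unstable under parametric-bootstrap resampling of the probe-level data.
"""

import numpy as np

from rhythmboot import BootstrapConfig, DetectorMethod, score_pipeline
from rhythmboot.simulate import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(G=60, P=6, T=48, fraction_rhythmic=0.5, seed=21)
dataset, truth = generate_dataset(cfg)

theta, robust = score_pipeline(
    dataset,
    "quantile",
    DetectorMethod("cosinor_f", period=24),
    BootstrapConfig(B=50, seed=21),
)

print(f"{'gene':<10} {'rhythmic':<9} {'M':>7} {'E_hat':>7} {'RMSE':>7} {'M_robust':>9}")
order = np.argsort(~truth.is_rhythmic)  # rhythmic genes first
for g in list(order[:5]) + list(order[-5:]):
    print(
        f"{theta.gene_ids[g]:<10} {str(truth.is_rhythmic[g]):<9} "
        f"{theta.M[g]:7.3f} {robust.E_hat[g]:7.3f} "
        f"{robust.RMSE_hat[g]:7.3f} {robust.M_robust[g]:9.3f}"
    )

print(
    "\nStrongly rhythmic genes keep M_robust near 1 (small bootstrap RMSE); "
    "flat or borderline genes are pulled down by the variability penalty."
)
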