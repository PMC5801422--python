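"""Two-way median polish of probe-level data and RMA-style summarization.

Generates a tiny noise-free synthetic gene, decomposes its probe x time
log2 intensity matrix into overall + probe effects + array effects, and
shows that summarization returns exactly the planted temporal profile.
"""

import numpy as np

from rhythmboot import fit_median_polish, summarize_expression
from rhythmboot.simulate import SyntheticConfig, generate_dataset, noise_free

cfg = noise_free(SyntheticConfig(G=1, P=4, T=12, fraction_rhythmic=1.0, seed=7))
dataset, truth = generate_dataset(cfg)

fit = fit_median_polish(dataset.intensities[0])
print("overall (log2 baseline):", round(fit.overall, 3))
print("probe effects (affinities):", np.round(fit.probe_effects, 3))
print("array effects (temporal profile):", np.round(fit.array_effects, 3))
print("max |residual|:", float(np.max(np.abs(fit.residuals))))

expr = summarize_expression(dataset)
amp = (expr.values[0].max() - expr.values[0].min()) / 2
t = np.arange(cfg.T)
planted = truth.true_amplitude[0] * np.cos(
    2 * np.pi * (t - truth.true_phase[0]) / cfg.effective_period
)
planted_amp = (planted.max() - planted.min()) / 2
print(f"\nsummarized half-range: {amp:.3f} "
      f"(planted cosine sampled on this grid: {planted_amp:.3f})")
print("With zero noise the additive model is exact: residuals are 0 and the "
      "summarized profile reproduces the planted oscillation exactly.")
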