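"""Mid-quantile subsampling as a noise-reduction device.

With heavy additive weight noise, low-threshold strength samples pick up a
contaminated bulk and tail, and AICc selection drifts from the bounded model
toward the truncated power law.  Extracting n = 50 points at mid-quantile
positions of the empirical cumulative (0.01, 0.03, ..., 0.99) discards the
noise-sensitive extreme order statistics and restores the bounded model.
"""

import warnings
from collections import Counter

import conncrit as cc

warnings.simplefilter("ignore")

raw_wins, sub_wins = Counter(), Counter()
n_matrices = 20
for index in range(n_matrices):
    matrix = cc.generate_connectivity(
        cc.SyntheticConfig(noise_sd=0.1, seed=8), matrix_index=index
    )
    sample = cc.prepare_fit_data(cc.strength(matrix, 0.15))
    raw_wins[cc.compare_models(sample).best_model] += 1
    reduced, scheme = cc.subsample(sample, 50)
    sub_wins[cc.compare_models(reduced).best_model] += 1

print(f"heavy-noise collection ({n_matrices} matrices, r_c = 0.15)")
print(f"raw samples:        best-model counts = {dict(raw_wins)}")
print(f"subsampled (n=50):  best-model counts = {dict(sub_wins)}")
print(
    f"\nsubsampling lifts the bounded model from "
    f"{raw_wins['restricted']}/{n_matrices} to "
    f"{sub_wins['restricted']}/{n_matrices} selections: trimming the extreme "
    "order statistics removes exactly the points the noise distorts most."
)
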