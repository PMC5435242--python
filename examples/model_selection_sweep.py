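"""AICc model selection for node-strength distributions across thresholds.

At each threshold, each matrix's positive node strengths are fitted by
three candidate models -- bounded ("restricted") power law, exponentially
truncated power law, and pure power law -- and the AICc minimiser is
selected.  Selection ratios are aggregated across the collection.
"""

import warnings

import conncrit as cc

warnings.simplefilter("ignore")

collection = cc.generate_collection(cc.SyntheticConfig(n_matrices=10, seed=2))
summaries = cc.comparison_sweep(
    collection, thresholds=(0.2, 0.3, 0.4, 0.5), stat_kind="strength"
)

print("r_c   restricted  truncated  powerlaw   (selection ratio)")
for s in summaries:
    r = s.selection_ratio
    print(
        f"{s.threshold:.1f}   {r['restricted']:9.2f}  {r['truncated']:9.2f}"
        f"  {r['powerlaw']:8.2f}"
    )

best = summaries[2]
print(
    f"\nAt r_c = {best.threshold:.1f} the bounded model is selected for "
    f"{100 * best.selection_ratio['restricted']:.0f}% of matrices: the hard "
    "upper limit on node strength (an energy-style constraint) matches the "
    "generated data better than a soft exponential cutoff."
)
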