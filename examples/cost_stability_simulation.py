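"""Network-cost stability: simulated mean strength under fitted models.

Both candidate models are fitted to the same bounded strength samples, then
node strengths are re-simulated by inverse-CDF sampling and the average
strength <s> (a network-cost proxy) is compared with the empirical value.
The bounded model cannot produce values beyond its fitted ceiling; the
truncated model's open exponential tail typically inflates the spread of
its simulated <s> across replicates.
"""

import warnings

import numpy as np

import conncrit as cc

warnings.simplefilter("ignore")

generator = cc.RestrictedPowerLaw(gamma=2.22, x_min=0.546, x_max=33.5)
rng = np.random.default_rng(3)

ratios = []
n_collections = 10
for rep in range(n_collections):
    sample = generator.sample(177, rng)
    reference = sample.mean()
    sims = {}
    for name, fit in (
        ("restricted", cc.fit_restricted(sample)),
        ("truncated", cc.fit_truncated(sample)),
    ):
        sims[name] = cc.simulate_strength_means(
            name, fit.params, n_nodes=177, n_replicates=100, seed=100 + rep
        )
        cc.delta_mean_strength(sims[name], reference)
    ratios.append(
        sims["truncated"].replicate_means.std()
        / sims["restricted"].replicate_means.std()
    )
    if rep == 0:
        print(f"collection 0: empirical <s> = {reference:.3f}")
        for name, sim in sims.items():
            print(
                f"  {name:10s}: simulated <s> = {sim.mean_of_means:.3f}, "
                f"delta = {sim.delta_mean:+.3f}, "
                f"replicate spread = {sim.replicate_means.std():.3f}"
            )

print(
    f"\nover {n_collections} collections: median replicate-spread ratio "
    f"(truncated / restricted) = {np.median(ratios):.2f}."
)
print(
    "Both maximum-likelihood fits centre on the empirical mean, so the "
    "difference is in stability: a ratio above 1 means the bounded model's "
    "single-run cost prediction fluctuates less, because its support "
    "ceiling suppresses the tail excursions the truncated model allows."
)
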