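"""Quarter-set discordance: planted order versus exchangeable null.

Splits each synthetic ensemble into 4 balanced subject groups, builds the
consensus appearance order per group, and estimates the probability that two
random common edges appear in strictly opposite order in two random groups.
Random orders would give 1/2; a robust, reproducible order gives much less.
"""

from ccdyn import (
    BrainGraphEnsemble,
    appearance_orders,
    common_items,
    discordance,
    edge_frequencies,
    planted_model,
    quarter_partition,
    sample_ensemble,
)


def quarter_discordance(ensemble, seed):
    part = quarter_partition(ensemble.n, g=4, seed=seed)
    tables = [
        edge_frequencies(
            BrainGraphEnsemble.from_graphs(
                [ensemble.graphs[i] for i in idx], ensemble.atlas
            )
        )
        for idx in part.groups()
    ]
    items = common_items(tables, kind="edge")
    orders = [appearance_orders(t)[0] for t in tables]
    return discordance(orders, items, n_samples=300_000, seed=seed + 1)


for coupling, label in ((1.0, "planted order"), (0.0, "exchangeable null")):
    model = planted_model(N=100, n_edges=600, coupling=coupling,
                          q_max=0.95, q_min=0.05, seed=21)
    ensemble = sample_ensemble(model, n_subjects=400, seed=22)
    est = quarter_discordance(ensemble, seed=23)
    print(f"{label:18s}: discordance = {est.probability:.3f} "
          f"± {est.standard_error:.3f} "
          f"({est.n_common_items} common edges)")

print(
    "\nThe planted-order ensemble is far below the 1/2 random-order level: "
    "its appearance order barely depends on which quarter of the subjects "
    "built it. The null ensemble sits at the random-order level (slightly "
    "under 1/2 because tied appearance steps count as concordant)."
)
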