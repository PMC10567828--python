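"""Ammonia niche-breadth classification on a synthetic incubation study.

Generates a complete two-community incubation experiment with planted
sensitive / tolerant / enriched taxa, runs the abundance pipeline
(rarefaction, absolute abundances), classifies every taxon by Hurlbert's
niche breadth along the NH3 gradient, and compares against the planted
ground truth.
"""

from adniche import SyntheticConfig, generate_experiment, rarefy, weight_to_absolute
from adniche.chemistry import speciate_metadata
from adniche.niche import niche_classification

exp = generate_experiment(SyntheticConfig(seed=11))
meta = speciate_metadata(exp.metadata).set_index("sample_id", drop=False)
rare = rarefy(exp.table, depth=15000, seed=1)
absolute = weight_to_absolute(rare, dict(zip(meta["sample_id"], meta["copies_per_ml"])))

for community in ("unadapted", "preadapted"):
    samples = [s for s in absolute.samples if s.startswith(community)]
    sub = absolute.subset_samples(samples)
    states = (
        meta.loc[samples, "medium"].astype(str) + "_d" + meta.loc[samples, "day"].astype(str)
    ).tolist()
    result, null = niche_classification(
        sub, meta.loc[samples, "nh3"].to_numpy(), seed=2, resource_groups=states
    )
    counts = result["nh3_class"].value_counts().to_dict()
    agree = (result["nh3_class"] == exp.truth.taxa.loc[result.index, "nh3_class"]).mean()
    print(f"{community}: classified {counts}")
    print(
        f"  null thresholds B' < {null.lower_threshold:.2f} (sensitive), "
        f"> {null.upper_threshold:.2f} (enriched); "
        f"{100 * agree:.1f}% agree with the planted classes"
    )

print()
print(
    "B' near 0 = abundance concentrated at low NH3 (sensitive);\n"
    "B' near 1 = abundance tracks NH3 availability (enriched)."
)
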