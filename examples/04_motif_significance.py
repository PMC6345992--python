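"""Assign per-motif significance by deletion likelihood-ratio tests.

For each motif, a perturbed model without it is retrained under identical
folds; 2*(llf - llp) is referred to chi-squared (1 df).
"""

from motiflogit import (SyntheticSpec, all_motif_significance,
                        generate_binding_dataset, rank_motifs, train)

spec = SyntheticSpec(n_loci=1500, n_motifs=10, n_causal=3,
                     true_weights=(1.0, -2.0, 3.0), seed=41)
ds = generate_binding_dataset(spec)
model, _ = train(ds.features, ds.labels, seed=41)
records = all_motif_significance(ds.features, ds.labels, seed=41)
table = rank_motifs(records, model)

print(table[["motif", "weight", "direction", "p_value"]].head(6).to_string(index=False))
print("planted causal motifs:", ", ".join(ds.causal_names))

# The causal motifs should top the ranking with tiny p-values; the sign of
# the weight says whether the motif is enriched (positive) or depleted
# (negative) at binding sites. Non-causal motifs drift toward p = 1.
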