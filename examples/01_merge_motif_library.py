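"""Merge a redundant motif library into a non-redundant one.

Builds a synthetic library with two planted duplicate groups, clusters it at
aligned Pearson correlation 0.9, and shows the recovered groups.
"""

from motiflogit import SyntheticSpec, cluster_and_merge, generate_library

spec = SyntheticSpec(n_motifs=8, n_causal=2, true_weights=(1.0, 2.0), seed=11,
                     n_duplicate_groups=2, duplicates_per_group=2)
library = generate_library(spec)
clusters = cluster_and_merge(library, threshold=0.9)

print(f"{len(library)} motifs -> {len(clusters)} after merging")
for cluster in clusters:
    if len(cluster.member_names) > 1:
        print("merged:", ", ".join(cluster.member_names),
              f"(length {cluster.merged.length})")

# Each multi-member line is one group of near-identical matrices collapsed to
# a single averaged motif; singletons pass through unchanged, so the merged
# library spans the same sequence preferences with fewer redundant columns.
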