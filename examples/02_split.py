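"""The realistically-novel train/held-out split.

Samples a synthetic library with skewed chemical-series sizes, clusters it by
Tanimoto similarity (Butina leader clustering), allocates whole clusters
largest-first to the training set, and reports how chemically novel the
held-out compounds are.
"""

from pdiff.chem import cluster, cross_split_similarity, realistic_split
from pdiff.synthetic import sample_library

library = sample_library(400, 8, n_series=60, profile_width=8, seed=7)
records = [c.record for c in library]

clusters = cluster(records, similarity_cutoff=0.6)
sizes = [len(c) for c in clusters.clusters]
print(f"{len(clusters.clusters)} clusters; largest {sizes[0]}, "
      f"singletons {sizes.count(1)}")

train_ids, heldout_ids = realistic_split(clusters, train_fraction=0.9)
print(f"train {len(train_ids)} / heldout {len(heldout_ids)}")
# Whole clusters go to training largest-first; the held-out set collects the
# singletons and small series, i.e. chemistry unlike anything trained on.

by_id = {c.compound_id: c.record for c in library}
_, median_sim = cross_split_similarity(
    [by_id[i] for i in train_ids], [by_id[i] for i in heldout_ids]
)
print(f"median max-Tanimoto of held-out vs train: {median_sim:.2f}")
# Low values mean the split really does test extrapolation to novel scaffolds.
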