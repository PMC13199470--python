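"""Virtual hit expansion with the Sinkhorn divergence.

Compounds are represented by the sets of per-image segmentation features;
similarity between compounds is the debiased entropic-OT divergence between
those sets.  Queries retrieve their nearest candidates, and the overlap with
ground-truth neighbors is compared against a random-selection baseline.
"""

import numpy as np
import pandas as pd

from pdiff import evaluate, expansion
from pdiff.synthetic import render_field, sample_library

library = sample_library(80, 8, profile_width=8, seed=3)
by_id = {c.compound_id: c for c in library}
ids = sorted(by_id)
query_ids, cand_ids = ids[:20], ids[20:]

def image_set(cid, base, n=6):
    p = by_id[cid].true_phenotype
    return np.stack([render_field(p, 64, 64, seed=base + j, reference_size=64)
                     for j in range(n)])

feats_q = evaluate.feature_table({c: image_set(c, 100) for c in query_ids})
feats_real = evaluate.feature_table({c: image_set(c, 900) for c in cand_ids})
feats_gen = evaluate.feature_table({c: image_set(c, 5000) for c in cand_ids})

_, stats = expansion.standardize_feature_sets(pd.concat([feats_q, feats_real]))
sets_q, _ = expansion.standardize_feature_sets(feats_q, stats=stats)
sets_real, _ = expansion.standardize_feature_sets(feats_real, stats=stats)
sets_gen, _ = expansion.standardize_feature_sets(feats_gen, stats=stats)

k = 10
truth = {r.query_id: r.neighbors
         for r in expansion.retrieve_all(sets_q, sets_real, k=k, epsilon=0.05)}
gen_res = expansion.retrieve_all(sets_q, sets_gen, k=k, epsilon=0.05)
gen_overlap = np.array([expansion.percent_overlap(truth[r.query_id], r.neighbors)
                        for r in gen_res])
rand_overlap = expansion.baseline_random(len(sets_q), len(cand_ids), k, seed=4)

print(f"median overlap with ground-truth top-{k} neighbors:")
print(f"  image sets from a faithful generator: {np.median(gen_overlap):.0f}%")
print(f"  random selection:                     {np.median(rand_overlap):.0f}%")
tests = expansion.compare_distributions({"generator": gen_overlap,
                                         "random": rand_overlap})
print(tests.to_string(index=False))
# A high generator overlap with a small adjusted p means the generated images
# carry enough phenotype to find the same neighbors the real images would.
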