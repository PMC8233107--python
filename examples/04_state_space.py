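"""State-space embedding and watershed segmentation.

A distance matrix over training states is embedded onto 2-D with UMAP
(precomputed-distance mode); held-out points are projected out-of-sample,
converted to a Gaussian grid density (bandwidth factor 0.08 of the extent,
256-pixel grid, aspect-trimmed), and segmented with a watershed transform.
"""

import numpy as np

import brainstates as bs
from brainstates import stats

cfg = bs.StudyConfig(n_volunteers=3, n_regions=12, seed=13)
study = bs.generate_study(cfg)
fb = bs.build_filterbank(tr=cfg.tr)
tvfc = [bs.compute_tvfc(s, fb) for s in study]
features = stats.prepare_features(tvfc, ["H0"])

plan = stats.make_split(tvfc, seed=1, n_train=80, n_eval=100)
print("volunteer groups:", plan.embed_group, plan.cluster_group,
      plan.test_group)

D_train, R_cluster = stats._metric_blocks(
    features, "H0", plan.embed_group, plan.train_subsample,
    plan.cluster_group, plan.eval_subsample)
emb = bs.fit_embedding(D_train, seed=1)
print(f"embedded {emb.n} training states onto 2-D "
      f"(n_neighbors={emb.n_neighbors}, min_dist={emb.min_dist})")

coords = bs.project(emb, R_cluster)
seg = bs.density_and_watershed(coords)
print(f"projected {coords.shape[0]} clustering-group states; "
      f"watershed found {seg.n_clusters} clusters on a "
      f"{seg.density.shape[0]}x{seg.density.shape[1]} grid")

sizes = np.bincount(seg.assignments)[1:]
print("cluster occupancies:", sizes.tolist())
print("Each cluster is a candidate brain state: a dense region of the "
      "embedding grown from a local density maximum.")
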