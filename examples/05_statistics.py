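"""Bootstrap statistics: volunteer generalizability, stimulus enrichment,
effect sizes, and task-performance valence.

Each bootstrap draw re-splits the volunteers into embedding / clustering /
testing thirds, re-embeds, re-segments, and re-tests. Label-permutation
nulls (300 permutations, alpha = 0.05, Bonferroni over clusters x labels)
decide which watershed clusters are tied to volunteers, stimuli, or
performance levels.
"""

import numpy as np

import brainstates as bs
from brainstates import stats

cfg = bs.StudyConfig(n_volunteers=6, n_regions=16, seed=21)
study = bs.generate_study(cfg)
fb = bs.build_filterbank(tr=cfg.tr)
tvfc = [bs.compute_tvfc(s, fb) for s in study]
features = stats.prepare_features(tvfc, ["node", "H0"])

boot = stats.bootstrap_driver(features, ["node", "H0"], n_boot=4, seed=2,
                              n_eval=120)
print("mean stimulus colocalization over 4 draws (%):")
print(boot.summary().pivot(index="condition", columns="metric",
                           values="mean_pct").round(1))
print("Higher percentages mean more of a condition's test points fall in "
      "clusters significantly enriched for that condition.")

print("\nvolunteer-generalizability bins (% of test points, draw means):")
for metric in ("node", "H0"):
    bins = boot.bins[metric].mean(axis=0)
    print(f"  {metric:>5}:", {int(k): round(v, 1) for k, v in bins.items()})
print("Bin b holds points in clusters where exactly b of the volunteers are "
      "not significantly underrepresented; right-heavy = group-general.")

# effect sizes for one draw: real vs permuted-label colocalization
draw = boot.draws["H0"][0]
a = draw.test_assignments
conds = draw.test_meta["condition"].to_numpy()
real = boot.colocalization["H0"]
yellow = stats.permuted_colocalization(a, conds, draw.enrichment.significant,
                                       n_perm=30, seed=3)
black = stats.false_positive_colocalization(a, conds, n_draws=5, seed=4)
eff = stats.enrichment_effect_size(real, yellow, black)
print("\nCohen's d, real vs permuted colocalization:",
      {k: round(v, 2) for k, v in eff.cohen_d.items()})
print("black-box false-positive colocalization mean:",
      round(black.to_numpy().mean(), 2), "%")

# performance valence for the math task on this draw
perf = draw.test_meta["performance"].to_numpy(dtype=float)
sig_math = sorted({c for c, cc in draw.enrichment.significant if cc == "math"})
pr = stats.performance_test(a, conds, perf, "math", sig_math, seed=5)
print(f"\nmath-significant clusters: {sig_math}; "
      f"high-performance: {pr.high_clusters}, low: {pr.low_clusters}")
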