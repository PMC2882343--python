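"""Evaluate how well a baseline supports stock identification.

Runs the two standard baseline-evaluation experiments on a synthetic
baseline calibrated near the realistic 4% among-site differentiation:
single-origin (100%) mixtures and the equal-proportion 8-unit design, with
mixture fish drawn from the *true* population frequencies so the baseline
is an imperfect finite sample, as in reality.  Accuracy rises with the
reporting level (site < catchment < region) - the central practical
finding for weakly differentiated baselines.
"""

import numpy as np

import salmix as sx
from salmix.evaluate import multi_origin_eval, single_origin_eval
from salmix.genotype_io import pool_collections

spec = sx.HierarchySpec(seed=11)  # 8 regions x 3 catchments x 2 sites, 12 loci
registry, truth = sx.simulate_registry(spec, n_per_site=30)
print(f"baseline: {len(registry.collections)} sites, global F_ST ~ "
      f"{sx.wc_theta(registry.collections, registry.loci).estimate:.3f}")

unit = "R1C1S1"
pooled = pool_collections(registry)
row = single_origin_eval(
    registry, unit, n_mix=100, reps=25, seed=1, pooled_registry=pooled, source=truth
)
print(f"\nsingle-origin mixtures from {unit} (100 fish, 25 replicates):")
for level in ("unit", "catchment", "pooled_catchment", "region"):
    print(f"  apportioned to correct {level:17s} {row[level + '_mean']:.3f} "
          f"(SD {row[level + '_sd']:.3f})")

units = tuple(f"R{r}C1S1" for r in range(1, 9))
design = sx.MixtureSpec(units=units, proportions=(0.125,) * 8, n=100)
df = multi_origin_eval(registry, design, reps=50, seed=2, source=truth)
print("\nequal-proportion mixture (8 units x 12.5%, 50 replicates):")
print(df[["unit", "unit_estimate_mean", "region_estimate_mean"]]
      .round(3).to_string(index=False))
print(f"\nmean unit-level estimate {df.unit_estimate_mean.mean():.3f} "
      "(biased low: similar neighbour sites absorb proportion), "
      f"region-level MAE {np.abs(df.region_estimate_mean - 0.125).mean():.3f} "
      "(accurate: regions are the reliable reporting level).")
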