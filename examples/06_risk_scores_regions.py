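"""Composite risk scoring and regionalization: quintile scores per
variable, cumulative category scores, an overall composite, LISA hot spots,
and SKATER contiguous regions. Also the inequity-score variant."""

import numpy as np
import pandas as pd

from hextable import (
    adjacency_orders, build_weights, inequity_scores, local_moran,
    make_autocorrelated_field, make_grid_geography, risk_table,
    skater_cluster,
)

geo = make_grid_geography(8, 8, cell_km=10.0, blocks_per_county=1)
adj = adjacency_orders(geo.counties)
w = build_weights(adj)
codes = sorted(adj.first_order)

# six correlated risk variables in two categories
rng = np.random.default_rng(2)
data = pd.DataFrame({
    f"v{k}": make_autocorrelated_field(w, 0.5, seed=100 + k).loc[codes].to_numpy()
    for k in range(6)
})
categories = {
    "susceptibility": [("v0", True), ("v1", True), ("v2", True)],
    "access": [("v3", True), ("v4", False), ("v5", True)],  # v4 protective
}
rt = risk_table(codes, data, categories)
print("composite risk: min {:.0f}, median {:.0f}, max {:.0f} "
      "(range {}..{})".format(
          rt.composite.min(), np.median(rt.composite), rt.composite.max(),
          2 * len(categories["susceptibility"]),
          2 * 5 * len(categories["susceptibility"])))

# where does compounded risk cluster?
lisa = local_moran(rt.composite, w, n_perm=999, seed=5)
labels = pd.Series(lisa.labels).value_counts().to_dict()
print("LISA labels on the composite:", labels)

# contiguous regions sharing similar risk profiles
regions = skater_cluster(codes, data.to_numpy(), adj, k=6)
sizes = pd.Series(regions.labels).value_counts().sort_index().tolist()
print(f"6 contiguous risk regions, sizes {sizes}, "
      f"within-cluster SS {regions.within_ss:.1f}")

# inequity scores: 7 social + 4 access measures, combined = mean of domains
n = len(codes)
social = pd.DataFrame(rng.uniform(0, 1, (n, 7)),
                      columns=[f"s{i}" for i in range(7)])
access = pd.DataFrame(rng.uniform(0, 1, (n, 4)),
                      columns=[f"a{i}" for i in range(4)])
reach = rng.random(n) < 0.3  # counties a telehealth program reaches
res = inequity_scores(codes, social, access, reach_flag=reach)
print(f"combined inequity: all units {res.mean_combined_all:.2f}, "
      f"program-reach units {res.mean_combined_reach:.2f}")
# Scores are quintile-standardised (1 = least, 5 = most inequitable), so a
# reach-cohort mean above the overall mean says the program is reaching the
# more inequitable places.
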