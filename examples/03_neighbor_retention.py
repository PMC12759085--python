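"""Quantify collective vs dispersive movement via neighbor retention.

Neighbors are cells within 15 μm. For a cell tracked between two
timepoints, the retention rate is the fraction of its initial neighbors
still neighboring it later: ~1 for cells moving as a group, falling toward
0 as cells rearrange. Comparing rates across interval lengths with a
one-way ANOVA (Tukey HSD post hoc) shows whether movement decollectivizes
over time.
"""

import numpy as np

from morphlineage import PositionFrame, compare_interval_groups, neighbor_rate

rng = np.random.default_rng(11)
n_cells = 80
positions = rng.uniform(0, 60, size=(n_cells, 3))
ids = [f"cell{i}" for i in range(n_cells)]

# Brownian rearrangement: every frame each cell takes a random 1.5 um step
frames = {}
cur = positions.copy()
for t in range(45):
    frames[t] = PositionFrame(t, ids, cur.copy())
    cur = cur + rng.normal(0, 1.5, size=cur.shape)

intervals = [(1, 5), (1, 10), (1, 20), (1, 44)]
groups = {}
for t0, t1 in intervals:
    table = neighbor_rate(frames, t0, t1, radius=15.0)
    label = f"T{t0}-T{t1}"
    groups[label] = table.table["rate"].to_numpy()
    print(
        f"{label}: mean retention {groups[label].mean():.3f} "
        f"({len(groups[label])} cells, {table.n_isolated} isolated excluded)"
    )

res = compare_interval_groups(groups)
print(f"\none-way ANOVA: F = {res.f_statistic:.2f}, p = {res.p_value:.2e}")
print("Tukey HSD adjusted p-values:")
for _, row in res.tukey.iterrows():
    print(f"  {row['group1']} vs {row['group2']}: p_adj = {row['p_adj']}")
# The mean rate drops monotonically with interval length: neighborhoods
# are conserved over short windows (collective motion) and progressively
# lost over long ones (dispersive motion); ANOVA confirms the interval
# effect.
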