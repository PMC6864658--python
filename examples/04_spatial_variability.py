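"""Spatial variability from the published campaign tables.

Loads the printed 15-site pairwise COD and R2 matrices and the site
distances, summarises heterogeneity against the conventional COD = 0.2
threshold, and fits the distance-decay relation.
"""

from pmnet import core, spatial

cod = core.load_fixture_table("table5")
r2 = core.load_fixture_table("table4")
dist = core.load_fixture_table("table3")

for label, matrix in (("hourly", cod.hourly), ("daily", cod.daily)):
    s = spatial.summarize_matrix(matrix)
    print(f"COD {label:>6}: mean {s['mean']:.2f}, range {s['min']:.2f} - {s['max']:.2f} ({s['n_pairs']} pairs)")
for label, matrix in (("hourly", r2.hourly), ("daily", r2.daily)):
    s = spatial.summarize_matrix(matrix)
    print(f"R2  {label:>6}: mean {s['mean']:.2f}, range {s['min']:.2f} - {s['max']:.2f}")

matrix = spatial.PairwiseStatMatrix("cod", "hourly", cod.hourly, cod.hourly * 0 + 1)
table, frac = spatial.classify_homogeneity(matrix)
print(f"\nhourly pairs at or above the 0.2 threshold: {int(frac * len(table))} of {len(table)}"
      f" ({100 * frac:.0f}% heterogeneous)")

decay_cod = spatial.distance_decay(cod.hourly, dist.km)
decay_r2 = spatial.distance_decay(r2.hourly, dist.km)
print(f"\ndistance decay (hourly): COD slope {decay_cod['slope']:+.4f}/km (p = {decay_cod['p_value']:.1e}),"
      f" R2 slope {decay_r2['slope']:+.4f}/km")
print()
print("A mean COD near 0.2 with divergence growing a few thousandths per km")
print("says the domain is mostly homogeneous at hourly resolution, with")
print("heterogeneity only between the most distant site pairs; daily")
print("averages smooth most of it away.")
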