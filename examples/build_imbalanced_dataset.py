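"""Constructing imbalanced datasets by random-grouping undersampling.

Partitions nine categories into three random groups, subsamples each group at
its slot proportion, and prints the share/ratio statistics — then shows the
three bundled reference compositions of increasing severity.
"""

from leafdet.imbalance import (
    REFERENCE_COMPOSITIONS, DatasetIndex, ImbalanceSpec, apply_proportions,
    imbalance_stats, random_group_partition, reference_index,
)

base = DatasetIndex.from_counts({c: 1000 + 50 * c for c in range(9)})
groups = random_group_partition(list(range(9)), seed=4)
spec = ImbalanceSpec(groups=groups,
                     proportions=[[0.1, 0.2, 0.3], [0.4, 0.5, 0.6],
                                  [0.7, 0.8, 0.9]], seed=4)
subset = apply_proportions(base, spec)
stats = imbalance_stats(subset)
print(f"random groups: {groups}")
print(f"retained counts: {stats['counts']}")
print(f"shares (%): {stats['shares']}")
print(f"imbalance ratio (max:min rounded share): {stats['ratio']}:1\n")

print("bundled reference compositions:")
for name in ("exp1", "exp2", "exp3"):
    s = imbalance_stats(reference_index(name))
    print(f"  {name}: total {s['total']:>5d}, max share {s['max_share']:>5.1f}%, "
          f"min share {s['min_share']:.1f}%, ratio {s['ratio']}:1")
print("-> severity grows from exp1 to exp3 (the proportions span "
      f"{REFERENCE_COMPOSITIONS['exp3']['proportions'][0][0]} to 0.9).")
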