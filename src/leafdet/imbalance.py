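"""Random-grouping undersampling for constructing imbalanced detection sets.

To manufacture controlled class imbalance from a roughly balanced nine-way
corpus, the nine categories are randomly partitioned into three groups of
three, each group slot is assigned a retention proportion, and every category
is subsampled (uniformly, without replacement) to ``round(p * count)``.  The
severity of the resulting imbalance is summarised by per-category shares (in
percent, one decimal) and the ratio of the largest to the smallest rounded
share.

Three reference compositions (``exp1`` < ``exp2`` < ``exp3`` in severity) are
bundled for demonstrations and tests; their printed per-category quantities
are carried as fixed inputs rather than recomputed from a base corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetIndex", "ImbalanceSpec", "random_group_partition",
    "apply_proportions", "imbalance_stats", "stratified_split",
    "REFERENCE_COMPOSITIONS", "reference_index",
]

CATEGORY_NAMES = {
    0: "Early Blight", 1: "Healthy", 2: "Late Blight", 3: "Leaf Miner",
    4: "Leaf Mold", 5: "Mosaic Virus", 6: "Septoria", 7: "Spider Mites",
    8: "Yellow Leaf Curl Virus",
}

# Bundled imbalanced compositions: group order (three groups of three
# categories), slot proportions and the resulting per-category quantities.
REFERENCE_COMPOSITIONS = {
    "exp1": {
        "groups": [[3, 5, 7], [0, 4, 6], [1, 8, 2]],
        "proportions": [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]],
        "quantities": [[136, 391, 324], [534, 875, 787], [1092, 1610, 1021]],
    },
    "exp2": {
        "groups": [[4, 5, 2], [7, 6, 1], [3, 8, 0]],
        "proportions": [[0.05, 0.1, 0.15], [0.2, 0.3, 0.4], [0.5, 0.6, 0.7]],
        "quantities": [[60, 132, 220], [170, 358, 762], [553, 1370, 819]],
    },
    "exp3": {
        "groups": [[5, 8, 2], [0, 6, 7], [3, 4, 1]],
        "proportions": [[0.01, 0.05, 0.1], [0.2, 0.3, 0.4], [0.7, 0.8, 0.9]],
        "quantities": [[164, 66, 19], [285, 323, 284], [746, 966, 1446]],
    },
}


@dataclass
class DatasetIndex:
    """Per-category sample-ID lists for a detection dataset."""

    samples: dict = field(default_factory=dict)   # {category_id: [sample ids]}

    def __post_init__(self):
        seen: set = set()
        for c, ids in self.samples.items():
            for s in ids:
                if s in seen:
                    raise ValueError(f"sample id {s!r} appears in more than one category")
                seen.add(s)

    @property
    def categories(self):
        return sorted(self.samples)

    def count(self, category: int) -> int:
        return len(self.samples.get(category, ()))

    @property
    def counts(self) -> dict:
        return {c: len(ids) for c, ids in sorted(self.samples.items())}

    @property
    def total(self) -> int:
        return sum(len(ids) for ids in self.samples.values())

    @classmethod
    def from_counts(cls, counts: dict) -> "DatasetIndex":
        """Synthetic index with ids ``"<cat>:<i>"`` for the given counts."""
        return cls({c: [f"{c}:{i}" for i in range(n)] for c, n in counts.items()})


def reference_index(name: str) -> DatasetIndex:
    """A DatasetIndex whose counts equal a bundled composition's quantities."""
    comp = REFERENCE_COMPOSITIONS[name]
    counts = {}
    for group, qty in zip(comp["groups"], comp["quantities"]):
        for c, n in zip(group, qty):
            counts[c] = n
    return DatasetIndex.from_counts(counts)


@dataclass(frozen=True)
class ImbalanceSpec:
    """A partition of nine categories into 3 groups of 3, with slot proportions."""

    groups: tuple
    proportions: tuple
    seed: int = 0

    def __post_init__(self):
        groups = tuple(tuple(g) for g in self.groups)
        props = tuple(tuple(p) for p in self.proportions)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "proportions", props)
        flat = [c for g in groups for c in g]
        if len(groups) != 3 or any(len(g) != 3 for g in groups):
            raise ValueError("expected 3 groups of 3 categories")
        if len(set(flat)) != 9:
            raise ValueError("groups must partition 9 distinct categories")
        if len(props) != 3 or any(len(p) != 3 for p in props):
            raise ValueError("expected 3 proportion triples")
        for p in (x for trip in props for x in trip):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"proportions must lie in (0, 1], got {p}")


def random_group_partition(category_ids, seed: int):
    """Seeded uniform partition of nine categories into 3 ordered groups of 3."""
    ids = list(category_ids)
    if len(ids) != 9:
        raise ValueError(f"expected exactly 9 category ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return [shuffled[0:3], shuffled[3:6], shuffled[6:9]]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def apply_proportions(index: DatasetIndex, spec: ImbalanceSpec) -> DatasetIndex:
    """Retain ``round(p * count)`` samples per category, seeded and uniform.

    Categories are processed in the spec's printed (group, slot) order with a
    single generator, so identical spec + seed reproduce identical subsets.
    """
    for g in spec.groups:
        for c in g:
            if index.count(c) == 0:
                raise ValueError(f"category {c} is empty or missing")
    rng = np.random.default_rng(spec.seed)
    out: dict = {}
    for group, props in zip(spec.groups, spec.proportions):
        for c, p in zip(group, props):
            ids = list(index.samples[c])
            keep = _round_half_up(p * len(ids))
            chosen = rng.choice(len(ids), size=keep, replace=False)
            out[c] = [ids[i] for i in sorted(chosen)]
    return DatasetIndex(out)


def imbalance_stats(index: DatasetIndex) -> dict:
    """Per-category shares (%) and the rounded-share max:min ratio.

    ``share(c) = 100 * count(c) / total`` rounded to one decimal; the ratio
    divides the largest rounded share by the smallest, again to one decimal.
    """
    total = index.total
    if total == 0:
        raise ValueError("empty index")
    shares = {c: round(100.0 * n / total, 1) for c, n in index.counts.items()}
    max_share = max(shares.values())
    min_share = min(shares.values())
    return {
        "total": total,
        "counts": index.counts,
        "shares": shares,
        "max_share": max_share,
        "min_share": min_share,
        "ratio": round(max_share / min_share, 1),
    }


def stratified_split(index: DatasetIndex, test_fraction: float, seed: int):
    """Per-category seeded split into (train, test) with disjoint IDs."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: dict = {}
    test: dict = {}
    for c in index.categories:
        ids = list(index.samples[c])
        n_test = _round_half_up(test_fraction * len(ids))
        chosen = set(rng.choice(len(ids), size=n_test, replace=False).tolist())
        test[c] = [s for i, s in enumerate(ids) if i in chosen]
        train[c] = [s for i, s in enumerate(ids) if i not in chosen]
    return DatasetIndex(train), DatasetIndex(test)
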