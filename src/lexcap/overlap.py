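"""Observed and percent-maximum overlap across k-way resource intersections.

For every subset of k resources we count the items documented by *all* of
them and normalize by the size of the smallest per-resource item set — the
"percent maximum overlap": 100 means the smallest of the k resources is
perfectly nested within the others.  Items are either concepts (a concept
counts toward a resource if any of its terms carries that resource's bit)
or concept-term pairs (the record itself must carry the bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import pandas as pd

from .io import Compendium

Level = Literal["concept", "pair"]


@dataclass(frozen=True)
class OverlapRecord:
    resource_indices: tuple[int, ...]
    resource_names: tuple[str, ...]
    observed: int
    max_possible: int

    @property
    def k(self) -> int:
        return len(self.resource_indices)

    @property
    def percent_max(self) -> float:
        if self.max_possible == 0:
            return 0.0
        return 100.0 * self.observed / self.max_possible


def resource_item_sets(compendium: Compendium, level: Level) -> list[set]:
    """Per-resource sets of items (concepts or (concept, term) pairs)."""
    d = compendium.resources.d
    sets: list[set] = [set() for _ in range(d)]
    for cid, rec in compendium.iter_records():
        item = cid if level == "concept" else (cid, rec.term)
        for i, bit in enumerate(rec.presence):
            if bit:
                sets[i].add(item)
    return sets


def overlap_table(
    compendium: Compendium,
    level: Level = "concept",
    k_range: Iterable[int] = (2,),
) -> list[OverlapRecord]:
    """All C(D, k) k-way overlap records for each requested k.

    Only the requested k values are enumerated; for large D, asking for
    every k is a combinatorial blow-up left to the caller's judgement.
    """
    d = compendium.resources.d
    names = compendium.resources.names
    ks = sorted(set(int(k) for k in k_range))
    for k in ks:
        if not 2 <= k <= d:
            raise ValueError(f"k={k} outside [2, D={d}]")
    sets = resource_item_sets(compendium, level)
    records: list[OverlapRecord] = []
    for k in ks:
        for idx in combinations(range(d), k):
            inter = set.intersection(*(sets[i] for i in idx))
            max_possible = min(len(sets[i]) for i in idx)
            records.append(
                OverlapRecord(
                    resource_indices=idx,
                    resource_names=tuple(names[i] for i in idx),
                    observed=len(inter),
                    max_possible=max_possible,
                )
            )
    return records


def overlap_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [r.k for r in records],
            "resources": [",".join(r.resource_names) for r in records],
            "observed": [r.observed for r in records],
            "max_possible": [r.max_possible for r in records],
            "percent_max": [r.percent_max for r in records],
        }
    )


def nestedness_summary(records: list[OverlapRecord]) -> pd.DataFrame:
    """Per-k mean and median percent-maximum overlap."""
    if not records:
        raise ValueError("no overlap records to summarize")
    df = overlap_frame(records)
    out = (
        df.groupby("k")["percent_max"]
        .agg(["mean", "median", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_percent_max", "median": "median_percent_max"})
    )
    return out
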