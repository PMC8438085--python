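"""Presence/absence co-occurrence of genera across the four farm compartments.

Implements Venn-style partitioning of the genus pool into the 15 exclusive
regions defined by membership in soil, phyllosphere, cow-teat and milk;
shared-fraction percentages; and per-compartment genus-richness summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_tables import (
    COMPARTMENTS,
    GenusCountTable,
    RelAbundanceTable,
    SampleMetadata,
)

Region = frozenset


def all_regions() -> list[frozenset[str]]:
    """The 15 non-empty subsets of the four compartments."""
    out = []
    for k in range(1, 5):
        out.extend(frozenset(c) for c in combinations(COMPARTMENTS, k))
    return out


@dataclass
class PartitionCounts:
    """Exclusive-region genus counts over the 4-compartment Venn partition."""

    counts: dict[frozenset[str], int]
    total: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("region counts must be non-negative")
        if sum(self.counts.values()) != self.total:
            raise ValueError("region counts must sum to the union size")

    def count(self, *compartments: str) -> int:
        return self.counts.get(frozenset(compartments), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in all_regions():
            rows.append(
                {**{c: int(c in region) for c in COMPARTMENTS},
                 "n_genera": self.counts.get(region, 0)}
            )
        return pd.DataFrame(rows)


def presence_absence(table: GenusCountTable | RelAbundanceTable) -> pd.DataFrame:
    """Binary table: 1 where abundance is strictly positive."""
    df = table.counts if isinstance(table, GenusCountTable) else table.values
    return (df > 0).astype(np.int8)


def compartment_genus_sets(
    table: GenusCountTable | RelAbundanceTable,
    metadata: SampleMetadata,
    by_farm: bool = False,
) -> dict:
    """Genus sets per compartment, as unions over that compartment's samples.

    With ``by_farm`` the union is per (farm, compartment):
    ``{farm: {compartment: set}}``; otherwise ``{compartment: set}`` across all
    farms (the farm-network level).
    """
    binary = presence_absence(table)
    meta = metadata.for_samples(binary.index)
    if by_farm:
        sets: dict[str, dict[str, set]] = {}
        for (farm, comp), block in binary.groupby(
            [meta["farm"].to_numpy(), meta["compartment"].to_numpy()]
        ):
            present = block.any(axis=0)
            sets.setdefault(farm, {})[comp] = set(binary.columns[present])
        return sets
    sets_flat: dict[str, set] = {}
    for comp, block in binary.groupby(meta["compartment"].to_numpy()):
        present = block.any(axis=0)
        sets_flat[comp] = set(binary.columns[present])
    return sets_flat


def venn_partition(sets: Mapping[str, set]) -> PartitionCounts:
    """Count genera in each exclusive region of the 4-set Venn partition."""
    missing = [c for c in COMPARTMENTS if c not in sets]
    if missing:
        raise ValueError(f"missing compartments: {missing}")
    union = set().union(*(sets[c] for c in COMPARTMENTS))
    counts: dict[frozenset[str], int] = {r: 0 for r in all_regions()}
    for genus in union:
        region = frozenset(c for c in COMPARTMENTS if genus in sets[c])
        counts[region] += 1
    return PartitionCounts(counts=counts, total=len(union))


def merge_farm_sets(per_farm: Mapping[str, Mapping[str, set]]) -> dict[str, set]:
    """Network-level compartment sets: union of each compartment over farms."""
    merged: dict[str, set] = {c: set() for c in COMPARTMENTS}
    for farm_sets in per_farm.values():
        for comp, genera in farm_sets.items():
            merged[comp] |= genera
    return merged


def shared_fraction(
    counts: PartitionCounts, regions: Iterable[frozenset[str]]
) -> float:
    """Percentage of the genus union falling in the requested regions,
    rounded to one decimal."""
    if counts.total == 0:
        raise ValueError("empty genus union: shared fraction undefined")
    n = sum(counts.counts.get(frozenset(r), 0) for r in regions)
    return round(100.0 * n / counts.total, 1)


def regions_by_size(k: int) -> list[frozenset[str]]:
    """All exclusive regions spanning exactly ``k`` compartments."""
    return [r for r in all_regions() if len(r) == k]


def richness_summary(per_farm: Mapping[str, Mapping[str, set]]) -> pd.DataFrame:
    """Per-compartment genus-richness summary over farms.

    Rows are compartments; columns are min, max, mean, SE (sd/sqrt(n)),
    CV (sd/mean, a ratio) and the cumulated (union) genus count.
    """
    if not per_farm:
        raise ValueError("at least one farm is required")
    rows = []
    for comp in COMPARTMENTS:
        sizes = np.array(
            [len(farm_sets.get(comp, set())) for farm_sets in per_farm.values()],
            dtype=float,
        )
        union: set = set()
        for farm_sets in per_farm.values():
            union |= farm_sets.get(comp, set())
        sd = sizes.std(ddof=1) if len(sizes) > 1 else 0.0
        mean = sizes.mean()
        rows.append(
            {
                "compartment": comp,
                "min": sizes.min(),
                "max": sizes.max(),
                "mean": mean,
                "se": sd / np.sqrt(len(sizes)),
                "cv": sd / mean if mean > 0 else np.nan,
                "cumulated": len(union),
            }
        )
    return pd.DataFrame(rows).set_index("compartment")


def region_frequency(
    per_farm: Mapping[str, Mapping[str, set]]
) -> pd.DataFrame:
    """Fraction of farms in which each genus occupies each Venn region."""
    farms = list(per_farm)
    tally: dict[tuple[str, frozenset[str]], int] = {}
    for farm in farms:
        sets = per_farm[farm]
        union = set().union(*(sets.get(c, set()) for c in COMPARTMENTS))
        for genus in union:
            region = frozenset(c for c in COMPARTMENTS if genus in sets.get(c, set()))
            tally[(genus, region)] = tally.get((genus, region), 0) + 1
    def sort_key(item):
        (genus, region), _ = item
        return (str(genus), tuple(int(c in region) for c in COMPARTMENTS))

    rows = [
        {
            "genus": genus,
            **{c: int(c in region) for c in COMPARTMENTS},
            "farm_fraction": n / len(farms),
        }
        for (genus, region), n in sorted(tally.items(), key=sort_key)
    ]
    return pd.DataFrame(rows)
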