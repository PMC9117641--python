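"""Named locus subsets (disease/eSTR lists, catalog strata) and their
variability composition summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import StrLocus
from .errors import EmptySubsetError, InputError
from .variability import decile_distribution, tier_proportions

SUBSET_SOURCES = ("dstr", "estr", "fm_estr", "motif_size", "region", "unit", "custom")


@dataclass(frozen=True)
class LocusSubset:
    name: str
    locus_ids: frozenset[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("subset name must be non-empty")
        if self.source not in SUBSET_SOURCES:
            raise InputError(f"unknown subset source {self.source!r}")


@dataclass(frozen=True)
class SubsetSummary:
    """Tier/decile composition of a subset over its scored loci."""

    name: str
    n_loci_scored: int
    n_unscored: int
    tier_proportions: tuple[float, ...]
    decile_proportions: tuple[float, ...]


def build_strata(catalog: Sequence[StrLocus], by: str) -> list[LocusSubset]:
    """Partition a catalog by motif size, region class, or canonical unit.

    Every locus lands in exactly one subset, so subset sizes sum to the
    catalog size. Subsets are returned sorted by name.
    """
    if by == "motif_size":
        key = lambda l: f"{len(l.motif)}bp"
        source = "motif_size"
    elif by == "region":
        key = lambda l: l.region_class
        source = "region"
    elif by == "canonical_unit":
        key = lambda l: l.canonical
        source = "unit"
    else:
        raise InputError(f"unknown stratification {by!r}")
    groups: dict[str, set[str]] = {}
    for locus in catalog:
        groups.setdefault(key(locus), set()).add(locus.locus_id)
    return [
        LocusSubset(name=name, locus_ids=frozenset(ids), source=source)
        for name, ids in sorted(groups.items())
    ]


def resolve_subset(
    entries: pd.DataFrame,
    catalog: Sequence[StrLocus],
    name: str,
    source: str = "custom",
) -> tuple[LocusSubset, list[str]]:
    """Resolve a subset file against a catalog.

    Entries may name loci by ``locus_id`` or by a (chrom, start, end)
    triple. Unresolvable entries are returned (not fatal), mirroring how
    published locus lists are keyed by coordinates.
    """
    by_id = {l.locus_id for l in catalog}
    by_coord = {(l.chrom, l.start, l.end): l.locus_id for l in catalog}
    resolved: set[str] = set()
    unresolved: list[str] = []
    if "locus_id" in entries.columns:
        for raw in entries["locus_id"]:
            if raw in by_id:
                resolved.add(raw)
            else:
                unresolved.append(str(raw))
    elif {"chrom", "start", "end"} <= set(entries.columns):
        for _, row in entries.iterrows():
            key = (str(row["chrom"]), int(row["start"]), int(row["end"]))
            if key in by_coord:
                resolved.add(by_coord[key])
            else:
                unresolved.append(f"{key[0]}:{key[1]}-{key[2]}")
    else:
        raise InputError(
            "subset table needs a locus_id column or chrom/start/end columns"
        )
    return LocusSubset(name=name, locus_ids=frozenset(resolved), source=source), unresolved


def summarize_subset(records: pd.DataFrame, subset: LocusSubset) -> SubsetSummary:
    """Tier and decile proportions of a subset over scored loci only.

    ``records`` is the variability frame (indexed by or carrying locus_id,
    with nrdi). Subset members that exist but were not scored are counted
    in ``n_unscored`` and excluded from the proportions.
    """
    frame = records
    if "locus_id" in frame.columns:
        frame = frame.set_index("locus_id")
    members = frame.index.intersection(list(subset.locus_ids))
    scored = frame.loc[members, "nrdi"].dropna()
    if scored.empty:
        raise EmptySubsetError(
            f"subset {subset.name!r} has no scored loci in the records"
        )
    deciles = decile_distribution(frame, subset.locus_ids)
    return SubsetSummary(
        name=subset.name,
        n_loci_scored=int(scored.size),
        n_unscored=int(len(members) - scored.size),
        tier_proportions=tuple(tier_proportions(scored.to_numpy())),
        decile_proportions=tuple(deciles),
    )


def summaries_frame(summaries: Iterable[SubsetSummary]) -> pd.DataFrame:
    """Flatten summaries into a writable table (one row per subset)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "name": s.name,
            "n_loci_scored": s.n_loci_scored,
            "n_unscored": s.n_unscored,
        }
        from .variability import TIERS

        row.update({f"tier_{t}": p for t, p in zip(TIERS, s.tier_proportions)})
        row.update(
            {f"decile_{i}": p for i, p in enumerate(s.decile_proportions, start=1)}
        )
        rows.append(row)
    return pd.DataFrame(rows)
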