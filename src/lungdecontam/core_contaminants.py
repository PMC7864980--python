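"""Methodological core microbiota of the negative controls.

Each DNA-extraction kit carries its own reagent contaminants.  An OTU is
"core" for a kit when it reaches the abundance cutoff (default 0.001%
relative abundance, ``>=``) in at least the frequency-cutoff fraction of
that kit's controls (default 40%, i.e. at least two of five controls,
computed as a ceiling).  Singletons are removed from the pooled control
table before any per-kit subsetting — stated explicitly because the order
changes sample totals.  The per-kit core sets are then partitioned into the
seven nonempty kit subsets (the Venn regions), each annotated with the
per-kit sum of the member OTUs' mean relative abundances; abundance sums
are per-kit and deliberately do not add up to 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import OtuTable, Parameters


@dataclass
class CoreSet:
    """Core-contaminant OTUs of one extraction kit's controls."""

    kit: str
    otu_ids: set[str]
    mean_abundance: pd.Series  # mean relative abundance across ALL the kit's controls
    n_controls: int
    min_controls_required: int
    #: OTUs reaching the abundance cutoff in >= 1 control but failing the
    #: frequency cutoff (the "non-core" statistic).
    non_core_otu_ids: set[str] = field(default_factory=set)


@dataclass
class VennPartition:
    """Exact-membership partition of the union of per-kit core sets.

    ``regions`` maps each nonempty kit subset (frozenset) to the OTUs whose
    core membership is exactly that subset; ``region_stats`` carries the OTU
    count and, for every kit in the region, the summed mean relative
    abundance of the member OTUs in that kit's controls.  ``non_core`` gives,
    per kit, the count and summed mean abundance of OTUs that reach the
    abundance cutoff in at least one control but fail the frequency cutoff.
    """

    regions: dict[frozenset, set[str]]
    region_stats: pd.DataFrame
    non_core: pd.DataFrame


def present(rel_abundance: float, cutoff: float) -> bool:
    """Presence call: relative abundance >= cutoff (inclusive boundary)."""
    if not 0 <= rel_abundance <= 1:
        raise ValueError("relative abundance must lie in [0, 1]")
    return rel_abundance >= cutoff


def core_set(controls_table: OtuTable, kit: str,
             params: Parameters | None = None) -> CoreSet:
    """Core OTUs of one kit's controls.

    ``controls_table`` should already be singleton-free (apply
    ``remove_singletons`` to the pooled control table first).  Presence is
    evaluated per control on relative abundances; the frequency threshold is
    ``ceil(core_frequency_cutoff * n_controls)``.  Mean relative abundance is
    averaged over all the kit's controls, zeros included.
    """
    params = params or Parameters()
    sub = controls_table.subset(extraction_kit=kit, sample_type="control")
    if sub.n_samples == 0:
        raise ValueError(f"no controls for extraction kit {kit!r}")
    rel = sub.relative_abundances()
    n = sub.n_samples
    need = math.ceil(params.core_frequency_cutoff * n)
    hits = (rel >= params.core_abundance_cutoff).sum(axis=0)
    members = set(hits.index[hits >= need])
    non_core = set(hits.index[(hits >= 1) & (hits < need)])
    return CoreSet(
        kit=kit,
        otu_ids=members,
        mean_abundance=rel.mean(axis=0),
        n_controls=n,
        min_controls_required=need,
        non_core_otu_ids=non_core,
    )


def venn_partition(core_sets: list[CoreSet]) -> VennPartition:
    """Classify every core OTU by its exact kit-membership subset."""
    if len(core_sets) < 2:
        raise ValueError("venn_partition needs core sets from at least 2 kits")
    kits = [cs.kit for cs in core_sets]
    by_kit = {cs.kit: cs for cs in core_sets}
    universe = set().union(*(cs.otu_ids for cs in core_sets))
    regions: dict[frozenset, set[str]] = {}
    for otu in universe:
        member = frozenset(k for k in kits if otu in by_kit[k].otu_ids)
        regions.setdefault(member, set()).add(otu)

    rows = []
    # deterministic region order: by size descending then kit names
    all_regions = sorted(regions, key=lambda r: (-len(r), tuple(sorted(r))))
    for region in all_regions:
        otus = regions[region]
        row = {"region": "&".join(sorted(region)), "otu_count": len(otus)}
        for k in kits:
            if k in region:
                row[f"abundance_{k}"] = float(
                    by_kit[k].mean_abundance.reindex(sorted(otus)).fillna(0).sum()
                )
            else:
                row[f"abundance_{k}"] = np.nan
        rows.append(row)
    region_stats = pd.DataFrame(
        rows, columns=["region", "otu_count"] + [f"abundance_{k}" for k in kits]
    )

    nc_rows = []
    for cs in core_sets:
        nc_rows.append(
            {
                "kit": cs.kit,
                "otu_count": len(cs.non_core_otu_ids),
                "abundance": float(
                    cs.mean_abundance.reindex(sorted(cs.non_core_otu_ids))
                    .fillna(0)
                    .sum()
                ),
            }
        )
    non_core = pd.DataFrame(nc_rows, columns=["kit", "otu_count", "abundance"])
    return VennPartition(regions=regions, region_stats=region_stats,
                         non_core=non_core)


def genus_profile(otu_set: set[str], controls_table: OtuTable,
                  kits: list[str] | None = None) -> pd.DataFrame:
    """Per-genus mean relative abundance of a Venn region or core set.

    Members are agglomerated by genus; for every kit the per-genus value is
    the sum over member OTUs of their mean relative abundance across that
    kit's controls.  Rows are ordered by descending overall abundance, ties
    broken alphabetically.
    """
    if kits is None:
        kits = sorted(controls_table.meta["extraction_kit"].unique())
    if not otu_set:
        return pd.DataFrame(columns=["genus"] + [f"abundance_{k}" for k in kits])
    genera = controls_table.taxonomy.loc[sorted(otu_set), "genus"]
    per_kit = {}
    for kit in kits:
        sub = controls_table.subset(extraction_kit=kit, sample_type="control")
        mean_rel = sub.relative_abundances().mean(axis=0)
        per_kit[f"abundance_{kit}"] = (
            mean_rel.reindex(genera.index).fillna(0).groupby(genera).sum()
        )
    out = pd.DataFrame(per_kit)
    overall = out.sum(axis=1)
    out = out.loc[sorted(out.index, key=lambda g: (-overall[g], g))]
    return out.rename_axis("genus").reset_index()
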