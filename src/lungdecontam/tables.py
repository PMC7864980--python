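"""Core data model for 16S OTU count tables.

An :class:`OtuTable` couples a samples-by-OTUs integer count matrix with a
six-rank taxonomy table and per-sample metadata (patient, tissue type,
DNA-extraction kit, replicate).  Samples are joined to metadata by sample
identity, never by position, so reordered input files cannot silently
mis-assign rows.  Counts are always integers; relative abundances are derived
views computed on demand and never stored back into the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

#: Fixed taxonomic ranks, mothur/SILVA six-level output, shallow to deep.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

SAMPLE_TYPES: tuple[str, ...] = ("cancerous", "healthy", "control")
EXTRACTION_KITS: tuple[str, ...] = ("Blood", "Microbial", "Powersoil")

UNCLASSIFIED = "unclassified"


class TableValidationError(ValueError):
    """A table violated a structural invariant (shapes, signs, joins)."""


class ZeroTotalSampleError(ValueError):
    """A sample with zero total reads reached an operation that needs totals."""


def pad_lineage(labels: Iterable[str]) -> tuple[str, ...]:
    """Normalise a lineage to exactly six ranks.

    Deeper strings are truncated; shallower ones are padded following the
    mothur convention: the deepest assigned label gains an ``_unclassified``
    suffix which is then repeated (``Xanthobacteraceae`` at family ->
    ``Xanthobacteraceae_unclassified`` at genus).
    """
    labs = [str(x).strip() for x in labels]
    labs = [x for x in labs if x][: len(RANKS)]
    if not labs:
        labs = [UNCLASSIFIED]
    while len(labs) < len(RANKS):
        last = labs[-1]
        if last == UNCLASSIFIED or last.endswith("_" + UNCLASSIFIED):
            labs.append(last)
        else:
            labs.append(last + "_" + UNCLASSIFIED)
    return tuple(labs)


@dataclass(frozen=True)
class Taxonomy:
    """One OTU's lineage as an ordered (rank, label) sequence over :data:`RANKS`."""

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = tuple(r for r, _ in self.ranks)
        if names != RANKS:
            raise TableValidationError(f"taxonomy ranks must be {RANKS}, got {names}")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "Taxonomy":
        return cls(tuple(zip(RANKS, pad_lineage(labels))))

    def label(self, rank: str) -> str:
        for r, lab in self.ranks:
            if r == rank:
                return lab
        raise KeyError(rank)

    @property
    def genus(self) -> str:
        return self.ranks[-1][1]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample study metadata."""

    sample_id: str
    patient_id: str
    sample_type: str
    extraction_kit: str
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise TableValidationError(
                f"sample {self.sample_id!r}: sample_type {self.sample_type!r} "
                f"not in {SAMPLE_TYPES}"
            )
        if self.extraction_kit not in EXTRACTION_KITS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: extraction_kit {self.extraction_kit!r} "
                f"not in {EXTRACTION_KITS}"
            )
        if self.replicate < 0:
            raise TableValidationError(
                f"sample {self.sample_id!r}: replicate must be nonnegative"
            )


META_COLUMNS = ("patient_id", "sample_type", "extraction_kit", "replicate")


def meta_frame(metas: Iterable[SampleMeta]) -> pd.DataFrame:
    """Assemble a metadata DataFrame (indexed by sample_id) from records."""
    rows = list(metas)
    ids = [m.sample_id for m in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableValidationError(f"duplicate sample_id(s): {dupes}")
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in rows],
            "sample_type": [m.sample_type for m in rows],
            "extraction_kit": [m.extraction_kit for m in rows],
            "replicate": [int(m.replicate) for m in rows],
        },
        index=pd.Index(ids, name="sample_id"),
    )


def taxonomy_frame(taxa: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Assemble a taxonomy DataFrame (indexed by otu_id, columns RANKS)."""
    recs = {otu: pad_lineage(lineage) for otu, lineage in taxa.items()}
    return pd.DataFrame.from_dict(recs, orient="index", columns=list(RANKS)).rename_axis(
        "otu_id"
    )


@dataclass
class Parameters:
    """Tunable analysis parameters.

    ratio_threshold
        An OTU present in a patient's negative control is kept only when its
        relative abundance in *both* paired tissues is strictly greater than
        ``ratio_threshold`` times its relative abundance in the control.
    core_abundance_cutoff
        Minimum per-control relative abundance (default 1e-5, i.e. 0.001%)
        for an OTU to count as present when computing core contaminants.
    core_frequency_cutoff
        Fraction of a kit's controls an OTU must be present in to be "core"
        (default 0.40, i.e. at least two of five controls).
    permutations
        Permutation count for the one-way PERMANOVA (ADONIS) test.
    alpha
        Significance threshold used in reports.
    """

    ratio_threshold: float = 1000.0
    core_abundance_cutoff: float = 1e-5
    core_frequency_cutoff: float = 0.40
    permutations: int = 5000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if self.core_abundance_cutoff <= 0:
            raise ValueError("core_abundance_cutoff must be > 0")
        if not 0 < self.core_frequency_cutoff <= 1:
            raise ValueError("core_frequency_cutoff must be in (0, 1]")
        if self.permutations <= 0:
            raise ValueError("permutations must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class OtuTable:
    """Sample x OTU count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Nonnegative integer DataFrame; index = sample ids, columns = OTU ids.
    taxonomy
        DataFrame indexed by OTU id with the six rank columns; must cover
        every OTU in ``counts`` (extra entries are dropped on alignment).
    meta
        Optional DataFrame indexed by sample id with columns
        ``patient_id, sample_type, extraction_kit, replicate``; must cover
        every sample in ``counts``.  May be ``None`` for bare count tables
        (e.g. spike-in replicates scored without study metadata).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise TableValidationError("duplicate sample ids in counts")
        if c.columns.has_duplicates:
            raise TableValidationError("duplicate OTU ids in counts")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise TableValidationError("counts must be integers")
            c = c.astype(np.int64)
        if arr.size and (c.to_numpy() < 0).any():
            raise TableValidationError("counts must be nonnegative")
        self.counts = c

        missing = [o for o in c.columns if o not in self.taxonomy.index]
        if missing:
            raise TableValidationError(f"OTUs without taxonomy: {missing[:5]}")
        tax = self.taxonomy.loc[list(c.columns), list(RANKS)]
        self.taxonomy = tax

        if self.meta is not None:
            lost = [s for s in c.index if s not in self.meta.index]
            if lost:
                raise TableValidationError(f"samples without metadata: {lost[:5]}")
            m = self.meta.loc[list(c.index), list(META_COLUMNS)].copy()
            bad_t = sorted(set(m["sample_type"]) - set(SAMPLE_TYPES))
            if bad_t:
                raise TableValidationError(
                    f"unknown sample_type {bad_t}; allowed: {list(SAMPLE_TYPES)}"
                )
            bad_k = sorted(set(m["extraction_kit"]) - set(EXTRACTION_KITS))
            if bad_k:
                raise TableValidationError(
                    f"unknown extraction_kit {bad_k}; allowed: {list(EXTRACTION_KITS)}"
                )
            m["replicate"] = m["replicate"].astype(int)
            self.meta = m

    # -- basic accessors ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def copy(self) -> "OtuTable":
        return OtuTable(
            self.counts.copy(),
            self.taxonomy.copy(),
            None if self.meta is None else self.meta.copy(),
        )

    # -- elementary transformations ---------------------------------------

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample proportions (each row sums to 1).

        Raises
        ------
        ZeroTotalSampleError
            If any sample has zero total reads; an empty sample signals a
            failed library, never a silently-NaN row.
        """
        tot = self.totals()
        empty = tot.index[tot == 0].tolist()
        if empty:
            raise ZeroTotalSampleError(
                f"sample(s) with zero total reads: {empty}"
            )
        return self.counts.div(tot, axis=0)

    def agglomerate_by_rank(self, rank: str) -> "OtuTable":
        """Sum counts of OTUs sharing the same label at ``rank``.

        The returned table is keyed by taxon label at that rank; per-sample
        totals are conserved exactly.  Ranks deeper than ``rank`` in the
        output taxonomy are set to the shared label's ``_unclassified``
        padding (they are no longer meaningful after pooling).
        """
        if rank not in RANKS:
            raise KeyError(f"rank must be one of {RANKS}, got {rank!r}")
        labels = self.taxonomy[rank]
        agg = self.counts.T.groupby(labels.loc[self.counts.columns]).sum().T
        depth = RANKS.index(rank)
        tax_rows = {}
        for label in agg.columns:
            members = labels.index[labels == label]
            lineage = list(self.taxonomy.loc[members[0], list(RANKS[:depth])])
            lineage.append(label)
            tax_rows[label] = pad_lineage(lineage)
        tax = pd.DataFrame.from_dict(tax_rows, orient="index", columns=list(RANKS))
        return OtuTable(agg, tax.rename_axis("otu_id"), self.meta)

    def remove_singletons(self) -> "OtuTable":
        """Drop OTUs whose total count across all samples equals exactly 1."""
        keep = self.counts.columns[self.counts.sum(axis=0) != 1]
        return OtuTable(
            self.counts[list(keep)].copy(),
            self.taxonomy.loc[list(keep)].copy(),
            None if self.meta is None else self.meta.copy(),
        )

    def subset(
        self,
        predicate: Callable[[pd.Series], bool] | None = None,
        *,
        drop_empty_otus: bool = False,
        **field_filters,
    ) -> "OtuTable":
        """Select samples by a metadata predicate or by field equality.

        ``subset(sample_type="control", extraction_kit="Blood")`` keeps the
        Blood-kit controls; ``subset(lambda m: m.replicate > 0)`` applies an
        arbitrary predicate to each metadata row.  An empty result is
        returned, not an error.  All-zero OTU columns are kept unless
        ``drop_empty_otus`` is set.
        """
        if self.meta is None:
            raise TableValidationError("subset requires sample metadata")
        mask = pd.Series(True, index=self.counts.index)
        for col, val in field_filters.items():
            if col not in META_COLUMNS:
                raise KeyError(f"unknown metadata field {col!r}")
            mask &= self.meta[col] == val
        if predicate is not None:
            mask &= self.meta.apply(predicate, axis=1).astype(bool)
        keep = list(self.counts.index[mask])
        counts = self.counts.loc[keep].copy()
        if drop_empty_otus:
            counts = counts.loc[:, counts.sum(axis=0) > 0]
        return OtuTable(counts, self.taxonomy.loc[list(counts.columns)].copy(),
                        self.meta.loc[keep].copy())


# Functional aliases matching the operation names used throughout reports.

def relative_abundances(table: OtuTable) -> pd.DataFrame:
    return table.relative_abundances()


def agglomerate_by_rank(table: OtuTable, rank: str) -> OtuTable:
    return table.agglomerate_by_rank(rank)


def remove_singletons(table: OtuTable) -> OtuTable:
    return table.remove_singletons()
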