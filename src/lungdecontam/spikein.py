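"""Mock-community spike-in recovery scoring.

A commercial even mixture of 20 bacterial strains (5% each, shipped as
whole cells or purified genomic DNA) is spiked into tissue homogenates;
recovery is scored on the sequenced OTU tables after agglomerating OTUs at
the genus rank.  Because the 20-strain panel contains two *Staphylococcus*
and two *Streptococcus* strains, it collapses to 18 distinct genera, and the
primary detection percentage uses that genus denominator (the per-strain
denominator of 20 is reported alongside).  Per-replicate percentages are
averaged arithmetically across the replicates.

The packaged reference panel (``data/mock_panel.tsv``) lists the 20-strain
even mix; it is an editable TSV (columns strain, genus, proportion) so a
corrected panel can be dropped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tables import OtuTable, ZeroTotalSampleError

#: Genera found naturally in unspiked tissue homogenates in the validation
#: study; they overlap the panel, so background screening treats them apart.
NATURAL_GENERA: tuple[str, ...] = ("Acinetobacter", "Staphylococcus")

#: Stated spike loads: whole cells per gram of tissue; genomes per sample.
WHOLE_CELLS_PER_GRAM = 2.5e3
GENOMES_PER_SAMPLE = 1.25e3


@dataclass(frozen=True)
class MockPanel:
    """The reference spike-in community."""

    strains: tuple[tuple[str, str, float], ...]  # (strain, genus, proportion)
    panel_kind: str = "whole_cell"  # or "genomic"

    def __post_init__(self) -> None:
        if self.panel_kind not in ("whole_cell", "genomic"):
            raise ValueError("panel_kind must be 'whole_cell' or 'genomic'")
        props = [p for _, _, p in self.strains]
        if self.strains and abs(sum(props) - 1.0) > 1e-6:
            raise ValueError("panel proportions must sum to 1")

    @classmethod
    def from_tsv(cls, path, panel_kind: str = "whole_cell") -> "MockPanel":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("strain", "genus", "proportion") if c not in df.columns]
        if missing:
            raise ValueError(f"panel file missing column(s) {missing}")
        return cls(
            tuple(
                (str(r.strain), str(r.genus), float(r.proportion))
                for r in df.itertuples()
            ),
            panel_kind=panel_kind,
        )

    @classmethod
    def default(cls, panel_kind: str = "whole_cell") -> "MockPanel":
        """The packaged 20-strain even-mix reference panel."""
        ref = resources.files("lungdecontam").joinpath("data/mock_panel.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, panel_kind=panel_kind)

    @property
    def strain_names(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.strains)

    @property
    def distinct_genera(self) -> frozenset:
        return collapse_to_genera(self)

    def genus_of(self, strain: str) -> str:
        for s, g, _ in self.strains:
            if s == strain:
                return g
        raise KeyError(strain)


def collapse_to_genera(panel: MockPanel) -> frozenset:
    """Distinct genus labels after collapsing congeneric strains (idempotent)."""
    return frozenset(g for _, g, _ in panel.strains)


@dataclass
class DetectionReport:
    """Per-replicate genus detection outcomes and summary percentages."""

    detected: pd.DataFrame            # replicates x genera, boolean
    percent_per_replicate: pd.Series  # on the distinct-genus denominator
    mean_percent: float               # arithmetic mean across replicates
    mean_percent_strains: float       # same, on the 20-strain denominator
    never_detected: list[str]         # genera missed in every replicate
    partially_detected: list[str]     # genera missed in some but not all
    strains_credited: list[str]       # strains whose genus was seen in >= 1 replicate
    background_excluded: list[str]    # genera discounted due to background presence


def detect(
    table: OtuTable,
    panel: MockPanel,
    background: OtuTable | None = None,
    min_reads: int = 1,
    *,
    natural_genera: tuple[str, ...] = NATURAL_GENERA,
    strict_background: bool = False,
) -> DetectionReport:
    """Score mock-community recovery on spiked-replicate rows.

    A genus counts as detected in a replicate when its genus-agglomerated
    read count reaches ``min_reads`` (default 1 — any read is detection; the
    protocol states no threshold).  When an unspiked ``background`` table is
    supplied, genera found in the background cannot be credited to the
    spike — except the known naturally occurring genera, which stay credited
    unless ``strict_background`` is set.
    """
    totals = table.totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ZeroTotalSampleError(f"replicate(s) with zero total reads: {empty}")
    genera = sorted(panel.distinct_genera)
    by_genus = table.agglomerate_by_rank("genus").counts
    counts = by_genus.reindex(columns=genera, fill_value=0)

    excluded: list[str] = []
    if background is not None:
        bg = background.agglomerate_by_rank("genus").counts
        bg_present = {g for g in genera if g in bg.columns and bg[g].sum() > 0}
        for g in sorted(bg_present):
            if g in natural_genera and not strict_background:
                continue
            excluded.append(g)

    detected = counts >= min_reads
    for g in excluded:
        detected[g] = False

    denom = len(genera)
    if denom == 0:
        raise ValueError("cannot score detection against an empty panel")
    percent = detected.sum(axis=1) / denom * 100.0
    n_strains = len(panel.strains)
    strain_hits = [
        s for s, g, _ in panel.strains if g in detected.columns and detected[g].any()
    ]
    per_rep_strain = pd.Series(
        {
            rep: sum(detected.loc[rep, g] for _, g, _ in panel.strains) / n_strains * 100.0
            for rep in detected.index
        }
    ) if n_strains else pd.Series(dtype=float)

    col_all = detected.all(axis=0)
    col_any = detected.any(axis=0)
    return DetectionReport(
        detected=detected,
        percent_per_replicate=percent,
        mean_percent=float(percent.mean()) if len(percent) else float("nan"),
        mean_percent_strains=float(per_rep_strain.mean()) if len(per_rep_strain) else float("nan"),
        never_detected=sorted(col_any.index[~col_any]),
        partially_detected=sorted(col_any.index[col_any & ~col_all]),
        strains_credited=strain_hits,
        background_excluded=excluded,
    )


def spike_load(kind: str, tissue_mass_g: float) -> float:
    """Expected spiked organisms (whole_cell, per gram) or genomes (genomic, flat)."""
    if tissue_mass_g <= 0:
        raise ValueError("tissue mass must be positive")
    if kind == "whole_cell":
        return WHOLE_CELLS_PER_GRAM * tissue_mass_g
    if kind == "genomic":
        return GENOMES_PER_SAMPLE
    raise ValueError("kind must be 'whole_cell' or 'genomic'")
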