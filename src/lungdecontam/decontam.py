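"""Single-control, ratio-based contaminant-OTU removal.

Each patient contributes a (cancerous, healthy, control) triplet processed
with one DNA-extraction kit; the negative control is an empty tube carried
through every wet-lab step, so it accumulates exactly the method's
contaminants.  Because controls have far lower richness than tissues, a
contaminant's *relative* abundance is much higher in the control than in the
tissues.  The removal rule exploits this: an OTU present in the control is
kept only when its relative abundance in **both** paired tissues is strictly
greater than ``ratio_threshold`` (default 1000) times its relative abundance
in the control; otherwise it is zeroed out of both tissues at once, so that
no artificial intra-patient variation is introduced.  On the canonical scale
of a 20,000-read control, a single-OTU tissue at 100% relative abundance
tolerates at most 19 control reads (0.095%) before the whole OTU is removed.

The control row itself is never filtered, and removal zeroes counts rather
than deleting columns so that downstream diagnostics operate on a stable OTU
universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable, Parameters, ZeroTotalSampleError


@dataclass(frozen=True)
class PatientTriplet:
    """The (cancerous, healthy, control) sample trio of one patient and kit."""

    patient_id: str
    cancerous_sample_id: str
    healthy_sample_id: str
    control_sample_id: str
    extraction_kit: str = ""

    @property
    def tissue_ids(self) -> tuple[str, str]:
        return (self.cancerous_sample_id, self.healthy_sample_id)


@dataclass
class DecontamResult:
    """Outcome of ratio-based removal for one patient triplet.

    ``removed_otus`` and ``kept_control_otus`` partition the control-present
    OTUs; OTUs absent from the control are never candidates for removal.
    ``filtered_table`` holds the full input table with removed OTUs zeroed in
    both tissue rows (the control row is untouched).
    """

    patient_id: str
    removed_otus: set[str]
    kept_control_otus: set[str]
    filtered_table: OtuTable
    percent_remaining: dict[str, float]
    triplet: PatientTriplet | None = None
    decisions: pd.DataFrame | None = field(default=None, repr=False)


def find_triplets(table: OtuTable) -> list[PatientTriplet]:
    """Group the table's samples into complete patient/kit triplets.

    Every (patient, kit) group must contain exactly one sample of each type;
    incomplete or ambiguous groups raise.
    """
    if table.meta is None:
        raise ValueError("find_triplets requires sample metadata")
    triplets = []
    for (patient, kit), grp in table.meta.groupby(["patient_id", "extraction_kit"],
                                                  sort=True):
        slots = {}
        for stype in ("cancerous", "healthy", "control"):
            ids = list(grp.index[grp["sample_type"] == stype])
            if len(ids) != 1:
                raise ValueError(
                    f"patient {patient!r} / kit {kit!r}: expected exactly one "
                    f"{stype} sample, found {len(ids)}"
                )
            slots[stype] = ids[0]
        triplets.append(
            PatientTriplet(patient, slots["cancerous"], slots["healthy"],
                           slots["control"], kit)
        )
    return triplets


def keep_decision(c_rel: float, h_rel: float, k_rel: float, ratio: float) -> bool:
    """Keep/remove predicate for one control-present OTU.

    Keep iff the OTU's relative abundance exceeds ``ratio`` times its control
    relative abundance in the cancerous AND the healthy tissue (strict
    inequality).  Only OTUs actually present in the control (``k_rel > 0``)
    are tested.
    """
    if k_rel <= 0:
        raise ValueError("keep_decision applies only to control-present OTUs (k_rel > 0)")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    bar = ratio * k_rel
    return (c_rel > bar) and (h_rel > bar)


def percent_remaining_otus(before, after) -> float:
    """Percentage of observed (count > 0) OTUs surviving removal in one sample."""
    before = np.asarray(before)
    after = np.asarray(after)
    n_before = int((before > 0).sum())
    if n_before == 0:
        raise ZeroTotalSampleError("no observed OTUs before removal")
    n_after = int((after > 0).sum())
    return 100.0 * n_after / n_before


def decontaminate_patient(
    table: OtuTable, triplet: PatientTriplet, params: Parameters | None = None
) -> DecontamResult:
    """Apply the ratio rule to one patient's paired tissues.

    Relative abundances are computed per sample independently, before any
    removal.  Every OTU with a positive control count is tested with
    :func:`keep_decision`; a removed OTU is zeroed in both tissue rows.
    OTUs present in the control but absent from both tissues are still
    recorded in ``removed_otus`` (keeping the partition invariant simple)
    even though zeroing them has no observable effect.
    """
    params = params or Parameters()
    ids = [triplet.cancerous_sample_id, triplet.healthy_sample_id,
           triplet.control_sample_id]
    for sid in ids:
        if sid not in table.counts.index:
            raise KeyError(f"sample {sid!r} not in table")
        if int(table.counts.loc[sid].sum()) == 0:
            raise ZeroTotalSampleError(
                f"sample {sid!r} has zero total reads; cannot apply the ratio rule"
            )
    tot = table.counts.loc[ids].sum(axis=1)
    rel = table.counts.loc[ids].div(tot, axis=0)
    c_rel = rel.loc[triplet.cancerous_sample_id]
    h_rel = rel.loc[triplet.healthy_sample_id]
    k_rel = rel.loc[triplet.control_sample_id]

    control_present = [o for o in table.otu_ids if k_rel[o] > 0]
    removed, kept = set(), set()
    rows = []
    for otu in control_present:
        keep = keep_decision(float(c_rel[otu]), float(h_rel[otu]),
                             float(k_rel[otu]), params.ratio_threshold)
        (kept if keep else removed).add(otu)
        rows.append((otu, float(c_rel[otu]), float(h_rel[otu]), float(k_rel[otu]),
                     "keep" if keep else "remove"))
    decisions = pd.DataFrame(
        rows, columns=["otu_id", "c_rel", "h_rel", "k_rel", "decision"]
    )

    filtered = table.copy()
    if removed:
        cols = [o for o in table.otu_ids if o in removed]
        filtered.counts.loc[list(triplet.tissue_ids), cols] = 0

    percent = {}
    for sid in triplet.tissue_ids:
        percent[sid] = percent_remaining_otus(
            table.counts.loc[sid].to_numpy(), filtered.counts.loc[sid].to_numpy()
        )

    return DecontamResult(
        patient_id=triplet.patient_id,
        removed_otus=removed,
        kept_control_otus=kept,
        filtered_table=filtered,
        percent_remaining=percent,
        triplet=triplet,
        decisions=decisions,
    )


def decontaminate_all(
    table: OtuTable, params: Parameters | None = None
) -> tuple[OtuTable, list[DecontamResult]]:
    """Run :func:`decontaminate_patient` over every triplet in the study.

    Returns one table with all patients' removals applied (each triplet only
    touches its own two tissue rows, so the per-patient filters commute) plus
    the per-patient results.
    """
    triplets = find_triplets(table)
    merged = table.copy()
    results = []
    for trip in triplets:
        res = decontaminate_patient(table, trip, params)
        results.append(res)
        for sid in trip.tissue_ids:
            merged.counts.loc[sid] = res.filtered_table.counts.loc[sid]
    return merged, results


def control_correlation(
    table: OtuTable, sample_id: str, control_id: str, *, use_relative: bool = True
) -> tuple[float, float, float]:
    """Pearson correlation between a tissue and its control, before removal.

    Vectors span the full OTU universe of the table (zeros included) and are
    per-sample relative abundances by default (``use_relative=False`` gives
    the raw-count variant).  Shapiro-Wilk p-values for both vectors are
    returned as diagnostics only; microbiome profiles are zero-inflated and
    essentially never normal, and the analysis proceeds with Pearson anyway.
    """
    rows = table.counts.loc[[sample_id, control_id]]
    if use_relative:
        tot = rows.sum(axis=1)
        empty = tot.index[tot == 0].tolist()
        if empty:
            raise ZeroTotalSampleError(f"sample(s) with zero total reads: {empty}")
        rows = rows.div(tot, axis=0)
    x = rows.loc[sample_id].to_numpy(dtype=float)
    y = rows.loc[control_id].to_numpy(dtype=float)
    for name, v in ((sample_id, x), (control_id, y)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"sample {name!r} has a constant abundance vector; "
                "Pearson correlation is undefined"
            )
    r = float(stats.pearsonr(x, y).statistic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on heavily tied vectors
        p_x = float(stats.shapiro(x).pvalue)
        p_y = float(stats.shapiro(y).pvalue)
    return r, p_x, p_y
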