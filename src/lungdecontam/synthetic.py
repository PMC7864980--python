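"""Synthetic low-biomass lung-microbiota studies with ground truth.

The generator emulates the validation study's design: per patient and
DNA-extraction kit, a (cancerous, healthy, control) triplet.  Negative
controls are empty tubes, so their reads come exclusively from a kit-borne
contaminant profile — a core contaminant pool shared by all kits plus
kit-specific taxa — while tissues mix an endogenous lung community with that
same contaminant profile at a configurable fraction.  Counts are drawn
multinomially at a fixed sequencing depth, so every sample row totals
exactly ``depth`` reads.  Every taxon carries a ground-truth label
(endogenous / core contaminant / kit contaminant), which makes
sensitivity/specificity evaluation of the removal rule exact.

An optional ``leakage`` parameter lets endogenous reads bleed into controls
to stress-test cross-contamination; by default controls are pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .decontam import DecontamResult
from .tables import (
    EXTRACTION_KITS,
    OtuTable,
    RANKS,
    SampleMeta,
    meta_frame,
)

#: Contaminant genera reported from negative controls in low-biomass work;
#: used to label synthetic contaminant taxa so reports read naturally.
CONTAMINANT_GENERA = (
    "Brevundimonas", "Cutibacterium", "Micrococcus", "Nitrobacter",
    "Ralstonia", "Staphylococcus", "Xanthobacteraceae_unclassified",
    "Sphingomonas", "Methylobacterium", "Bradyrhizobium", "Delftia",
    "Stenotrophomonas", "Acinetobacter", "Pseudomonas", "Burkholderia",
    "Herbaspirillum", "Phyllobacterium", "Comamonas", "Afipia", "Curvibacter",
)

#: Genera typical of the (low-biomass) human airway community.
ENDOGENOUS_GENERA = (
    "Streptococcus", "Prevotella", "Veillonella", "Haemophilus",
    "Fusobacterium", "Neisseria", "Rothia", "Porphyromonas", "Gemella",
    "Actinomyces", "Leptotrichia", "Campylobacter", "Capnocytophaga",
    "Selenomonas", "Megasphaera", "Oribacterium", "Atopobium", "Granulicatella",
)


@dataclass
class SynthConfig:
    """Study-design parameters of the generator.

    Defaults echo the validation study's scale: 5 patients, all three kits
    (45 samples, 15 of them controls), 20,000 reads per sample, 10 core
    contaminants shared by every kit and ~30 kit-specific contaminants per
    kit, with 5% of a tissue's reads expected to come from the contaminant
    profile.
    """

    n_patients: int = 5
    kits: tuple[str, ...] = EXTRACTION_KITS
    depth: int = 20_000
    n_endogenous_taxa: int = 40
    n_core_contaminants: int = 10
    n_kit_specific_contaminants: int = 30
    contaminant_fraction_in_tissue: float = 0.05
    tissue_dirichlet_alpha: float = 0.5
    cancer_vs_healthy_perturbation: float = 0.5
    leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.depth < 1:
            raise ValueError("n_patients and depth must be positive")
        if not self.kits or not set(self.kits) <= set(EXTRACTION_KITS):
            raise ValueError(f"kits must be a nonempty subset of {EXTRACTION_KITS}")
        for name in ("contaminant_fraction_in_tissue", "leakage"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.tissue_dirichlet_alpha <= 0:
            raise ValueError("tissue_dirichlet_alpha must be > 0")
        if self.cancer_vs_healthy_perturbation < 0:
            raise ValueError("cancer_vs_healthy_perturbation must be >= 0")
        if min(self.n_endogenous_taxa, self.n_core_contaminants,
               self.n_kit_specific_contaminants) < 1:
            raise ValueError("taxon pool sizes must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth for every taxon and sample."""

    labels: pd.Series                 # otu_id -> endogenous | core_contaminant | kit_contaminant:<kit>
    mixture_weights: pd.DataFrame     # samples x taxa expected proportions
    config: SynthConfig

    def contaminant_otus(self) -> set[str]:
        return set(self.labels.index[self.labels != "endogenous"])

    def endogenous_otus(self) -> set[str]:
        return set(self.labels.index[self.labels == "endogenous"])


def _genus_pool(base: tuple[str, ...], n: int, tag: str) -> list[str]:
    """Cycle through plausible genus labels, suffixing extras to stay unique."""
    out = []
    for i in range(n):
        g = base[i % len(base)]
        out.append(g if i < len(base) else f"{g}_{tag}{i // len(base)}")
    return out


def _taxonomy_rows(otu_ids, genera) -> pd.DataFrame:
    rows = {
        otu: ("Bacteria", "SynthPhylum", "SynthClass", "SynthOrder",
              "SynthFamily", genus)
        for otu, genus in zip(otu_ids, genera)
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(RANKS)).rename_axis("otu_id")


def simulate_study(config: SynthConfig) -> tuple[OtuTable, GroundTruth]:
    """Draw one complete synthetic study (table + ground truth)."""
    rng = np.random.default_rng(config.seed)
    kits = tuple(config.kits)

    otu_ids: list[str] = []
    genera: list[str] = []
    labels: dict[str, str] = {}

    def add_taxa(n: int, label: str, genus_pool: list[str]) -> list[str]:
        start = len(otu_ids)
        ids = [f"Otu{start + i + 1:04d}" for i in range(n)]
        otu_ids.extend(ids)
        genera.extend(genus_pool)
        for o in ids:
            labels[o] = label
        return ids

    endo_ids = add_taxa(
        config.n_endogenous_taxa, "endogenous",
        _genus_pool(ENDOGENOUS_GENERA, config.n_endogenous_taxa, "e"),
    )
    core_ids = add_taxa(
        config.n_core_contaminants, "core_contaminant",
        _genus_pool(CONTAMINANT_GENERA[:7], config.n_core_contaminants, "c"),
    )
    kit_ids: dict[str, list[str]] = {}
    for kit in kits:
        kit_ids[kit] = add_taxa(
            config.n_kit_specific_contaminants, f"kit_contaminant:{kit}",
            [f"{g}_{kit[:2]}" for g in _genus_pool(
                CONTAMINANT_GENERA[7:], config.n_kit_specific_contaminants, "k")],
        )

    n_taxa = len(otu_ids)
    idx = {o: i for i, o in enumerate(otu_ids)}

    # Per-kit contaminant profile over core + kit-specific taxa.  Core taxa
    # get a larger Dirichlet weight so the shared pool reliably shows up in
    # every kit's controls, as the shared "core microbiota" does in practice.
    kit_profile: dict[str, np.ndarray] = {}
    for kit in kits:
        support = core_ids + kit_ids[kit]
        alpha = np.concatenate([
            np.full(len(core_ids), 2.0),
            np.full(len(kit_ids[kit]), 0.5),
        ])
        w = rng.dirichlet(alpha)
        prof = np.zeros(n_taxa)
        prof[[idx[o] for o in support]] = w
        kit_profile[kit] = prof

    metas, rows, weights = [], {}, {}
    for p in range(1, config.n_patients + 1):
        patient = f"P{p:02d}"
        base = rng.dirichlet(
            np.full(config.n_endogenous_taxa, config.tissue_dirichlet_alpha)
        )
        endo_profiles = {}
        for tissue in ("cancerous", "healthy"):
            pert = base * np.exp(
                rng.normal(0.0, config.cancer_vs_healthy_perturbation,
                           config.n_endogenous_taxa)
            )
            prof = np.zeros(n_taxa)
            prof[[idx[o] for o in endo_ids]] = pert / pert.sum()
            endo_profiles[tissue] = prof
        for kit in kits:
            f = config.contaminant_fraction_in_tissue
            for tissue in ("cancerous", "healthy"):
                sid = f"{patient}_{kit}_{tissue[0].upper()}"
                w = (1 - f) * endo_profiles[tissue] + f * kit_profile[kit]
                rows[sid] = rng.multinomial(config.depth, w)
                weights[sid] = w
                metas.append(SampleMeta(sid, patient, tissue, kit))
            sid = f"{patient}_{kit}_K"
            w = (1 - config.leakage) * kit_profile[kit] \
                + config.leakage * endo_profiles["healthy"]
            rows[sid] = rng.multinomial(config.depth, w)
            weights[sid] = w
            metas.append(SampleMeta(sid, patient, "control", kit))

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=otu_ids)
    counts.index.name = "sample_id"
    table = OtuTable(counts.astype(np.int64), _taxonomy_rows(otu_ids, genera),
                     meta_frame(metas))
    truth = GroundTruth(
        labels=pd.Series(labels, name="label").loc[otu_ids],
        mixture_weights=pd.DataFrame.from_dict(weights, orient="index",
                                               columns=otu_ids),
        config=config,
    )
    return table, truth


def evaluate_decontam(
    result: DecontamResult, truth: GroundTruth
) -> tuple[float | None, float | None]:
    """Sensitivity/specificity of one patient's removal against ground truth.

    Sensitivity: removed contaminant-labelled OTUs over contaminant-labelled
    OTUs observed in the patient's tissues.  Specificity: endogenous OTUs
    observed in the tissues that survived, over endogenous OTUs observed.
    An empty denominator yields ``None`` (undefined), not an error.
    """
    trip = result.triplet
    if trip is None:
        raise ValueError("DecontamResult lacks its triplet; cannot locate tissues")
    before = result.filtered_table.counts  # removed OTUs zeroed; need originals
    # tissue-observed = positive in either tissue *before* removal: an OTU in
    # removed_otus was observed iff it is zeroed now but was positive before;
    # reconstruct from decisions (c_rel/h_rel) plus surviving counts.
    observed: set[str] = set()
    for sid in trip.tissue_ids:
        row = before.loc[sid]
        observed |= set(row.index[row > 0])
    if result.decisions is not None:
        dec = result.decisions
        seen = dec.loc[(dec["c_rel"] > 0) | (dec["h_rel"] > 0), "otu_id"]
        observed |= set(seen)

    contaminants = truth.contaminant_otus() & observed
    endogenous = truth.endogenous_otus() & observed
    sens = (
        len(result.removed_otus & contaminants) / len(contaminants)
        if contaminants else None
    )
    spec = (
        len(endogenous - result.removed_otus) / len(endogenous)
        if endogenous else None
    )
    return sens, spec


def write_study(table: OtuTable, truth: GroundTruth | None, out_dir,
                prefix: str = "study") -> dict[str, Path]:
    """Write the study as ``.shared`` + ``.cons.taxonomy`` + metadata (+ truth) TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "shared": out / f"{prefix}.shared",
        "taxonomy": out / f"{prefix}.cons.taxonomy",
        "metadata": out / f"{prefix}.metadata.tsv",
    }
    io_formats.write_shared(table.counts, paths["shared"])
    io_formats.write_cons_taxonomy(
        table.taxonomy, paths["taxonomy"],
        sizes=table.counts.sum(axis=0).to_dict(),
    )
    io_formats.write_metadata(table.meta, paths["metadata"])
    if truth is not None:
        paths["truth"] = out / f"{prefix}.truth.tsv"
        truth.labels.rename_axis("otu_id").reset_index().to_csv(
            paths["truth"], sep="\t", index=False, lineterminator="\n"
        )
    return paths
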