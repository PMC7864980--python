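"""End-to-end workflow wiring the analysis stages together.

Stage order is fixed: load -> control-association diagnostics (computed
*before* any removal, enforced by the pipeline rather than left to the
caller) -> per-patient ratio-rule decontamination -> alpha diversity with
paired kit comparisons -> Bray-Curtis / PCoA / ADONIS on the controls ->
core-contaminant profiling (on the singleton-free control table) ->
optional spike-in scoring -> report TSVs plus a run log recording versions,
seed and parameters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, core_contaminants, decontam, diversity, io_formats
from .spikein import MockPanel, detect
from .tables import OtuTable, Parameters

log = logging.getLogger("lungdecontam")


@dataclass
class RunConfig:
    """Inputs and knobs of one full pipeline run."""

    shared: str
    taxonomy: str
    metadata: str
    qc: str | None = None
    panel: str | None = None
    params: Parameters = field(default_factory=Parameters)
    out_prefix: str = "run"
    seed: int = 0
    drop_empty_otus: bool = False


def _out(config: RunConfig, suffix: str) -> Path:
    path = Path(f"{config.out_prefix}.{suffix}")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the mapping of outputs written."""
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        table = io_formats.load_study(config.shared, config.taxonomy,
                                      config.metadata)
        log.info("loaded %d samples x %d OTUs", table.n_samples, table.n_otus)

        stage = "decontam"
        triplets = decontam.find_triplets(table)
        diag_rows, removal_frames = [], []
        merged = table.copy()
        for trip in triplets:
            # diagnostics on the unfiltered table (before removal)
            for sid in trip.tissue_ids:
                r, p_s, p_c = decontam.control_correlation(
                    table, sid, trip.control_sample_id
                )
                diag_rows.append(
                    {"sample_id": sid, "patient_id": trip.patient_id,
                     "extraction_kit": trip.extraction_kit,
                     "pearson_r": r, "shapiro_p_sample": p_s,
                     "shapiro_p_control": p_c}
                )
            res = decontam.decontaminate_patient(table, trip, config.params)
            for sid in trip.tissue_ids:
                for row in diag_rows:
                    if row["sample_id"] == sid:
                        row["percent_remaining"] = res.percent_remaining[sid]
            dec = res.decisions.copy()
            dec.insert(0, "patient_id", trip.patient_id)
            dec.insert(1, "extraction_kit", trip.extraction_kit)
            dec["genus"] = table.taxonomy.loc[dec["otu_id"], "genus"].to_numpy()
            removal_frames.append(dec)
            for sid in trip.tissue_ids:
                merged.counts.loc[sid] = res.filtered_table.counts.loc[sid]

        filtered = merged
        if config.drop_empty_otus:
            keep = filtered.counts.columns[filtered.counts.sum(axis=0) > 0]
            filtered = OtuTable(filtered.counts[list(keep)],
                                filtered.taxonomy.loc[list(keep)], filtered.meta)
        outputs["filtered_shared"] = _out(config, "filtered.shared")
        io_formats.write_shared(filtered.counts, outputs["filtered_shared"])
        outputs["removal_report"] = _out(config, "removal.tsv")
        io_formats.write_report(pd.concat(removal_frames, ignore_index=True),
                                outputs["removal_report"])
        outputs["diagnostics"] = _out(config, "diagnostics.tsv")
        io_formats.write_report(pd.DataFrame(diag_rows), outputs["diagnostics"])

        stage = "alpha_diversity"
        alpha = diversity.shannon_per_sample(table)
        alpha_df = table.meta.copy()
        alpha_df["shannon"] = alpha
        outputs["alpha"] = _out(config, "alpha.tsv")
        io_formats.write_report(alpha_df.rename_axis("sample_id").reset_index(),
                                outputs["alpha"])

        # paired kit comparisons within tissue type, paired on patient
        kits = sorted(table.meta["extraction_kit"].unique())
        test_rows = []
        for tissue in ("cancerous", "healthy"):
            sub = alpha_df[alpha_df["sample_type"] == tissue]
            wide = sub.pivot_table(index="patient_id", columns="extraction_kit",
                                   values="shannon")
            for ka, kb in itertools.combinations(kits, 2):
                pair = wide[[ka, kb]].dropna()
                if len(pair) < 3:
                    continue
                try:
                    p_t = diversity.paired_ttest(pair[ka], pair[kb])
                except ValueError:
                    p_t = np.nan
                try:
                    p_w = diversity.paired_wilcoxon(pair[ka], pair[kb])
                except ValueError:
                    p_w = np.nan
                test_rows.append({"tissue": tissue, "kit_a": ka, "kit_b": kb,
                                  "n_pairs": len(pair), "paired_t_p": p_t,
                                  "paired_wilcoxon_p": p_w})
        outputs["alpha_tests"] = _out(config, "alpha_tests.tsv")
        io_formats.write_report(pd.DataFrame(test_rows), outputs["alpha_tests"])

        stage = "beta_diversity"
        controls = table.subset(sample_type="control")
        adonis_rows, coord_frames = [], []
        for weighted in (True, False):
            tag = "weighted" if weighted else "unweighted"
            dm = diversity.bray_curtis(controls, weighted=weighted)
            out_dm = _out(config, f"braycurtis_{tag}.tsv")
            io_formats.write_report(
                pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
                out_dm, index=True,
            )
            outputs[f"braycurtis_{tag}"] = out_dm
            ord_res = diversity.pcoa(dm)
            coords = ord_res.coordinates.iloc[:, :2].copy()
            coords.insert(0, "metric", tag)
            coord_frames.append(coords.rename_axis("sample_id").reset_index())
            ad = diversity.permanova(
                dm, controls.meta["extraction_kit"],
                permutations=config.params.permutations, seed=config.seed,
            )
            adonis_rows.append({"metric": tag, "pseudo_F": ad.pseudo_F,
                                "r_squared": ad.r_squared, "p_value": ad.p_value,
                                "permutations": ad.permutations_used})
        outputs["pcoa"] = _out(config, "pcoa.tsv")
        io_formats.write_report(pd.concat(coord_frames, ignore_index=True),
                                outputs["pcoa"])
        outputs["adonis"] = _out(config, "adonis.tsv")
        io_formats.write_report(pd.DataFrame(adonis_rows), outputs["adonis"])

        stage = "core_contaminants"
        controls_ns = table.remove_singletons().subset(sample_type="control")
        sets = [core_contaminants.core_set(controls_ns, kit, config.params)
                for kit in kits]
        venn = core_contaminants.venn_partition(sets)
        outputs["core_regions"] = _out(config, "core_regions.tsv")
        io_formats.write_report(venn.region_stats, outputs["core_regions"])
        outputs["core_noncore"] = _out(config, "core_noncore.tsv")
        io_formats.write_report(venn.non_core, outputs["core_noncore"])
        shared_region = frozenset(kits)
        shared_otus = venn.regions.get(shared_region, set())
        prof = core_contaminants.genus_profile(shared_otus, controls_ns, kits)
        outputs["core_genus_profile"] = _out(config, "core_genera.tsv")
        io_formats.write_report(prof, outputs["core_genus_profile"])

        stage = "qc"
        if config.qc is not None:
            qc = io_formats.read_qc(config.qc)
            qc = qc.assign(
                dna_ng_per_g=[
                    diversity.dna_yield_per_gram(r.dna_ng_per_ul, r.eluate_ul,
                                                 r.tissue_g)
                    for r in qc.itertuples()
                ]
            )
            outputs["qc"] = _out(config, "qc.tsv")
            io_formats.write_report(qc.rename_axis("sample_id").reset_index(),
                                    outputs["qc"])

        stage = "spikein"
        if config.panel is not None:
            panel = MockPanel.from_tsv(config.panel)
            tissues = table.subset(lambda m: m.sample_type != "control")
            rep_rows = []
            for kit in kits:
                rep = detect(tissues.subset(extraction_kit=kit), panel)
                rep_rows.append({"kit": kit, "mean_percent": rep.mean_percent,
                                 "mean_percent_strains": rep.mean_percent_strains,
                                 "never_detected": ";".join(rep.never_detected)})
            outputs["spikein"] = _out(config, "spikein.tsv")
            io_formats.write_report(pd.DataFrame(rep_rows), outputs["spikein"])
        else:
            log.info("no mock panel supplied; spike-in stage skipped")

        stage = "log"
        outputs["log"] = _out(config, "log.txt")
        with open(outputs["log"], "w", encoding="utf-8") as fh:
            fh.write(f"lungdecontam {__version__}\n")
            fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
            fh.write(f"seed={config.seed}\n")
            fh.write(f"parameters={config.params}\n")
            fh.write("stages=load,decontam,alpha_diversity,beta_diversity,"
                     "core_contaminants,qc,spikein\n")
            fh.write(f"spikein={'run' if config.panel else 'skipped (no panel)'}\n")
            fh.write(f"qc={'run' if config.qc else 'skipped (no QC table)'}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
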