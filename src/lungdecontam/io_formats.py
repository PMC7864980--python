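"""Readers and writers for the mothur table dialects and study TSVs.

The pipeline starts at a clustered OTU table: a mothur ``.shared`` count
table plus its ``.cons.taxonomy`` consensus taxonomy, joined to a
tab-separated sample-metadata table and (optionally) an extraction-QC table.
All readers validate and reject malformed input rather than coercing it; all
writers emit UTF-8, tab-delimited, LF-terminated files that their paired
reader round-trips exactly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    EXTRACTION_KITS,
    META_COLUMNS,
    RANKS,
    OtuTable,
    SAMPLE_TYPES,
    TableValidationError,
    pad_lineage,
)


class ParseError(ValueError):
    """Malformed input file; message names the file and the offence."""


SHARED_HEADER = ("label", "Group", "numOtus")
QC_COLUMNS = ("sample_id", "dna_ng_per_ul", "eluate_ul", "tissue_g",
              "a260_280", "a260_230")

_BOOTSTRAP_RE = re.compile(r"\((\d+(?:\.\d+)?)\)$")


def _read_lines(path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    return [line.split("\t") for line in text.splitlines() if line.strip()]


def read_shared(path, label: str | None = None) -> pd.DataFrame:
    """Read a mothur ``.shared`` file into a samples-by-OTUs count DataFrame.

    Only a single clustering label is supported; a file holding several
    labels requires an explicit ``label`` argument selecting one.
    """
    rows = _read_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty shared file")
    header = rows[0]
    if tuple(header[:3]) != SHARED_HEADER:
        raise ParseError(
            f"{path}: shared header must begin {SHARED_HEADER}, got {header[:3]}"
        )
    otu_ids = header[3:]
    if len(set(otu_ids)) != len(otu_ids):
        raise ParseError(f"{path}: duplicate OTU ids in header")
    labels_seen = {r[0] for r in rows[1:]}
    if label is None:
        if len(labels_seen) > 1:
            raise ParseError(
                f"{path}: multiple clustering labels {sorted(labels_seen)}; "
                "pass label= to select one"
            )
    else:
        rows = [rows[0]] + [r for r in rows[1:] if r[0] == label]
        if len(rows) == 1:
            raise ParseError(f"{path}: no rows with label {label!r}")
    records: dict[str, list[int]] = {}
    for r in rows[1:]:
        if len(r) != 3 + len(otu_ids):
            raise ParseError(
                f"{path}: row for Group {(r[1] if len(r) > 1 else '?')!r} has "
                f"{len(r) - 3} count fields, expected {len(otu_ids)}"
            )
        group = r[1]
        if group in records:
            raise ParseError(f"{path}: duplicate Group {group!r}")
        try:
            num_otus = int(r[2])
            counts = [int(x) for x in r[3:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer count in Group {group!r}") from exc
        if num_otus != len(otu_ids):
            raise ParseError(
                f"{path}: Group {group!r} declares numOtus={num_otus} but the "
                f"header lists {len(otu_ids)} OTUs"
            )
        if any(c < 0 for c in counts):
            raise ParseError(f"{path}: negative count in Group {group!r}")
        records[group] = counts
    counts = pd.DataFrame.from_dict(records, orient="index", columns=otu_ids)
    counts.index.name = "sample_id"
    return counts.astype(np.int64)


def write_shared(counts: pd.DataFrame, path, label: str = "0.03") -> None:
    """Write a counts DataFrame as a single-label mothur ``.shared`` file."""
    otu_ids = list(counts.columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(list(SHARED_HEADER) + otu_ids) + "\n")
        for sample, row in counts.iterrows():
            fields = [label, str(sample), str(len(otu_ids))]
            fields += [str(int(v)) for v in row.to_numpy()]
            fh.write("\t".join(fields) + "\n")


def parse_taxonomy_string(s: str) -> tuple[str, ...]:
    """Split a mothur lineage string, strip bootstrap values, pad to 6 ranks."""
    if not s or not s.strip(";").strip():
        raise ParseError("empty taxonomy string")
    parts = [p for p in s.strip().split(";") if p.strip()]
    return pad_lineage(_BOOTSTRAP_RE.sub("", p.strip()) for p in parts)


def read_cons_taxonomy(path) -> pd.DataFrame:
    """Read a mothur ``.cons.taxonomy`` file into a taxonomy DataFrame.

    Bootstrap percentages are parsed and discarded; lineages are padded or
    truncated to the six fixed ranks.
    """
    rows = _read_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty taxonomy file")
    header = [h.strip() for h in rows[0]]
    if header[:3] != ["OTU", "Size", "Taxonomy"]:
        raise ParseError(
            f"{path}: taxonomy header must be OTU/Size/Taxonomy, got {header[:3]}"
        )
    recs = {}
    for r in rows[1:]:
        if len(r) < 3:
            raise ParseError(f"{path}: taxonomy row with missing columns: {r}")
        otu = r[0]
        if otu in recs:
            raise ParseError(f"{path}: duplicate OTU {otu!r}")
        try:
            recs[otu] = parse_taxonomy_string(r[2])
        except ParseError as exc:
            raise ParseError(f"{path}: OTU {otu!r}: {exc}") from exc
    tax = pd.DataFrame.from_dict(recs, orient="index", columns=list(RANKS))
    tax.index.name = "otu_id"
    return tax


def write_cons_taxonomy(
    taxonomy: pd.DataFrame, path, sizes: Mapping[str, int] | None = None
) -> None:
    """Write a taxonomy DataFrame as a ``.cons.taxonomy`` file (no bootstraps)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, row in taxonomy.iterrows():
            size = 0 if sizes is None else int(sizes.get(otu, 0))
            lineage = ";".join(row[list(RANKS)]) + ";"
            fh.write(f"{otu}\t{size}\t{lineage}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV; validates enums and uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample_id",) + META_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ParseError(f"{path}: duplicate sample_id(s) {dupes}")
    bad = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
    if bad:
        raise ParseError(
            f"{path}: unknown sample_type {bad}; allowed values: {list(SAMPLE_TYPES)}"
        )
    bad = sorted(set(df["extraction_kit"]) - set(EXTRACTION_KITS))
    if bad:
        raise ParseError(
            f"{path}: unknown extraction_kit {bad}; allowed values: "
            f"{list(EXTRACTION_KITS)}"
        )
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return df[list(META_COLUMNS)]


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta[list(META_COLUMNS)].copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_qc(path) -> pd.DataFrame:
    """Read the extraction-QC TSV (concentration, eluate volume, tissue mass, purity ratios)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing QC column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in QC table")
    df = df.set_index("sample_id")
    return df[[c for c in QC_COLUMNS if c != "sample_id"]].astype(float)


def write_report(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a report TSV with deterministic column order and 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def load_study(shared_path, taxonomy_path, metadata_path,
               label: str | None = None) -> OtuTable:
    """Assemble an :class:`OtuTable` from the three study files."""
    counts = read_shared(shared_path, label=label)
    tax = read_cons_taxonomy(taxonomy_path)
    meta = read_metadata(metadata_path)
    try:
        return OtuTable(counts, tax, meta)
    except TableValidationError as exc:
        raise ParseError(f"inconsistent study files: {exc}") from exc
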