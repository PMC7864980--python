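"""Shared fixtures: hand-built toy tables and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lungdecontam import OtuTable, SampleMeta, meta_frame, taxonomy_frame
from lungdecontam.synthetic import SynthConfig, simulate_study


def build_table(counts: dict[str, list[int]], otus: list[str],
                genera: list[str] | None = None,
                metas: list[SampleMeta] | None = None) -> OtuTable:
    """Assemble a small OtuTable from literal rows."""
    df = pd.DataFrame.from_dict(counts, orient="index", columns=otus)
    df.index.name = "sample_id"
    if genera is None:
        genera = [f"Genus{i}" for i in range(len(otus))]
    tax = taxonomy_frame(
        {o: ("Bacteria", "P", "C", "O", "F", g) for o, g in zip(otus, genera)}
    )
    meta = meta_frame(metas) if metas is not None else None
    return OtuTable(df.astype(np.int64), tax, meta)


@pytest.fixture
def toy_patient_table() -> OtuTable:
    """One patient triplet with hand-checkable removal outcomes.

    Totals: cancerous 1000, healthy 1000, control 100.  OTU B and D are
    control-present and fail the ratio test; A and C are control-absent.
    """
    metas = [
        SampleMeta("C1", "P1", "cancerous", "Blood"),
        SampleMeta("H1", "P1", "healthy", "Blood"),
        SampleMeta("K1", "P1", "control", "Blood"),
    ]
    return build_table(
        {"C1": [500, 300, 150, 50], "H1": [400, 1, 500, 99],
         "K1": [0, 1, 0, 99]},
        otus=["A", "B", "C", "D"],
        metas=metas,
    )


@pytest.fixture(scope="session")
def small_study():
    """Default-design synthetic study (5 patients x 3 kits, depth 20,000)."""
    return simulate_study(SynthConfig(seed=11))


def random_triplet_table(rng: np.random.Generator, n_otus: int | None = None):
    """A random single-patient triplet table for oracle-equivalence checks.

    Counts are sparse smallish integers; rows are re-drawn until all three
    samples have positive totals.
    """
    n = n_otus or int(rng.integers(3, 21))
    otus = [f"O{i}" for i in range(n)]
    metas = [
        SampleMeta("C", "P", "cancerous", "Blood"),
        SampleMeta("H", "P", "healthy", "Blood"),
        SampleMeta("K", "P", "control", "Blood"),
    ]
    while True:
        rows = {
            sid: (rng.integers(0, 50, n) * (rng.random(n) < 0.6)).astype(int)
            for sid in ("C", "H", "K")
        }
        if all(r.sum() > 0 for r in rows.values()):
            break
    return build_table({k: list(v) for k, v in rows.items()}, otus, metas=metas)


def brute_force_removal(table: OtuTable, c_id: str, h_id: str, k_id: str,
                        ratio: float = 1000.0) -> set[str]:
    """Independent plain-loop implementation of the ratio rule."""
    counts = {sid: dict(table.counts.loc[sid]) for sid in (c_id, h_id, k_id)}
    totals = {sid: sum(v.values()) for sid, v in counts.items()}
    removed = set()
    for otu in table.otu_ids:
        k_rel = counts[k_id][otu] / totals[k_id]
        if k_rel <= 0:
            continue
        c_rel = counts[c_id][otu] / totals[c_id]
        h_rel = counts[h_id][otu] / totals[h_id]
        if not (c_rel > ratio * k_rel and h_rel > ratio * k_rel):
            removed.add(otu)
    return removed
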