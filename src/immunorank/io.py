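"""Readers and writers for the pipeline's plain-text interchange formats.

* ``counts.tsv`` — sample, batch, then one column per gene; no-template
  controls appear as ``NTC_<batch>`` rows.
* ``clinical.csv`` — one row per study sample; missing MSI/TMB cells are
  empty.
* ``mutations.tsv`` — tidy long form: sample, gene, altered (0/1).
* ``percentiles.tsv`` — tidy long form: sample, gene, nrpm, rank, category.
* GMT — standard ``Name<TAB>description<TAB>gene1<TAB>gene2...`` lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import RawPanelCounts

__all__ = [
    "write_counts", "read_counts",
    "write_clinical", "read_clinical",
    "write_mutations", "read_mutations",
    "write_gmt", "read_gmt",
    "write_percentiles", "read_percentiles", "percentiles_wide",
]


def write_counts(raw: RawPanelCounts, path) -> None:
    rows = []
    for i, sid in enumerate(raw.sample_ids):
        rows.append([sid, raw.batch_of[sid], *raw.counts[i].tolist()])
    for batch in sorted(raw.ntc_of):
        rows.append([f"NTC_{batch}", batch, *np.asarray(raw.ntc_of[batch]).tolist()])
    frame = pd.DataFrame(rows, columns=["sample", "batch", *raw.gene_ids])
    frame.to_csv(path, sep="\t", index=False)


def read_counts(path) -> RawPanelCounts:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "batch": str})
    gene_ids = [c for c in frame.columns if c not in ("sample", "batch")]
    is_ntc = frame["sample"].str.startswith("NTC_")
    samples = frame[~is_ntc]
    ntcs = frame[is_ntc]
    return RawPanelCounts(
        sample_ids=samples["sample"].tolist(),
        gene_ids=gene_ids,
        counts=samples[gene_ids].to_numpy(dtype=np.int64),
        batch_of=dict(zip(samples["sample"], samples["batch"])),
        ntc_of={
            row["batch"]: row[gene_ids].to_numpy(dtype=np.int64)
            for _, row in ntcs.iterrows()
        },
    )


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"sample": str, "cancer_type": str, "sex": str, "msi": str, "tmb_high": str},
    )
    for col in ("has_clinical", "ici_treated"):
        if col in frame.columns and frame[col].dtype != bool:
            frame[col] = frame[col].astype(str).str.lower().eq("true")
    return frame


def write_mutations(mutations: pd.DataFrame, path) -> None:
    long = (
        mutations.rename_axis("sample")
        .reset_index()
        .melt(id_vars="sample", var_name="gene", value_name="altered")
        .sort_values(["sample", "gene"], kind="stable")
    )
    long.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "altered": int})
    wide = long.pivot(index="sample", columns="gene", values="altered")
    wide.columns.name = None
    wide.index.name = None
    return wide.astype(int)


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic gene set", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = [m for m in members if m]
    return sets


def write_percentiles(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_percentiles(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"sample": str, "gene": str, "nrpm": float, "rank": float, "category": str},
    )


def percentiles_wide(table: pd.DataFrame, value: str = "rank") -> pd.DataFrame:
    """Pivot the tidy percentile table to samples x genes for one value."""
    wide = table.pivot(index="sample", columns="gene", values=value)
    wide.columns.name = None
    wide.index.name = None
    return wide
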