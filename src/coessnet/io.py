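"""Readers and writers for the small tabular formats the pipeline consumes."""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_driver_table",
    "read_drug_gene_table",
    "read_response_table",
    "read_survival_table",
]

ASSOCIATION_TYPES = {"direct_target", "biomarker"}


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_driver_table(path) -> dict[str, list[str]]:
    """Driver TSV (cancer_type <tab> gene) -> cancer type -> gene list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cancer_type", "gene"} <= set(df.columns):
        raise ValueError("driver table needs columns cancer_type, gene")
    return {c: sorted(set(g["gene"])) for c, g in df.groupby("cancer_type")}


def read_drug_gene_table(path) -> pd.DataFrame:
    """Drug-gene TSV with columns drug_id, gene, association_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "gene", "association_type"}
    if not required <= set(df.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    bad = set(df["association_type"]) - ASSOCIATION_TYPES
    if bad:
        raise ValueError(f"unknown association type(s): {sorted(bad)}")
    if df.duplicated(["drug_id", "gene"]).any():
        raise ValueError("duplicate (drug_id, gene) pairs")
    return df


def read_response_table(path) -> pd.DataFrame:
    """Drug response TSV with columns drug_id, cell_line, ic50."""
    df = pd.read_csv(path, sep="\t")
    required = {"drug_id", "cell_line", "ic50"}
    if not required <= set(df.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    df["ic50"] = df["ic50"].astype(float)
    return df


def read_survival_table(path) -> pd.DataFrame:
    """Survival TSV with columns patient, time, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return df.set_index("patient")
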