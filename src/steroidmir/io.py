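"""Readers and writers for the pipeline's interchange formats.

TSV with a header row is the interchange dialect for tables (clinical
tables, count matrices, expression matrices with a sample-metadata
sidecar), GMT for gene sets, JSON for manifests and truth records.
Readers validate headers strictly and name the offending column on
failure; every write/read pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .caster import CASTER_FEATURES
from .lcl import PairedExprSet


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- clinical

def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("subject_id").to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    missing = [c for c in CASTER_FEATURES if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing column(s): {missing}")
    if df.index.duplicated().any():
        dups = list(df.index[df.index.duplicated()][:3])
        raise FormatError(f"duplicated subject_id(s): {dups}")
    return df


# ------------------------------------------------------------------ counts

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("mirna").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "mirna":
        raise FormatError(
            f"count matrix must have a 'mirna' index column, found {df.index.name!r}"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError("count matrix has duplicated miRNA or subject ids")
    if (df.to_numpy() < 0).any():
        raise FormatError("count matrix has negative entries")
    df.columns.name = "subject_id"
    return df.astype("int64", errors="ignore")


# ------------------------------------------------------------- expression

def write_paired_expr(x: PairedExprSet, path: str | Path, sidecar: str | Path) -> None:
    x.values.rename_axis("probe").to_csv(path, sep="\t")
    x.samples.rename_axis("sample_id").to_csv(sidecar, sep="\t")


def read_paired_expr(path: str | Path, sidecar: str | Path) -> PairedExprSet:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.name != "probe":
        raise FormatError(
            f"expression matrix must have a 'probe' index column, found {values.index.name!r}"
        )
    samples = pd.read_csv(sidecar, sep="\t", index_col="sample_id")
    for col in ("subject_id", "condition"):
        if col not in samples.columns:
            raise FormatError(f"sample sidecar missing column: {col!r}")
    return PairedExprSet(values=values, samples=samples)


# --------------------------------------------------------------------- GMT

def write_gmt(sets: dict[str, set], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set]:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {ln}: need at least name and description")
            out[parts[0]] = set(parts[2:])
    return out


# -------------------------------------------------------------------- JSON

def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
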