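"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices are TSV with a ``feature_id`` first column and one column per
sample.  Genomic intervals use BED conventions (0-based, half-open); signal
uses 4-column bedGraph.  All writers emit deterministic, timestamp-free
output so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InputFormatError

SAMPLE_SHEET_COLUMNS = ("sample", "patient", "condition", "genotype")
COHORT_COLUMNS = (
    "patient", "hes1", "hes2", "hey1", "hey2", "ciita", "notch1_mutated", "time", "event",
)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InputFormatError(f"{path}: duplicate feature ids")
    if df.columns.has_duplicates:
        raise InputFormatError(f"{path}: duplicate sample ids")
    df.index.name = "feature_id"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df = df.rename_axis("feature_id")
    df.to_csv(path, sep="\t")


def validate_sample_sheet(sheet: pd.DataFrame, require_pairs: bool = True) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise InputFormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample"].duplicated().any():
        raise InputFormatError("sample sheet has duplicate sample ids")
    if sheet.duplicated(subset=["patient", "condition"]).any():
        raise InputFormatError("sample sheet repeats a (patient, condition) pair")
    if require_pairs:
        by_pat = sheet.groupby("patient")["condition"].apply(set)
        for pat, conds in by_pat.items():
            if "treated" in conds and "control" not in conds:
                raise InputFormatError(f"patient {pat} has a treated sample but no control")
    return sheet


def read_sample_sheet(path, require_pairs: bool = True) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet, require_pairs=require_pairs)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def _check_intervals(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        row = bad.iloc[0]
        raise InputFormatError(
            f"{path}: malformed interval {row['chrom']}:{row['start']}-{row['end']}"
        )
    return df


def read_bed(path, extra_columns: tuple = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_columns]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, usecols=range(len(names)),
                         comment="#")
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    if not len(df):
        return df
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise InputFormatError(f"{path}: non-integer coordinates in column '{col}'")
    return _check_intervals(df, path)


def read_gene_bed(path) -> pd.DataFrame:
    """BED6 gene models: chrom start end gene_id score strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     usecols=range(6))
    _check_intervals(df, path)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise InputFormatError(f"{path}: gene strand must be '+' or '-'")
    return df.drop(columns="score")


def write_bed(df: pd.DataFrame, path, columns: tuple = ("chrom", "start", "end")) -> None:
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = read_bed(path, extra_columns=("value",))
    if len(df):
        df["value"] = df["value"].astype(float)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "value"]].copy()
    out["value"] = out["value"].map(repr)  # full precision
    out.to_csv(path, sep="\t", header=False, index=False)


def read_state_map(path) -> dict:
    """Two-column TSV: state label, active flag (1/0 or true/false)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["state", "active"], dtype=str)
    truthy, falsy = {"1", "true", "yes", "active"}, {"0", "false", "no", "inactive"}
    mapping = {}
    for _, row in df.iterrows():
        flag = str(row["active"]).strip().lower()
        if flag in truthy:
            mapping[row["state"]] = True
        elif flag in falsy:
            mapping[row["state"]] = False
        else:
            raise InputFormatError(f"{path}: unrecognized active flag {row['active']!r}")
    return mapping


def write_state_map(mapping: Mapping[str, bool], path) -> None:
    with open(path, "w") as fh:
        for state, active in mapping.items():
            fh.write(f"{state}\t{int(active)}\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: cohort table missing columns {missing}")
    if (df["time"] <= 0).any():
        raise InputFormatError(f"{path}: times must be positive")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
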