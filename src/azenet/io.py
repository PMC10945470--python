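"""Strict TSV readers/writers for the pipeline's table dialects.

All tables are tab-delimited UTF-8 with a header row.  Readers validate
row shape and name the offending line on failure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def _read_tsv_strict(path: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise ValidationError(
                f"{path}: line {i} has {len(parts)} fields, expected {width}"
            )
        rows.append(parts)
    return pd.DataFrame(rows, columns=header)


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Gene/ASV x sample counts; first column holds the feature id."""
    df = _read_tsv_strict(path)
    idx_col = df.columns[0]
    df = df.set_index(idx_col)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count ({exc})") from exc
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str, index_name: str = "gene") -> None:
    out = counts.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_condition_map(path: str) -> pd.Series:
    df = _read_tsv_strict(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns sample, condition")
    s = pd.Series(
        df.iloc[:, 1].astype(int).values, index=df.iloc[:, 0].values, name="condition"
    )
    return s


def write_condition_map(cond: pd.Series, path: str) -> None:
    pd.DataFrame({"sample": cond.index, "condition": cond.values}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes: list[str], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_pathways(path: str) -> dict[str, set[str]]:
    """Long-format membership table (gene, pathway_id) -> gene -> pathways."""
    df = _read_tsv_strict(path)
    out: dict[str, set[str]] = {}
    for gene, pw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(pw)
    return out


def write_pathways(membership: dict[str, set[str]], path: str) -> None:
    rows = [
        {"gene": g, "pathway_id": pw}
        for g in sorted(membership)
        for pw in sorted(membership[g])
    ]
    pd.DataFrame(rows, columns=["gene", "pathway_id"]).to_csv(path, sep="\t", index=False)


def read_tracer_tsv(path: str) -> pd.DataFrame:
    """Columns time_min, replicate, delta_permil."""
    df = _read_tsv_strict(path)
    required = {"time_min", "replicate", "delta_permil"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    df["time_min"] = df["time_min"].astype(float)
    df["delta_permil"] = df["delta_permil"].astype(float)
    return df


def write_tracer_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_group_map(path: str) -> pd.Series:
    df = _read_tsv_strict(path)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_group_map(group: pd.Series, path: str) -> None:
    pd.DataFrame({"sample": group.index, "group": group.values}).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path: str) -> pd.DataFrame:
    df = _read_tsv_strict(path)
    if "asv" not in df.columns:
        raise ValidationError(f"{path}: expected an 'asv' column")
    return df.set_index("asv")


def write_taxonomy(tax: pd.DataFrame, path: str) -> None:
    out = tax.copy()
    out.index.name = "asv"
    out.to_csv(path, sep="\t")
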