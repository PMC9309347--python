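"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices, sample sheets, hit tables, gene-to-protein maps and
interaction tables are tab-separated; gene/protein sets travel as GMT or as
one-id-per-line text. Everything is diff-able text, nothing binary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

FLOAT_FMT = "%.10g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2-intensity table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) sheet into a sample -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"sample sheet {path} needs >= 2 columns (sample, group)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_sample_sheet(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a (query, subject, score) similarity table."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["query", "subject", "score"]
    df["score"] = df["score"].astype(float)
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a two-column (gene, protein) mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["gene", "protein"]
    return df


def write_mapping(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> member ids...

    Returns an ordered mapping set-name -> member list.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *members = fields
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: Mapping[str, list[str] | set[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_id_set(path: str | Path) -> set[str]:
    """Read a protein/gene set: GMT (union of all sets) or one id per line."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = read_gmt(path)
        return set().union(*sets.values()) if sets else set()
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_set(ids: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
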