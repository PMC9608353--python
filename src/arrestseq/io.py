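"""Readers and writers for the plain-text interchange formats.

All tables are TSV. Count matrices have a ``gene_id`` first column and one
column per sample; spike-in rows carry the ``ERCC-`` prefix. Normalized
matrices carry a ``#unit:`` comment header recording the unit.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from . import SPIKE_PREFIX


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (integer values, gene_id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in sheet.columns:
        raise ValueError(f"sample sheet {path} lacks a sample_id column")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_spikes(path: str | os.PathLike) -> pd.DataFrame:
    spikes = pd.read_csv(path, sep="\t", comment="#")
    required = {"spike_id", "conc_attomol_per_ul", "volume_ul"}
    missing = required - set(spikes.columns)
    if missing:
        raise ValueError(f"spike table {path} lacks columns: {sorted(missing)}")
    return spikes


def write_spikes(spikes: pd.DataFrame, path: str | os.PathLike) -> None:
    spikes.to_csv(path, sep="\t", index=False)


def spike_mask(counts: pd.DataFrame) -> pd.Series:
    """Boolean mask over count-matrix rows flagging spike-in species."""
    return counts.index.to_series().astype(str).str.startswith(SPIKE_PREFIX)


def write_matrix(values: pd.DataFrame, path: str | os.PathLike, unit: str,
                 extra_comments: Sequence[str] = ()) -> None:
    """Write a real-valued matrix with a ``#unit:`` header comment."""
    with open(path, "w") as fh:
        fh.write(f"#unit: {unit}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        values.to_csv(fh, sep="\t", index_label="gene_id")


def read_matrix(path: str | os.PathLike) -> tuple[pd.DataFrame, str]:
    """Read a matrix written by :func:`write_matrix`; returns (matrix, unit)."""
    unit = ""
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("#unit:"):
                unit = line.split(":", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df, unit


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: member gene ids}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT record in {path}: {raw[:80]!r}")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, name)
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")
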