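"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere. SEG files are 1-based
inclusive on disk; the BED-like germline resource is 0-based half-open; the
conversions happen here and only here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinCountTable, NBModel

__all__ = [
    "read_seg",
    "write_seg",
    "read_bincounts",
    "write_bincounts",
    "read_germline",
    "write_germline",
    "model_to_json",
    "model_from_json",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def _normalize_chrom(chrom: pd.Series, strip_chr: bool) -> pd.Series:
    chrom = chrom.astype(str)
    if strip_chr:
        return chrom.str.replace(r"^chr", "", regex=True)
    return chrom.where(chrom.str.startswith("chr"), "chr" + chrom)


def read_seg(
    path, value_kind: str = "log2", strip_chr: bool = False
) -> pd.DataFrame:
    """Read a SEG segmentation file into internal records.

    ``value_kind`` declares the Segment_Mean semantics: ``"log2"`` (standard
    SEG, log2(copy/2); converted to absolute copies as 2·2^value) or
    ``"copies"`` (already absolute). Disk coordinates are 1-based inclusive
    and are converted to 0-based half-open.
    """
    if value_kind not in ("log2", "copies"):
        raise ValueError("value_kind must be 'log2' or 'copies'")
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 5:
        raise ValueError(f"{path}: SEG needs at least 5 tab-delimited columns")
    df = df.iloc[:, :6] if df.shape[1] >= 6 else df
    names = ["sample", "chrom", "start", "end", "num_probes", "value"]
    df.columns = names[: df.shape[1]]
    if "value" not in df.columns:  # 5-column dialect without Num_Probes
        df.columns = ["sample", "chrom", "start", "end", "value"]
    bad = pd.to_numeric(df["start"], errors="coerce").isna() | pd.to_numeric(
        df["end"], errors="coerce"
    ).isna()
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()[:5]
        raise ValueError(f"{path}: unparseable rows at lines {lines}")
    df["start"] = df["start"].astype(int) - 1  # 1-based incl -> 0-based half-open
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: segments with end <= start")
    df["chrom"] = _normalize_chrom(df["chrom"], strip_chr)
    value = df["value"].astype(float)
    copies = 2.0 * np.power(2.0, value) if value_kind == "log2" else value
    if (copies < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    out = pd.DataFrame(
        {
            "sample": df["sample"],
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "copies": copies,
        }
    )
    return out


def write_seg(records: pd.DataFrame, path, value_kind: str = "log2") -> None:
    """Write internal records as a SEG file (1-based inclusive on disk)."""
    if value_kind not in ("log2", "copies"):
        raise ValueError("value_kind must be 'log2' or 'copies'")
    copies = records["copies"].astype(float)
    if value_kind == "log2":
        value = np.log2(np.maximum(copies, 1e-6) / 2.0)
    else:
        value = copies
    out = pd.DataFrame(
        {
            "Sample": records["sample"],
            "Chromosome": records["chrom"],
            "Start": records["start"].astype(int) + 1,
            "End": records["end"].astype(int),
            "Num_Probes": records.get(
                "num_probes", pd.Series(0, index=records.index)
            ),
            "Segment_Mean": value,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bincounts(table: BinCountTable, path) -> None:
    """Write a bin-count table as TSV: chrom, start, end, gc, mask, counts…"""
    df = table.bins.copy()
    df["gc"] = table.gc
    df["mask"] = table.mask.astype(int)
    for j, name in enumerate(table.samples):
        df[name] = table.counts[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bincounts(path, bin_size: int | None = None) -> BinCountTable:
    """Read a bin-count TSV written by :func:`write_bincounts`.

    A ``mask`` column is optional; every column after the coordinate/gc
    block is a sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "start", "end", "gc"]
    if not set(needed).issubset(df.columns):
        raise ValueError(f"{path}: bin-count TSV needs columns {needed}")
    mask = None
    fixed = list(needed)
    if "mask" in df.columns:
        mask = df["mask"].astype(bool).to_numpy()
        fixed.append("mask")
    samples = [c for c in df.columns if c not in fixed]
    if not samples:
        raise ValueError(f"{path}: no sample count columns found")
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    return BinCountTable(
        bins=df[["chrom", "start", "end"]],
        gc=df["gc"].to_numpy(),
        counts=df[samples].to_numpy().astype(np.int64),
        samples=samples,
        mask=mask,
        bin_size=bin_size,
    )


def write_germline(resource: pd.DataFrame, path) -> None:
    """Write a germline AF resource as BED-like TSV (0-based half-open)."""
    resource[["chrom", "start", "end", "af"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_germline(path) -> pd.DataFrame:
    """Read a BED-like germline allele-frequency resource."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "start", "end", "af"]
    if not set(needed).issubset(df.columns):
        raise ValueError(f"{path}: germline resource needs columns {needed}")
    if ((df["af"] < 0) | (df["af"] > 1)).any():
        raise ValueError(f"{path}: allele frequencies outside [0, 1]")
    return df[needed].sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


def model_to_json(model: NBModel, path=None) -> str:
    """Serialise an NB model (m, r, bin_size, read_length, depth) to JSON."""
    payload = dataclasses.asdict(model)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def model_from_json(source) -> NBModel:
    """Load an NB model from a JSON file path or string."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    payload = json.loads(text)
    return NBModel(**payload)
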