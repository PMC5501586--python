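"""Coarse "ctDNA-detectable" copy-number profiles from tumor segmentations.

Tumor segmentation records (per-sample copy-number segments) are converted to
per-sample vectors over a fixed 5 Mb or 100 Mb genome grid:

1. germline filtering — segments that reciprocally overlap a population CNV
   with allele frequency above 1% are removed;
2. average copy deviation — for each grid segment, the length-weighted mean
   of (copies − 2) over the overlapping records (uncovered basepairs count
   as diploid);
3. detectability — a segment is callable from cfDNA when the average
   deviation reaches one full extra (or missing) copy, e.g. a 1 Mb event of
   +5 copies inside a 5 Mb segment averages +1 and is detectable, as is a
   whole segment gained once;
4. symbolic discretization to five ordered copy states (2-copy loss, 1-copy
   loss, near-normal, 1-copy gain, ≥2-copy gain) by rounding the average
   deviation to the nearest integer copy state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CopyState, GenomeGrid

__all__ = [
    "CopyProfileSet",
    "filter_germline",
    "segment_average_copy",
    "flag_detectable",
    "sax_discretize",
    "build_profiles",
    "cohort_detectable_fraction",
]


def filter_germline(
    records: pd.DataFrame,
    af_resource: pd.DataFrame,
    af_threshold: float = 0.01,
    reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Drop records matching common germline CNVs.

    A record is removed when it has reciprocal overlap of at least
    ``reciprocal_overlap`` (both as a fraction of the record and of the
    resource interval) with any resource interval whose allele frequency
    exceeds ``af_threshold``.
    """
    if records.empty or af_resource.empty:
        return records.copy()
    if (records["end"] <= records["start"]).any():
        raise ValueError("malformed record intervals (end <= start)")
    if (af_resource["end"] <= af_resource["start"]).any():
        raise ValueError("malformed resource intervals (end <= start)")

    common = af_resource[af_resource["af"] > af_threshold]
    if common.empty:
        return records.copy()

    keep = np.ones(len(records), dtype=bool)
    for chrom, res in common.groupby("chrom"):
        sel = np.flatnonzero((records["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        rs = records["start"].to_numpy()[sel][:, None]
        re_ = records["end"].to_numpy()[sel][:, None]
        qs = res["start"].to_numpy()[None, :]
        qe = res["end"].to_numpy()[None, :]
        overlap = np.minimum(re_, qe) - np.maximum(rs, qs)
        overlap = np.clip(overlap, 0, None)
        hit = (
            (overlap >= reciprocal_overlap * (re_ - rs))
            & (overlap >= reciprocal_overlap * (qe - qs))
        ).any(axis=1)
        keep[sel[hit]] = False
    return records.loc[keep].reset_index(drop=True)


def _resolve_overlaps(
    starts: np.ndarray, ends: np.ndarray, devs: np.ndarray
) -> list[tuple[int, int, float]]:
    """Flatten possibly-overlapping records; the later record wins.

    Returns disjoint (start, end, deviation) pieces covering exactly the
    union of the input intervals.
    """
    points = np.unique(np.concatenate([starts, ends]))
    pieces = []
    for lo, hi in zip(points[:-1], points[1:]):
        covering = np.flatnonzero((starts <= lo) & (ends >= hi))
        if covering.size:
            pieces.append((int(lo), int(hi), float(devs[covering[-1]])))
    return pieces


def segment_average_copy(
    records: pd.DataFrame, grid: GenomeGrid
) -> np.ndarray:
    """Length-weighted average copy deviation per grid segment for one sample.

    ``avg_dev(segment) = Σ (copies − 2) · overlap_length / segment_length``
    over all record pieces intersecting the segment; basepairs not covered by
    any record contribute zero deviation (diploid). Records overlapping each
    other are resolved with later-record precedence (warned).
    """
    dev_sum = np.zeros(grid.n_segments)
    seg = grid.segments
    lengths = grid.lengths().astype(float)
    if records.empty:
        return dev_sum

    for chrom, recs in records.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"record on unknown chromosome {chrom!r}")
        csize = grid.chrom_sizes[chrom]
        starts = recs["start"].to_numpy()
        ends = recs["end"].to_numpy()
        if (ends > csize).any() or (starts < 0).any():
            raise ValueError(f"record beyond chromosome end on {chrom!r}")
        order = np.argsort(starts, kind="stable")
        if np.any(starts[order][1:] < ends[order][:-1]):
            warnings.warn(
                "overlapping records within a sample; later record wins",
                RuntimeWarning,
                stacklevel=2,
            )
        devs = recs["copies"].to_numpy(dtype=float) - 2.0

        seg_idx = np.flatnonzero((seg["chrom"] == chrom).to_numpy())
        seg_starts = seg["start"].to_numpy()[seg_idx]
        seg_ends = seg["end"].to_numpy()[seg_idx]
        for lo, hi, dev in _resolve_overlaps(starts, ends, devs):
            if dev == 0.0:
                continue
            first = np.searchsorted(seg_ends, lo, side="right")
            last = np.searchsorted(seg_starts, hi, side="left")
            for k in range(first, last):
                ov = min(hi, seg_ends[k]) - max(lo, seg_starts[k])
                if ov > 0:
                    dev_sum[seg_idx[k]] += dev * ov
    return dev_sum / lengths


def flag_detectable(avg_dev: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Segments whose average deviation reaches one full copy (either sign)."""
    return np.abs(np.asarray(avg_dev, dtype=float)) >= threshold


def sax_discretize(avg_dev: np.ndarray) -> np.ndarray:
    """Discretize average copy deviations to the five ordered copy states.

    Breakpoints round to the nearest integer copy state:
    (−∞,−1.5] → DEL2, (−1.5,−0.5] → DEL1, (−0.5,0.5) → NEUTRAL,
    [0.5,1.5) → AMP1, [1.5,∞) → AMP2PLUS.
    """
    x = np.asarray(avg_dev, dtype=float)
    out = np.zeros(x.shape, dtype=np.int8)
    out[x >= 0.5] = CopyState.AMP1
    out[x >= 1.5] = CopyState.AMP2PLUS
    out[x <= -0.5] = CopyState.DEL1
    out[x <= -1.5] = CopyState.DEL2
    return out


@dataclass
class CopyProfileSet:
    """Per-sample coarse copy profiles on one genome grid.

    ``avg_dev``, ``categories`` (integer copy-state codes −2…2) and
    ``detectable`` are samples × segments frames sharing index and columns;
    columns are grid segment names in genomic order.
    """

    grid: GenomeGrid
    avg_dev: pd.DataFrame
    categories: pd.DataFrame
    detectable: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.avg_dev.index)

    def category_matrix(self) -> np.ndarray:
        return self.categories.to_numpy(dtype=np.int8)


def build_profiles(
    records: pd.DataFrame,
    grid: GenomeGrid,
    samples: list[str] | None = None,
    germline_resource: pd.DataFrame | None = None,
    af_threshold: float = 0.01,
    detect_threshold: float = 1.0,
) -> CopyProfileSet:
    """Full segmentation → profile conversion for a cohort.

    ``samples`` fixes the output rows (samples without records get flat
    profiles); by default the distinct sample ids found in the records are
    used. When a germline resource is supplied the records are filtered
    before averaging.
    """
    if germline_resource is not None:
        records = filter_germline(records, germline_resource, af_threshold)
    if samples is None:
        samples = list(pd.unique(records["sample"]))
    by_sample = dict(tuple(records.groupby("sample", sort=False)))
    empty = records.iloc[0:0]
    rows = [
        segment_average_copy(by_sample.get(s, empty), grid) for s in samples
    ]
    avg = pd.DataFrame(rows, index=samples, columns=grid.segment_names())
    cats = pd.DataFrame(
        sax_discretize(avg.to_numpy()), index=avg.index, columns=avg.columns
    )
    det = pd.DataFrame(
        flag_detectable(avg.to_numpy(), detect_threshold),
        index=avg.index,
        columns=avg.columns,
    )
    return CopyProfileSet(grid=grid, avg_dev=avg, categories=cats, detectable=det)


def cohort_detectable_fraction(
    profiles: CopyProfileSet,
    labels: pd.DataFrame,
    min_events: int = 1,
    segment_subset: list[str] | None = None,
) -> pd.Series:
    """Fraction of samples per type with >= ``min_events`` detectable segments.

    ``segment_subset`` optionally restricts the count to selected grid
    segments (e.g. the segments a random forest deems discriminative). An
    empty subset yields zero fractions.
    """
    lab = labels.set_index("sample")["type"]
    missing = set(profiles.samples) - set(lab.index)
    if missing:
        raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
    det = profiles.detectable
    if segment_subset is not None:
        det = det.loc[:, [c for c in det.columns if c in set(segment_subset)]]
    n_det = det.sum(axis=1)
    hit = (n_det >= min_events).astype(float)
    types = lab.loc[hit.index]
    return hit.groupby(types).mean().rename("fraction")
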