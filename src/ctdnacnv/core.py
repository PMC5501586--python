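"""Core containers for binned cfDNA counts, count models and genome grids.

All internal coordinates are 0-based half-open; conversions to/from on-disk
conventions (SEG is 1-based inclusive) happen only in :mod:`ctdnacnv.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CopyState",
    "BinCountTable",
    "NBModel",
    "PoissonModel",
    "GenomeGrid",
    "DegenerateDataError",
    "synthetic_chrom_sizes",
    "make_bins",
]


class DegenerateDataError(ValueError):
    """Raised when an input is too degenerate to estimate from
    (e.g. constant counts giving a singular scatter matrix)."""


class CopyState(IntEnum):
    """Five-level copy-number category used for coarse ctDNA profiles.

    The integer codes are ordered copy deviations from the diploid state,
    so adjacency (|difference| == 1) is meaningful for distances.
    """

    DEL2 = -2
    DEL1 = -1
    NEUTRAL = 0
    AMP1 = 1
    AMP2PLUS = 2


#: Category order used everywhere (most deleted -> most amplified).
COPY_STATES = [
    CopyState.DEL2,
    CopyState.DEL1,
    CopyState.NEUTRAL,
    CopyState.AMP1,
    CopyState.AMP2PLUS,
]


def _check_intervals(bins: pd.DataFrame) -> None:
    required = {"chrom", "start", "end"}
    if not required.issubset(bins.columns):
        raise ValueError(f"interval frame needs columns {sorted(required)}")
    if (bins["end"] <= bins["start"]).any():
        raise ValueError("intervals must have end > start (half-open)")
    # sorted & non-overlapping within each chromosome
    for _, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError("intervals must be sorted by start within chrom")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("intervals overlap within a chromosome")


@dataclass
class BinCountTable:
    """Per-bin read counts for one or more cfDNA samples.

    Parameters
    ----------
    bins:
        Frame with columns ``chrom``, ``start``, ``end`` (0-based half-open,
        fixed width except possibly trailing bins).
    gc:
        GC fraction per bin, in [0, 1].
    counts:
        Integer array of shape ``(n_bins, n_samples)``.
    samples:
        Sample names, one per count column.
    mask:
        Per-bin usability flag (True = usable). Outlier masking clears it.
    meta:
        Free-form metadata. Synthetic tables carry their generation recipe
        here (``expected_means``, ``dispersion``) so spike-in operations can
        redraw counts from the true model.
    """

    bins: pd.DataFrame
    gc: np.ndarray
    counts: np.ndarray
    samples: list[str]
    mask: np.ndarray | None = None
    bin_size: int = 10_000
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        _check_intervals(self.bins)
        self.gc = np.asarray(self.gc, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        n = len(self.bins)
        if self.gc.shape != (n,):
            raise ValueError("gc must have one value per bin")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")
        if self.counts.shape[0] != n:
            raise ValueError("counts rows must match number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("one sample name per count column required")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask must have one flag per bin")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def usable_counts(self) -> np.ndarray:
        """Counts restricted to usable (unmasked) bins."""
        return self.counts[self.mask]

    def region_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean index of bins fully inside ``[start, end)`` on ``chrom``."""
        if end <= start:
            raise ValueError("region must have positive length")
        b = self.bins
        hit = (b["chrom"] == chrom) & (b["start"] >= start) & (b["end"] <= end)
        return hit.to_numpy()

    def copy(self) -> "BinCountTable":
        return BinCountTable(
            bins=self.bins.copy(),
            gc=self.gc.copy(),
            counts=self.counts.copy(),
            samples=list(self.samples),
            mask=self.mask.copy(),
            bin_size=self.bin_size,
            meta=dict(self.meta),
        )

    def with_counts(self, counts: np.ndarray) -> "BinCountTable":
        new = self.copy()
        new.counts = np.asarray(counts)
        if new.counts.shape != self.counts.shape:
            raise ValueError("replacement counts must keep the table shape")
        return new


@dataclass(frozen=True)
class NBModel:
    """Negative-binomial model of reads per bin.

    The pmf is ``P(X=k) = (r/(r+m))^r * Gamma(r+k) / (k! Gamma(r)) *
    (m/(r+m))^k`` with mean ``m`` and variance ``m + m^2/r``; ``r`` is the
    dispersion (shape) parameter and the model approaches Poisson as
    ``r -> inf``.
    """

    m: float
    r: float
    bin_size: int = 10_000
    read_length: int = 100
    depth: float | None = None

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.r > 0):
            raise ValueError("NB model requires m > 0 and r > 0")
        if self.depth is None:
            # haploid coverage implied by the per-bin mean
            object.__setattr__(
                self, "depth", self.m * self.read_length / self.bin_size
            )

    @property
    def variance(self) -> float:
        return self.m + self.m**2 / self.r

    def at_depth(self, depth: float) -> "NBModel":
        """Rescale the mean to another haploid coverage.

        Binomial thinning of NB(m, r) leaves r unchanged, so only the mean
        scales with depth.
        """
        if depth <= 0:
            raise ValueError("depth must be positive")
        scale = depth / self.depth
        return replace(self, m=self.m * scale, depth=depth)


@dataclass(frozen=True)
class PoissonModel:
    """Poisson model of reads per bin (the equidispersed alternative)."""

    m: float
    bin_size: int = 10_000
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("Poisson model requires m > 0")

    @property
    def variance(self) -> float:
        return self.m


@dataclass
class GenomeGrid:
    """Fixed tiling of a genome into coarse segments (nominally 5 or 100 Mb).

    Segments tile each chromosome without gaps or overlaps; the trailing
    segment of a chromosome may be shorter than the nominal width.
    """

    segments: pd.DataFrame
    chrom_sizes: dict[str, int]
    width: int

    def __post_init__(self) -> None:
        self.segments = self.segments.reset_index(drop=True)
        _check_intervals(self.segments)

    @classmethod
    def from_chrom_sizes(
        cls, chrom_sizes: Mapping[str, int], width: int
    ) -> "GenomeGrid":
        if width <= 0:
            raise ValueError("grid width must be positive")
        if not chrom_sizes:
            raise ValueError("empty genome")
        rows = []
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size")
            for start in range(0, size, width):
                rows.append((chrom, start, min(start + width, size)))
        segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(segments=segments, chrom_sizes=dict(chrom_sizes), width=width)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"]).to_numpy()

    def segment_names(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in self.segments[["chrom", "start", "end"]].itertuples(
                index=False
            )
        ]


def synthetic_chrom_sizes(total_bp: int, n_chroms: int = 8) -> dict[str, int]:
    """Partition a synthetic linear genome into named pseudo-chromosomes."""
    if total_bp <= 0 or n_chroms <= 0:
        raise ValueError("total_bp and n_chroms must be positive")
    n_chroms = min(n_chroms, total_bp)
    base = total_bp // n_chroms
    sizes = {}
    remaining = total_bp
    for i in range(n_chroms):
        size = base if i < n_chroms - 1 else remaining
        sizes[f"chr{i + 1}"] = size
        remaining -= size
    return sizes


def make_bins(n_bins: int, bin_size: int = 10_000, n_chroms: int = 8) -> pd.DataFrame:
    """Exactly ``n_bins`` adjacent fixed-width bins over a synthetic genome.

    Chromosome sizes are forced to whole multiples of ``bin_size`` so every
    bin has the nominal width.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    n_chroms = max(1, min(n_chroms, n_bins))
    per = n_bins // n_chroms
    chrom_bins = [per] * (n_chroms - 1) + [n_bins - per * (n_chroms - 1)]
    chroms = np.repeat(
        [f"chr{i + 1}" for i in range(n_chroms)], chrom_bins
    )
    idx = np.concatenate([np.arange(b) for b in chrom_bins])
    starts = idx * bin_size
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + bin_size}
    )
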