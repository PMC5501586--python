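"""Theoretical limit of detection for ctDNA copy-number variants.

Given a negative-binomial model of reads per bin fitted on healthy cfDNA,
this module answers: at sequencing depth *d*, ctDNA fraction *f* and copy
change Δc, how small a CNV (length *L*) is detectable?

A CNV region of length L is treated as one super-bin. A sum of n i.i.d.
NB(m, r) variables with a common success probability is NB(n·m, n·r), so the
region baseline is NB(M0, R) with M0 = d·L/ℓ reads (ℓ the read length) and
R = r_bin · L / bin_size. A carrier's cfDNA is a linear tumor/normal mixture,
so the affected expectation is M1 = M0 · (1 + f·Δc/2). The detection p-value
is the right tail of the baseline NB at ⌈M1⌉ for gains (left tail at ⌊M1⌋
for losses), detected when p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import NBModel

__all__ = [
    "PowerQuery",
    "nb_pmf",
    "nb_right_tail",
    "nb_left_tail",
    "expected_region_counts",
    "detection_pvalue",
    "min_detectable_size",
    "lod_grid",
    "default_size_grid",
    "P_THRESHOLD",
]

#: Detection p-value threshold.
P_THRESHOLD = 0.01

MB = 1_000_000


@dataclass(frozen=True)
class PowerQuery:
    """One limit-of-detection question.

    depth
        Haploid genome coverage *d*.
    fraction
        ctDNA fraction *f* of total cfDNA, in [0, 1].
    copy_delta
        Signed copy change Δc of the tumor relative to diploid (tumor copy
        number is 2 + Δc).
    size
        CNV length *L* in bp.
    read_length
        Read length ℓ in bp.
    """

    depth: float
    fraction: float
    copy_delta: int
    size: int
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("ctDNA fraction must lie in [0, 1]")
        if 2 + self.copy_delta < 0:
            raise ValueError("tumor copy number 2 + copy_delta must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.size <= 0:
            raise ValueError("size must be positive")


def _validate_nb(m: float, r: float) -> None:
    if not (m > 0 and r > 0):
        raise ValueError("NB parameters m and r must be positive")


def nb_pmf(k, m: float, r: float):
    """Negative-binomial pmf with mean ``m`` and dispersion ``r``.

    ``P(X=k) = (r/(r+m))^r · Γ(r+k)/(k!·Γ(r)) · (m/(r+m))^k``, evaluated in
    log space. At r = 1 this is geometric; as r → ∞ it tends to Poisson(m).
    """
    _validate_nb(m, r)
    k = np.asarray(k)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer) and np.any(k != np.floor(k)):
        raise ValueError("k must be a non-negative integer")
    out = np.exp(stats.nbinom.logpmf(k, r, r / (r + m)))
    return float(out) if out.ndim == 0 else out


def nb_right_tail(k, m: float, r: float):
    """Upper tail P(X >= k) of NB(m, r)."""
    _validate_nb(m, r)
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = stats.nbinom.sf(k - 1, r, r / (r + m))
    return float(out) if out.ndim == 0 else out


def nb_left_tail(k, m: float, r: float):
    """Lower tail P(X <= k) of NB(m, r)."""
    _validate_nb(m, r)
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = stats.nbinom.cdf(k, r, r / (r + m))
    return float(out) if out.ndim == 0 else out


def expected_region_counts(
    q: PowerQuery, model: NBModel
) -> tuple[float, float, float]:
    """Baseline mean M0, affected mean M1 and dispersion R for a CNV region.

    The region is floored to whole bins (with a warning when the requested
    size is not a bin multiple). The per-bin dispersion is invariant under
    depth changes (binomial thinning of an NB leaves r unchanged), so R
    depends only on the number of bins spanned.
    """
    n_bins = q.size // model.bin_size
    if n_bins < 1:
        raise ValueError("CNV size must span at least one bin")
    if q.size % model.bin_size:
        warnings.warn(
            "CNV size is not a whole number of bins; flooring",
            RuntimeWarning,
            stacklevel=2,
        )
    length = n_bins * model.bin_size
    m0 = q.depth * length / q.read_length
    m1 = m0 * (1.0 + q.fraction * q.copy_delta / 2.0)
    big_r = model.r * n_bins
    return m0, m1, big_r


def detection_pvalue(q: PowerQuery, model: NBModel) -> float:
    """Detection p-value for a CNV region under the baseline NB model.

    Gains: right tail of NB(M0, R) at ⌈M1⌉. Losses: left tail at ⌊M1⌋.
    A ctDNA fraction of zero gives M1 = M0 and a p-value near 0.5 — never
    detected at the 0.01 threshold.
    """
    m0, m1, big_r = expected_region_counts(q, model)
    if q.copy_delta >= 0:
        return float(nb_right_tail(int(np.ceil(m1)), m0, big_r))
    return float(nb_left_tail(int(np.floor(m1)), m0, big_r))


def default_size_grid(
    max_mb: int = 250, step_mb: int = 1
) -> np.ndarray:
    """CNV sizes from 1 Mb to ``max_mb`` in ``step_mb`` steps (bp)."""
    return np.arange(step_mb, max_mb + step_mb, step_mb) * MB


def min_detectable_size(
    depth: float,
    fraction: float,
    copy_delta: int,
    model: NBModel,
    size_grid: np.ndarray | None = None,
    p_threshold: float = P_THRESHOLD,
    read_length: int | None = None,
) -> int | None:
    """Smallest grid size whose detection p-value beats the threshold.

    Returns ``None`` when no size on the grid is detectable (e.g. very low
    ctDNA fraction at shallow depth).
    """
    if size_grid is None:
        size_grid = default_size_grid()
    size_grid = np.asarray(size_grid)
    if size_grid.size == 0:
        raise ValueError("empty size grid")
    if np.any(np.diff(size_grid) <= 0):
        raise ValueError("size grid must be sorted ascending")
    if read_length is None:
        read_length = model.read_length
    for size in size_grid:
        q = PowerQuery(
            depth=depth,
            fraction=fraction,
            copy_delta=copy_delta,
            size=int(size),
            read_length=read_length,
        )
        if detection_pvalue(q, model) < p_threshold:
            return int(size)
    return None


def lod_grid(
    depths,
    fractions,
    copy_deltas,
    model: NBModel,
    size_grid: np.ndarray | None = None,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Limit-of-detection table over the Cartesian product of query axes.

    Rows hold the minimal detectable size in Mb (NaN when undetectable on
    the grid) and the p-value achieved at that size; plot-ready for
    depth-vs-LOD curves per ctDNA fraction and copy change.
    """
    depths = list(depths)
    fractions = list(fractions)
    copy_deltas = list(copy_deltas)
    if not depths or not fractions or not copy_deltas:
        raise ValueError("all query axes must be non-empty")
    rows = []
    for dc in copy_deltas:
        for f in fractions:
            for d in depths:
                size = min_detectable_size(
                    d, f, dc, model, size_grid, p_threshold
                )
                if size is None:
                    rows.append((d, f, dc, np.nan, np.nan))
                else:
                    q = PowerQuery(
                        depth=d,
                        fraction=f,
                        copy_delta=dc,
                        size=size,
                        read_length=model.read_length,
                    )
                    rows.append(
                        (d, f, dc, size / MB, detection_pvalue(q, model))
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "depth",
            "fraction",
            "copy_delta",
            "min_size_mb",
            "p_at_min_size",
        ],
    )


def normal_approx_min_size(
    depth: float,
    fraction: float,
    copy_delta: int,
    model: NBModel,
    p_threshold: float = P_THRESHOLD,
    read_length: int | None = None,
) -> float:
    """Closed-form LOD size from the normal approximation (in bp).

    Solves ``(f·|Δc|/2) / sqrt(1/M0 + 1/R) = z`` for L, with
    ``M0 = d·L/ℓ`` and ``R = r·L/bin``:
    ``L* = z² (ℓ/d + bin/r) / (f·|Δc|/2)²``. Used as an independent oracle
    for the exact NB computation at large expected counts.
    """
    if fraction <= 0 or copy_delta == 0:
        return float("inf")
    if read_length is None:
        read_length = model.read_length
    z = stats.norm.isf(p_threshold)
    effect = fraction * abs(copy_delta) / 2.0
    return float(
        z**2 * (read_length / depth + model.bin_size / model.r) / effect**2
    )
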