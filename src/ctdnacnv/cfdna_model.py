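"""Preprocessing and count-distribution modelling of binned cfDNA reads.

The chain mirrors low-pass cfDNA practice: (1) mask mismapping-prone bins by
Mahalanobis distance from a robust Minimum Covariance Determinant estimate of
the per-bin count distribution across donors, (2) remove GC bias with a LOESS
fit of count against GC fraction, (3) fit negative-binomial and Poisson
models to the cleaned counts and compare them with a chi-squared
goodness-of-fit test. Depth subsampling (binomial thinning) supplies the
model parameters at lower sequencing depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.covariance import MinCovDet
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import BinCountTable, DegenerateDataError, NBModel, PoissonModel

__all__ = [
    "mcd_outlier_mask",
    "gc_correct",
    "fit_count_model",
    "gof_chisq",
    "subsample_depth",
    "FitDiagnostics",
]

#: Cap on the fitted dispersion; at r = 1e8 the NB is numerically Poisson.
R_CAP = 1e8


def mcd_outlier_mask(
    table: BinCountTable,
    distance_threshold: float = 15.0,
    support_fraction: float = 0.75,
    random_state: int = 0,
) -> tuple[BinCountTable, np.ndarray]:
    """Mask outlier bins by robust Mahalanobis distance.

    Each bin is one observation whose coordinates are its counts across the
    samples. Location and scatter are the raw MCD estimates (covariance of
    the determinant-minimising h-subset times the chi-squared-median
    consistency factor); bins whose Mahalanobis distance from that estimate
    exceeds ``distance_threshold`` are marked unusable.

    Returns the table with an updated mask together with the per-bin
    distances (NaN for bins that were already masked).
    """
    if table.n_samples < 2:
        raise ValueError("MCD masking needs at least 2 samples")
    usable = np.flatnonzero(table.mask)
    X = table.counts[usable].astype(float)
    if X.shape[0] < 10 * table.n_samples:
        raise ValueError("need at least 10x more usable bins than samples")
    if np.any(X.std(axis=0) == 0):
        raise DegenerateDataError("constant counts give a singular scatter")

    mcd = MinCovDet(
        support_fraction=support_fraction, random_state=random_state
    ).fit(X)
    loc = mcd.raw_location_
    cov = mcd.raw_covariance_
    # consistency correction: median raw distance matched to chi2 median
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateDataError("singular MCD scatter matrix") from exc
    centered = X - loc
    d2_raw = np.einsum("ij,jk,ik->i", centered, prec, centered)
    factor = np.median(d2_raw) / stats.chi2.ppf(0.5, df=table.n_samples)
    if factor <= 0:
        raise DegenerateDataError("degenerate MCD distances")
    dist = np.sqrt(d2_raw / factor)

    new = table.copy()
    distances = np.full(table.n_bins, np.nan)
    distances[usable] = dist
    new.mask = table.mask & ~(distances > distance_threshold)
    return new, distances


def gc_correct(
    table: BinCountTable, loess_span: float = 0.3
) -> BinCountTable:
    """Remove GC bias by LOESS normalisation to the grand mean count.

    Per sample, a locally weighted regression of count on GC fraction over
    usable bins gives the expected count ``c(gc)``; corrected counts are
    ``round(raw * M / c(gc))`` where ``M`` is the grand mean count over all
    usable bins and samples. Using a common target also equalises
    library-size differences between samples, so the corrected counts pool
    into a single count distribution. Masked bins pass through unchanged.
    """
    if not (0.0 < loess_span <= 1.0):
        raise ValueError("loess_span must lie in (0, 1]")
    usable = table.mask
    if usable.sum() < 1000:
        raise ValueError("GC correction needs at least 1000 usable bins")
    gc = table.gc[usable]
    if np.ptp(gc) == 0:
        raise DegenerateDataError("GC values are constant")

    grand_mean = table.counts[usable].mean()
    new = table.copy()
    span = np.ptp(gc)
    for j in range(table.n_samples):
        y = table.counts[usable, j].astype(float)
        fit = lowess(
            y, gc, frac=loess_span, it=2, delta=0.005 * span, return_sorted=True
        )
        fitted = np.interp(table.gc, fit[:, 0], fit[:, 1])
        if np.any(fitted[usable] <= 0):
            raise DegenerateDataError("non-positive LOESS fit; cannot correct")
        corrected = np.rint(
            table.counts[:, j] * grand_mean / fitted
        ).astype(table.counts.dtype)
        new.counts[usable, j] = np.maximum(corrected[usable], 0)
    new.meta.pop("expected_means", None)  # recipe no longer matches
    new.meta["gc_corrected"] = True
    return new


@dataclass(frozen=True)
class FitDiagnostics:
    loglik_nb: float
    loglik_poisson: float
    n_obs: int
    underdispersed: bool

    @property
    def delta_loglik(self) -> float:
        """NB minus Poisson log-likelihood (positive favours NB)."""
        return self.loglik_nb - self.loglik_poisson


def _nb_loglik(counts: np.ndarray, m: float, r: float) -> float:
    p = r / (r + m)
    return float(np.sum(stats.nbinom.logpmf(counts, r, p)))


def fit_count_model(
    table: BinCountTable,
    read_length: int | None = None,
) -> tuple[NBModel, PoissonModel, FitDiagnostics]:
    """Fit negative-binomial and Poisson models to pooled usable counts.

    The NB mean MLE is the sample mean; the dispersion r is found by
    maximising the profile log-likelihood, initialised at the
    method-of-moments estimate ``m^2 / (var - m)``. Underdispersed data
    (variance < mean) cannot identify r; the fit is then reported with r
    capped at a large finite value and flagged.
    """
    counts = table.usable_counts().ravel()
    if counts.size < 1000:
        raise ValueError("model fitting needs at least 1000 usable counts")
    m = float(counts.mean())
    if m <= 0:
        raise DegenerateDataError("all counts are zero")
    var = float(counts.var())
    if var == 0:
        raise DegenerateDataError("constant counts: nothing to fit")
    if read_length is None:
        read_length = int(table.meta.get("read_length", 100))

    underdispersed = var <= m
    if underdispersed:
        warnings.warn(
            "variance <= mean: dispersion not identifiable, capping r",
            RuntimeWarning,
            stacklevel=2,
        )
        r = R_CAP
    else:
        r0 = m**2 / (var - m)
        # profile likelihood in log r, bracketed around the moment estimate
        def neg_ll(log_r: float) -> float:
            return -_nb_loglik(counts, m, np.exp(log_r))

        res = optimize.minimize_scalar(
            neg_ll,
            bounds=(np.log(r0) - 5.0, min(np.log(r0) + 5.0, np.log(R_CAP))),
            method="bounded",
            options={"xatol": 1e-6},
        )
        r = float(np.exp(res.x))

    nb = NBModel(
        m=m, r=r, bin_size=table.bin_size, read_length=read_length
    )
    pois = PoissonModel(m=m, bin_size=table.bin_size, read_length=read_length)
    diag = FitDiagnostics(
        loglik_nb=_nb_loglik(counts, m, r),
        loglik_poisson=float(np.sum(stats.poisson.logpmf(counts, m))),
        n_obs=int(counts.size),
        underdispersed=underdispersed,
    )
    return nb, pois, diag


def _model_dist(model: NBModel | PoissonModel):
    if isinstance(model, NBModel):
        return stats.nbinom(model.r, model.r / (model.r + model.m)), 2
    return stats.poisson(model.m), 1


def gof_chisq(
    table: BinCountTable,
    model: NBModel | PoissonModel,
    n_cells: int = 30,
) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit over equal-probability count cells.

    Cell edges are model quantiles at ``i/n_cells``; cells whose expected
    count falls below 5 are merged into their neighbour. Degrees of freedom
    are ``cells - fitted parameters - 1``.
    """
    if n_cells < 5:
        raise ValueError("need at least 5 cells")
    counts = table.usable_counts().ravel()
    dist, n_params = _model_dist(model)
    n = counts.size

    qs = np.arange(1, n_cells) / n_cells
    edges = np.unique(dist.ppf(qs)).astype(int)  # integer upper bounds
    # cell i: counts in (edges[i-1], edges[i]]; outermost cells open-ended
    cdf_at = dist.cdf(edges)
    probs = np.diff(np.concatenate([[0.0], cdf_at, [1.0]]))
    obs_cum = np.searchsorted(np.sort(counts), edges, side="right")
    obs = np.diff(np.concatenate([[0], obs_cum, [n]]))

    # merge low-expectation cells left to right
    exp = probs * n
    merged_obs, merged_exp = [], []
    acc_o, acc_e = 0.0, 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0:
        if merged_exp:
            merged_obs[-1] += acc_o
            merged_exp[-1] += acc_e
        else:
            raise ValueError("too few observations to populate cells")
    obs_a = np.asarray(merged_obs)
    exp_a = np.asarray(merged_exp)
    if len(obs_a) < n_params + 2:
        raise ValueError("too few populated cells for the test")

    statistic = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    df = len(obs_a) - n_params - 1
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value


def subsample_depth(
    table: BinCountTable, target_fraction: float, seed: int
) -> BinCountTable:
    """Thin every count binomially to emulate a lower sequencing depth."""
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    new = table.copy()
    if target_fraction < 1.0:
        new.counts = rng.binomial(table.counts, target_fraction)
        if "expected_means" in new.meta:
            new.meta["expected_means"] = (
                np.asarray(new.meta["expected_means"]) * target_fraction
            )
    new.meta["depth_fraction"] = (
        table.meta.get("depth_fraction", 1.0) * target_fraction
    )
    return new
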