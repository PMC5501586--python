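"""Synthetic-data generators with known ground truth.

Everything the screening pipeline consumes can be generated here: healthy
cfDNA bin counts (negative-binomial with GC bias, library-size variation and
planted outlier bins), ctDNA spike-ins, tumor segmentation cohorts with
cancer-type-specific recurrent copy-number signatures, and a germline
allele-frequency resource. Generators are bit-reproducible under a fixed
seed and return the ground truth needed for parameter-recovery tests.

No raw reads, fragment-length distributions or sequencing errors are
simulated: the entry point of the pipeline is the binned count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinCountTable, GenomeGrid, make_bins

__all__ = [
    "HealthySimParams",
    "HealthySim",
    "CancerSignature",
    "RecurrentEvent",
    "quadratic_gc_bias",
    "gen_healthy_bincounts",
    "spike_cnv",
    "gen_tumor_cohort",
    "separable_signatures",
    "gen_germline_resource",
]

#: Default Beta parameters for per-bin GC fractions (mean 0.41, sd ~0.107),
#: mimicking the genome-wide GC distribution of 10 kb bins.
DEFAULT_GC_BETA = (8.2, 11.8)

#: Copy-delta distribution for passenger (non-recurrent) events.
PASSENGER_DELTAS = {-2: 0.10, -1: 0.35, 1: 0.35, 2: 0.15, 3: 0.05}


def quadratic_gc_bias(
    amplitude: float = 0.3,
    center: float | None = None,
    gc_beta: tuple[float, float] = DEFAULT_GC_BETA,
) -> tuple[float, float, float]:
    """Coefficients of a smooth quadratic multiplicative GC-bias curve.

    The raw curve is ``1 + amplitude * (1 - ((gc - center)/s)^2)`` with
    ``s = max(center, 1 - center)``, which peaks at ``center`` and stays
    strictly positive on [0, 1] for ``amplitude > -1``. It is then divided
    by its expectation under the Beta GC distribution so the genome-wide
    mean count is not shifted by the bias.

    Returns ascending polynomial coefficients ``(c0, c1, c2)`` to be
    evaluated as ``c0 + c1*gc + c2*gc^2``.
    """
    a, b = gc_beta
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    if center is None:
        center = mean
    s = max(center, 1.0 - center)
    # expand 1 + A*(1 - ((g-c)/s)^2) in powers of g
    c0 = 1.0 + amplitude * (1.0 - center**2 / s**2)
    c1 = amplitude * 2.0 * center / s**2
    c2 = -amplitude / s**2
    # normalise: E[(g-c)^2] = var + (mean-c)^2
    e_bias = 1.0 + amplitude * (1.0 - (var + (mean - center) ** 2) / s**2)
    return (c0 / e_bias, c1 / e_bias, c2 / e_bias)


def _eval_bias(coeffs: tuple[float, ...], gc: np.ndarray) -> np.ndarray:
    return np.polyval(list(reversed(coeffs)), gc)


@dataclass(frozen=True)
class HealthySimParams:
    """Generation recipe for healthy-donor cfDNA bin counts.

    Defaults emulate the study conditions: ~300 reads expected per 10 kb bin
    (roughly 3x haploid coverage of 100 bp reads), negative-binomial
    dispersion r = 50, a quadratic GC bias of about +-30% amplitude, 1% of
    bins inflated 10-fold (mismapping-prone regions), nine donors, and a 5%
    log-normal library-size spread across donors.
    """

    mean_per_bin: float = 300.0
    dispersion: float = 50.0
    gc_bias_coeffs: tuple[float, ...] = field(
        default_factory=lambda: quadratic_gc_bias(0.3)
    )
    outlier_fraction: float = 0.01
    outlier_multiplier: float = 10.0
    n_bins: int = 200_000
    n_samples: int = 9
    seed: int = 0
    bin_size: int = 10_000
    read_length: int = 100
    n_chroms: int = 8
    gc_beta: tuple[float, float] = DEFAULT_GC_BETA
    sample_scale_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_per_bin <= 0:
            raise ValueError("mean_per_bin must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier_multiplier must be positive")
        if self.n_bins <= 0 or self.n_samples <= 0:
            raise ValueError("n_bins and n_samples must be positive")
        grid = np.linspace(0.0, 1.0, 1001)
        if np.any(_eval_bias(self.gc_bias_coeffs, grid) <= 0):
            raise ValueError("GC bias curve must be strictly positive on [0,1]")


@dataclass
class HealthySim:
    """A simulated healthy cohort plus its ground truth."""

    table: BinCountTable
    outlier_bins: np.ndarray  # indices of planted outlier bins
    sample_scales: np.ndarray  # realized library-size factors s_j
    params: HealthySimParams

    @property
    def expected_means(self) -> np.ndarray:
        return self.table.meta["expected_means"]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    """Draw NB(mean, r) counts; mean 0 yields 0 exactly."""
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_healthy_bincounts(params: HealthySimParams) -> HealthySim:
    """Simulate a healthy-donor bin-count table with known ground truth.

    Counts for bin *i*, sample *j* are NB with mean
    ``mean_per_bin * bias(gc_i) * s_j`` and dispersion ``r``; a random
    ``outlier_fraction`` of bins has its mean inflated by
    ``outlier_multiplier`` in every sample (mimicking mismapping-prone
    regions that the MCD masking step must find).
    """
    rng = np.random.default_rng(params.seed)
    bins = make_bins(params.n_bins, params.bin_size, params.n_chroms)
    gc = rng.beta(*params.gc_beta, size=params.n_bins)
    bias = _eval_bias(params.gc_bias_coeffs, gc)
    scales = np.exp(
        rng.normal(0.0, params.sample_scale_sigma, size=params.n_samples)
    )
    means = params.mean_per_bin * bias[:, None] * scales[None, :]

    n_out = int(np.floor(params.outlier_fraction * params.n_bins))
    outlier_bins = np.sort(
        rng.choice(params.n_bins, size=n_out, replace=False)
    )
    means[outlier_bins, :] *= params.outlier_multiplier

    counts = _nb_draw(rng, means, params.dispersion)
    table = BinCountTable(
        bins=bins,
        gc=gc,
        counts=counts,
        samples=[f"donor{j + 1}" for j in range(params.n_samples)],
        bin_size=params.bin_size,
        meta={
            "expected_means": means,
            "dispersion": params.dispersion,
            "read_length": params.read_length,
        },
    )
    return HealthySim(
        table=table,
        outlier_bins=outlier_bins,
        sample_scales=scales,
        params=params,
    )


def spike_cnv(
    table: BinCountTable,
    region: tuple[str, int, int],
    copy_delta: int,
    fraction: float,
    seed: int,
    samples: list[str] | None = None,
) -> BinCountTable:
    """Spike a ctDNA copy-number variant into a simulated count table.

    cfDNA from a carrier is a linear mixture of tumor and normal fragments,
    so a region at tumor copy number ``2 + copy_delta`` present at ctDNA
    fraction ``f`` has its expected read depth scaled by
    ``1 + f * copy_delta / 2``. Counts for bins inside the region are redrawn
    from the table's stored NB recipe with the scaled mean; bins outside are
    untouched.

    Requires a table produced by :func:`gen_healthy_bincounts` (the recipe
    lives in ``table.meta``).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("ctDNA fraction must lie in [0, 1]")
    if 2 + copy_delta < 0:
        raise ValueError("tumor copy number 2 + copy_delta must be >= 0")
    if "expected_means" not in table.meta or "dispersion" not in table.meta:
        raise ValueError(
            "spike_cnv needs a synthetic table carrying its generation "
            "recipe in table.meta"
        )
    chrom, start, end = region
    hit = table.region_index(chrom, start, end)
    if not hit.any():
        raise ValueError("region contains no whole bins of the table")

    rng = np.random.default_rng(seed)
    scale = 1.0 + fraction * copy_delta / 2.0
    r = table.meta["dispersion"]
    means = np.asarray(table.meta["expected_means"])
    cols = (
        slice(None)
        if samples is None
        else [table.samples.index(s) for s in samples]
    )
    new = table.copy()
    region_means = means[hit][:, cols] * scale
    new.counts[np.ix_(hit, np.arange(table.n_samples)[cols])] = _nb_draw(
        rng, region_means, r
    )
    new_means = means.copy()
    new_means[np.ix_(hit, np.arange(table.n_samples)[cols])] = region_means
    new.meta["expected_means"] = new_means
    new.meta.setdefault("spikes", []).append(
        {"region": region, "copy_delta": copy_delta, "fraction": fraction}
    )
    return new


@dataclass(frozen=True)
class RecurrentEvent:
    """One recurrent CNV event of a cancer-type signature."""

    segment: int  # index into the GenomeGrid
    probability: float  # per-sample Bernoulli probability
    copy_deltas: tuple[tuple[int, float], ...] = ((2, 1.0),)

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("event probability must lie in [0, 1]")
        probs = [p for _, p in self.copy_deltas]
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("copy_deltas must be a probability distribution")
        if any(2 + d < 0 for d, _ in self.copy_deltas):
            raise ValueError("copy deltas below -2 are impossible")


@dataclass(frozen=True)
class CancerSignature:
    """Recurrent-CNV signature of one cancer type.

    ``flatness`` scales all event probabilities, letting CNV-poor types
    (near-flat profiles) be emulated; ``passenger_rate`` is the expected
    number of random extra events per sample.
    """

    type_name: str
    recurrent_events: tuple[RecurrentEvent, ...] = ()
    passenger_rate: float = 0.0
    flatness: float = 1.0

    def __post_init__(self) -> None:
        if self.passenger_rate < 0:
            raise ValueError("passenger_rate must be >= 0")
        if not (0.0 <= self.flatness <= 1.0):
            raise ValueError("flatness must lie in [0, 1]")


def separable_signatures(
    type_names: list[str],
    grid: GenomeGrid,
    segments_per_type: int = 2,
    copy_delta: int = 2,
    passenger_rate: float = 0.5,
) -> list[CancerSignature]:
    """Disjoint probability-1 signatures, one per type, for recovery tests.

    Type *t* receives ``segments_per_type`` consecutive grid segments
    starting at ``t * segments_per_type``; every sample of the type carries
    all of them (Bernoulli probability 1), plus Poisson-many passengers.
    """
    need = len(type_names) * segments_per_type
    if need > grid.n_segments:
        raise ValueError("grid too small for disjoint signatures")
    sigs = []
    for t, name in enumerate(type_names):
        events = tuple(
            RecurrentEvent(
                segment=t * segments_per_type + k,
                probability=1.0,
                copy_deltas=((copy_delta, 1.0),),
            )
            for k in range(segments_per_type)
        )
        sigs.append(
            CancerSignature(
                type_name=name,
                recurrent_events=events,
                passenger_rate=passenger_rate,
            )
        )
    return sigs


def gen_tumor_cohort(
    signatures: list[CancerSignature],
    n_per_type: dict[str, int],
    grid: GenomeGrid,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tumor segmentation cohort from per-type CNV signatures.

    Returns ``(records, labels)``: segmentation records with columns
    ``sample, chrom, start, end, copies`` (absolute copy number; events span
    whole grid segments) and a per-sample label table. A signature with no
    events and zero passenger rate yields flat (record-free) samples.
    """
    by_name = {s.type_name: s for s in signatures}
    if len(by_name) != len(signatures):
        raise ValueError("type_name must be unique within a cohort spec")
    unknown = set(n_per_type) - set(by_name)
    if unknown:
        raise ValueError(f"n_per_type names unknown signatures: {sorted(unknown)}")
    for sig in signatures:
        for ev in sig.recurrent_events:
            if not (0 <= ev.segment < grid.n_segments):
                raise ValueError(
                    f"signature {sig.type_name!r} references segment "
                    f"{ev.segment} outside the grid"
                )

    rng = np.random.default_rng(seed)
    seg = grid.segments
    pass_deltas = np.array(list(PASSENGER_DELTAS))
    pass_probs = np.array(list(PASSENGER_DELTAS.values()))

    rows = []
    labels = []
    counter = 0
    for name in n_per_type:  # insertion order: deterministic
        sig = by_name[name]
        for _ in range(n_per_type[name]):
            counter += 1
            sample = f"S{counter:04d}"
            labels.append((sample, name))
            for ev in sig.recurrent_events:
                if rng.random() < ev.probability * sig.flatness:
                    deltas = [d for d, _ in ev.copy_deltas]
                    probs = [p for _, p in ev.copy_deltas]
                    delta = int(rng.choice(deltas, p=probs))
                    c, s, e = seg.iloc[ev.segment][["chrom", "start", "end"]]
                    rows.append((sample, c, int(s), int(e), 2.0 + delta))
            n_pass = rng.poisson(sig.passenger_rate)
            for _ in range(n_pass):
                j = int(rng.integers(grid.n_segments))
                delta = int(rng.choice(pass_deltas, p=pass_probs))
                c, s, e = seg.iloc[j][["chrom", "start", "end"]]
                rows.append((sample, c, int(s), int(e), 2.0 + delta))

    records = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "copies"]
    )
    label_table = pd.DataFrame(labels, columns=["sample", "type"])
    return records, label_table


def gen_germline_resource(
    grid: GenomeGrid,
    n_events: int,
    af_range: tuple[float, float] = (0.001, 0.2),
    length_range: tuple[int, int] = (50_000, 1_000_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a population CNV resource (BED-like with allele frequency).

    Emits ``n_events`` intervals at random genome positions with allele
    frequencies uniform over ``af_range``; the ``common`` column marks the
    ground truth of which events exceed the 1% germline-filter threshold.
    """
    lo, hi = af_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("af_range must lie within [0, 1]")
    if grid.n_segments == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    rows = []
    chroms = list(grid.chrom_sizes)
    for _ in range(n_events):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = grid.chrom_sizes[chrom]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        length = min(length, size)
        start = int(rng.integers(0, size - length + 1))
        af = float(rng.uniform(lo, hi))
        rows.append((chrom, start, start + length, af))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "af"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df["common"] = df["af"] > 0.01
    return df


def binomial_thin(
    counts: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Binomial thinning of counts at the given retention fraction.

    Thinning an NB(m, r) count at rate p yields NB(p*m, r): the dispersion
    parameter is invariant, which is what lets the power model reuse the
    fitted r across sequencing depths.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(np.asarray(counts), fraction)
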