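"""End-to-end orchestration: simulate → preprocess → power → profile → classify.

Every stage writes plain-text artifacts into the output directory and logs
the exact parameters used, so any downstream number is auditable. Runs are
deterministic under a fixed configuration: two invocations with the same
seeds produce byte-identical outputs.

Default problem sizes are scaled for quick desk runs (20k bins, a few
hundred cohort samples); all sizes are configuration fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cfdna_model, classify, detectability, io, power, synthdata
from .core import GenomeGrid, synthetic_chrom_sizes

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("ctdnacnv")

MB = 1_000_000


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """Configuration for the full in-silico screening pipeline."""

    outdir: str = "ctdnacnv_run"
    seed: int = 0
    # healthy cfDNA simulation / preprocessing
    bin_size: int = 10_000
    read_length: int = 100
    n_bins: int = 20_000
    n_donors: int = 9
    mean_per_bin: float = 300.0
    dispersion: float = 50.0
    gc_bias_amplitude: float = 0.3
    outlier_fraction: float = 0.01
    outlier_multiplier: float = 10.0
    mcd_distance_threshold: float = 15.0
    loess_span: float = 0.3
    # power analysis
    p_threshold: float = 0.01
    depths: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    fractions: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1)
    copy_deltas: tuple[int, ...] = (1, 4)
    # cohort simulation / profiling
    grid_size: int = 5 * MB
    genome_bp: int = 1_200 * MB
    n_chroms: int = 10
    cancer_types: tuple[str, ...] = ("typeA", "typeB", "typeC", "typeD", "typeE")
    n_per_cancer_type: int = 40
    n_normal: int = 80
    segments_per_signature: int = 2
    signature_copy_delta: int = 2
    passenger_rate: float = 0.5
    n_germline_events: int = 60
    af_threshold: float = 0.01
    # classification
    cv_folds: int = 10
    knn_k: int | None = None
    rf_trees: int = 100

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.af_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.mcd_distance_threshold <= 0:
            raise ValueError("mcd_distance_threshold must be positive")
        if self.grid_size % self.bin_size:
            raise ValueError("grid_size must be a multiple of bin_size")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("depths", "fractions", "copy_deltas", "cancer_types"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate-healthy")
def _simulate_healthy(cfg: PipelineConfig, outdir: Path) -> synthdata.HealthySim:
    params = synthdata.HealthySimParams(
        mean_per_bin=cfg.mean_per_bin,
        dispersion=cfg.dispersion,
        gc_bias_coeffs=synthdata.quadratic_gc_bias(cfg.gc_bias_amplitude),
        outlier_fraction=cfg.outlier_fraction,
        outlier_multiplier=cfg.outlier_multiplier,
        n_bins=cfg.n_bins,
        n_samples=cfg.n_donors,
        seed=cfg.seed,
        bin_size=cfg.bin_size,
        read_length=cfg.read_length,
    )
    sim = synthdata.gen_healthy_bincounts(params)
    io.write_bincounts(sim.table, outdir / "healthy_bincounts.tsv")
    truth = {
        "outlier_bins": sim.outlier_bins.tolist(),
        "sample_scales": sim.sample_scales.tolist(),
        "mean_per_bin": params.mean_per_bin,
        "dispersion": params.dispersion,
    }
    (outdir / "healthy_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return sim


@_stage("preprocess")
def _preprocess(cfg: PipelineConfig, outdir: Path, sim: synthdata.HealthySim):
    masked, distances = cfdna_model.mcd_outlier_mask(
        sim.table, distance_threshold=cfg.mcd_distance_threshold
    )
    corrected = cfdna_model.gc_correct(masked, loess_span=cfg.loess_span)
    nb, pois, diag = cfdna_model.fit_count_model(corrected)
    stat_nb, p_nb = cfdna_model.gof_chisq(corrected, nb)
    stat_p, p_p = cfdna_model.gof_chisq(corrected, pois)
    io.model_to_json(nb, outdir / "nb_model.json")
    summary = {
        "n_bins": sim.table.n_bins,
        "n_masked": int((~masked.mask).sum()),
        "nb": {"m": nb.m, "r": nb.r, "depth": nb.depth},
        "poisson_mean": pois.m,
        "loglik_nb": diag.loglik_nb,
        "loglik_poisson": diag.loglik_poisson,
        "gof_nb": {"statistic": stat_nb, "p_value": p_nb},
        "gof_poisson": {"statistic": stat_p, "p_value": p_p},
    }
    (outdir / "preprocess_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return nb


@_stage("power")
def _power(cfg: PipelineConfig, outdir: Path, nb) -> pd.DataFrame:
    lod = power.lod_grid(
        cfg.depths, cfg.fractions, cfg.copy_deltas, nb, p_threshold=cfg.p_threshold
    )
    lod.to_csv(outdir / "lod_table.tsv", sep="\t", index=False, float_format="%.6g")
    return lod


@_stage("simulate-cohort")
def _simulate_cohort(cfg: PipelineConfig, outdir: Path):
    sizes = synthetic_chrom_sizes(cfg.genome_bp, cfg.n_chroms)
    grid = GenomeGrid.from_chrom_sizes(sizes, cfg.grid_size)
    sigs = synthdata.separable_signatures(
        list(cfg.cancer_types),
        grid,
        segments_per_type=cfg.segments_per_signature,
        copy_delta=cfg.signature_copy_delta,
        passenger_rate=cfg.passenger_rate,
    )
    sigs.append(synthdata.CancerSignature(type_name="normal"))
    n_per_type = {t: cfg.n_per_cancer_type for t in cfg.cancer_types}
    n_per_type["normal"] = cfg.n_normal
    records, labels = synthdata.gen_tumor_cohort(
        sigs, n_per_type, grid, seed=cfg.seed + 1
    )
    germline = synthdata.gen_germline_resource(
        grid, n_events=cfg.n_germline_events, seed=cfg.seed + 2
    )
    io.write_seg(records, outdir / "cohort.seg", value_kind="log2")
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    io.write_germline(germline, outdir / "germline_af.bed")
    return records, labels, germline, grid


@_stage("profile")
def _profile(cfg: PipelineConfig, outdir: Path, records, labels, germline, grid):
    profiles = detectability.build_profiles(
        records,
        grid,
        samples=list(labels["sample"]),
        germline_resource=germline,
        af_threshold=cfg.af_threshold,
    )
    tag = f"{cfg.grid_size // MB}mb"
    profiles.avg_dev.to_csv(
        outdir / f"profiles_{tag}_avgdev.tsv", sep="\t", float_format="%.6g"
    )
    profiles.categories.to_csv(outdir / f"profiles_{tag}_categories.tsv", sep="\t")
    profiles.detectable.astype(int).to_csv(
        outdir / f"profiles_{tag}_detectable.tsv", sep="\t"
    )
    frac1 = detectability.cohort_detectable_fraction(profiles, labels, min_events=1)
    frac2 = detectability.cohort_detectable_fraction(profiles, labels, min_events=2)
    pd.DataFrame({"ge1_event": frac1, "ge2_events": frac2}).to_csv(
        outdir / f"detectable_fractions_{tag}.tsv", sep="\t", float_format="%.6g"
    )
    return profiles


def _report_payload(report: classify.ClassifierReport) -> dict:
    payload = {
        "classes": report.classes,
        "accuracy": report.accuracy,
        "accuracy_sd": report.accuracy_sd,
        "tpr": {k: _na(v) for k, v in report.tpr.items()},
        "ppv": {k: _na(v) for k, v in report.ppv.items()},
        "params": report.params,
    }
    if report.optimal_points is not None:
        payload["optimal_points"] = {
            c: {k: _na(v) for k, v in row.items()}
            for c, row in report.optimal_points.iterrows()
        }
    return payload


def _na(v):
    return None if pd.isna(v) else float(v)


@_stage("classify")
def _classify(cfg: PipelineConfig, outdir: Path, profiles, labels):
    y = labels.set_index("sample")["type"].loc[profiles.samples]
    X = profiles.categories

    knn_pred = classify.knn_leave_one_out(X.to_numpy(), y.to_numpy(), k=cfg.knn_k)
    knn_report = classify.report_from_predictions(
        y, pd.Series(knn_pred, index=X.index)
    )
    knn_report.confusion.to_csv(outdir / "knn_confusion.tsv", sep="\t")
    (outdir / "knn_report.json").write_text(
        json.dumps(_report_payload(knn_report), indent=2, sort_keys=True) + "\n"
    )

    _, rf_report = classify.rf_model(
        X, y, n_trees=cfg.rf_trees, cv_folds=cfg.cv_folds, seed=cfg.seed + 3
    )
    rf_report.confusion.to_csv(outdir / "rf_confusion.tsv", sep="\t")
    rf_report.importances.to_csv(
        outdir / "rf_importances.tsv", sep="\t", float_format="%.6g"
    )
    (outdir / "rf_report.json").write_text(
        json.dumps(_report_payload(rf_report), indent=2, sort_keys=True) + "\n"
    )
    for c, curve in rf_report.roc_points.items():
        curve.to_csv(
            outdir / f"roc_{c}.tsv", sep="\t", index=False, float_format="%.6g"
        )

    sim = classify.misclass_similarity(rf_report.confusion, exclude=("normal",))
    sim.heatmap_matrix().to_csv(
        outdir / "misclass_similarity.tsv", sep="\t", float_format="%.6g"
    )

    important = classify.important_segments(rf_report, top_q=50)
    pd.Series(important, name="segment").to_csv(
        outdir / "important_segments.tsv", sep="\t", index=False
    )
    return knn_report, rf_report


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the artifact directory.

    Stages abort with a stage-named :class:`PipelineError`; artifacts of
    completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    sim = _simulate_healthy(config, outdir)
    nb = _preprocess(config, outdir, sim)
    _power(config, outdir, nb)
    records, labels, germline, grid = _simulate_cohort(config, outdir)
    profiles = _profile(config, outdir, records, labels, germline, grid)
    _classify(config, outdir, profiles, labels)
    logger.info("pipeline complete: %s", outdir)
    return outdir
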