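"""Preprocessing chain: outlier masking, GC correction, count-model fits."""

import numpy as np
import pytest
from scipy import stats

import ctdnacnv as c
from ctdnacnv.core import BinCountTable, DegenerateDataError, make_bins


def _table_from_counts(counts, seed=0):
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] < counts.shape[1]:
        counts = counts.T
    n = counts.shape[0]
    rng = np.random.default_rng(seed)
    return BinCountTable(
        bins=make_bins(n),
        gc=rng.beta(8.2, 11.8, size=n),
        counts=counts,
        samples=[f"s{j}" for j in range(counts.shape[1])],
    )


class TestMcdMask:
    def test_planted_outliers_found_clean_bins_kept(self, small_sim):
        masked, dist = c.mcd_outlier_mask(small_sim.table)
        planted = np.zeros(small_sim.table.n_bins, dtype=bool)
        planted[small_sim.outlier_bins] = True
        newly = ~masked.mask
        assert newly[planted].mean() >= 0.95
        assert newly[~planted].mean() <= 0.01

    def test_infinite_threshold_masks_nothing(self, small_sim):
        masked, _ = c.mcd_outlier_mask(small_sim.table, np.inf)
        assert masked.mask.all()

    def test_masking_is_nearly_idempotent(self, small_sim):
        once, _ = c.mcd_outlier_mask(small_sim.table)
        twice, _ = c.mcd_outlier_mask(once)
        extra = once.mask & ~twice.mask
        assert extra.mean() <= 0.01

    def test_constant_counts_are_degenerate(self):
        table = _table_from_counts(np.full((2000, 3), 100))
        with pytest.raises(DegenerateDataError):
            c.mcd_outlier_mask(table)

    def test_single_sample_rejected(self):
        table = _table_from_counts(np.arange(2000) + 100)
        with pytest.raises(ValueError):
            c.mcd_outlier_mask(table)


class TestGcCorrect:
    def test_no_bias_is_near_identity(self):
        params = c.HealthySimParams(
            n_bins=20_000, n_samples=2, gc_bias_coeffs=(1.0,),
            outlier_fraction=0.0, sample_scale_sigma=0.0, seed=2,
        )
        table = c.gen_healthy_bincounts(params).table
        out = c.gc_correct(table)
        rel = np.abs(out.counts - table.counts) / np.maximum(table.counts, 1)
        assert rel.mean() < 0.01

    def test_sample_means_preserved_without_library_variation(self):
        params = c.HealthySimParams(
            n_bins=20_000, n_samples=3, outlier_fraction=0.0,
            sample_scale_sigma=0.0, seed=4,
        )
        table = c.gen_healthy_bincounts(params).table
        out = c.gc_correct(table)
        before = table.counts.mean(axis=0)
        after = out.counts.mean(axis=0)
        assert np.all(np.abs(after - before) / before < 0.01)

    def test_equal_gc_gets_equal_correction_factor(self):
        params = c.HealthySimParams(
            n_bins=5_000, n_samples=1, outlier_fraction=0.0,
            sample_scale_sigma=0.0, seed=5,
        )
        table = c.gen_healthy_bincounts(params).table
        table.gc[1] = table.gc[0]  # force a duplicated GC value
        out = c.gc_correct(table)
        f0 = out.counts[0, 0] / max(table.counts[0, 0], 1)
        f1 = out.counts[1, 0] / max(table.counts[1, 0], 1)
        assert abs(f0 - f1) < 0.02  # identical up to integer rounding

    def test_masked_bins_pass_through(self, small_sim):
        table = small_sim.table.copy()
        table.mask[:50] = False
        out = c.gc_correct(table)
        assert np.array_equal(out.counts[:50], table.counts[:50])

    def test_bad_span_rejected(self, small_sim):
        with pytest.raises(ValueError):
            c.gc_correct(small_sim.table, loess_span=0.0)


class TestFit:
    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(50, 50 / 350, size=100_000)
        nb, pois, diag = c.fit_count_model(_table_from_counts(counts))
        assert abs(nb.m - 300) / 300 < 0.02
        assert abs(nb.r - 50) / 50 < 0.15
        assert diag.delta_loglik > 0
        assert pois.m == pytest.approx(nb.m)

    def test_poisson_data_fits_effectively_poisson(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(300, size=100_000)
        nb, _, _ = c.fit_count_model(_table_from_counts(counts))
        assert nb.r > 10 * nb.m

    def test_constant_counts_degenerate(self):
        with pytest.raises(DegenerateDataError):
            c.fit_count_model(_table_from_counts(np.full(5000, 42)))


class TestGof:
    def test_pvalues_calibrated_under_the_true_family(self):
        """GOF p-values of NB fits on NB data are ~uniform (KS at 200 reps)."""
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            counts = rng.negative_binomial(50, 50 / 350, size=5000)
            table = _table_from_counts(counts)
            nb, _, _ = c.fit_count_model(table)
            _, p = c.gof_chisq(table, nb, n_cells=20)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rejects_poisson_for_overdispersed_counts(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(20, 20 / 320, size=20_000)
        table = _table_from_counts(counts)
        stat, p = c.gof_chisq(table, c.PoissonModel(m=300.0), n_cells=20)
        assert stat >= 0
        assert p < 1e-6

    def test_prefers_generating_family(self):
        """NB data: the NB fit beats Poisson in >= 19/20 replicates."""
        rng = np.random.default_rng(12)
        wins = 0
        for _ in range(20):
            counts = rng.negative_binomial(50, 50 / 350, size=200_000)
            table = _table_from_counts(counts)
            nb, pois, _ = c.fit_count_model(table)
            _, p_nb = c.gof_chisq(table, nb, n_cells=20)
            _, p_pois = c.gof_chisq(table, pois, n_cells=20)
            wins += p_nb > p_pois
        assert wins >= 19

    def test_too_few_cells_rejected(self, small_sim):
        with pytest.raises(ValueError):
            c.gof_chisq(small_sim.table, c.NBModel(m=300, r=50), n_cells=3)


class TestSubsample:
    def test_identity_at_full_fraction(self, small_sim):
        out = c.subsample_depth(small_sim.table, 1.0, seed=1)
        assert np.array_equal(out.counts, small_sim.table.counts)

    def test_total_never_grows(self, small_sim):
        out = c.subsample_depth(small_sim.table, 0.3, seed=1)
        assert out.counts.sum() <= small_sim.table.counts.sum()

    def test_thinning_closure_halves_mean_keeps_dispersion(self):
        rng = np.random.default_rng(13)
        counts = rng.negative_binomial(50, 50 / 350, size=200_000)
        table = _table_from_counts(counts)
        thin = c.subsample_depth(table, 0.5, seed=2)
        nb, _, _ = c.fit_count_model(thin)
        assert abs(nb.m - 150) / 150 < 0.02
        assert abs(nb.r - 50) / 50 < 0.15

    def test_bad_fraction_rejected(self, small_sim):
        with pytest.raises(ValueError):
            c.subsample_depth(small_sim.table, 0.0, seed=1)
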