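"""Generators: moment fidelity, determinism, spike arithmetic, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ctdnacnv as c
from ctdnacnv.synthdata import binomial_thin, quadratic_gc_bias, _eval_bias


def test_flat_bias_counts_match_nb_moments():
    """NB(300, 50) moments: mean within 1%, variance/mean within 5% of 7."""
    params = c.HealthySimParams(
        mean_per_bin=300.0,
        dispersion=50.0,
        gc_bias_coeffs=(1.0,),
        outlier_fraction=0.0,
        n_bins=200_000,
        n_samples=1,
        sample_scale_sigma=0.0,
        seed=11,
    )
    sim = c.gen_healthy_bincounts(params)
    counts = sim.table.counts[:, 0]
    assert abs(counts.mean() - 300.0) / 300.0 < 0.01
    vmr = counts.var() / counts.mean()
    assert abs(vmr - 7.0) / 7.0 < 0.05


def test_same_seed_reproduces_table_bitwise():
    p = c.HealthySimParams(n_bins=2000, n_samples=3, seed=5)
    a = c.gen_healthy_bincounts(p)
    b = c.gen_healthy_bincounts(p)
    assert np.array_equal(a.table.counts, b.table.counts)
    assert np.array_equal(a.table.gc, b.table.gc)
    assert np.array_equal(a.outlier_bins, b.outlier_bins)


def test_unit_outlier_multiplier_leaves_means_unchanged():
    p = c.HealthySimParams(
        n_bins=2000, n_samples=2, outlier_fraction=0.1,
        outlier_multiplier=1.0, gc_bias_coeffs=(1.0,),
        sample_scale_sigma=0.0, seed=3,
    )
    sim = c.gen_healthy_bincounts(p)
    means = sim.expected_means
    assert np.allclose(means[sim.outlier_bins], means[0])


def test_gc_bias_curve_is_mean_one_and_positive():
    coeffs = quadratic_gc_bias(0.3)
    gc = np.linspace(0, 1, 1001)
    assert np.all(_eval_bias(coeffs, gc) > 0)
    # unit mean under the default Beta GC distribution (Monte Carlo)
    rng = np.random.default_rng(0)
    draws = rng.beta(8.2, 11.8, size=200_000)
    assert abs(_eval_bias(coeffs, draws).mean() - 1.0) < 0.005


@pytest.mark.parametrize(
    "bad",
    [
        dict(mean_per_bin=0.0),
        dict(dispersion=-1.0),
        dict(outlier_fraction=0.6),
        dict(gc_bias_coeffs=(-1.0,)),
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        c.HealthySimParams(n_bins=100, n_samples=2, seed=0, **bad)


@pytest.fixture(scope="module")
def spike_sim():
    p = c.HealthySimParams(
        n_bins=2000, n_samples=3, outlier_fraction=0.0,
        gc_bias_coeffs=(1.0,), sample_scale_sigma=0.0, seed=7,
    )
    return c.gen_healthy_bincounts(p)


class TestSpike:
    @pytest.fixture()
    def sim(self, spike_sim):
        return spike_sim

    def test_gain_scales_region_mean(self, sim):
        region = ("chr1", 0, 500_000)
        out = c.spike_cnv(sim.table, region, copy_delta=1, fraction=0.1, seed=1)
        hit = sim.table.region_index(*region)
        assert np.allclose(
            out.meta["expected_means"][hit],
            sim.expected_means[hit] * 1.05,
        )
        assert np.array_equal(out.counts[~hit], sim.table.counts[~hit])

    def test_pure_tumor_homozygous_loss_zeroes_region(self, sim):
        region = ("chr1", 0, 500_000)
        out = c.spike_cnv(sim.table, region, copy_delta=-2, fraction=1.0, seed=1)
        assert out.counts[sim.table.region_index(*region)].sum() == 0

    def test_zero_fraction_keeps_the_recipe(self, sim):
        region = ("chr1", 0, 500_000)
        out = c.spike_cnv(sim.table, region, copy_delta=4, fraction=0.0, seed=1)
        assert np.array_equal(out.meta["expected_means"], sim.expected_means)

    @pytest.mark.parametrize("frac,delta", [(-0.1, 1), (1.5, 1), (0.5, -3)])
    def test_domain_violations(self, sim, frac, delta):
        with pytest.raises(ValueError):
            c.spike_cnv(sim.table, ("chr1", 0, 100_000), delta, frac, seed=0)

    def test_region_with_no_bins_rejected(self, sim):
        with pytest.raises(ValueError):
            c.spike_cnv(sim.table, ("chr1", 100_000, 50_000), 1, 0.1, seed=0)


class TestCohort:
    def test_probability_one_event_in_every_sample(self, grid_5mb):
        ev = c.RecurrentEvent(segment=7, probability=1.0, copy_deltas=((2, 1.0),))
        sig = c.CancerSignature(type_name="T", recurrent_events=(ev,))
        records, labels = c.gen_tumor_cohort([sig], {"T": 20}, grid_5mb, seed=1)
        seg = grid_5mb.segments.iloc[7]
        per_sample = records.groupby("sample")
        assert len(per_sample) == 20
        for _, recs in per_sample:
            row = recs.iloc[0]
            assert (row["chrom"], row["start"], row["end"], row["copies"]) == (
                seg["chrom"], seg["start"], seg["end"], 4.0
            )

    def test_flat_signature_emits_no_records(self, grid_5mb):
        sig = c.CancerSignature(type_name="normal")
        records, labels = c.gen_tumor_cohort([sig], {"normal": 10}, grid_5mb, seed=2)
        assert records.empty
        assert len(labels) == 10

    def test_label_counts_match_request(self, grid_5mb):
        sigs = c.separable_signatures(["A", "B"], grid_5mb, passenger_rate=0.0)
        sigs.append(c.CancerSignature(type_name="normal"))
        _, labels = c.gen_tumor_cohort(
            sigs, {"A": 30, "B": 30, "normal": 40}, grid_5mb, seed=3
        )
        assert labels["type"].value_counts().to_dict() == {
            "A": 30, "B": 30, "normal": 40
        }

    def test_signature_outside_grid_rejected(self, grid_5mb):
        ev = c.RecurrentEvent(segment=grid_5mb.n_segments, probability=1.0)
        sig = c.CancerSignature(type_name="bad", recurrent_events=(ev,))
        with pytest.raises(ValueError):
            c.gen_tumor_cohort([sig], {"bad": 1}, grid_5mb, seed=0)


class TestGermline:
    def test_high_af_range_is_all_filterable(self, grid_5mb):
        res = c.gen_germline_resource(grid_5mb, 50, af_range=(0.05, 0.10), seed=1)
        assert res["common"].all()

    def test_empty_and_deterministic(self, grid_5mb):
        assert c.gen_germline_resource(grid_5mb, 0, seed=1).empty
        a = c.gen_germline_resource(grid_5mb, 25, seed=4)
        b = c.gen_germline_resource(grid_5mb, 25, seed=4)
        pd.testing.assert_frame_equal(a, b)


@given(st.integers(0, 2**31 - 1))
def test_thinning_preserves_dispersion(seed):
    """Binomial thinning of NB(m, r) at rate p has NB(p*m, r) moments."""
    rng = np.random.default_rng(seed)
    m, r, p = 300.0, 50.0, 0.5
    counts = rng.negative_binomial(r, r / (r + m), size=50_000)
    thin = binomial_thin(counts, p, seed=seed)
    assert abs(thin.mean() - p * m) / (p * m) < 0.03
    vmr = thin.var() / thin.mean()
    assert abs(vmr - (1 + p * m / r)) / (1 + p * m / r) < 0.08
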