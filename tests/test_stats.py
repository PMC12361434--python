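import numpy as np
import pytest

import replitime as rt
from replitime import (
    BinnedTrack,
    DegenerateDataError,
    NullDistribution,
    Region,
    SamplingInfeasibleError,
    aggregate_wt_control,
    area_between,
    delta_curve,
    empirical_pvalue,
    null_area_distribution,
    sample_null_regions,
)
from replitime import test_delta_delta as run_delta_delta_test


def curve_from(values, genome, chrom="chr1"):
    n = genome.n_bins(chrom)
    arr = np.full(n, np.nan)
    arr[: len(values)] = values
    return BinnedTrack(genome, {chrom: arr}, stage="delta")


class TestDeltaCurve:
    def test_identical_profiles_zero(self, small_genome, make_constant):
        a = make_constant(small_genome, 0.7)
        out = delta_curve(a, a.copy())
        assert np.allclose(out.flatten(), 0.0)

    def test_constant_shift(self, small_genome, make_constant):
        con = make_constant(small_genome, 0.3)
        dele = make_constant(small_genome, -0.2)
        out = delta_curve(dele, con)
        assert np.allclose(out.flatten(), -0.5)

    def test_missing_propagates(self, small_genome, make_constant):
        con = make_constant(small_genome, 0.0)
        dele = make_constant(small_genome, 1.0)
        dele["chr1"][5] = np.nan
        con["chr2"][7] = np.nan
        out = delta_curve(dele, con)
        assert np.isnan(out["chr1"][5]) and np.isnan(out["chr2"][7])


class TestAggregateControl:
    def test_single_profile_identity(self, small_genome, make_constant):
        a = make_constant(small_genome, 0.2)
        assert np.allclose(aggregate_wt_control([a]).flatten(), 0.2)

    def test_mean_of_two(self, small_genome, make_constant):
        out = aggregate_wt_control(
            [make_constant(small_genome, 0.2), make_constant(small_genome, 0.6)]
        )
        assert np.allclose(out.flatten(), 0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_wt_control([])


class TestAreaBetween:
    def test_zero_curve(self, small_genome, make_constant):
        c = make_constant(small_genome, 0.0, stage="delta")
        assert area_between(c, Region("chr1", 0, 2_000_000)) == 0.0

    def test_constant_over_41_bins(self):
        # a region covering 41 bin midpoints of a constant -1 curve -> -40
        genome = rt.make_genome(1, 60_000_000, bin_size=50_000)
        c = BinnedTrack(
            genome, {"chr1": np.full(1200, -1.0)}, stage="delta"
        )
        region = Region("chr1", 0, 2_050_000)
        sl = genome.midpoint_bins(region)
        assert sl.stop - sl.start == 41
        assert area_between(c, region) == pytest.approx(-40.0)

    def test_matches_refined_trapezoid_oracle(self, small_genome):
        rng = np.random.default_rng(21)
        for _ in range(50):
            vals = rng.normal(size=40)
            # some interior bins missing
            miss = rng.choice(np.arange(5, 35), size=4, replace=False)
            vals[miss] = np.nan
            curve = curve_from(vals, small_genome)
            region = Region("chr1", 0, 2_000_000)
            assert area_between(curve, region) == pytest.approx(
                refined_oracle(vals), abs=1e-9
            )

    def test_missing_edges_trimmed(self, small_genome):
        vals = np.array([np.nan, np.nan, 1.0, 1.0, 1.0, np.nan])
        curve = curve_from(vals, small_genome)
        # 6 bins' midpoints in region; after trimming: 3 bins, 2 widths
        assert area_between(curve, Region("chr1", 0, 300_000)) == pytest.approx(2.0)

    def test_too_few_bins_degenerate(self, small_genome):
        vals = np.array([1.0, np.nan, np.nan, np.nan])
        with pytest.raises(DegenerateDataError):
            area_between(curve_from(vals, small_genome), Region("chr1", 0, 200_000))


def refined_oracle(vals, refine=10):
    """Composite trapezoid on a 10x-refined linear interpolation."""
    vals = np.asarray(vals, dtype=float)
    finite = np.isfinite(vals)
    idx = np.flatnonzero(finite)
    lo, hi = idx[0], idx[-1]
    x = np.arange(lo, hi + 1, dtype=float)
    y = vals[lo : hi + 1]
    ok = np.isfinite(y)
    y = np.interp(x, x[ok], y[ok])
    fine_x = np.linspace(lo, hi, (hi - lo) * refine + 1)
    fine_y = np.interp(fine_x, x, y)
    return float(np.trapezoid(fine_y, fine_x))


class TestNullRegionSampling:
    def test_starts_within_bounds(self):
        genome = rt.make_genome(1, 60_000_000, bin_size=50_000)
        regions = sample_null_regions(genome, 2_000_000, 500, seed=1)
        assert all(r.start <= 58_000_000 and r.end <= 60_000_000 for r in regions)
        assert all(r.length == 2_000_000 for r in regions)

    def test_blacklisted_chromosome_never_sampled(self):
        genome = rt.make_genome(2, 60_000_000, bin_size=50_000)
        bl = (Region("chr2", 0, 60_000_000),)
        regions = sample_null_regions(genome, 1_000_000, 500, blacklist=bl, seed=2)
        assert all(r.chrom == "chr1" for r in regions)

    def test_no_blacklist_overlap_exhaustive(self, null_processed, null_dataset):
        prof = rt.allele_profiles(null_processed)
        curve = delta_curve(prof[rt.DELETION_ALLELE], prof[rt.CONTROL_ALLELE])
        bl = null_dataset.truth.blacklist
        regions = sample_null_regions(
            null_dataset.genome, 2_000_000, 2_000, blacklist=bl, seed=3,
            curve=curve,
        )
        assert not any(r.overlaps(b) for r in regions for b in bl)

    def test_same_seed_identical_regions(self):
        genome = rt.make_genome(3, 60_000_000, bin_size=50_000)
        a = sample_null_regions(genome, 2_000_000, 200, seed=7)
        b = sample_null_regions(genome, 2_000_000, 200, seed=7)
        assert a == b

    def test_infeasible_when_no_placement(self):
        genome = rt.make_genome(1, 1_000_000, bin_size=50_000)
        with pytest.raises(SamplingInfeasibleError):
            sample_null_regions(genome, 2_000_000, 10, seed=1)

    def test_high_missing_regions_rejected(self, small_genome):
        vals = np.full(small_genome.n_bins("chr1"), np.nan)
        vals[:10] = 1.0  # only the first 10 bins usable
        curve = BinnedTrack(small_genome, {"chr1": vals}, stage="delta")
        bl = (Region("chr2", 0, 2_999_999),)
        regions = sample_null_regions(
            small_genome, 500_000, 100, blacklist=bl, seed=4, curve=curve
        )
        # all sampled regions must sit in the covered prefix of chr1
        assert all(r.chrom == "chr1" for r in regions)
        for r in regions:
            v = curve.region_values(r)
            assert (~np.isfinite(v)).mean() <= 0.2


class TestEmpiricalPvalue:
    def test_observed_below_all_nulls(self):
        null = np.linspace(-1, 1, 10_000)
        p = empirical_pvalue(-5.0, null, alternative="delay")
        assert p == pytest.approx(1 / 10_001)

    def test_observed_above_all_nulls(self):
        null = np.linspace(-1, 1, 10_000)
        assert empirical_pvalue(5.0, null, alternative="delay") == 1.0

    def test_observed_at_median_of_symmetric_null(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=10_001)
        p = empirical_pvalue(float(np.median(null)), null, alternative="delay")
        assert p == pytest.approx(0.5, abs=0.01)

    def test_two_sided_counts_magnitudes(self):
        null = np.array([-3.0, -1.0, 0.5, 2.0])
        assert empirical_pvalue(2.5, null, "two-sided") == pytest.approx(2 / 5)
        assert empirical_pvalue(0.0, null, "two-sided") == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.0, np.array([]))


class TestDelayTest:
    def test_internal_control_mode_recorded(self, null_dataset, null_processed):
        res = rt.test_rt_delay(
            [null_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
            [null_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)],
            null_dataset.truth.query_domain,
            blacklist=null_dataset.truth.blacklist,
            n_random=200, seed=1,
        )
        assert res.control_mode == "internal"
        assert 1 / 201 <= res.pvalue <= 1.0

    def test_homozygous_clone_uses_aggregate_control(
        self, null_dataset, null_processed
    ):
        wt = [null_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)]
        res = rt.test_rt_delay(
            [null_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
            None,
            null_dataset.truth.query_domain,
            blacklist=null_dataset.truth.blacklist,
            n_random=200, seed=1, all_wt_profiles=wt,
        )
        assert res.control_mode == "aggregate"

    def test_no_control_at_all_rejected(self, null_processed, null_dataset):
        with pytest.raises(ValueError):
            rt.test_rt_delay(
                [null_processed[(rt.DELETION_ALLELE, 1)]], None,
                null_dataset.truth.query_domain, n_random=10, seed=0,
            )

    def test_strong_delay_is_significant(self, delayed_dataset, delayed_processed):
        res = rt.test_rt_delay(
            [delayed_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
            [delayed_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)],
            delayed_dataset.truth.query_domain,
            blacklist=delayed_dataset.truth.blacklist,
            n_random=1_000, seed=2,
        )
        assert res.significant
        assert res.delta_area < 0  # delay is the negative direction
        assert res.abs_delta_area == pytest.approx(1.5 * 40, rel=0.25)


class TestDeltaDeltaTest:
    def test_same_clone_gives_zero_area_p_one(self, null_dataset, null_processed):
        dels = [null_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)]
        cons = [null_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)]
        res = run_delta_delta_test(
            (dels, cons), (dels, cons), null_dataset.truth.query_domain,
            blacklist=null_dataset.truth.blacklist, n_random=200, seed=3,
        )
        assert res.delta_area == 0.0
        assert res.pvalue == 1.0

    def test_distinct_delays_detected(self, delayed_dataset, delayed_processed):
        other = rt.simulate_default(seed=17, delay=0.0, noise_seed=9_117)
        other_proc = rt.process_dataset(other)
        res = run_delta_delta_test(
            (
                [delayed_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
                [delayed_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)],
            ),
            (
                [other_proc[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
                [other_proc[(rt.CONTROL_ALLELE, r)] for r in (1, 2)],
            ),
            delayed_dataset.truth.query_domain,
            blacklist=delayed_dataset.truth.blacklist,
            n_random=1_000, seed=4,
        )
        assert res.significant
        assert res.kind == "delta_delta"


class TestPvalueBounds:
    def test_p_within_add_one_bounds(self, null_dataset, null_processed):
        for seed in range(5):
            res = rt.test_rt_delay(
                [null_processed[(rt.DELETION_ALLELE, r)] for r in (1, 2)],
                [null_processed[(rt.CONTROL_ALLELE, r)] for r in (1, 2)],
                null_dataset.truth.query_domain,
                blacklist=null_dataset.truth.blacklist,
                n_random=100, seed=seed,
            )
            assert 1 / 101 <= res.pvalue <= 1.0
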