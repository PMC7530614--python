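import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from haplosweep import (
    WindowSpec,
    core_span,
    ehh_decay,
    garud_h,
    haplotype_diversity,
    jackknife_haplotypes,
    moving_scan,
    simulate_cohort,
)
from conftest import make_dataset, sweep_cohort_config


class TestEHH:
    def test_first_flank_two_two_split(self):
        # 4 haplotypes splitting 2/2 at the first right flank: EHH = 2/6
        m = np.array([[0, 0, 0, 0], [0, 0, 1, 1]])
        curve = ehh_decay(m, core_index=0, positions=np.array([100, 200]))
        assert curve.right["ehh"].iloc[0] == pytest.approx(2 / 6)

    def test_identical_haplotypes_give_one_everywhere(self):
        m = np.zeros((5, 6), dtype=int)
        curve = ehh_decay(m, 2, np.arange(5) * 100)
        assert (curve.left["ehh"] == 1).all()
        assert (curve.right["ehh"] == 1).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_string_counting_oracle(self, random_matrix, seed):
        m = random_matrix(seed)
        core = 10
        curve = ehh_decay(m, core, np.arange(20) * 50)
        np.testing.assert_allclose(
            curve.right["ehh"], oracles.ehh_curve(m, core, "right")
        )
        np.testing.assert_allclose(
            curve.left["ehh"], oracles.ehh_curve(m, core, "left")
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_nonincreasing_away_from_core(self, random_matrix, seed):
        m = random_matrix(50 + seed)
        curve = ehh_decay(m, 10, np.arange(20) * 50)
        for side in (curve.left, curve.right):
            assert (np.diff(side["ehh"]) <= 1e-12).all()

    def test_group_of_one_errors(self):
        with pytest.raises(ValueError):
            ehh_decay(np.zeros((3, 1)), 0, np.arange(3))


class TestCoreSpan:
    def _curve(self):
        # identical over positions 100..600, divergence beyond
        m = np.zeros((7, 4), dtype=int)
        m[0, :2] = 1
        m[6, 2:] = 1
        pos = np.array([50, 100, 200, 300, 400, 600, 700])
        return ehh_decay(m, core_index=3, positions=pos)

    def test_span_between_last_passing_flanks(self):
        curve = self._curve()
        # flanks 100..600 hold EHH=1; 50 and 700 break it
        assert core_span(curve, upper=0.95) == 500

    def test_upper_one_with_immediate_divergence_gives_zero(self):
        m = np.array([[0, 0, 0, 0], [0, 0, 1, 1], [0, 1, 0, 1]])
        curve = ehh_decay(m, 0, np.array([10, 20, 30]))
        assert core_span(curve, upper=1.0) == 0

    def test_symmetric_construction_gives_symmetric_span(self):
        m = np.zeros((5, 4), dtype=int)
        m[0, :2] = 1
        m[4, :2] = 1
        pos = np.array([100, 200, 300, 400, 500])
        curve = ehh_decay(m, 2, pos)
        assert core_span(curve, upper=0.95) == 200  # 200..400


class TestGarudH:
    def test_single_class(self):
        m = np.zeros((4, 6), dtype=int)
        assert garud_h(m) == (1.0, 1.0, 1.0, 0.0)

    def test_fifty_fifty(self):
        m = np.zeros((1, 4), dtype=int)
        m[0, 2:] = 1
        h1, h12, _, h2h1 = garud_h(m)
        assert (h1, h12, h2h1) == (pytest.approx(0.5), pytest.approx(1.0), pytest.approx(0.5))

    def test_three_class_spectrum(self):
        # frequencies 0.6 / 0.3 / 0.1 over 10 haplotypes
        m = np.zeros((2, 10), dtype=int)
        m[0, 6:9] = 1
        m[1, 9] = 1
        h1, h12, h123, h2h1 = garud_h(m)
        assert h1 == pytest.approx(0.46)
        assert h12 == pytest.approx(0.82)
        assert h123 == pytest.approx(1.0)
        assert h2h1 == pytest.approx(0.10 / 0.46)

    @given(arrays(np.int8, (8, 6), elements=st.integers(0, 1)))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_spectrum_ordering_holds_for_any_matrix(self, m):
        h1, h12, h123, h2h1 = garud_h(m)
        assert 0 <= h1 <= h12 + 1e-12
        assert h12 <= h123 + 1e-12 <= 1 + 1e-12
        assert -1e-12 <= h2h1 <= 1 + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_identities_against_class_counting_oracle(self, random_matrix, seed):
        m = random_matrix(200 + seed)
        np.testing.assert_allclose(garud_h(m), oracles.garud_h(m))
        h1, h12, h123, h2h1 = garud_h(m)
        assert 0 <= h1 <= h12 <= h123 <= 1
        assert 0 <= h2h1 <= 1


class TestHaplotypeDiversity:
    def test_single_class_zero(self):
        assert haplotype_diversity(np.zeros((3, 5), dtype=int)) == 0.0

    def test_all_distinct_exactly_one(self):
        m = np.eye(6, dtype=int)
        assert haplotype_diversity(m) == pytest.approx(1.0)

    def test_two_two_split(self):
        m = np.zeros((1, 4), dtype=int)
        m[0, 2:] = 1
        assert haplotype_diversity(m) == pytest.approx((1 - 0.5) * 4 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, random_matrix, seed):
        m = random_matrix(300 + seed)
        assert haplotype_diversity(m) == pytest.approx(oracles.hap_diversity(m))


class TestMovingScan:
    def test_window_arithmetic(self, random_matrix):
        m = random_matrix(1, n_var=1000, n_hap=10)
        ds = make_dataset(m)
        res = moving_scan(ds, None, WindowSpec("variant_count", 500, 100))
        assert len(res.windows) == 6

    def test_constant_dataset_h1_one_everywhere(self):
        ds = make_dataset(np.zeros((300, 8), dtype=int))
        res = moving_scan(ds, None, WindowSpec("variant_count", 100, 50))
        assert (res.windows["h1"] == 1.0).all()

    def test_scan_equals_per_window_scalar_calls(self, random_matrix):
        m = random_matrix(2, n_var=120, n_hap=10)
        ds = make_dataset(m)
        res = moving_scan(ds, None, WindowSpec("variant_count", 50, 10))
        for row in res.windows.itertuples(index=False):
            w = m[row.start_index : row.stop_index]
            assert row.h12 == pytest.approx(garud_h(w)[1])
            assert row.hap_diversity == pytest.approx(haplotype_diversity(w))


class TestJackknife:
    def test_constant_statistic_zero_se(self, random_matrix):
        m = random_matrix(3)
        mean, se = jackknife_haplotypes(lambda h: 7.0, m)
        assert (mean, se) == (7.0, 0.0)

    def test_three_haplotype_enumeration(self):
        # statistic = mean allele count; hand-enumerated delete-one values
        m = np.array([[1, 0, 0], [1, 1, 0]])
        stat = lambda h: float(h.sum(axis=0).mean())
        t1 = float(m[:, [1, 2]].sum(axis=0).mean())  # drop col0 -> (1+0)/2 = 0.5
        t2 = float(m[:, [0, 2]].sum(axis=0).mean())  # 1.0
        t3 = float(m[:, [0, 1]].sum(axis=0).mean())  # 1.5
        expect_mean = np.mean([t1, t2, t3])
        expect_se = np.sqrt(2 / 3 * sum((t - expect_mean) ** 2 for t in [t1, t2, t3]))
        mean, se = jackknife_haplotypes(stat, m)
        assert mean == pytest.approx(expect_mean)
        assert se == pytest.approx(expect_se)

    def test_reorder_invariance(self, random_matrix):
        m = random_matrix(4)
        stat = lambda h: float(np.var(h.sum(axis=0)))
        _, se1 = jackknife_haplotypes(stat, m)
        _, se2 = jackknife_haplotypes(stat, m[:, ::-1])
        assert se1 == pytest.approx(se2)

    def test_requires_three(self):
        with pytest.raises(ValueError):
            jackknife_haplotypes(lambda h: 0.0, np.zeros((2, 2)))


class TestSweepSignal:
    def test_hard_sweep_group_beats_neutral_group(self):
        """Carriers show higher H12, lower H2/H1 and diversity, longer span."""
        ds, truth = simulate_cohort(sweep_cohort_config(seed=17, n_variants=1500))
        carriers = np.flatnonzero(truth.haplotypes["sweep_carrier"].to_numpy())
        wt_pop1 = np.flatnonzero(
            (~truth.haplotypes["sweep_carrier"]
             & ~truth.haplotypes["introgression_recipient"]
             & (truth.haplotypes["population"] == "P1")).to_numpy()
        )[: len(carriers)]
        region = ds.region("2L:40000-60000")
        core = region.variant_index("2L", 50_000)
        sw = region.take_haplotypes(carriers).matrix
        wt = region.take_haplotypes(wt_pop1).matrix
        h_sw, h_wt = garud_h(sw), garud_h(wt)
        assert h_sw[1] > h_wt[1]  # H12
        assert h_sw[3] < h_wt[3]  # H2/H1
        assert haplotype_diversity(sw) < haplotype_diversity(wt)
        span_sw = core_span(ehh_decay(sw, core, region.positions))
        span_wt = core_span(ehh_decay(wt, core, region.positions))
        assert span_sw > span_wt

    def test_introgressed_tract_gives_asymmetric_ehh_decay(self):
        """Recipients decay faster outside the introgressed tract side."""
        cfg = sweep_cohort_config(seed=23, introgression=True, n_variants=1500)
        cfg.introgression_events[0].tract_half_length = 8_000
        # shift the core off-centre of the tract: compare decay at equal
        # distances falling inside vs outside the tract
        ds, truth = simulate_cohort(cfg)
        rec = np.flatnonzero(truth.haplotypes["introgression_recipient"].to_numpy())
        region = ds.region("2L:35000-65000")
        core = region.variant_index("2L", 50_000)
        curve = ehh_decay(region.take_haplotypes(rec).matrix, core, region.positions)
        # inside the +/-8 kb tract recipients are identical: EHH stays 1
        inside_right = curve.right[curve.right["pos"] < 58_000]
        assert (inside_right["ehh"] == 1.0).all()
        # well outside the tract homozygosity collapses
        far_right = curve.right[curve.right["pos"] > 60_000]
        assert far_right["ehh"].iloc[-1] < 0.5
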