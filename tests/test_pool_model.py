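"""Unit and property tests for the generative pooled-measurement model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolsim.pool_model import (
    BiasModel,
    GenotypeVector,
    PoolDesign,
    PoolingError,
    SequencingDesign,
    allocate_reads,
    assign_genotypes,
    contribution_probabilities,
    draw_alt_reads,
    draw_contributions,
    draw_depth,
    estimate_frequency,
    simulate_snp,
    simulate_snps,
)


class TestContributions:
    def test_zero_variance_is_deterministic(self, rng):
        out = draw_contributions(PoolDesign(4, 10.0, 0.0), rng)
        assert np.array_equal(out, [10.0, 10.0, 10.0, 10.0])
        assert np.array_equal(
            draw_contributions(PoolDesign(1, 5.0, 0.0), rng), [5.0]
        )

    def test_moments_match_normal(self, rng):
        # sigma^2 = 4 is the largest pooling error studied (40% of c = 10)
        draws = np.concatenate(
            [draw_contributions(PoolDesign(200, 10.0, 4.0), rng) for _ in range(500)]
        )
        n = draws.size
        assert draws.mean() == pytest.approx(10.0, abs=4 * 2.0 / math.sqrt(n))
        assert draws.var(ddof=1) == pytest.approx(4.0, rel=0.1)

    def test_clamped_at_zero(self, rng):
        out = draw_contributions(PoolDesign(2000, 0.1, 100.0), rng)
        assert (out >= 0).all()

    def test_unusable_pool_raises(self):
        class ZeroRng:
            def normal(self, loc, scale, size):
                return np.full(size, -1.0)

        with pytest.raises(PoolingError, match="zero"):
            draw_contributions(PoolDesign(3, 1.0, 100.0), ZeroRng())

    @pytest.mark.parametrize(
        "amounts, expected",
        [
            ([10, 10, 10, 10], [0.25, 0.25, 0.25, 0.25]),
            ([30, 10], [0.75, 0.25]),
            ([0, 0, 8], [0.0, 0.0, 1.0]),
        ],
    )
    def test_probabilities(self, amounts, expected):
        assert contribution_probabilities(amounts) == pytest.approx(expected)

    def test_zero_sum_raises(self):
        with pytest.raises(PoolingError):
            contribution_probabilities([0.0, 0.0])

    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=100).filter(
        lambda a: sum(a) > 0))
    def test_probabilities_sum_to_one(self, amounts):
        p = contribution_probabilities(amounts)
        assert abs(p.sum() - 1.0) <= 1e-12
        assert (p >= 0).all()


class TestGenotypes:
    def test_hwe_counts_at_half(self):
        gv = assign_genotypes(200, 0.5, "hardy_weinberg")
        assert gv.n_hom_alt == 50 and gv.n_het == 100

    def test_zero_frequency_all_ref(self):
        gv = assign_genotypes(100, 0.0, "hardy_weinberg")
        assert not gv.genotypes.any()

    def test_all_het_preferred_rare(self):
        gv = assign_genotypes(10, 0.05, "all_het_preferred")
        assert gv.n_het == 1 and gv.n_hom_alt == 0
        assert gv.genotypes.sum() == 1

    @given(
        n=st.integers(1, 500),
        freq=st.floats(0.0, 1.0),
        composition=st.sampled_from(["hardy_weinberg", "all_het_preferred"]),
    )
    def test_exact_dosage_invariant(self, n, freq, composition):
        gv = assign_genotypes(n, freq, composition)
        assert gv.genotypes.sum() == round(2 * n * freq)
        assert gv.n_samples == n

    @given(n=st.integers(1, 500), freq=st.floats(0.0, 1.0))
    def test_all_het_maximises_heterozygotes(self, n, freq):
        het = assign_genotypes(n, freq, "all_het_preferred").n_het
        hwe = assign_genotypes(n, freq, "hardy_weinberg").n_het
        assert het >= hwe

    def test_invalid_frequency_raises(self):
        with pytest.raises(PoolingError):
            assign_genotypes(10, 1.5)


class TestDepthAndAllocation:
    def test_poisson_moments(self, rng):
        seq = SequencingDesign(mean_depth=200)
        draws = np.array([draw_depth(seq, rng) for _ in range(20_000)])
        se = math.sqrt(200 / draws.size)
        assert draws.mean() == pytest.approx(200, abs=4 * se)
        assert draws.var(ddof=1) == pytest.approx(200, rel=0.1)

    def test_near_zero_rate(self, rng):
        seq = SequencingDesign(mean_depth=1e-6)
        assert sum(draw_depth(seq, rng) for _ in range(1000)) <= 1

    def test_depth_parameterisations_agree(self):
        assert SequencingDesign(per_sample_depth=2).mean_depth_for(300) == 600
        assert SequencingDesign(mean_depth=600).mean_depth_for(300) == 600
        with pytest.raises(PoolingError):
            SequencingDesign()
        with pytest.raises(PoolingError):
            SequencingDesign(mean_depth=600, per_sample_depth=1).mean_depth_for(300)

    def test_allocation_edge_cases(self, rng):
        assert not allocate_reads(0, [0.5, 0.5], rng).any()
        assert allocate_reads(17, [1.0], rng)[0] == 17

    def test_allocation_multinomial_moments(self, rng):
        counts = allocate_reads(10**6, [0.25] * 4, rng)
        sd = math.sqrt(10**6 * 0.25 * 0.75)
        assert counts.sum() == 10**6
        assert np.abs(counts - 250_000).max() <= 4 * sd

    @given(depth=st.integers(0, 10_000), k=st.integers(1, 30))
    def test_allocation_conserves_depth(self, depth, k):
        rng = np.random.default_rng(depth * 31 + k)
        probs = rng.dirichlet(np.ones(k))
        assert allocate_reads(depth, probs, rng).sum() == depth


class TestAltReads:
    def _gv(self, genotypes, freq):
        return GenotypeVector(np.asarray(genotypes), freq)

    def test_no_alt_alleles(self, rng):
        gv = self._gv([0, 0, 0], 0.0)
        assert draw_alt_reads([5, 3, 2], gv, None, rng) == 0

    def test_fixation(self, rng):
        gv = self._gv([2, 2], 1.0)
        assert draw_alt_reads([7, 3], gv, None, rng) == 10

    def test_het_balance_mean(self, rng):
        # deterministic balance 0.483, one big heterozygous pool
        gv = self._gv([1, 1], 0.5)
        bias = BiasModel(0.483, 0.0)
        total = 10**6
        alt = draw_alt_reads([total // 2, total // 2], gv, bias, rng)
        se = math.sqrt(0.483 * 0.517 / total)
        assert alt / total == pytest.approx(0.483, abs=4 * se)

    def test_length_mismatch_raises(self, rng):
        gv = self._gv([1, 1], 0.5)
        with pytest.raises(PoolingError):
            draw_alt_reads([1, 2, 3], gv, None, rng)


class TestEstimator:
    @pytest.mark.parametrize("alt,depth,expected", [(5, 10, 0.5), (0, 100, 0.0)])
    def test_ratio(self, alt, depth, expected):
        assert estimate_frequency(alt, depth) == expected

    def test_zero_depth_is_undefined(self):
        assert math.isnan(estimate_frequency(0, 0))

    def test_overflow_raises(self):
        with pytest.raises(PoolingError):
            estimate_frequency(7, 0)


class TestComposedSimulation:
    def test_single_snp_contract(self, rng):
        res = simulate_snp(
            PoolDesign(50, 10.0, 1.0),
            SequencingDesign(mean_depth=100),
            0.2,
            rng=rng,
        )
        assert 0 <= res.alt_reads <= res.depth
        assert res.estimated_frequency == res.alt_reads / res.depth
        assert res.target_frequency == 0.2

    def test_fixation_always_one(self, rng):
        for _ in range(50):
            res = simulate_snp(
                PoolDesign(2, 10.0, 0.0), SequencingDesign(mean_depth=2), 1.0,
                rng=rng,
            )
            if res.depth > 0:
                assert res.estimated_frequency == 1.0

    def test_unbiasedness_across_frequencies(self, rng):
        # sigma^2 = 0 and balance 0.5: F-hat is a conditionally binomial
        # proportion, so its mean over replicates must sit on F
        pool = PoolDesign(200, 10.0, 0.0)
        seq = SequencingDesign(mean_depth=800)
        for f in (0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5):
            batch = simulate_snps(pool, seq, f, replicates=10_000, rng=rng)
            est = batch.estimated_frequencies
            est = est[~np.isnan(est)]
            se = est.std(ddof=1) / math.sqrt(est.size)
            assert abs(est.mean() - f) <= 4 * se

    def test_sd_matches_poisson_binomial_oracle(self, rng):
        # closed form: Var(F-hat) = F(1-F) E[1/D | D>0] under the ideal model
        from poolsim.metrics import mean_inverse_depth

        pool = PoolDesign(200, 10.0, 0.0)
        for lam in (200, 800, 2500):
            batch = simulate_snps(
                pool, SequencingDesign(mean_depth=lam), 0.3,
                replicates=10_000, rng=rng,
            )
            est = batch.estimated_frequencies
            est = est[~np.isnan(est)]
            expected_sd = math.sqrt(0.3 * 0.7 * mean_inverse_depth(lam))
            assert est.std(ddof=0) == pytest.approx(expected_sd, rel=0.05)

    def test_vectorised_path_matches_op_path(self):
        # same law for the literal op composition and the reduced fast path
        pool = PoolDesign(3, 10.0, 4.0)
        seq = SequencingDesign(mean_depth=5)
        rng1 = np.random.default_rng(11)
        single = np.array(
            [simulate_snp(pool, seq, 0.5, rng=rng1).alt_reads for _ in range(4000)]
        )
        rng2 = np.random.default_rng(12)
        batch = simulate_snps(pool, seq, 0.5, replicates=4000, rng=rng2)
        stat = stats.ks_2samp(single, batch.alt_reads)
        assert stat.pvalue > 0.001

    def test_pooling_variance_inflates_error(self):
        # more pooling noise can only hurt at fixed depth
        seq = SequencingDesign(mean_depth=500)
        out = {}
        for sigma2 in (1e-5, 4.0):
            rng = np.random.default_rng(99)
            batch = simulate_snps(
                PoolDesign(200, 10.0, sigma2), seq, 0.5,
                replicates=20_000, rng=rng,
            )
            est = batch.estimated_frequencies
            out[sigma2] = np.nanstd(est)
        assert out[4.0] > out[1e-5]

    def test_batch_excludes_zero_depth(self, rng):
        batch = simulate_snps(
            PoolDesign(2, 10.0, 0.0), SequencingDesign(mean_depth=0.5), 0.5,
            replicates=2000, rng=rng,
        )
        zero = batch.depths == 0
        assert batch.n_excluded == zero.sum() > 0
        assert np.isnan(batch.estimated_frequencies[zero]).all()
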