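"""Dosage-probability estimation: naive binomial and noise-aware posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyassoc.dosage import (
    DosageModelParams,
    DosageProbabilityMatrix,
    call_dosage,
    continuous_dosage,
    dosage_matrix,
    estimate_noise_params,
    filter_mgf,
    major_genotype_frequency,
    naive_dosage_probs,
    noise_aware_posterior,
)
from polyassoc.vcf_io import ReadCountTable


def one_hot(rows, K=6):
    probs = np.zeros((len(rows), K + 1))
    probs[np.arange(len(rows)), rows] = 1.0
    return DosageProbabilityMatrix(probs=probs, mask=np.zeros(len(rows), bool))


class TestNaiveDosageProbs:
    def test_balanced_counts_are_symmetric_with_mode_at_three(self):
        p = naive_dosage_probs(30, 15)
        assert np.allclose(p, p[::-1])
        assert np.argmax(p) == 3

    def test_all_reference_reads_at_depth_ten(self):
        # oracle: normalized binomial likelihoods at r = {e, 1/6..5/6, 1-e}
        p = naive_dosage_probs(10, 10)
        r = DosageModelParams().r
        expected = stats.binom.pmf(10, 10, r)
        expected /= expected.sum()
        assert np.allclose(p, expected, atol=1e-12)
        assert p[6] == pytest.approx(0.8463, abs=5e-4)
        assert p[5] == pytest.approx(0.1381, abs=5e-4)
        assert p[4] == pytest.approx(0.0148, abs=5e-4)

    def test_all_alternative_reads_mirror(self):
        assert np.allclose(naive_dosage_probs(10, 0), naive_dosage_probs(10, 10)[::-1])

    @pytest.mark.parametrize("dp,rd", [(5, 6), (10, -1), (0, 0)])
    def test_invalid_counts_rejected(self, dp, rd):
        with pytest.raises(ValueError):
            naive_dosage_probs(dp, rd)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 400), st.data())
    def test_normalization_and_reversal_symmetry(self, dp, data):
        rd = data.draw(st.integers(0, dp))
        p = naive_dosage_probs(dp, rd)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p >= 0).all()
        assert np.allclose(p, naive_dosage_probs(dp, dp - rd)[::-1])

    def test_concentration_with_depth_at_matching_ratio(self):
        vals = [naive_dosage_probs(dp, dp // 3)[2] for dp in (30, 120, 600)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0.999


class TestDosageMatrix:
    def make_table(self):
        return ReadCountTable(
            individual_ids=["a", "b", "c"], marker_ids=["m1"],
            DP=[[30], [10], [0]], RD=[[15], [10], [0]],
            mask=[[False], [False], [True]],
        )

    def test_cells_match_single_cell_oracle(self):
        mats = dosage_matrix(self.make_table())
        assert len(mats) == 1
        M = mats[0]
        assert np.allclose(M.probs[0], naive_dosage_probs(30, 15))
        assert np.allclose(M.probs[1], naive_dosage_probs(10, 10))
        assert M.mask.tolist() == [False, False, True]

    def test_fully_masked_marker_flagged(self):
        t = ReadCountTable(
            individual_ids=["a", "b"], marker_ids=["m"],
            DP=[[0], [0]], RD=[[0], [0]], mask=[[True], [True]],
        )
        assert dosage_matrix(t)[0].all_masked


class TestContinuousDosage:
    def test_one_hot_uniform_and_worked_row(self):
        M = one_hot([4])
        assert continuous_dosage(M)[0] == 4.0
        U = DosageProbabilityMatrix(probs=np.full((1, 7), 1 / 7), mask=[False])
        assert continuous_dosage(U)[0] == pytest.approx(3.0)
        row = naive_dosage_probs(10, 10)
        D = DosageProbabilityMatrix(probs=row[None, :], mask=[False])
        assert continuous_dosage(D)[0] == pytest.approx(5.8297, abs=5e-4)

    def test_masked_rows_are_nan(self):
        M = DosageProbabilityMatrix(probs=np.zeros((1, 7)), mask=[True])
        assert np.isnan(continuous_dosage(M)[0])

    def test_linearity_under_mixture(self, rng):
        A = rng.dirichlet(np.ones(7), size=5)
        B = rng.dirichlet(np.ones(7), size=5)
        lam = 0.3
        mix = DosageProbabilityMatrix(probs=lam * A + (1 - lam) * B, mask=np.zeros(5, bool))
        Ma = DosageProbabilityMatrix(probs=A, mask=np.zeros(5, bool))
        Mb = DosageProbabilityMatrix(probs=B, mask=np.zeros(5, bool))
        assert np.allclose(
            continuous_dosage(mix),
            lam * continuous_dosage(Ma) + (1 - lam) * continuous_dosage(Mb),
        )


class TestCallDosage:
    def test_clear_maximum(self):
        M = DosageProbabilityMatrix(
            probs=[[0.05, 0.9, 0.05, 0, 0, 0, 0]], mask=[False]
        )
        assert call_dosage(M)[0] == 1

    def test_tie_breaks_low_and_counts(self):
        M = DosageProbabilityMatrix(
            probs=[[0, 0, 0.5, 0, 0.5, 0, 0]], mask=[False]
        )
        calls, ties = call_dosage(M, return_ties=True)
        assert calls[0] == 2 and ties == 1

    def test_masked_row_is_minus_one(self):
        M = DosageProbabilityMatrix(probs=np.zeros((1, 7)), mask=[True])
        assert call_dosage(M)[0] == -1


class TestMgf:
    def test_uniform_rows_give_one_seventh(self):
        M = DosageProbabilityMatrix(probs=np.full((4, 7), 1 / 7), mask=np.zeros(4, bool))
        assert major_genotype_frequency(M) == pytest.approx(1 / 7)

    def test_one_hot_and_split_classes(self):
        assert major_genotype_frequency(one_hot([3, 3, 3])) == 1.0
        assert major_genotype_frequency(one_hot([2, 2, 4, 4])) == 0.5

    def test_call_mode_matches_probability_mode_on_hard_calls(self):
        M = one_hot([1, 1, 2])
        assert major_genotype_frequency(M, "call") == pytest.approx(2 / 3)
        assert major_genotype_frequency(M) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n_major,expect_kept", [(24, False), (19, True)])
    def test_filter_mgf_strict_boundary(self, n_major, expect_kept):
        # 24/25 = 0.96 dropped; 19/20 = 0.95 exactly retained
        n_other = 1
        M = one_hot([3] * n_major + [1] * n_other)
        kept = filter_mgf([M], threshold=0.95)
        assert (len(kept) == 1) is expect_kept

    def test_polymorphic_marker_retained(self):
        assert len(filter_mgf([one_hot([0, 1, 1, 2])])) == 1


class TestNoiseAwarePosterior:
    def test_reduces_to_binomial_likelihood_without_noise(self, rng):
        dp = np.full(20, 30)
        rd = rng.integers(0, 31, size=20)
        M = noise_aware_posterior(dp, rd, np.full(7, 1 / 7), bias=1.0, od=0.0, seq_error=0.0)
        d = np.arange(7) / 6
        expected = stats.binom.pmf(rd[:, None], dp[:, None], d[None, :])
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.allclose(M.probs, expected, atol=1e-12)

    def test_prior_support_is_respected(self):
        prior = np.array([0.25, 0, 0.5, 0, 0.25, 0, 0])
        M = noise_aware_posterior([40] * 5, [5, 10, 20, 30, 38], prior)
        assert np.all(M.probs[:, prior == 0] == 0)

    def test_posterior_rows_normalized(self, rng):
        dp = np.full(50, 20)
        rd = rng.integers(0, 21, size=50)
        M = noise_aware_posterior(dp, rd, np.full(7, 1 / 7), bias=0.5, od=0.05)
        assert np.allclose(M.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_od_rejected(self):
        with pytest.raises(ValueError):
            noise_aware_posterior([20], [10], np.full(7, 1 / 7), od=1.5)


class TestEstimateNoiseParams:
    def prior(self):
        from polyassoc.simulate import offspring_dosage_distribution

        return offspring_dosage_distribution(6, 2)

    def test_null_noise_recovered(self, rng):
        prior = self.prior()
        d = rng.choice(7, size=500, p=prior)
        rd = rng.binomial(100, d / 6)
        bias, od = estimate_noise_params(np.full(500, 100), rd, prior, seq_error=0.0)
        assert 0.85 <= bias <= 1.17
        assert od <= 0.002

    def test_recovers_bias_and_overdispersion(self, rng):
        """Parameter recovery within one grid step in >= 80% of replicates."""
        from polyassoc.noise import expected_ref_fraction, sample_read_counts

        prior = self.prior()
        hits = 0
        reps = 50
        for _ in range(reps):
            d = rng.choice(7, size=200, p=prior)
            xi = expected_ref_fraction(d / 6, 0.5, 0.001)
            rd = sample_read_counts(rng, np.full(200, 100), xi, od=0.05)
            bias, od = estimate_noise_params(np.full(200, 100), rd, prior)
            # one geometric grid step around the truth
            if 0.5 / 1.25 <= bias <= 0.5 * 1.25 and 0.022 <= od <= 0.115:
                hits += 1
        assert hits >= 0.8 * reps

    def test_degenerate_counts_warn_and_return_null(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bias, od = estimate_noise_params(
                np.full(30, 40), np.full(30, 40), np.full(7, 1 / 7)
            )
        assert (bias, od) == (1.0, 0.0)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="20"):
            estimate_noise_params(np.full(10, 40), np.full(10, 20), np.full(7, 1 / 7))
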