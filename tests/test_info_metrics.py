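"""Entropy, mutual information, Fano-factor noise and output range,
including the brute-force joint-table oracle and data-processing checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signoise import (
    ResponseEnsemble,
    average_fano,
    bootstrap_information_se,
    metrics_triple,
    mutual_information,
    normalize_series,
    output_range,
    shannon_entropy,
)


def _ensemble(pmf_rows, support=None, levels=None):
    pmf = np.asarray(pmf_rows, dtype=float)
    support = np.arange(pmf.shape[1]) if support is None else np.asarray(support)
    levels = np.arange(1, pmf.shape[0] + 1) if levels is None else np.asarray(levels)
    return ResponseEnsemble(levels, support, pmf, replicates_per_level=100)


def brute_force_mi(ensemble):
    """Independent oracle: explicit double sum over the joint table."""
    n = ensemble.n_levels
    joint = ensemble.pmf / n
    p_s = joint.sum(axis=1)
    p_o = joint.sum(axis=0)
    total = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            if joint[i, j] > 0:
                total += joint[i, j] * math.log2(joint[i, j] / (p_s[i] * p_o[j]))
    return total


class TestShannonEntropy:
    def test_uniform_eight_values_is_three_bits(self):
        assert shannon_entropy([0.125] * 8) == pytest.approx(3.0)

    def test_point_mass_is_zero(self):
        assert shannon_entropy([0, 1.0, 0]) == 0.0

    def test_biased_coin(self):
        assert shannon_entropy([0.75, 0.25]) == pytest.approx(0.811278, abs=1e-6)

    def test_unnormalized_pmf_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.4, 0.4])


class TestMutualInformation:
    def test_perfectly_distinguishable_levels(self):
        assert mutual_information(_ensemble([[1, 0], [0, 1]])) == pytest.approx(1.0)

    def test_identical_conditionals_carry_no_information(self):
        row = [0.2, 0.5, 0.3]
        assert mutual_information(_ensemble([row, row, row])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_binary_symmetric_channel_value(self):
        ens = _ensemble([[0.75, 0.25], [0.25, 0.75]])
        assert mutual_information(ens) == pytest.approx(0.188722, abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(2, 5), st.integers(2, 7), st.integers(0, 10_000))
    def test_matches_brute_force_joint_sum(self, n_levels, n_out, seed):
        rng = np.random.default_rng(seed)
        pmf = rng.dirichlet(np.full(n_out, 0.5), size=n_levels)
        ens = _ensemble(pmf)
        got = mutual_information(ens, max_support=None)
        assert got == pytest.approx(brute_force_mi(ens), abs=1e-10)
        # information-theoretic bounds
        h_s = math.log2(n_levels)
        h_o = shannon_entropy(pmf.mean(axis=0))
        assert -1e-12 <= got <= min(h_s, h_o) + 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_merging_output_bins_never_increases_information(self, seed):
        rng = np.random.default_rng(seed)
        pmf = rng.dirichlet(np.full(40, 0.3), size=4)
        ens = _ensemble(pmf)
        raw = mutual_information(ens, max_support=None)
        for bins in (20, 8, 3, 1):
            assert mutual_information(ens.coarsened(bins), max_support=None) <= raw + 1e-9

    def test_wide_support_is_coarsened_by_default(self):
        rng = np.random.default_rng(5)
        samples = [rng.poisson(lam, 200) for lam in (300, 320, 340, 360)]
        ens = ResponseEnsemble.from_samples([1, 2, 3, 4], samples)
        assert ens.support.size > 64
        binned = mutual_information(ens)
        raw = mutual_information(ens, max_support=None)
        assert binned < raw  # removes most of the undersampling bias
        assert 0.0 <= binned <= 2.0


class TestAverageFano:
    def test_point_masses_are_noise_free(self):
        assert average_fano(_ensemble([[1, 0, 0], [0, 0, 1]])) == 0.0

    def test_two_level_average(self):
        # (mean, var) = (10, 5) and (20, 40) -> (0.5 + 2.0) / 2 = 1.25
        ens = ResponseEnsemble(
            signal_levels=[1, 2],
            support=[5, 10, 15, 20, 30],
            pmf=[[0.1, 0.8, 0.1, 0, 0], [0, 0.2, 0, 0.6, 0.2]],
            replicates_per_level=100,
        )
        assert average_fano(ens) == pytest.approx(1.25)

    def test_poisson_sampling_recovers_unit_fano(self):
        rng = np.random.default_rng(11)
        n = 10_000
        samples = [rng.poisson(20, n) for _ in range(3)]
        ens = ResponseEnsemble.from_samples([1, 2, 3], samples)
        se = math.sqrt((2 + 1 / 20) / n)  # asymptotic SE of var/mean for Poisson
        assert abs(average_fano(ens) - 1.0) < 3 * se

    def test_all_zero_level_contributes_zero(self):
        ens = _ensemble([[1.0, 0.0], [0.5, 0.5]])
        assert average_fano(ens) == pytest.approx(0.25)  # (0 + 0.25/0.5) / 2

    def test_depends_only_on_each_conditional_pmf(self):
        a = _ensemble([[0.5, 0.5, 0], [0, 0.5, 0.5]], support=[3, 5, 7])
        b = _ensemble([[0, 0.5, 0.5], [0.5, 0.5, 0]], support=[3, 5, 7], levels=[9, 4])
        assert average_fano(a) == pytest.approx(average_fano(b))


class TestOutputRange:
    def test_examples(self):
        means_to_pmf = lambda m: [[1 if s == v else 0 for s in (3, 7, 10)] for v in m]
        ens = _ensemble(means_to_pmf([3, 10, 7]), support=[3, 7, 10])
        assert output_range(ens) == pytest.approx(7.0)
        same = _ensemble([[0.5, 0.5]] * 3)
        assert output_range(same) == 0.0

    def test_fractional_means(self):
        ens = _ensemble([[0.9, 0.1], [0.8, 0.2]])
        assert output_range(ens) == pytest.approx(0.1)


class TestNormalizeSeries:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 4], [0.25, 0.5, 1.0]),
            ([5], [1.0]),
            ([0, 0], [0.0, 0.0]),
        ],
    )
    def test_examples(self, values, expected):
        assert normalize_series(values) == pytest.approx(expected)


class TestEnsembleContainer:
    def test_pmf_rows_must_normalize(self):
        with pytest.raises(ValueError):
            _ensemble([[0.5, 0.4]])

    def test_from_samples_builds_common_support(self):
        ens = ResponseEnsemble.from_samples(
            [10, 20], [np.array([0, 0, 1]), np.array([1, 2, 2])]
        )
        assert ens.support.tolist() == [0, 1, 2]
        assert ens.pmf[0] == pytest.approx([2 / 3, 1 / 3, 0])
        assert ens.pmf[1] == pytest.approx([0, 1 / 3, 2 / 3])

    def test_tsv_round_trip(self, tmp_path):
        ens = _ensemble([[0.25, 0.75, 0], [0.1, 0.4, 0.5]], support=[2, 5, 9])
        path = tmp_path / "ens.tsv"
        ens.to_tsv(path)
        back = ResponseEnsemble.from_tsv(path)
        assert back.support.tolist() == [2, 5, 9]
        assert np.allclose(back.pmf, ens.pmf)
        assert metrics_triple(back) == metrics_triple(ens)

    def test_bootstrap_se_is_positive_and_small_for_clean_channels(self, rng):
        samples = [rng.poisson(5, 300), rng.poisson(50, 300)]
        se = bootstrap_information_se(samples, [1, 2], rng, n_boot=50)
        assert 0.0 < se < 0.2
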