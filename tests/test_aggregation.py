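"""Unit and property tests for the host-level aggregation analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lousepop as lp
from lousepop.aggregation import NoHostsError, NoOverdispersionError

count_vectors = st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=40)


class TestSummarize:
    def test_census_descriptive_triple(self, census):
        s = lp.summarize_counts(census)
        assert s.n_hosts == 30
        assert s.n_infested == 12
        assert s.prevalence == pytest.approx(0.40)
        assert s.total == 468
        assert s.mean_intensity == pytest.approx(39.0)
        assert s.mean_abundance == pytest.approx(15.6)
        assert 7 <= s.count_range[0] and s.count_range[1] <= 83

    def test_no_infested_hosts(self):
        s = lp.summarize_counts(lp.HostCounts.from_sequence([0, 0, 0, 0]))
        assert s.prevalence == 0
        assert s.mean_abundance == 0
        assert s.mean_intensity is None
        assert s.count_range is None

    def test_constant_counts(self):
        s = lp.summarize_counts(lp.HostCounts.from_sequence([7, 7, 7, 7]))
        assert s.prevalence == 1.0
        assert s.mean_intensity == s.mean_abundance == 7
        assert s.variance_to_mean == 0

    def test_empty_input_rejected(self):
        with pytest.raises(NoHostsError):
            lp.HostCounts.from_sequence([])

    def test_negative_and_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            lp.HostCounts.from_sequence([1, -2])
        with pytest.raises(ValueError):
            lp.HostCounts(np.array([1.5, 2.0]))

    @given(counts=count_vectors)
    def test_abundance_identity(self, counts):
        """mean_abundance = prevalence * mean_intensity whenever defined."""
        s = lp.summarize_counts(lp.HostCounts.from_sequence(counts))
        if s.n_infested > 0:
            assert s.mean_abundance == pytest.approx(s.prevalence * s.mean_intensity)
        assert s.n_infested <= s.n_hosts
        assert s.variance == pytest.approx(np.var(counts, ddof=1))


class TestMomentFit:
    @given(counts=count_vectors)
    def test_closed_form(self, counts):
        """Moment k equals mean^2/(variance - mean) exactly; else an error."""
        x = np.asarray(counts, dtype=float)
        m, v = x.mean(), x.var(ddof=1)
        hc = lp.HostCounts.from_sequence(counts)
        if v > m:
            fit = lp.fit_negbin_moments(hc)
            assert fit.k == pytest.approx(m * m / (v - m), rel=1e-12)
            assert fit.method == "moments" and fit.converged
        else:
            with pytest.raises(NoOverdispersionError):
                lp.fit_negbin_moments(hc)

    def test_recovery_from_simulated_sample(self):
        sample = lp.simulate_host_counts(1000, mean=15.0, k=0.5, seed=42)
        fit = lp.fit_negbin_moments(sample)
        assert fit.k == pytest.approx(0.5, abs=0.15)


class TestMLEFit:
    def test_recovery_heavily_aggregated(self):
        sample = lp.simulate_host_counts(1000, mean=15.6, k=0.12, seed=7)
        fit = lp.fit_negbin_mle(sample)
        assert fit.converged
        assert fit.mean == pytest.approx(float(sample.counts.mean()))
        assert fit.k == pytest.approx(0.12, abs=0.04)

    def test_matches_brute_force_grid(self, census):
        """Profile MLE agrees with a dumb grid search over k (scipy pmf route)."""
        from scipy import stats

        x = census.counts
        m = x.mean()
        grid = np.logspace(-3, 2, 4000)
        ll = np.array(
            [stats.nbinom.logpmf(x, k, k / (k + m)).sum() for k in grid]
        )
        k_grid = grid[np.argmax(ll)]
        fit = lp.fit_negbin_mle(census)
        assert fit.k == pytest.approx(k_grid, rel=2e-3)
        assert fit.loglik >= ll.max() - 1e-8

    def test_consistent_with_moments_on_large_sample(self):
        sample = lp.simulate_host_counts(10_000, mean=10.0, k=1.0, seed=11)
        k_mom = lp.fit_negbin_moments(sample).k
        k_mle = lp.fit_negbin_mle(sample).k
        assert abs(k_mle - k_mom) / k_mom < 0.10

    def test_constant_counts_flagged(self):
        fit = lp.fit_negbin_mle(lp.HostCounts.from_sequence([5, 5, 5, 5]))
        assert not fit.converged

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lp.fit_negbin_mle(lp.HostCounts.from_sequence([0, 0, 0]))


def brute_force_discrepancy(counts) -> float:
    """Independent oracle via the mean-absolute-difference (Gini) identity:
    D = [sum_ij |x_i - x_j| / (2 N^2 mean)] * N / (N + 1)."""
    x = list(counts)
    n = len(x)
    mean = sum(x) / n
    total_diff = sum(abs(a - b) for a in x for b in x)
    return total_diff / (2 * n * n * mean) * n / (n + 1)


class TestDiscrepancy:
    def test_hand_worked_example(self):
        d = lp.index_of_discrepancy(lp.HostCounts.from_sequence([0, 0, 0, 10]))
        assert d.D == pytest.approx(0.6)

    def test_uniform_counts_give_zero(self):
        d = lp.index_of_discrepancy(lp.HostCounts.from_sequence([5, 5, 5, 5]))
        assert d.D == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lp.index_of_discrepancy(lp.HostCounts.from_sequence([0, 0]))

    @given(counts=count_vectors.filter(lambda c: sum(c) > 0))
    def test_permutation_invariance_and_range(self, counts):
        d = lp.index_of_discrepancy(lp.HostCounts.from_sequence(counts)).D
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(counts))
        d2 = lp.index_of_discrepancy(lp.HostCounts.from_sequence(perm)).D
        assert d == pytest.approx(d2, abs=1e-12)
        assert 0 - 1e-12 <= d < 1
        assert d == pytest.approx(brute_force_discrepancy(counts), abs=1e-12)

    def test_pigou_dalton_transfer_increases_d(self):
        """Moving a louse from a poorer to a strictly richer host raises D."""
        base = [2, 3, 5, 9]
        d0 = lp.index_of_discrepancy(lp.HostCounts.from_sequence(base)).D
        transferred = [1, 3, 5, 10]
        d1 = lp.index_of_discrepancy(lp.HostCounts.from_sequence(transferred)).D
        assert d1 > d0


class TestGOF:
    def test_expected_mass_sums_to_n(self, census):
        fit = lp.fit_negbin_mle(census)
        gof = lp.gof_negbin(census, fit, min_expected=1.0)
        total_expected = sum(e for _, _, e in gof.classes)
        assert total_expected == pytest.approx(census.n_hosts, abs=1e-6)
        assert sum(o for _, o, _ in gof.classes) == census.n_hosts
        assert gof.df == len(gof.classes) - 3
        assert 0 <= gof.p_value <= 1

    def test_pooling_respects_threshold(self):
        sample = lp.simulate_host_counts(400, mean=8.0, k=0.6, seed=3)
        fit = lp.fit_negbin_mle(sample)
        gof = lp.gof_negbin(sample, fit, min_expected=1.0)
        assert all(e >= 1.0 for _, _, e in gof.classes)

    def test_perfect_match_gives_small_chi2(self):
        """Observed classes set equal to rounded expected counts -> chi2 ~ 0."""
        from scipy import stats

        k, m, n = 1.2, 4.0, 500
        p = k / (k + m)
        counts = []
        for j in range(40):
            counts.extend([j] * int(round(n * stats.nbinom.pmf(j, k, p))))
        hc = lp.HostCounts.from_sequence(counts)
        fit = lp.NegBinFit(k=k, mean=m, method="mle", loglik=None, converged=True)
        gof = lp.gof_negbin(hc, fit, min_expected=1.0)
        # expected recomputed for len(counts) hosts; rounding leaves crumbs only
        assert gof.chi2 < 2.0
        assert gof.p_value > 0.95

    def test_too_few_classes_rejected(self):
        hc = lp.HostCounts.from_sequence([0, 0, 1, 1, 1, 0])
        fit = lp.fit_negbin_mle(hc)
        with pytest.raises(ValueError, match="pooled classes"):
            lp.gof_negbin(hc, fit, min_expected=1.0)


def test_exhaustive_discrepancy_vs_brute_force():
    """D matches the independent oracle on every vector of length <= 5, total <= 12."""
    for n in range(2, 6):
        for vec in itertools.product(range(13), repeat=n):
            if not 0 < sum(vec) <= 12:
                continue
            d = lp.index_of_discrepancy(lp.HostCounts.from_sequence(vec)).D
            assert d == pytest.approx(brute_force_discrepancy(vec), abs=1e-12)
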