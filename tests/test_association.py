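import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cnvaccord import association as assoc
from cnvaccord.types import HYPOTHESES, UndefinedFDRError
from conftest import build_map, build_states


def hypergeom_enumeration_p(table) -> float:
    """Independent two-sided Fisher oracle: enumerate the conditional
    hypergeometric support and sum outcomes no more probable than the
    observed one."""
    a, b = table[0]
    c, d = table[1]
    n1, n2, K = a + b, c + d, a + c
    support = range(max(0, K - n2), min(K, n1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n1 + n2, K, n1) for k in support}
    return min(1.0, sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7)))


class TestTabulateSite:
    def test_exhaustive_count_all_diploid(self):
        m = build_states([[2], [2]], [[2], [2]])
        t = assoc.tabulate_site(m, 0)
        assert np.array_equal(t.counts, [[0, 0, 2, 0, 0], [0, 0, 2, 0, 0]])

    def test_hand_tabulated_loss_table(self):
        m = build_states([[1], [1], [2]], [[2], [2], [2]])
        t = assoc.tabulate_site(m, 0)
        assert np.array_equal(t.collapsed["loss"], [[2, 1], [0, 3]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_collapsed_margins_match_full_table(self, seed):
        rng = np.random.default_rng(seed)
        m = build_states(rng.integers(0, 5, (4, 3)), rng.integers(0, 5, (5, 3)))
        t = assoc.tabulate_site(m, int(rng.integers(0, 3)))
        for h in HYPOTHESES:
            assert np.array_equal(t.collapsed[h].sum(axis=1), t.counts.sum(axis=1))

    def test_out_of_range_index(self):
        m = build_states([[2]], [[2]])
        with pytest.raises(ValueError):
            assoc.tabulate_site(m, 1)


class TestTestSite:
    def test_identical_distributions_give_p_one(self):
        m = build_states([[1]] * 10 + [[2]] * 10, [[1]] * 10 + [[2]] * 10)
        r = assoc.test_site(assoc.tabulate_site(m, 0))
        assert r.p_pearson == 1.0

    def test_gain_p_matches_hypergeometric_enumeration(self):
        table = [[8, 2], [1, 9]]
        m = build_states([[3]] * 8 + [[2]] * 2, [[4]] + [[2]] * 9)
        r = assoc.test_site(assoc.tabulate_site(m, 0))
        assert r.p_gain == pytest.approx(hypergeom_enumeration_p(table), rel=1e-9)

    def test_degenerate_all_diploid_gives_all_ones(self):
        m = build_states([[2]] * 5, [[2]] * 5)
        r = assoc.test_site(assoc.tabulate_site(m, 0))
        assert (r.p_pearson, r.p_loss, r.p_gain, r.p_abnm, r.p_trend) == (1,) * 5

    def test_best_hypothesis_has_smallest_p(self, rng):
        for _ in range(20):
            m = build_states(rng.integers(0, 5, (12, 1)), rng.integers(0, 5, (15, 1)))
            r = assoc.test_site(assoc.tabulate_site(m, 0))
            best = {"loss": r.p_loss, "gain": r.p_gain, "abnm": r.p_abnm}[r.best_hypothesis]
            assert best == min(r.p_loss, r.p_gain, r.p_abnm)

    def test_trend_p_matches_correlation_identity(self, rng):
        # Cochran-Armitage chi2 equals N * r^2 with r the Pearson correlation
        # between individual scores and case status — an independent route.
        for _ in range(10):
            states = rng.integers(0, 5, size=40)
            case = rng.random(40) < 0.5
            if case.all() or (~case).all() or len(np.unique(states)) < 2:
                continue
            counts = np.zeros((2, 5))
            np.add.at(counts[0], states[case], 1)
            np.add.at(counts[1], states[~case], 1)
            r = np.corrcoef(states, case)[0, 1]
            expected = stats.chi2.sf(len(states) * r * r, 1)
            assert assoc.trend_test_p(counts) == pytest.approx(expected, rel=1e-9)


class TestBatchMatchesSingleSite:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 3000))
    def test_batch_and_scipy_paths_agree(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = 6
        states = build_states(rng.integers(0, 5, (9, n_sites)), rng.integers(0, 5, (11, n_sites)))
        counts = assoc.site_state_counts(states)
        batch = assoc.batch_site_tests(counts)
        for i in range(n_sites):
            single = assoc.test_site(assoc.tabulate_site(states, i))
            assert batch["p_pearson"][i] == pytest.approx(single.p_pearson, rel=1e-9)
            assert batch["p_loss"][i] == pytest.approx(single.p_loss, rel=1e-7)
            assert batch["p_gain"][i] == pytest.approx(single.p_gain, rel=1e-7)
            assert batch["p_abnm"][i] == pytest.approx(single.p_abnm, rel=1e-7)
            assert batch["p_trend"][i] == pytest.approx(single.p_trend, rel=1e-9)
            # ties between hypotheses may break differently across the two
            # routes; the chosen hypothesis must attain the minimum p
            chosen = batch[f"p_{HYPOTHESES[batch['best_hypothesis'][i]]}"][i]
            assert chosen == pytest.approx(single.p_best, rel=1e-7)

    def test_permuted_counts_match_direct_tabulation(self, rng):
        states = build_states(rng.integers(0, 5, (8, 4)), rng.integers(0, 5, (7, 4)))
        masks = assoc.permutation_masks(states.case_mask, 5, rng)
        perm = assoc.permuted_state_counts(states, masks)
        for m in range(5):
            direct = assoc.site_state_counts(states, masks[m])
            assert np.array_equal(perm[m], direct)


class TestWindows:
    def test_half_width_zero_is_single_site(self, small_map, rng):
        states = build_states(rng.integers(0, 5, (10, 10)), rng.integers(0, 5, (10, 10)))
        results = assoc.test_all_sites(states, small_map)
        w = assoc.window_test(results, small_map, ["s3"], half_width=0)
        h = results.loc[3, "best_hypothesis"]
        expected = -np.log10(max(results.loc[3, f"p_{h}"], assoc.P_FLOOR))
        assert w["s_w"][0] == pytest.approx(expected)
        assert w["members"][0] == ("s3",)

    def test_five_members_at_p_point_one_sum_to_five(self):
        members = np.arange(5)[None, :].repeat(5, axis=0)
        p_hyp = np.full((5, 3), 0.1)
        s = assoc.window_statistics(p_hyp, np.zeros(5, dtype=int), members)
        assert np.allclose(s, 5.0)

    def test_window_truncated_at_large_gap(self, small_map, rng):
        # s2 at 21 kb; the next gap (21k -> 71k) is 50 kb > 30 kb
        states = build_states(rng.integers(0, 5, (6, 10)), rng.integers(0, 5, (6, 10)))
        results = assoc.test_all_sites(states, small_map)
        w = assoc.window_test(results, small_map, ["s2"], half_width=2, max_gap=30_000)
        assert w["members"][0] == ("s0", "s1", "s2")

    def test_windows_never_cross_chromosomes(self, small_map):
        members = assoc.window_members(small_map, 2, 1_000_000)
        chroms = small_map.chroms
        for i in range(len(small_map)):
            mem = members[i][members[i] >= 0]
            assert (chroms[mem] == chroms[i]).all()

    def test_unknown_candidate_rejected(self, small_map, rng):
        states = build_states(rng.integers(0, 5, (4, 10)), rng.integers(0, 5, (4, 10)))
        results = assoc.test_all_sites(states, small_map)
        with pytest.raises(ValueError):
            assoc.window_test(results, small_map, ["nope"])


class TestPermutationFDR:
    def test_empty_null_tail_gives_zero(self):
        fdr = assoc.permutation_fdr(np.array([5.0, 1.0]), np.array([[0.1, 0.2]]), 4.0)
        assert fdr == 0.0

    def test_identity_permutation_gives_one(self):
        observed = np.array([3.0, 1.0, 2.0])
        ensemble = np.tile(observed, (4, 1))
        for t in observed:
            assert assoc.permutation_fdr(observed, ensemble, t) == 1.0

    def test_hand_counted_example(self):
        observed = np.array([3.0, 1.0, 2.0])
        ensemble = np.array([[2.5, 0.5, 0.5], [1.5, 3.5, 0.1]])
        # threshold 2: observed >= 2 -> 2 sites; null >= 2 -> 2 entries
        assert assoc.permutation_fdr(observed, ensemble, 2.0) == pytest.approx(2 / (2 * 2))

    def test_no_observed_passer_is_an_error(self):
        with pytest.raises(UndefinedFDRError):
            assoc.permutation_fdr(np.array([1.0]), np.array([[2.0]]), 5.0)

    def test_qvalues_monotone_in_statistic(self, rng):
        observed = rng.normal(size=60)
        ensemble = rng.normal(size=(30, 60))
        q = assoc.fdr_qvalues(observed, ensemble)
        order = np.argsort(observed)
        assert (np.diff(q[order]) <= 1e-12).all()

    def test_qvalue_never_exceeds_raw_fdr(self, rng):
        observed = rng.normal(size=40)
        ensemble = rng.normal(size=(10, 40))
        q = assoc.fdr_qvalues(observed, ensemble)
        for i in range(len(observed)):
            assert q[i] <= assoc.permutation_fdr(observed, ensemble, observed[i]) + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2000))
    def test_permutation_masks_preserve_cohort_sizes(self, seed):
        rng = np.random.default_rng(seed)
        case_mask = np.zeros(17, dtype=bool)
        case_mask[:8] = True
        masks = assoc.permutation_masks(case_mask, 6, rng)
        assert (masks.sum(axis=1) == 8).all()
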