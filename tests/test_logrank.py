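"""Logrank tests: hand-accumulated oracle, reference equivalence, invariances."""

import itertools

import numpy as np
import pytest

import survfig as sf


def brute_force_logrank(groups):
    """Independent two-or-more-group oracle: explicit accumulation of
    observed minus expected and the hypergeometric covariance at each
    distinct event time, quadratic form on the first k-1 groups."""
    k = len(groups)
    all_t = np.concatenate([t for t, _ in groups])
    all_s = np.concatenate([s for _, s in groups]).astype(bool)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in sorted(set(all_t[all_s].tolist())):
        n = np.array([(np.asarray(t) >= u).sum() for t, _ in groups], float)
        d = np.array([((np.asarray(t) == u) & np.asarray(s, bool)).sum()
                      for t, s in groups], float)
        N, D = n.sum(), d.sum()
        O += d
        E += D * n / N
        if N > 1:
            for g in range(k):
                for h in range(k):
                    delta = 1.0 if g == h else 0.0
                    V[g, h] += D * (N - D) / (N - 1) * (n[g] / N) * (
                        delta - n[h] / N)
    diff = (O - E)[:-1]
    stat = float(diff @ np.linalg.pinv(V[:-1, :-1]) @ diff)
    return O, E, stat


class TestGlobal:
    def test_identical_groups_give_null_result(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        s = np.array([1, 0, 1, 1])
        res = sf.logrank_global([(t, s), (t, s)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_data_matches_hand_accumulation(self):
        # A: events at 1, 2; B: events at 3, 4.
        # t=1: n=(2,2), E_A += 1/2, V += 1/4
        # t=2: n=(1,2), E_A += 1/3, V += 2/9
        # t=3: n=(0,2), no contribution to E_A or V
        # t=4: N=1, skipped (no variance)
        # => O_A - E_A = 7/6, V = 17/36, chi2 = 49/17
        groups = [(np.array([1.0, 2.0]), np.array([1, 1])),
                  (np.array([3.0, 4.0]), np.array([1, 1]))]
        res = sf.logrank_global(groups)
        assert res.statistic == pytest.approx(49 / 17, rel=1e-12)
        O, E, stat = brute_force_logrank(groups)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert np.allclose(res.observed, O) and np.allclose(res.expected, E)

    def test_observed_and_expected_totals_agree(self):
        rng = np.random.default_rng(5)
        groups = [(rng.exponential(10, 30).round(0) + 1, rng.integers(0, 2, 30))
                  for _ in range(3)]
        res = sf.logrank_global(groups)
        assert res.observed.sum() == pytest.approx(res.expected.sum())
        assert res.df == 2

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_data(self, k, seed):
        rng = np.random.default_rng(1000 * k + seed)
        groups = []
        for _ in range(k):
            n = int(rng.integers(3, 15))
            t = rng.integers(1, 10, size=n).astype(float)
            s = rng.integers(0, 2, size=n)
            groups.append((t, s))
        if not any(s.any() for _, s in groups):
            groups[0][1][0] = 1
        res = sf.logrank_global(groups)
        _, _, stat = brute_force_logrank(groups)
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_reference_implementation(self, seed):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        t = rng.integers(1, 9, size=n).astype(float)
        s = rng.integers(0, 2, size=n)
        g = rng.integers(0, 2, size=n)
        if len(set(g.tolist())) < 2 or not s.any():
            return
        res = sf.logrank_global([(t[g == 0], s[g == 0]), (t[g == 1], s[g == 1])])
        ref = multivariate_logrank_test(t, g, s)
        assert abs(res.statistic - ref.test_statistic) < 1e-10
        assert abs(res.p_value - ref.p_value) < 1e-10

    def test_group_order_irrelevant(self):
        rng = np.random.default_rng(9)
        groups = [(rng.exponential(5, 20).round(1), rng.integers(0, 2, 20))
                  for _ in range(3)]
        base = sf.logrank_global(groups)
        for perm in itertools.permutations(range(3)):
            res = sf.logrank_global([groups[i] for i in perm])
            assert res.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(11)
        groups = [(rng.exponential(5, 25) + 0.1, rng.integers(0, 2, 25))
                  for _ in range(2)]
        base = sf.logrank_global(groups)
        warped = [(np.sqrt(t) + t ** 3, s) for t, s in groups]
        res = sf.logrank_global(warped)
        assert res.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        t = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="two groups"):
            sf.logrank_global([(t, np.array([1, 1]))])
        with pytest.raises(ValueError, match="no events"):
            sf.logrank_global([(t, np.zeros(2)), (t, np.zeros(2))])


class TestPairwise:
    @pytest.fixture()
    def three_groups(self):
        rng = np.random.default_rng(21)
        return [(rng.exponential(30, 40).round(0) + 1, rng.integers(0, 2, 40))
                for _ in range(3)]

    def test_three_groups_give_three_pairs(self, three_groups):
        results = sf.logrank_pairwise(three_groups,
                                      labels=["1", "2", "3"])
        assert [r.description for r in results] == ["1, 2", "1, 3", "2, 3"]

    def test_descriptions_overridable(self, three_groups):
        names = ["Group 1 vs 2", "Group 1 vs 3", "Group 2 vs 3"]
        results = sf.logrank_pairwise(three_groups, descriptions=names)
        assert [r.description for r in results] == names

    def test_two_groups_identical_to_global(self):
        rng = np.random.default_rng(31)
        groups = [(rng.exponential(5, 20), rng.integers(0, 2, 20))
                  for _ in range(2)]
        pair, = sf.logrank_pairwise(groups)
        glob = sf.logrank_global(groups)
        assert pair.statistic == pytest.approx(glob.statistic)
        assert pair.p_value == pytest.approx(glob.p_value)

    def test_four_groups_give_six_pairs(self):
        rng = np.random.default_rng(41)
        groups = [(rng.exponential(5, 15), rng.integers(0, 2, 15))
                  for _ in range(4)]
        assert len(sf.logrank_pairwise(groups)) == 6


class TestFormatP:
    @pytest.mark.parametrize("p,digits,expected", [
        (0.123456, 4, "0.1235"),
        (1.0, 4, "1.0000"),
        (3.0e-6, 4, "<0.0001"),
        (0.05, 2, "0.05"),
        (0.0004, 3, "<0.001"),
        (0.0006, 3, "0.001"),
        (0.0, 4, "<0.0001"),
    ])
    def test_fixed_point_with_clip(self, p, digits, expected):
        assert sf.format_p(p, digits) == expected

    def test_default_precision_is_four(self):
        assert sf.format_p(0.5) == "0.5000"

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sf.format_p(bad)

    @pytest.mark.parametrize("digits", [0, 11])
    def test_bad_digits_rejected(self, digits):
        with pytest.raises(ValueError):
            sf.format_p(0.5, digits)
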