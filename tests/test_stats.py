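"""Unit and property tests for the statistics layer.

Independent oracles: scipy.stats implementations and brute-force
enumeration over permutations / hypergeometric support.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from seednet.stats import (
    ContingencyTable2x2,
    anova_bonferroni,
    dunn_posthoc,
    encode_severity,
    fisher_exact,
    kruskal_wallis,
    mann_whitney,
    midranks,
    one_sample_t,
)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisher:
    def test_boundary_of_support_is_one(self):
        assert fisher_exact([[0, 5], [5, 0]], tail="greater").p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        r = fisher_exact([[5, 0], [0, 5]], tail="greater")
        assert r.p_value == pytest.approx(1 / 252)

    def test_zero_margin_degenerate(self):
        r = fisher_exact([[0, 0], [3, 4]], tail="greater")
        assert r.p_value == 1.0 and r.degenerate

    @pytest.mark.parametrize("tail", ["greater", "less", "two_sided"])
    def test_matches_scipy_on_sample_tables(self, tail):
        scipy_alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[tail]
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if min(t.row1, t.row2, t.col1, t.col2) == 0:
                continue
            expected = sps.fisher_exact([[a, b], [c, d]], alternative=scipy_alt)[1]
            assert fisher_exact(t, tail=tail).p_value == pytest.approx(expected, rel=1e-9)

    def test_one_tailed_le_two_sided_when_directional(self):
        r_g = fisher_exact([[10, 2], [3, 9]], tail="greater")
        r_2 = fisher_exact([[10, 2], [3, 9]], tail="two_sided")
        assert r_g.p_value <= r_2.p_value + 1e-12


# ---------------------------------------------------------------------------
# One-sample t
# ---------------------------------------------------------------------------

class TestOneSampleT:
    def test_symmetric_data_gives_p_one(self):
        r = one_sample_t([-2, -1, 0, 1, 2], mu0=0)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_example(self):
        r = one_sample_t([1, 2, 3, 4, 5], mu0=0)
        assert r.statistic == pytest.approx(3 / (math.sqrt(2.5) / math.sqrt(5)), rel=1e-12)
        assert r.statistic == pytest.approx(4.2426, abs=1e-4)
        assert r.p_value == pytest.approx(0.0132, abs=2e-4)
        expected = sps.ttest_1samp([1, 2, 3, 4, 5], 0).pvalue
        assert r.p_value == pytest.approx(expected, rel=1e-9)

    def test_translation_invariance(self):
        xs = [0.3, 1.2, -0.7, 2.4]
        r0 = one_sample_t(xs, mu0=0.5)
        r1 = one_sample_t([x + 10 for x in xs], mu0=10.5)
        assert r0.statistic == pytest.approx(r1.statistic)
        assert r0.p_value == pytest.approx(r1.p_value)

    def test_zero_variance_degenerate(self):
        assert one_sample_t([3, 3, 3], mu0=3).p_value == 1.0
        assert one_sample_t([3, 3, 3], mu0=1).p_value == 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _brute_force_mw(x, y, tail="two_sided"):
    """Enumeration oracle: U via scipy midranks, p over all label splits."""
    pooled = np.concatenate([x, y])
    m = len(x)

    def u_of(idx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        ranks = sps.rankdata(pooled)
        return ranks[mask].sum() - m * (m + 1) / 2

    u_obs = u_of(range(m))
    mu = m * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), m)]
    if tail == "two_sided":
        p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us])
    elif tail == "greater":
        p = np.mean([u >= u_obs - 1e-9 for u in us])
    else:
        p = np.mean([u <= u_obs + 1e-9 for u in us])
    return u_obs, float(p)


class TestMannWhitney:
    def test_complete_ties_degenerate(self):
        r = mann_whitney([2, 2, 2], [2, 2])
        assert r.statistic == pytest.approx(3.0)
        assert r.p_value == 1.0

    def test_fully_separated_exact(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 20)

    def test_swap_symmetry(self):
        x, y = [1, 3, 3, 7], [2, 3, 8]
        rx = mann_whitney(x, y, mode="exact")
        ry = mann_whitney(y, x, mode="exact")
        assert rx.statistic + ry.statistic == pytest.approx(len(x) * len(y))
        assert rx.p_value == pytest.approx(ry.p_value)

    @pytest.mark.parametrize("x,y", [
        ([0, 0, 1, 2], [0, 1, 1]),           # heavy ties
        ([1.5, 2.5], [0.5, 1.5, 1.5, 3.5]),  # cross-group ties
        ([5], [1, 2, 3]),
        ([0, 0, 0, 1], [0, 0, 2, 2]),
    ])
    def test_exact_matches_enumeration_oracle(self, x, y):
        for tail in ("two_sided", "greater", "less"):
            u_exp, p_exp = _brute_force_mw(x, y, tail)
            r = mann_whitney(x, y, mode="exact", tail=tail)
            assert r.statistic == pytest.approx(u_exp)
            assert r.p_value == pytest.approx(p_exp)

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 200)
        y = rng.integers(0, 4, 250) + (rng.random(250) < 0.3)
        r = mann_whitney(x, y, mode="normal_approx")
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert r.p_value == pytest.approx(expected, rel=1e-6)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=6),
           st.lists(st.integers(0, 3), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_in_unit_interval_and_symmetric(self, x, y):
        r = mann_whitney(x, y, mode="exact")
        assert 0.0 <= r.p_value <= 1.0
        assert mann_whitney(y, x, mode="exact").p_value == pytest.approx(r.p_value)


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Dunn
# ---------------------------------------------------------------------------

class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[1, 1, 1], [1, 1], [1, 1, 1]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    @pytest.mark.parametrize("groups", [
        ([0, 0, 1], [1, 2, 2], [0, 2, 3]),
        ([1, 1, 1, 2], [2, 2, 3], [3, 3]),
        ([0.5, 1.5], [1.5, 1.5, 2.5], [0.5, 3.5]),
    ])
    def test_h_matches_scipy_with_ties(self, groups):
        r = kruskal_wallis(groups)
        expected = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(expected.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(expected.pvalue, rel=1e-9)

    def test_dunn_z_matches_hand_formula(self):
        groups = [[0, 0, 1, 2], [1, 2, 2], [2, 3, 3]]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie = float(np.sum(counts**3 - counts))
        var = n * (n + 1) / 12 - tie / (12 * (n - 1))
        mr = [ranks[:4].mean(), ranks[4:7].mean(), ranks[7:].mean()]
        res = dunn_posthoc(groups, adjust="none")
        for (i, j), r in res.items():
            z_exp = (mr[i] - mr[j]) / math.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
            assert r.statistic == pytest.approx(z_exp, rel=1e-12)
            assert r.p_value == pytest.approx(2 * sps.norm.sf(abs(z_exp)), rel=1e-9)

    def test_bonferroni_contract(self):
        groups = [[0, 1, 2], [1, 2, 3], [2, 3, 4]]
        raw = dunn_posthoc(groups, adjust="none")
        adj = dunn_posthoc(groups, adjust="bonferroni")
        for pair in raw:
            assert raw[pair].p_value <= adj[pair].p_value <= 1.0

    @given(st.lists(st.lists(st.integers(0, 3), min_size=1, max_size=5),
                    min_size=2, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, groups):
        r0 = kruskal_wallis(groups)
        transformed = [[2 * v**3 + 1 for v in g] for g in groups]  # strictly monotone
        r1 = kruskal_wallis(transformed)
        assert r0.statistic == pytest.approx(r1.statistic)
        assert r0.p_value == pytest.approx(r1.p_value)


# ---------------------------------------------------------------------------
# One-way ANOVA + Bonferroni
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_groups_near_zero_f(self):
        om, _ = anova_bonferroni([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert om.statistic == pytest.approx(0.0)
        assert om.p_value == pytest.approx(1.0)

    def test_two_groups_f_is_t_squared(self):
        g1, g2 = [1.2, 3.4, 2.2, 4.0], [2.5, 5.1, 3.3]
        om, pw = anova_bonferroni([g1, g2])
        t = sps.ttest_ind(g1, g2).statistic
        assert om.statistic == pytest.approx(t**2, rel=1e-10)
        assert pw[(0, 1)].statistic == pytest.approx(t, rel=1e-10)

    def test_hand_computed_example(self):
        om, _ = anova_bonferroni([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert om.statistic == pytest.approx(3.0)
        assert om.p_value == pytest.approx(0.125, abs=1e-3)
        expected = sps.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert om.p_value == pytest.approx(expected.pvalue, rel=1e-9)

    def test_pairwise_bonferroni_capped(self):
        _, pw = anova_bonferroni([[1, 2, 3], [1.1, 2.1, 3.1], [1, 2.2, 2.9]])
        for r in pw.values():
            assert 0.0 <= r.p_value <= 1.0


# ---------------------------------------------------------------------------
# Severity encoding and ranks
# ---------------------------------------------------------------------------

class TestSeverity:
    def test_bijection_and_synonym(self):
        assert encode_severity(["normal", "slight", "mild", "moderate"]) == [0, 1, 2, 3]
        assert encode_severity(["none"]) == [0]

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="severe"):
            encode_severity(["severe"])


@given(st.lists(st.integers(-5, 5), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_midranks_match_scipy(values):
    assert np.allclose(midranks(values), sps.rankdata(values))
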