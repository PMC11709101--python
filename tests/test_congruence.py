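import itertools
import math

import numpy as np
import pandas as pd
import pytest

from senmap.congruence import compare_congruence, congruence, de_test
from senmap.io import SignedGeneSet
from tests.conftest import make_matrix


def exact_ranksum_two_sided(x, y):
    """Enumeration oracle: exact two-sided rank-sum p for tie-free samples.

    Enumerates every assignment of the pooled values to the first group and
    uses the symmetric-tail definition P(|U - E[U]| >= |u_obs - E[U]|).
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    center = n1 * len(y) / 2
    total = 0
    hits = 0
    for combo in itertools.combinations(sorted(pooled), n1):
        u = sum(ranks[v] for v in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


class TestDeTest:
    def _matrix(self, ln):
        ln = np.asarray(ln, float)
        return make_matrix(np.zeros(ln.shape, int), lognorm=ln)

    def test_identical_groups_ns(self):
        ln = np.tile([[1.0, 2.0, 0.5, 1.0, 2.0, 0.5]], (3, 1))
        m = self._matrix(ln)
        de = de_test(m, np.arange(3), np.arange(3, 6))
        assert (de["log_fc"] == 0).all()
        assert (de["direction"] == "ns").all()

    def test_log_fc_formula(self):
        # in-group lognorm 2 everywhere, out-group 0: ln((e^2-1+1)/(0+1)) = 2
        ln = np.zeros((2, 8))
        ln[0, :4] = 2.0
        m = self._matrix(ln)
        de = de_test(m, np.arange(4), np.arange(4, 8))
        assert de["log_fc"].iloc[0] == pytest.approx(2.0)
        assert de["p"].iloc[0] < 0.05  # unadjusted exact rank-sum 4v4

    def test_fc_gate_precedes_testing(self):
        # strong separation but |log_fc| ~ 0.20 < 0.25: must be ns with p = 1
        lo, hi = 0.5, 0.65
        fc = math.log((math.expm1(hi) + 1) / (math.expm1(lo) + 1))
        assert 0.1 < fc < 0.25
        ln = np.zeros((1, 40))
        ln[0, :20] = hi
        ln[0, 20:] = lo
        m = self._matrix(ln)
        de = de_test(m, np.arange(20), np.arange(20, 40))
        assert de["direction"].iloc[0] == "ns"
        assert de["p"].iloc[0] == 1.0

    def test_bonferroni_multiplier_is_total_genes(self):
        rng = np.random.default_rng(0)
        ln = rng.uniform(0, 0.2, size=(50, 20))
        ln[0, :10] += 3.0
        m = self._matrix(ln)
        de = de_test(m, np.arange(10), np.arange(10, 20))
        g = de.iloc[0]
        assert g["p_bonf"] == pytest.approx(min(1.0, g["p"] * 50))

    def test_antisymmetric_in_group_swap(self):
        rng = np.random.default_rng(1)
        ln = rng.uniform(0, 3, size=(10, 30))
        m = self._matrix(ln)
        a, b = np.arange(15), np.arange(15, 30)
        d1 = de_test(m, a, b)
        d2 = de_test(m, b, a)
        np.testing.assert_allclose(d2["log_fc"], -d1["log_fc"], atol=1e-12)
        np.testing.assert_allclose(d2["p"], d1["p"], atol=1e-12)

    def test_overlap_and_small_groups_rejected(self):
        m = self._matrix(np.zeros((2, 10)))
        with pytest.raises(ValueError, match="overlap"):
            de_test(m, np.arange(5), np.arange(4, 10))
        with pytest.raises(ValueError, match="at least 3"):
            de_test(m, np.arange(2), np.arange(5, 10))

    def test_exact_path_matches_enumeration(self):
        """Exact rank-sum agrees with full enumeration for all small
        tie-free two-group fixtures (200 random draws, groups <= 6)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(3, 7, size=2)
            pooled = rng.permutation(rng.uniform(0.3, 3.0, size=n1 + n2))
            x, y = pooled[:n1], pooled[n1:]
            ln = np.concatenate([x, y])[None, :]
            m = self._matrix(ln)
            de = de_test(m, np.arange(n1), np.arange(n1, n1 + n2), fc_cutoff=0.0)
            assert de["p"].iloc[0] == pytest.approx(exact_ranksum_two_sided(x, y), abs=1e-12)


class TestCongruence:
    def _de(self, directions, log_fc=None):
        genes = list(directions)
        return pd.DataFrame(
            {
                "log_fc": log_fc or [1.0 if d == "up" else -1.0 if d == "down" else 0.0
                                     for d in directions.values()],
                "direction": list(directions.values()),
            },
            index=pd.Index(genes, name="gene"),
        )

    def test_full_agreement(self):
        de = self._de({"A": "up", "B": "down"})
        gs = SignedGeneSet("s", [("A", "up"), ("B", "down")])
        r = congruence(de, gs)
        assert r.n_congruent == 2 and r.n_total == 2

    def test_ns_is_incongruent(self):
        de = self._de({"A": "ns", "B": "down"})
        gs = SignedGeneSet("s", [("A", "up"), ("B", "down")])
        r = congruence(de, gs)
        assert r.n_congruent == 1 and r.proportion == 0.5

    def test_absent_genes_excluded_and_reported(self):
        de = self._de({"A": "up"})
        gs = SignedGeneSet("s", [("A", "up"), ("ZZZ", "down")])
        r = congruence(de, gs)
        assert r.n_total == 1 and r.absent_genes == ["ZZZ"]

    def test_direction_only_ignores_significance(self):
        de = self._de({"A": "ns"}, log_fc=[0.8])
        gs = SignedGeneSet("s", [("A", "up")])
        assert congruence(de, gs).n_congruent == 0
        assert congruence(de, gs, direction_only=True).n_congruent == 1

    def test_nested_significance_monotone(self):
        """Congruent counts can only drop when alpha tightens."""
        rng = np.random.default_rng(2)
        ln = rng.uniform(0, 1, size=(30, 40))
        ln[:10, :20] += rng.uniform(0.3, 1.5, size=(10, 1))
        m = make_matrix(np.zeros((30, 40), int), lognorm=ln)
        gs = SignedGeneSet("s", [(f"g{i}", "up") for i in range(10)])
        counts = []
        for alpha in (0.5, 0.05, 0.005):
            de = de_test(m, np.arange(20), np.arange(20, 40), alpha=alpha)
            counts.append(congruence(de, gs).n_congruent)
        assert counts[0] >= counts[1] >= counts[2]


class TestCompareCongruence:
    def test_headline_comparison_tiny_p(self):
        p = compare_congruence(139, 165, 44, 165, "less")
        assert p <= 2.2e-16

    def test_equal_proportions_not_significant(self):
        assert compare_congruence(80, 100, 80, 100, "less") >= 0.5

    def test_exact_tail_sum(self):
        assert compare_congruence(5, 10, 2, 10, "less") == pytest.approx(56 / 1024)

    def test_degenerate_null(self):
        assert compare_congruence(0, 10, 0, 10, "less") == 1.0
        assert compare_congruence(10, 10, 10, 10, "greater") == 1.0
        assert compare_congruence(10, 10, 9, 10, "less") == 0.0

    def test_monotone_in_k2(self):
        ps = [compare_congruence(139, 165, k2, 165, "less") for k2 in range(0, 166, 15)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_congruence(5, 4, 1, 10)
        with pytest.raises(ValueError):
            compare_congruence(1, 10, 1, 10, alternative="sideways")
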