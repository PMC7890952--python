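import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from oracles import bf_cmi, bf_la, bf_mi, bf_ms, bf_pcc, bf_vdw
from cernanet.io_harmonize import ExpressionMatrix, InteractionTable
from cernanet.pair_measures import (
    cmi,
    compute_pair_record,
    discretize,
    la,
    mi,
    ms,
    pair_context,
    pcc,
    vdw_scores,
)


class TestMS:
    def test_t_zero_is_one(self):
        assert ms(0, 4, 5, 10) == 1.0
        assert ms(0, 0, 0, 10) == 1.0

    def test_derived_example(self):
        # enumeration of C(4,i) C(6,5-i)/C(10,5) for i in {3,4}: 66/252
        assert ms(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_degenerate_full_overlap(self):
        q = 7
        assert ms(q, q, q, q) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_configurations(self):
        with pytest.raises(ValueError):
            ms(3, 2, 5, 10)  # t > T1
        with pytest.raises(ValueError):
            ms(1, 11, 5, 10)  # T1 > Q
        with pytest.raises(ValueError):
            ms(-1, 2, 2, 10)

    def test_matches_bruteforce_sample(self):
        for (t, T1, T2, Q) in [(1, 3, 4, 12), (2, 5, 5, 9), (4, 6, 7, 20)]:
            assert ms(t, T1, T2, Q) == pytest.approx(bf_ms(t, T1, T2, Q), abs=1e-12)

    @given(st.integers(1, 20).flatmap(
        lambda q: st.tuples(
            st.just(q), st.integers(0, 20), st.integers(0, 20)
        ).filter(lambda x: x[1] <= q and x[2] <= q)
    ))
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_in_t(self, qtt):
        q, t1, t2 = qtt
        vals = [ms(t, t1, t2, q) for t in range(min(t1, t2) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPCC:
    def test_perfect_linear(self):
        assert pcc(np.array([1, 2, 3.0]), np.array([2, 4, 6.0])) == pytest.approx(1.0)

    def test_anti(self):
        assert pcc(np.array([1, 2, 3.0]), np.array([3, 2, 1.0])) == pytest.approx(-1.0)

    def test_derived(self):
        assert pcc(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0])) == pytest.approx(0.8)

    def test_constant_returns_none(self):
        assert pcc(np.array([1, 1, 1.0]), np.array([1, 2, 3.0])) is None

    def test_against_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pcc(x, y) == pytest.approx(bf_pcc(list(x), list(y)), abs=1e-12)


class TestDiscretize:
    def test_equal_frequency(self):
        d = discretize(np.array([1, 2, 3, 4.0]), 2, "equal-frequency")
        np.testing.assert_array_equal(d.labels, [0, 0, 1, 1])

    def test_equal_width(self):
        d = discretize(np.array([1, 2, 3, 10.0]), 2, "equal-width")
        np.testing.assert_array_equal(d.labels, [0, 0, 0, 1])

    def test_constant(self):
        d = discretize(np.array([5, 5, 5.0]), 2)
        np.testing.assert_array_equal(d.labels, [0, 0, 0])

    def test_equal_frequency_balanced_no_ties(self, rng):
        x = rng.permutation(np.arange(12, dtype=float))
        d = discretize(x, 3)
        sizes = np.bincount(d.labels)
        assert sizes.max() - sizes.min() <= 1

    def test_labels_in_range(self, rng):
        x = rng.normal(size=20)
        for method in ("equal-frequency", "equal-width"):
            d = discretize(x, 4, method)
            assert d.labels.min() >= 0 and d.labels.max() < 4


class TestMI:
    def test_identical_two_level(self):
        d = discretize(np.array([1, 2, 3, 4.0]), 2)
        assert mi(d, d) == pytest.approx(math.log(2), abs=1e-12)

    def test_product_joint_zero(self):
        dx = discretize(np.array([1, 1, 2, 2.0]), 2)
        dy = discretize(np.array([1, 2, 1, 2.0]), 2)
        assert mi(dx, dy) == pytest.approx(0.0, abs=1e-12)

    def test_constant_partner_zero(self):
        dx = discretize(np.array([1, 2, 3, 4.0]), 2)
        dz = discretize(np.array([7, 7, 7, 7.0]), 2)
        assert mi(dx, dz) == 0.0

    def test_symmetry_and_oracle(self, rng):
        for _ in range(10):
            dx = discretize(rng.normal(size=16), 3)
            dy = discretize(rng.normal(size=16), 3)
            v = mi(dx, dy)
            assert v == pytest.approx(mi(dy, dx), abs=1e-12)
            assert v == pytest.approx(
                bf_mi(list(dx.labels), list(dy.labels)), abs=1e-12
            )
            assert v >= 0

    def test_self_mi_is_entropy(self, rng):
        dx = discretize(rng.normal(size=20), 4)
        counts = np.bincount(dx.labels) / len(dx)
        entropy = -sum(p * math.log(p) for p in counts if p > 0)
        assert mi(dx, dx) == pytest.approx(entropy, abs=1e-12)


class TestCMI:
    def test_constant_condition_equals_mi(self, rng):
        dx = discretize(rng.normal(size=16), 3)
        dy = discretize(rng.normal(size=16), 3)
        dz = discretize(np.full(16, 2.0), 3)
        assert cmi(dx, dy, dz) == pytest.approx(mi(dx, dy), abs=1e-12)

    def test_independent_products_zero(self):
        # full 2x2x2 product design over 8 samples
        dx = discretize(np.array([1, 1, 1, 1, 2, 2, 2, 2.0]), 2)
        dy = discretize(np.array([1, 1, 2, 2, 1, 1, 2, 2.0]), 2)
        dz = discretize(np.array([1, 2, 1, 2, 1, 2, 1, 2.0]), 2)
        assert cmi(dx, dy, dz) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_joint_oracle(self):
        x = np.array([1, 1, 2, 2, 1, 2, 2, 1.0])
        y = np.array([1, 2, 2, 1, 1, 1, 2, 2.0])
        z = np.array([1, 1, 1, 1, 2, 2, 2, 2.0])
        dx, dy, dz = (discretize(v, 2) for v in (x, y, z))
        assert cmi(dx, dy, dz) == pytest.approx(
            bf_cmi(list(dx.labels), list(dy.labels), list(dz.labels)), abs=1e-12
        )

    def test_symmetry_in_first_two(self, rng):
        for _ in range(5):
            dx = discretize(rng.normal(size=18), 3)
            dy = discretize(rng.normal(size=18), 3)
            dz = discretize(rng.normal(size=18), 3)
            assert cmi(dx, dy, dz) == pytest.approx(cmi(dy, dx, dz), abs=1e-12)
            assert cmi(dx, dy, dz) >= 0


class TestVdW:
    def test_n3_exact(self):
        s = vdw_scores(np.array([10, 20, 30.0]))
        assert s[1] == 0.0
        assert s[0] == pytest.approx(norm.ppf(0.25), abs=1e-15)
        assert s[2] == pytest.approx(norm.ppf(0.75), abs=1e-15)

    def test_monotone_invariance(self, rng):
        v = rng.normal(size=11)
        np.testing.assert_allclose(vdw_scores(v), vdw_scores(np.exp(v)), atol=1e-12)

    def test_two_way_tie_average_rank(self):
        v = np.array([5.0, 5.0, 1.0, 9.0])
        # ties at ranks 2,3 -> average 2.5 -> Phi^-1(2.5/5)
        s = vdw_scores(v)
        assert s[0] == s[1] == pytest.approx(norm.ppf(2.5 / 5), abs=1e-15)
        np.testing.assert_allclose(s, bf_vdw(list(v)), atol=1e-12)


class TestLA:
    def test_constant_modulator_zero(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert la(x, y, np.full(8, 3.0)) == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_triple_oracle_value(self):
        # independent oracle gives exactly 0 here: the two nonzero terms are
        # Phi^-1(0.25) + Phi^-1(0.75), which cancel
        v = np.array([1, 2, 3.0])
        assert la(v, v, v) == pytest.approx(bf_la(list(v), list(v), list(v)), abs=1e-12)
        assert la(v, v, v) == pytest.approx(0.0, abs=1e-15)

    def test_swap_symmetry(self, rng):
        x, y, m = rng.normal(size=9), rng.normal(size=9), rng.normal(size=9)
        assert la(x, y, m) == pytest.approx(la(y, x, m), abs=1e-15)

    def test_constant_x_returns_none(self):
        assert la(np.ones(5), np.arange(5.0), np.arange(5.0)) is None

    def test_affine_and_monotone_invariance(self, rng):
        x, y, m = rng.normal(size=10), rng.normal(size=10), rng.normal(size=10)
        base = la(x, y, m)
        assert la(3 * x + 2, y, m) == pytest.approx(base, rel=1e-12, abs=1e-12)
        assert la(x, -0.5 * y + 1, m) == pytest.approx(-base, rel=1e-12, abs=1e-12)
        assert la(x, y, np.exp(m)) == pytest.approx(base, rel=1e-12, abs=1e-12)

    def test_against_oracle(self, rng):
        for _ in range(10):
            x, y, m = rng.normal(size=12), rng.normal(size=12), rng.normal(size=12)
            assert la(x, y, m) == pytest.approx(
                bf_la(list(x), list(y), list(m)), abs=1e-12
            )


class TestPermutationInvariance:
    def test_all_measures(self, rng):
        n = 12
        x, y, m = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        perm = rng.permutation(n)
        assert pcc(x, y) == pytest.approx(pcc(x[perm], y[perm]), abs=1e-12)
        assert la(x, y, m) == pytest.approx(la(x[perm], y[perm], m[perm]), abs=1e-12)
        dx, dy = discretize(x, 3), discretize(y, 3)
        dxp, dyp = discretize(x[perm], 3), discretize(y[perm], 3)
        assert mi(dx, dy) == pytest.approx(mi(dxp, dyp), abs=1e-12)


class TestPairContext:
    def _setup(self):
        inter = InteractionTable.from_pairs(
            [("m1", "A"), ("m2", "A"), ("m2", "B"), ("m3", "B")]
        )
        mirna = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                index=pd.Index(["m1", "m2", "m3"], name="m"),
                columns=["s1", "s2"],
            )
        )
        return inter, mirna

    def test_counts(self):
        inter, mirna = self._setup()
        ctx = pair_context("A", "B", inter, mirna, {"m1", "m2", "m3", "m4", "m5"})
        assert (ctx.Q, ctx.T1, ctx.T2, ctx.t) == (5, 2, 2, 1)
        assert ctx.shared_mirnas == frozenset({"m2"})

    def test_disjoint_targets(self):
        inter = InteractionTable.from_pairs([("m1", "A"), ("m2", "B")])
        _, mirna = self._setup()
        ctx = pair_context("A", "B", inter, mirna, {"m1", "m2"})
        assert ctx.t == 0 and ctx.summed_mirna_expression is None

    def test_summed_expression(self):
        inter = InteractionTable.from_pairs(
            [("m1", "A"), ("m1", "B"), ("m2", "A"), ("m2", "B")]
        )
        _, mirna = self._setup()
        ctx = pair_context("A", "B", inter, mirna, {"m1", "m2", "m3"})
        np.testing.assert_array_equal(ctx.summed_mirna_expression, [4.0, 6.0])

    def test_t_leq_min_T_leq_Q(self):
        inter, mirna = self._setup()
        ctx = pair_context("A", "B", inter, mirna, {"m1", "m2", "m3"})
        assert ctx.t <= min(ctx.T1, ctx.T2) <= ctx.Q

    def test_record_canonical_order(self):
        inter, mirna = self._setup()
        cerna = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0], [2.0, 1.0]],
                index=pd.Index(["A", "B"], name="gene"),
                columns=["s1", "s2"],
            )
        )
        rec = compute_pair_record(
            "B", "A", "All|All", cerna, mirna, inter, {"m1", "m2", "m3"},
            measures=("MS", "PCC"),
        )
        assert (rec.gene1, rec.gene2) == ("A", "B")
        assert 0.0 <= rec.values["MS"] <= 1.0
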