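"""Blomberg's K, Fritz-Purvis D, Brownian simulation, permutation tests."""

import numpy as np
import pytest

from traitsignal import synthetic_data as syn
from traitsignal.phylo import TipTraitMap, parse_newick, vcv_matrix
from traitsignal.signal import (
    blomberg_k,
    estimate_d,
    signal_table,
    simulate_bm,
    threshold_binarize,
    transform_d,
)


class TestBlombergK:
    def test_star_tree_k_is_one(self, star5):
        x = {"A": 0.3, "B": 1.2, "C": -0.5, "D": 2.2, "E": 0.1}
        res = blomberg_k(star5, x, n_perm=0)
        assert res.K == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_algebra_oracle(self, balanced4):
        # independent oracle: hand-enumerated V and explicit inversion
        x = np.array([1.0, 2.0, 7.0, 8.0])  # A,B clade vs C,D clade
        V = np.array(
            [
                [2.0, 1.0, 0.0, 0.0],
                [1.0, 2.0, 0.0, 0.0],
                [0.0, 0.0, 2.0, 1.0],
                [0.0, 0.0, 1.0, 2.0],
            ]
        )
        Vi = np.linalg.inv(V)
        ones = np.ones(4)
        a = (ones @ Vi @ x) / (ones @ Vi @ ones)
        mse0 = (x - a) @ (x - a) / 3
        mse = (x - a) @ Vi @ (x - a) / 3
        expected = (np.trace(V) - 4 / (ones @ Vi @ ones)) / 3
        k_oracle = (mse0 / mse) / expected

        res = blomberg_k(
            balanced4, dict(zip("ABCD", x)), n_perm=0
        )
        assert res.K == pytest.approx(k_oracle, abs=1e-9)
        assert res.K > 1  # clade-clumped trait is more conserved than BM

    def test_affine_invariance(self, tree64, rng):
        x = dict(zip(tree64.tip_labels, rng.normal(size=64)))
        k1 = blomberg_k(tree64, x, n_perm=0).K
        y = {k: 3.7 * v - 11.0 for k, v in x.items()}
        k2 = blomberg_k(tree64, y, n_perm=0).K
        assert k1 == pytest.approx(k2, abs=1e-9)

    def test_constant_trait_errors(self, star5):
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(star5, {l: 1.0 for l in star5.tip_labels}, n_perm=0)

    def test_permutation_p_is_reproducible(self, tree64, rng):
        x = dict(zip(tree64.tip_labels, rng.normal(size=64)))
        r1 = blomberg_k(tree64, x, n_perm=199, seed=5)
        r2 = blomberg_k(tree64, x, n_perm=199, seed=5)
        assert r1.p_perm == r2.p_perm
        assert r1.p_perm * 200 == int(round(r1.p_perm * 200))

    def test_bm_trait_detected_on_deep_tree(self, tree128):
        x = simulate_bm(tree128, seed=21)
        res = blomberg_k(tree128, x, n_perm=199, seed=22)
        assert res.p_perm < 0.05


class TestSimulateBM:
    def test_star_tree_tip_variance_matches_closed_form(self, star5):
        reps = np.array(
            [
                list(simulate_bm(star5, sigma2=1.0, seed=s).values.values())
                for s in range(2000)
            ]
        )
        v = reps.var(axis=0, ddof=1)
        assert np.all((0.9 < v) & (v < 1.1))

    def test_tip_covariance_converges_to_sigma2_vcv(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        labels = t.tip_labels
        reps = np.array(
            [
                [simulate_bm(t, sigma2=0.5, seed=s).values[l] for l in labels]
                for s in range(4000)
            ]
        )
        emp = np.cov(reps.T)
        expect = 0.5 * vcv_matrix(t).to_numpy()
        assert np.allclose(emp, expect, atol=0.08)

    def test_zero_length_branch_copies_value(self):
        t = parse_newick("((A:0,B:1):1,C:2);")
        x = simulate_bm(t, seed=3).values
        # A sits at the end of a zero-length branch from its parent; its
        # value equals the parent's, which is also on the path to B
        t2 = parse_newick("((A:0,B:0):1,C:2);")
        x2 = simulate_bm(t2, seed=3).values
        assert x2["A"] == x2["B"]

    def test_invalid_sigma2(self, star5):
        with pytest.raises(ValueError):
            simulate_bm(star5, sigma2=0.0)


class TestThresholdBinarize:
    def test_largest_values_become_ones(self):
        out = threshold_binarize({"A": 0.1, "B": 0.9, "C": 0.5}, 1)
        assert out.values == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_k_equals_n_minus_one(self):
        out = threshold_binarize({"A": 0.1, "B": 0.9, "C": 0.5}, 2)
        assert sum(out.values.values()) == 2
        assert out.values["A"] == 0.0

    def test_ties_break_by_label_order(self):
        out = threshold_binarize({"B": 1.0, "A": 1.0, "C": 1.0}, 2)
        assert out.values == {"A": 1.0, "B": 1.0, "C": 0.0}

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            threshold_binarize({"A": 1.0, "B": 2.0}, 2)


class TestEstimateD:
    def test_d_obs_hand_enumeration(self, balanced4):
        # nodal pass: est(AB)=1, est(CD)=0, root diff |1-0| => d_obs = 1
        x = {"A": 1, "B": 1, "C": 0, "D": 0}
        res = estimate_d(balanced4, x, n_sims=200, seed=1)
        assert res.d_obs == pytest.approx(1.0)
        x2 = {"A": 1, "B": 0, "C": 1, "D": 0}
        res2 = estimate_d(balanced4, x2, n_sims=200, seed=1)
        # |1-0| + |1-0| + |0.5-0.5| = 2
        assert res2.d_obs == pytest.approx(2.0)

    def test_transform_is_exact_complement(self, tree64):
        tr = syn.simulate_trait(tree64, "shuffle", prevalence=0.3, seed=2)
        res = estimate_d(tree64, tr, n_sims=50, seed=3)
        assert res.minus_d_plus_1 == -res.D + 1

    def test_single_state_errors(self, balanced4):
        with pytest.raises(ValueError, match="both states"):
            estimate_d(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1}, n_sims=5)

    def test_relabeling_states_flips_nothing(self, tree64):
        # 0<->1 swap at 50% prevalence: d is label-symmetric, so D matches
        tr = syn.simulate_trait(tree64, "threshold", prevalence=0.5, seed=4)
        flipped = TipTraitMap(
            {k: 1.0 - v for k, v in tr.values.items()}, kind="binary"
        )
        r1 = estimate_d(tree64, tr, n_sims=100, seed=9)
        r2 = estimate_d(tree64, flipped, n_sims=100, seed=9)
        assert r1.d_obs == pytest.approx(r2.d_obs, abs=1e-9)
        assert r1.D == pytest.approx(r2.D, abs=0.15)

    def test_bit_reproducible_given_seed(self, tree64):
        tr = syn.simulate_trait(tree64, "shuffle", prevalence=0.4, seed=5)
        r1 = estimate_d(tree64, tr, n_sims=100, seed=6)
        r2 = estimate_d(tree64, tr, n_sims=100, seed=6)
        assert r1 == r2

    def test_polytomy_tree_accepted(self):
        t = parse_newick("(A:1,B:1,C:1,(D:1,E:1):1);")
        res = estimate_d(t, {"A": 1, "B": 0, "C": 0, "D": 1, "E": 1}, n_sims=20, seed=7)
        assert np.isfinite(res.D)


class TestTransformD:
    @pytest.mark.parametrize("d,expected", [(1.0, 0.0), (0.0, 1.0), (-0.5, 1.5)])
    def test_values(self, d, expected):
        assert transform_d(d) == expected


class TestSignalTable:
    def test_empty_trait_list(self, tree64):
        table = signal_table(tree64, [])
        assert table.empty

    def test_p_value_resolution_follows_n_perm(self, tree64, rng):
        x = TipTraitMap(
            dict(zip(tree64.tip_labels, rng.normal(size=64))), name="x"
        )
        table = signal_table(tree64, [x], n_perm=1000, seed=3)
        p = table.p_value.iloc[0]
        assert round(p * 1001) == pytest.approx(p * 1001, abs=1e-9)

    def test_failing_trait_gets_error_row(self, tree64):
        const = TipTraitMap({l: 5.0 for l in tree64.tip_labels}, name="const")
        table = signal_table(tree64, [const], n_perm=9, seed=1)
        assert len(table) == 1
        assert table.note.iloc[0] != ""
        assert not table.significant.iloc[0]

    def test_bm_flagged_shuffle_not(self, tree128):
        # deterministic given the fixed seeds: a Brownian trait should be
        # called significant and a shuffled binary trait should not, in
        # nearly all of the seeded runs
        hits_bm, hits_null = 0, 0
        n_runs = 20
        for i in range(n_runs):
            bm = syn.simulate_trait(tree128, "bm", seed=100 + i, name="bm")
            shuf = syn.simulate_trait(
                tree128, "shuffle", prevalence=0.5, seed=200 + i, name="shuf"
            )
            table = signal_table(
                tree128, [bm, shuf], n_perm=99, alpha=0.05, seed=300 + i
            )
            row = table.set_index("trait")
            hits_bm += int(row.loc["bm", "significant"])
            hits_null += int(not row.loc["shuf", "significant"])
        assert hits_bm >= 19
        assert hits_null >= 17
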