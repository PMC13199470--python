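"""Sinkhorn divergence, retrieval, baselines, and significance testing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pdiff.expansion import (
    FeatureSet,
    baseline_fingerprint,
    baseline_profile,
    baseline_random,
    compare_distributions,
    divergence_matrix,
    percent_overlap,
    retrieve,
    retrieve_all,
    sinkhorn_divergence,
    standardize_feature_sets,
)

RNG = np.random.default_rng(12)


def fset(cid, points):
    return FeatureSet(cid, np.asarray(points, dtype=float))


def exact_ot_cost(x, y):
    """Brute-force optimal assignment over all n! matchings (uniform weights)."""
    n = len(x)
    cost = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    return min(
        sum(cost[i, p[i]] for i in range(n)) / n
        for p in itertools.permutations(range(n))
    )


class TestSinkhorn:
    def test_self_divergence_is_zero(self):
        a = fset("a", RNG.standard_normal((6, 3)))
        assert abs(sinkhorn_divergence(a, a, epsilon=0.05)) < 1e-6

    def test_symmetry(self):
        a = fset("a", RNG.standard_normal((5, 3)))
        b = fset("b", RNG.standard_normal((7, 3)))
        ab = sinkhorn_divergence(a, b, epsilon=0.1)
        ba = sinkhorn_divergence(b, a, epsilon=0.1)
        assert ab == pytest.approx(ba, abs=1e-8)

    def test_small_epsilon_matches_exhaustive_assignment(self):
        x = RNG.standard_normal((4, 2))
        y = RNG.standard_normal((4, 2)) + 0.5
        exact = exact_ot_cost(x, y)
        approx = sinkhorn_divergence(fset("a", x), fset("b", y),
                                     epsilon=1e-3, max_iter=20_000)
        assert approx == pytest.approx(exact, rel=0.01)

    def test_agrees_with_hungarian_oracle(self):
        from scipy.optimize import linear_sum_assignment

        x = RNG.standard_normal((5, 3))
        y = RNG.standard_normal((5, 3)) - 0.3
        cost = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
        r, c = linear_sum_assignment(cost)
        exact = cost[r, c].mean()
        approx = sinkhorn_divergence(fset("a", x), fset("b", y),
                                     epsilon=1e-3, max_iter=20_000)
        assert approx == pytest.approx(exact, rel=0.01)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            sinkhorn_divergence(fset("a", [[0.0, 1.0]]), fset("b", [[0.0]]))

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            sinkhorn_divergence(fset("a", [[0.0]]), fset("b", [[1.0]]), epsilon=0)

    def test_non_convergence_reports_residual(self):
        a = fset("a", RNG.standard_normal((8, 2)) * 10)
        b = fset("b", RNG.standard_normal((8, 2)) * 10 + 20)
        with pytest.raises(RuntimeError, match="residual"):
            sinkhorn_divergence(a, b, epsilon=1e-4, max_iter=0, tol=1e-15)


class TestRetrieve:
    def test_identical_candidate_ranks_first(self):
        pts = RNG.standard_normal((4, 2))
        query = fset("q", pts)
        cands = [fset("same", pts.copy())] + [
            fset(f"c{i}", RNG.standard_normal((4, 2)) + 3) for i in range(3)
        ]
        res = retrieve(query, cands, k=2, epsilon=0.05)
        assert res.neighbors[0] == "same"

    def test_k_equals_candidates_returns_all(self):
        cands = [fset(f"c{i}", RNG.standard_normal((3, 2))) for i in range(4)]
        res = retrieve(fset("q", RNG.standard_normal((3, 2))), cands, k=4, epsilon=0.1)
        assert sorted(res.neighbors) == [c.compound_id for c in cands]

    def test_order_matches_independently_computed_divergences(self):
        query = fset("q", RNG.standard_normal((4, 2)))
        cands = [fset(f"c{i}", RNG.standard_normal((4, 2)) * (1 + i / 2)) for i in range(5)]
        res = retrieve(query, cands, k=5, epsilon=0.05)
        divs = {c.compound_id: sinkhorn_divergence(query, c, epsilon=0.05) for c in cands}
        expected = sorted(divs, key=lambda cid: (divs[cid], cid))
        assert res.neighbors == expected

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            retrieve(fset("q", [[0.0]]), [fset("c", [[1.0]])], k=2)

    def test_batch_retrieval_matches_single(self):
        queries = [fset(f"q{i}", RNG.standard_normal((3, 2))) for i in range(3)]
        cands = [fset(f"c{i}", RNG.standard_normal((3, 2))) for i in range(6)]
        batch = retrieve_all(queries, cands, k=4, epsilon=0.1)
        for q, res in zip(queries, batch):
            assert res.neighbors == retrieve(q, cands, k=4, epsilon=0.1).neighbors


class TestPercentOverlap:
    def test_equal_sets_full_overlap(self):
        assert percent_overlap({"a", "b"}, {"b", "a"}) == 100.0

    def test_disjoint_sets_zero(self):
        assert percent_overlap({"a"}, {"b"}) == 0.0

    def test_seven_of_fifty(self):
        a = {f"x{i}" for i in range(50)}
        b = {f"x{i}" for i in range(7)} | {f"y{i}" for i in range(43)}
        assert percent_overlap(a, b) == 14.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            percent_overlap({"a"}, {"a", "b"})


class TestBaselines:
    def test_random_with_k_equal_n_is_always_full(self):
        out = baseline_random(10, 20, 20, seed=0)
        assert np.all(out == 100.0)

    def test_random_mean_matches_hypergeometric(self):
        n, k, q = 375, 50, 2000
        out = baseline_random(q, n, k, seed=1)
        expected = 100.0 * k / n  # mean overlap fraction = k/n
        se = out.std(ddof=1) / np.sqrt(q)
        assert out.mean() == pytest.approx(expected, abs=3 * se)

    def test_identical_fingerprint_ranks_first(self):
        fp = (RNG.random(32) < 0.3).astype(int)
        qs = {"q": fp}
        cands = {"hit": fp.copy(), "miss": 1 - fp}
        res = baseline_fingerprint(qs, cands, k=1)
        assert res[0].neighbors == ["hit"]

    def test_profile_cosine_hand_order(self):
        q = {"q": np.array([1.0, 0.0])}
        cands = {
            "a": np.array([2.0, 0.0]),     # cos 1.0
            "b": np.array([1.0, 1.0]),     # cos 0.707
            "c": np.array([0.0, 3.0]),     # cos 0.0
        }
        res = baseline_profile(q, cands, k=3)
        assert res[0].neighbors == ["a", "b", "c"]

    def test_orthogonal_profiles_fall_to_id_tiebreak(self):
        q = {"q": np.array([1.0, 0.0])}
        cands = {"z": np.array([0.0, 1.0]), "a": np.array([0.0, 2.0])}
        res = baseline_profile(q, cands, k=2)
        assert res[0].neighbors == ["a", "z"]

    def test_zero_norm_profile_excluded_with_warning(self):
        q = {"q": np.array([1.0, 0.0])}
        cands = {"ok": np.array([1.0, 1.0]), "bad": np.zeros(2)}
        with pytest.warns(UserWarning, match="zero-norm"):
            res = baseline_profile(q, cands, k=1)
        assert res[0].neighbors == ["ok"]


class TestCompareDistributions:
    def test_identical_samples_give_d_zero_p_one(self):
        x = np.linspace(0, 100, 20)
        out = compare_distributions({"a": x, "b": x.copy()})
        assert out.loc[0, "ks_D"] == 0.0
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_shifted_distributions_significant_after_bh(self):
        out = compare_distributions(
            {"lo": np.zeros(30), "hi": np.full(30, 100.0), "mid": np.full(30, 50.0)}
        )
        assert (out["p_adjusted"] < 0.05).all()

    def test_bh_adjustment_is_monotone_step_up(self):
        rng = np.random.default_rng(0)
        methods = {f"m{i}": rng.normal(i * 0.3, 1, 40) for i in range(4)}
        out = compare_distributions(methods).sort_values("p_value")
        assert (out["p_adjusted"].to_numpy() >= out["p_value"].to_numpy() - 1e-15).all()
        assert out["p_adjusted"].is_monotonic_increasing

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            compare_distributions({"a": np.zeros(3), "b": np.zeros(9)})


class TestStandardization:
    def test_self_divergence_zero_after_standardization(self):
        feats = pd.DataFrame(
            {
                "compound_id": ["a"] * 4 + ["b"] * 4,
                "coverage": RNG.random(8),
                "cell_count": RNG.integers(1, 20, 8).astype(float),
                "mean_cell_size": RNG.random(8) * 30,
            }
        )
        sets, _ = standardize_feature_sets(feats)
        for s in sets:
            assert abs(sinkhorn_divergence(s, s, epsilon=0.05)) < 1e-6

    def test_ranking_invariant_to_affine_feature_rescaling(self):
        rows = []
        for i in range(6):
            for _ in range(4):
                rows.append({"compound_id": f"c{i}",
                             "coverage": RNG.random(),
                             "cell_count": float(RNG.integers(1, 20)),
                             "mean_cell_size": RNG.random() * 30})
        feats = pd.DataFrame(rows)
        scaled = feats.copy()
        scaled["cell_count"] = scaled["cell_count"] * 1000 + 77  # affine rescale
        sets_a, _ = standardize_feature_sets(feats)
        sets_b, _ = standardize_feature_sets(scaled)
        ra = retrieve(sets_a[0], sets_a[1:], k=5, epsilon=0.05).neighbors
        rb = retrieve(sets_b[0], sets_b[1:], k=5, epsilon=0.05).neighbors
        assert ra == rb
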