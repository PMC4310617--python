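import numpy as np
import pandas as pd
import pytest

from promarch.association import (
    cluster_by_correlation,
    correlate,
    fit_predictor,
    partial_correlation,
    shuffle_null,
)


class TestCorrelate:
    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        res = correlate(x, x)
        assert res.r == pytest.approx(1.0)

    def test_independent_draws_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(correlate(x, y).r) < 0.05

    def test_t_and_df_formula(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        res = correlate(x, y)
        assert res.df == 198
        assert res.t == pytest.approx(res.r * np.sqrt(198 / (1 - res.r**2)))
        # agrees with scipy's own p-value
        from scipy.stats import pearsonr

        assert res.p == pytest.approx(pearsonr(x, y).pvalue, rel=1e-6)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, 500)
        y = rng.uniform(1, 10, 500)
        a = correlate(x, y, "spearman").r
        b = correlate(np.exp(x), y, "spearman").r
        assert a == pytest.approx(b)

    def test_constant_vector_flagged(self):
        res = correlate([1.0] * 10, list(range(10)))
        assert res.constant_input and np.isnan(res.r)

    def test_kendall_has_p_value(self, rng):
        x = rng.normal(size=50)
        res = correlate(x, x + rng.normal(size=50), "kendall")
        assert -1 <= res.r <= 1 and 0 <= res.p <= 1


class TestPartialCorrelation:
    def test_empty_controls_equals_plain_spearman(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        assert partial_correlation(df, "a", "b") == pytest.approx(
            correlate(df["a"], df["b"], "spearman").r, abs=1e-10
        )

    def test_chain_attenuates_through_mediator(self, rng):
        # X -> M -> Y: controlling for M should kill the X~Y correlation
        n = 4000
        x = rng.normal(size=n)
        m = x + 0.5 * rng.normal(size=n)
        y = m + 0.5 * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        raw = correlate(x, y, "spearman").r
        part = partial_correlation(df, "x", "y", ["m"])
        assert raw > 0.5
        assert abs(part) < 0.1

    def test_symmetric_in_primary_arguments(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        assert partial_correlation(df, "a", "b", ["c"]) == pytest.approx(
            partial_correlation(df, "b", "a", ["c"])
        )

    def test_singular_matrix_names_collinear_columns(self, rng):
        a = rng.normal(size=100)
        df = pd.DataFrame({"a": a, "b": 2 * a, "y": rng.normal(size=100)})
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(df, "y", "a", ["b"])


class TestShuffleNull:
    def test_replicates_centered_at_zero(self, rng):
        x = rng.normal(size=500)
        y = 0.3 * x + rng.normal(size=500)
        nd = shuffle_null(x, y, n_reps=400, seed=1)
        se = nd.replicates.std() / np.sqrt(nd.n_reps)
        assert abs(nd.replicates.mean()) < 3 * se + 0.05

    def test_planted_coupling_attains_minimum_p(self, rng):
        x = np.arange(500.0)
        y = x + rng.normal(size=500)
        nd = shuffle_null(x, y, n_reps=199, seed=2)
        assert nd.empirical_p == pytest.approx(1 / 200)

    def test_identical_seed_identical_replicates(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        a = shuffle_null(x, y, n_reps=50, seed=9)
        b = shuffle_null(x, y, n_reps=50, seed=9)
        assert np.array_equal(a.replicates, b.replicates)

    def test_null_p_roughly_uniform(self, rng):
        # calibration: under independence the empirical p over many datasets
        # should be close to uniform
        ps = []
        for s in range(60):
            r = np.random.default_rng(s)
            x = r.normal(size=150)
            y = r.normal(size=150)
            ps.append(shuffle_null(x, y, n_reps=99, seed=s).empirical_p)
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.1).mean() < 0.25


class TestClustering:
    def test_duplicated_columns_merge_first(self, rng):
        a = rng.normal(size=100)
        df = pd.DataFrame({"a1": a, "a2": a, "b": rng.normal(size=100)})
        res = cluster_by_correlation(df)
        first = res.linkage[0]
        merged = {res.labels[int(first[0])], res.labels[int(first[1])]}
        assert merged == {"a1", "a2"} and first[2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_blocks_recovered(self, rng):
        n = 400
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        cols = {}
        for i in range(3):
            cols[f"x{i}"] = f1 + 0.3 * rng.normal(size=n)
            cols[f"y{i}"] = f2 + 0.3 * rng.normal(size=n)
        res = cluster_by_correlation(pd.DataFrame(cols))
        order = list(res.leaf_order)
        xpos = sorted(order.index(f"x{i}") for i in range(3))
        ypos = sorted(order.index(f"y{i}") for i in range(3))
        assert xpos[-1] - xpos[0] == 2 and ypos[-1] - ypos[0] == 2  # contiguous blocks

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        res = cluster_by_correlation(df)
        d = res.distance.to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
        with pytest.raises(ValueError, match="constant"):
            cluster_by_correlation(df)

    def test_newick_has_all_leaves(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        nwk = cluster_by_correlation(df).to_newick()
        assert nwk.endswith(";") and all(c in nwk for c in "abcde")


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(77)
    n = 2000
    X = rng.poisson(2.0, size=(n, 25)).astype(float)
    y = 1 / (1 + np.exp(-(X[:, :6].sum(axis=1) - 12) / 3)) + rng.normal(0, 0.08, n)
    return pd.DataFrame(X, columns=[f"tf{i}" for i in range(25)]), np.clip(y, 0, 1)


class TestPredictor:
    def test_controls(self, planted):
        X, y = planted
        rep = fit_predictor(X, y, split_seed=11)
        assert rep.r_retained > 0.9
        assert abs(rep.r_scrambled) < 0.1
        assert rep.r_prediction > 0.3

    def test_invariant_to_feature_column_order(self, planted):
        X, y = planted
        a = fit_predictor(X, y, split_seed=3)
        b = fit_predictor(X[list(reversed(X.columns))], y, split_seed=3)
        assert a.r_prediction == pytest.approx(b.r_prediction, abs=1e-9)

    def test_interactions_beat_simple_correlation(self):
        # when breadth is a nonlinear interactive function of several TF
        # columns the kernel machine must beat the count-sum correlation
        rng = np.random.default_rng(5)
        X = rng.poisson(3, size=(2500, 8)).astype(float)
        y = np.tanh(0.5 * X[:, 0] * X[:, 1] - 0.3 * X[:, 2] ** 2 + X[:, 3]) + rng.normal(0, 0.2, 2500)
        rep = fit_predictor(pd.DataFrame(X), y, split_seed=4)
        assert rep.r_prediction > abs(correlate(X.sum(axis=1), y).r) + 0.2

    def test_binary_mode_auc(self, planted):
        X, y = planted
        rep = fit_predictor(X, y, mode="binary", split_seed=6)
        assert rep.auc is not None and rep.auc > 0.7
        assert rep.r_retained > 0.95

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_predictor(np.zeros((40, 3)), np.zeros(40))
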