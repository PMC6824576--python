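import numpy as np
import pytest

from immunonoise import (
    anomaly_corroboration,
    log_likelihood_distance,
    predictor_importance,
    two_step_cluster,
)
from immunonoise.entropy import EntropyReport

from _oracles import log_likelihood_distance_direct


def _entropy_report(parameters, flags):
    parameters = tuple(parameters)
    return EntropyReport(
        parameters=parameters, n_distinct=(1,) * len(parameters), S=10,
        H=(0.0,) * len(parameters), H_squared=(0.0,) * len(parameters),
        H_max=1.0, H_max_squared=1.0, threshold=3.0, flags=tuple(flags))


def test_distance_worked_one_dimensional_example():
    """A={0,1}, B={10,11}: global population variance 25.25, within-cluster
    variances 0.25, so d = 2*(ln 50.5 - ln 25.5)."""
    d = log_likelihood_distance([0.0, 1.0], [10.0, 11.0], [25.25])
    assert d == pytest.approx(2 * (np.log(50.5) - np.log(25.5)), abs=1e-12)
    assert d == pytest.approx(1.3669, abs=5e-3)
    assert d == pytest.approx(
        log_likelihood_distance_direct([0, 1], [10, 11]), abs=1e-12)


def test_distance_identical_singletons_is_zero():
    assert log_likelihood_distance([3.0], [3.0], [4.0]) == pytest.approx(0.0)


def test_distance_symmetric_nonnegative_randomized():
    """Randomized 1-3-D merges: d(A,B) = d(B,A) >= 0, matching the direct
    formula oracle."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        d_dim = rng.integers(1, 4)
        na, nb = rng.integers(1, 8, size=2)
        a = rng.normal(size=(na, d_dim))
        b = rng.normal(loc=rng.normal(), size=(nb, d_dim))
        g = np.vstack([a, b]).var(axis=0)
        if np.any(g <= 0):
            continue
        d_ab = log_likelihood_distance(a, b, g)
        d_ba = log_likelihood_distance(b, a, g)
        assert d_ab == pytest.approx(d_ba, abs=1e-10)
        assert d_ab >= -1e-9


def test_distance_rejects_bad_inputs():
    with pytest.raises(ValueError):
        log_likelihood_distance(np.empty((0, 1)), [[1.0]], [1.0])
    with pytest.raises(ValueError):
        log_likelihood_distance([1.0], [2.0], [0.0])


def test_two_blobs_recovered_exactly_every_seed():
    """Two 10-SD-separated Gaussian blobs: the two-step assignment matches
    the generating labels perfectly for 20/20 seeds."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(50, 2))
        b = rng.normal(10.0, 1.0, size=(50, 2))
        x = np.vstack([a, b])
        truth = np.array([0] * 50 + [1] * 50)
        res = two_step_cluster(x, n_preclusters=20, k=2, seed=seed)
        assert not res.degenerate
        # adjusted Rand = 1 <=> the partition is identical up to labels
        same = res.labels[truth == 0]
        other = res.labels[truth == 1]
        assert len(set(same)) == 1 and len(set(other)) == 1
        assert same[0] != other[0]


def test_identical_points_degenerate_split_flagged():
    x = np.ones((30, 3))
    res = two_step_cluster(x, k=2, seed=0)
    assert res.degenerate
    assert res.n_clusters == 1
    assert set(res.labels) == {1}


def test_clustering_seeded_determinism_and_column_order_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(80, 4))
    x[:40] += 4.0
    a = two_step_cluster(x, seed=3)
    b = two_step_cluster(x, seed=3)
    np.testing.assert_array_equal(a.labels, b.labels)
    c = two_step_cluster(x[:, ::-1], seed=3)
    np.testing.assert_array_equal(a.labels, c.labels)


def test_cluster_ids_ordered_by_size():
    rng = np.random.default_rng(2)
    x = np.vstack([rng.normal(0, 1, size=(70, 1)),
                   rng.normal(12, 1, size=(30, 1))])
    res = two_step_cluster(x, seed=0)
    # label 1 = the larger cluster
    assert (res.labels == 1).sum() == 70


def test_importance_trivial_cases():
    rng = np.random.default_rng(3)
    n = 60
    labels = np.array([1] * 30 + [2] * 30)
    sep = np.concatenate([rng.normal(0, 1, 30), rng.normal(8, 1, 30)])
    flat = np.full(n, 2.5)
    noise = rng.normal(size=n)
    rep = predictor_importance(np.column_stack([sep, flat, noise]),
                               labels, ["sep", "flat", "noise"])
    imp = dict(zip(rep.parameters, rep.importance))
    assert imp["sep"] == 1.0
    assert imp["flat"] == 0.0
    assert imp["noise"] < 0.2
    assert rep.rank[0] == 1
    assert np.all((rep.importance >= 0) & (rep.importance <= 1))


def test_importance_requires_two_nontrivial_clusters():
    x = np.random.default_rng(4).normal(size=(10, 2))
    with pytest.raises(ValueError, match="2 clusters"):
        predictor_importance(x, np.ones(10, dtype=int))
    with pytest.raises(ValueError, match="single member"):
        predictor_importance(x, np.array([1] * 9 + [2]))


def test_corroboration_set_logic():
    imp_matrix = np.column_stack([
        np.concatenate([np.zeros(20), np.ones(20) * 6]),  # separates: high
        np.random.default_rng(5).normal(size=40),          # noise: low
        np.concatenate([np.zeros(20), np.ones(20) * 5]),  # separates: high
    ])
    labels = np.array([1] * 20 + [2] * 20)
    imp = predictor_importance(imp_matrix, labels, ["a", "b", "c"])

    # empty entropy flags -> empty corroborated set
    assert anomaly_corroboration(_entropy_report(["a", "b", "c"], []), imp) == set()
    # the noisy low-importance parameter is corroborated when flagged
    got = anomaly_corroboration(_entropy_report(["a", "b", "c"], ["b", "c"]), imp)
    assert got == {"b"}
    with pytest.raises(ValueError, match="share no parameters"):
        anomaly_corroboration(_entropy_report(["x"], ["x"]), imp)


def test_corroboration_reproduces_published_profile_selection():
    """On the published 17-parameter importance profile (anomalous five at
    0.00-0.05, the rest 0.09-1.00) both the absolute-cutoff and the
    lowest-third routes combined with the published entropy flags select
    exactly the five reported anomaly parameters."""
    params = ("adhesion", "chemotaxis", "CD4_pct", "CD8_pct",
              "CD4_CD8_ratio", "CD20_pct", "IL1", "IFNg",
              "IgG_Aa_SUNY67", "IgG_Aa_Y4", "IgG_Aa_ATCC29523",
              "IgG_Fn_ATCC25586", "IgG_Td_ATCC35405", "IgG_Pi_ATCC25611",
              "IgG_Pn_ATCC33563", "IgG_Co_S3", "IgG_Ec_ATCC23834")
    importance = np.array([0.09, 0.05, 0.02, 0.00, 0.03, 0.02, 0.46, 0.50,
                           1.00, 0.38, 0.04, 0.67, 0.60, 0.70, 0.52, 0.60,
                           0.24])
    flags = ("chemotaxis", "CD4_pct", "CD8_pct", "CD20_pct",
             "IgG_Aa_ATCC29523")
    order = np.lexsort((np.arange(17), -importance))
    rank = np.empty(17, dtype=int)
    rank[order] = np.arange(1, 18)
    from immunonoise.twostep import ClusterImportanceReport

    imp = ClusterImportanceReport(
        parameters=params, importance=importance, rank=rank,
        p_values=np.ones(17), labels=np.ones(2, dtype=int))
    ent = _entropy_report(params, flags)
    assert anomaly_corroboration(ent, imp, importance_cutoff=0.05,
                                 low_fraction=0.0) == set(flags)
    assert anomaly_corroboration(ent, imp, importance_cutoff=0.0,
                                 low_fraction=1 / 3) == set(flags)
    assert anomaly_corroboration(ent, imp) == set(flags)
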