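import numpy as np
import pytest

from mldp.data_model import CohortError, imbalance_ratio
from mldp.prep_ops import (apply_borderline_smote, apply_random_oversample,
                           apply_random_undersample, apply_smote,
                           apply_tomek_links, fit_apply_isolation_forest,
                           fit_pca, fit_pipeline, fit_sfs_r2,
                           isolation_forest_scores, tomek_links)
from mldp.pipeline_space import Pipeline

from conftest import make_cohort

# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_single_feature_r2(x, y):
    """R^2 of OLS y ~ 1 + x, computed from the closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = (xc @ xc) * (yc @ yc)
    if denom < 1e-30:
        return 0.0
    return float((xc @ yc) ** 2 / denom)


def oracle_r2(X, y):
    """R^2 of OLS y ~ 1 + X via lstsq."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    yc = y - y.mean()
    return float(1.0 - (resid @ resid) / (yc @ yc))


def oracle_tomek_links(X, y):
    """O(n^2) mutual-nearest-neighbor enumeration on z-scored features."""
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd
    n = len(y)
    D = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(1)
    return {(min(a, b), max(a, b))
            for a in range(n)
            for b in [int(nn[a])]
            if nn[b] == a and y[a] != y[b]}


# ---------------------------------------------------------------------------
# isolation forest


def test_isolation_forest_removes_planted_extreme(rng):
    X = np.vstack([rng.normal(0, 1, (50, 2)), [[100.0, 100.0]]])
    y = np.array([0, 1] * 25 + [1])
    c = make_cohort(X, y)
    scores = isolation_forest_scores(c, seed=0)
    assert int(np.argmax(scores)) == 50  # planted point tops the ranking
    assert scores[50] > 0.6
    # a threshold between the top-2 scores removes exactly the planted point
    thr = float(np.sort(scores)[-2]) + 1e-9
    out, step = fit_apply_isolation_forest(c, score_threshold=thr, seed=0)
    assert out.n_samples == 50
    assert "s50" not in out.sample_ids


def test_isolation_forest_threshold_one_removes_nothing(gaussian_cohort):
    out, _ = fit_apply_isolation_forest(gaussian_cohort, score_threshold=1.0)
    assert out.n_samples == gaussian_cohort.n_samples


def test_isolation_forest_output_is_row_subset(imbalanced_cohort):
    out, _ = fit_apply_isolation_forest(imbalanced_cohort, score_threshold=0.55)
    kept = [imbalanced_cohort.sample_ids.index(s) for s in out.sample_ids]
    assert np.array_equal(out.X, imbalanced_cohort.X[kept])
    assert np.array_equal(out.y, imbalanced_cohort.y[kept])


def test_isolation_forest_too_few_samples():
    c = make_cohort(np.arange(10, dtype=float).reshape(5, 2), [0, 1, 0, 1, 0])
    with pytest.raises(CohortError):
        fit_apply_isolation_forest(c)


def test_isolation_forest_never_empties_a_class(rng):
    # lone minority point far away would be flagged; the guard keeps it
    X = np.vstack([rng.normal(0, 1, (20, 2)), [[50.0, 50.0]]])
    y = np.array([0] * 20 + [1])
    with pytest.warns(UserWarning):
        out, _ = fit_apply_isolation_forest(make_cohort(X, y),
                                            score_threshold=0.6, seed=1)
    assert out.y.sum() == 1


# ---------------------------------------------------------------------------
# SFS


def test_sfs_perfect_predictor_selected_first(rng):
    X = rng.normal(0, 1, (30, 11))
    y = (X[:, 3] > 0).astype(int)
    X[:, 3] = y  # feature 3 equals the label exactly
    c = make_cohort(X, y)
    out, step = fit_sfs_r2(c, n_keep=3)
    assert step.state["selected"][0] == 3
    assert step.state["r2_trace"][0] == pytest.approx(1.0, abs=1e-10)


def test_sfs_first_pick_matches_bruteforce_argmax(rng):
    X = rng.normal(0, 1, (40, 8))
    y = (X[:, 2] + 0.5 * X[:, 5] + rng.normal(0, 0.5, 40) > 0).astype(int)
    c = make_cohort(X, y)
    _, step = fit_sfs_r2(c, n_keep=1)
    r2s = [oracle_single_feature_r2(X[:, j], y) for j in range(8)]
    assert step.state["selected"][0] == int(np.argmax(r2s))
    assert step.state["r2_trace"][0] == pytest.approx(max(r2s), abs=1e-10)


def test_sfs_greedy_trace_matches_bruteforce(rng):
    X = rng.normal(0, 1, (50, 5))
    y = (X[:, 0] - X[:, 4] + rng.normal(0, 0.8, 50) > 0).astype(int)
    c = make_cohort(X, y)
    _, step = fit_sfs_r2(c, n_keep=2, tol=0.0)
    # greedy oracle: best single feature, then best partner given it
    first = int(np.argmax([oracle_single_feature_r2(X[:, j], y) for j in range(5)]))
    pairs = {j: oracle_r2(X[:, [first, j]], y.astype(float))
             for j in range(5) if j != first}
    second = max(pairs, key=pairs.get)
    assert step.state["selected"] == [first, second]
    assert step.state["r2_trace"][1] == pytest.approx(pairs[second], abs=1e-8)


def test_sfs_n_keep_zero_rejected(gaussian_cohort):
    with pytest.raises(ValueError):
        fit_sfs_r2(gaussian_cohort, n_keep=0)


def test_sfs_constant_features_skipped(rng):
    X = np.column_stack([np.full(20, 3.0), rng.normal(0, 1, 20)])
    y = (X[:, 1] > 0).astype(int)
    _, step = fit_sfs_r2(make_cohort(X, y), n_keep=2)
    assert 0 not in step.state["selected"]


def test_sfs_all_constant_errors():
    X = np.ones((10, 3))
    with pytest.raises(CohortError):
        fit_sfs_r2(make_cohort(X, [0, 1] * 5), n_keep=1)


def test_sfs_transform_is_column_subset(gaussian_cohort):
    out, step = fit_sfs_r2(gaussian_cohort, n_keep=1)
    again = step.transform(gaussian_cohort)
    assert np.allclose(out.X, again.X, atol=1e-10)
    assert again.feature_names == out.feature_names


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_case():
    x = np.linspace(0, 1, 12)
    X = np.column_stack([x, 2 * x])  # perfectly correlated
    c = make_cohort(X, [0, 1] * 6)
    out, step = fit_pca(c, variance_retained=0.9)
    assert out.n_features == 1


def test_pca_full_variance_keeps_rank(rng):
    X = rng.normal(0, 1, (20, 4))
    X[:, 3] = X[:, 0] + X[:, 1]  # rank 3 after centering
    c = make_cohort(X, [0, 1] * 10)
    out, _ = fit_pca(c, variance_retained=1.0)
    centered = X - X.mean(0)
    assert out.n_features == np.linalg.matrix_rank(centered)


def test_pca_eigenvalues_match_dense_oracle(rng):
    X = rng.normal(0, 1, (25, 3))
    c = make_cohort(X, [0, 1] * 12 + [0])
    _, step = fit_pca(c, variance_retained=1.0)
    cov = np.cov(X, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    got = np.sort(step.state["explained_variance"])[::-1]
    assert np.allclose(got, eig[: len(got)], atol=1e-10)


def test_pca_bad_fraction_rejected(gaussian_cohort):
    with pytest.raises(ValueError):
        fit_pca(gaussian_cohort, variance_retained=1.5)


def test_pca_transform_reproduces_fit(gaussian_cohort):
    out, step = fit_pca(gaussian_cohort, variance_retained=0.95)
    again = step.transform(gaussian_cohort)
    assert np.allclose(out.X, again.X, atol=1e-10)


# ---------------------------------------------------------------------------
# resampling


def _counts(c):
    n1 = int(c.y.sum())
    return n1, c.n_samples - n1


def test_random_oversample_reaches_parity():
    X = np.arange(20, dtype=float).reshape(10, 2)
    c = make_cohort(X, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    out, _ = apply_random_oversample(c, target_ratio=1.0, seed=0)
    assert _counts(out) == (8, 8)
    # every duplicate equals an existing minority row
    for i in range(10, out.n_samples):
        assert any(np.array_equal(out.X[i], c.X[j]) for j in (0, 1))
        assert out.y[i] == 1


def test_random_oversample_bit_reproducible(imbalanced_cohort):
    a, _ = apply_random_oversample(imbalanced_cohort, seed=7)
    b, _ = apply_random_oversample(imbalanced_cohort, seed=7)
    assert a.sample_ids == b.sample_ids
    assert np.array_equal(a.X, b.X)


def test_random_oversample_noop_warns(gaussian_cohort):
    with pytest.warns(UserWarning):
        out, _ = apply_random_oversample(gaussian_cohort, target_ratio=1.0)
    assert out.n_samples == gaussian_cohort.n_samples


def test_random_undersample_reaches_parity():
    X = np.arange(20, dtype=float).reshape(10, 2)
    c = make_cohort(X, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    out, _ = apply_random_undersample(c, target_ratio=1.0, seed=0)
    assert _counts(out) == (2, 2)
    # outputs are a row subset and minority rows untouched
    assert set(out.sample_ids) <= set(c.sample_ids)
    assert {"s0", "s1"} <= set(out.sample_ids)


def test_smote_synthetic_points_on_segment():
    X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, 10 - i] for i in range(8)])
    y = np.array([1, 1] + [0] * 8)
    out, _ = apply_smote(make_cohort(X, y), k_neighbors=1, target_ratio=1.0, seed=3)
    new = out.X[10:]
    assert len(new) == 6
    for p in new:
        assert p[0] == pytest.approx(p[1], abs=1e-12)  # on the (t, t) segment
        assert -1e-12 <= p[0] <= 1 + 1e-12


def test_smote_row_accounting_3_to_9():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (12, 2))
    y = np.array([1, 1, 1] + [0] * 9)
    out, _ = apply_smote(make_cohort(X, y), k_neighbors=2, target_ratio=1.0, seed=0)
    assert out.n_samples == 18  # 6 synthetic rows added
    assert _counts(out) == (9, 9)


def test_smote_minority_too_small():
    X = np.arange(8, dtype=float).reshape(4, 2)
    with pytest.raises(CohortError):
        apply_smote(make_cohort(X, [1, 0, 0, 0]), seed=0)


def test_smote_hull_property(rng):
    X = np.vstack([rng.normal(0, 1, (5, 1)), rng.normal(10, 1, (15, 1))])
    y = np.array([1] * 5 + [0] * 15)
    out, _ = apply_smote(make_cohort(X, y), k_neighbors=3, seed=5)
    lo, hi = X[:5].min(), X[:5].max()
    new = out.X[20:]
    assert np.all(new >= lo - 1e-12) and np.all(new <= hi + 1e-12)


def test_bsmote_separated_classes_noop(gaussian_cohort):
    # make it imbalanced but fully separated: danger set empty
    c = gaussian_cohort.subset_samples(list(range(20)) + list(range(20, 28)))
    with pytest.warns(UserWarning):
        out, step = apply_borderline_smote(c, seed=0)
    assert out.n_samples == c.n_samples
    assert step.state["danger_ids"] == []


def test_bsmote_danger_membership_matches_bruteforce(rng):
    x0 = rng.normal(0.0, 1.0, 30)
    x1 = rng.normal(1.0, 1.0, 10)
    X = np.concatenate([x0, x1])[:, None]
    y = np.array([0] * 30 + [1] * 10)
    c = make_cohort(X, y)
    m = 7
    _, step = apply_borderline_smote(c, k_neighbors=3, m_danger_neighbors=m,
                                     target_ratio=1.0, seed=0)
    # brute-force m-NN majority counts on z-scored values
    z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
    expected = []
    for i in range(30, 40):
        d = np.abs(z - z[i])
        d[i] = np.inf
        nbr = np.argsort(d)[:m]
        cnt = int((y[nbr] == 0).sum())
        if m / 2.0 <= cnt < m:
            expected.append(c.sample_ids[i])
    assert sorted(step.state["danger_ids"]) == sorted(expected)


def test_bsmote_pure_noise_point_not_a_seed(rng):
    # one minority point deep inside the majority cloud, the rest far away
    X = np.vstack([rng.normal(0, 0.3, (12, 2)), [[0.0, 0.0]],
                   rng.normal(8, 0.3, (5, 2))])
    y = np.array([0] * 12 + [1] * 6)
    c = make_cohort(X, y)
    _, step = apply_borderline_smote(c, k_neighbors=2, m_danger_neighbors=5,
                                     target_ratio=1.0, seed=0)
    assert c.sample_ids[12] not in step.state["danger_ids"]


def test_tomek_1d_example():
    X = np.array([[0.0], [0.1], [5.0]])
    y = np.array([1, 0, 0])
    c = make_cohort(X, y)
    assert tomek_links(c) == [(0, 1)]
    out, _ = apply_tomek_links(c)
    assert out.n_samples == 2
    assert "s1" not in out.sample_ids  # the majority member was removed


def test_tomek_separated_classes_identity(gaussian_cohort):
    out, _ = apply_tomek_links(gaussian_cohort)
    assert out.sample_ids == gaussian_cohort.sample_ids


@pytest.mark.parametrize("seed", range(5))
def test_tomek_matches_bruteforce_on_random_cohorts(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (20, 3))
    y = (rng.random(20) < 0.4).astype(int)
    if 0 < y.sum() < 20:
        c = make_cohort(X, y)
        assert set(tomek_links(c)) == oracle_tomek_links(X, y)


# ---------------------------------------------------------------------------
# cross-cutting properties


@pytest.mark.parametrize("op,kwargs", [
    (apply_smote, {"k_neighbors": 3}),
    (apply_borderline_smote, {"k_neighbors": 3, "m_danger_neighbors": 5}),
    (apply_random_oversample, {}),
    (apply_random_undersample, {}),
])
def test_seeded_operators_bit_reproducible(imbalanced_cohort, op, kwargs):
    a, _ = op(imbalanced_cohort, target_ratio=1.0, seed=11, **kwargs)
    b, _ = op(imbalanced_cohort, target_ratio=1.0, seed=11, **kwargs)
    assert a.sample_ids == b.sample_ids
    assert np.array_equal(a.X, b.X)


@pytest.mark.parametrize("op", [apply_smote, apply_random_oversample])
def test_oversampling_to_parity_yields_50_50(imbalanced_cohort, op):
    out, _ = op(imbalanced_cohort, target_ratio=1.0, seed=2)
    assert str(imbalance_ratio(out)) == "50-vs-50"


def test_sample_space_ops_preserve_retained_rows(imbalanced_cohort):
    out, _ = apply_smote(imbalanced_cohort, target_ratio=1.0, seed=0)
    n = imbalanced_cohort.n_samples
    assert np.array_equal(out.X[:n], imbalanced_cohort.X)


def test_sample_space_step_refuses_transform(imbalanced_cohort):
    _, step = apply_smote(imbalanced_cohort, target_ratio=1.0, seed=0)
    with pytest.raises(RuntimeError):
        step.transform(imbalanced_cohort)


def test_fit_pipeline_partitions_scopes(imbalanced_cohort):
    pl = Pipeline.from_methods(["SFS", "SMOTE"], {"SFS": {"n_keep": 2}})
    prepared, fitted = fit_pipeline(imbalanced_cohort, pl, seed=0)
    assert [s.scope for s in fitted.steps] == ["feature_space", "sample_space"]
    val = fitted.transform_validation(imbalanced_cohort)
    assert val.n_samples == imbalanced_cohort.n_samples
    assert val.n_features == 2
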