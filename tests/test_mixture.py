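"""EM machinery: E/M steps against hand oracles, monotonicity, BIC,
model selection, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

import psaphen as pp
from psaphen.mixture import split_encoded


def _cont_frame(values):
    return pd.DataFrame({"x": np.asarray(values, dtype=float)})


def _params_1d(weights, means, variances):
    K = len(weights)
    return pp.MixtureParams(
        weights=np.asarray(weights, float),
        means=np.asarray(means, float).reshape(K, 1),
        variances=np.asarray(variances, float).reshape(K, 1),
        category_probs=[],
        continuous_names=["x"],
    )


# -- E step -----------------------------------------------------------------


def test_e_step_single_component_responsibilities_are_one():
    resp, _ = pp.e_step(_cont_frame([0.0, 1.0, 5.0]), _params_1d([1.0], [0.0], [1.0]))
    assert np.allclose(resp, 1.0)


def test_e_step_symmetric_equidistant_point_splits_evenly():
    params = _params_1d([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0])
    resp, _ = pp.e_step(_cont_frame([0.0]), params)
    assert np.allclose(resp, [[0.5, 0.5]])


def test_e_step_matches_bayes_rule_hand_computation():
    """One row, two Gaussian components: responsibilities and total
    log-likelihood recomputed from scipy.stats.norm directly."""
    pi, mu, var, x = np.array([0.3, 0.7]), np.array([0.0, 4.0]), np.array([1.0, 2.0]), 1.0
    dens = pi * norm.pdf(x, mu, np.sqrt(var))
    expected_resp = dens / dens.sum()
    resp, ll = pp.e_step(_cont_frame([x]), _params_1d(pi, mu, var))
    assert np.allclose(resp[0], expected_resp, atol=1e-12)
    assert ll == pytest.approx(np.log(dens.sum()))


def test_e_step_rejects_invalid_params():
    with pytest.raises(ValueError, match="sum to 1"):
        pp.e_step(_cont_frame([0.0]), _params_1d([0.6, 0.6], [0, 1], [1, 1]))


# -- M step -----------------------------------------------------------------


def _mixed_toy():
    return pd.DataFrame(
        {
            "x": [0.0, 1.0, 2.0, 10.0, 12.0],
            "c": pd.Categorical(["a", "b", "a", "b", "b"], categories=["a", "b", "c"]),
        }
    )


def test_m_step_single_component_equals_sample_statistics():
    X = _mixed_toy()
    resp = np.ones((5, 1))
    params = pp.m_step(X, resp, alpha=0.0)
    assert params.weights[0] == pytest.approx(1.0)
    assert params.means[0, 0] == pytest.approx(X["x"].mean())
    assert params.variances[0, 0] == pytest.approx(X["x"].var(ddof=0))
    assert np.allclose(params.category_probs[0][0], [2 / 5, 3 / 5, 0.0])


def test_m_step_hard_partition_gives_per_group_statistics():
    X = _cont_frame([0.0, 2.0, 10.0, 14.0])
    resp = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    params = pp.m_step(X, resp, alpha=0.0)
    assert np.allclose(params.weights, [0.5, 0.5])
    assert np.allclose(params.means[:, 0], [1.0, 12.0])
    assert np.allclose(params.variances[:, 0], [1.0, 4.0])


def test_m_step_matches_brute_force_weighted_moments():
    X = _mixed_toy()
    rng = np.random.default_rng(4)
    resp = rng.dirichlet(np.ones(2), size=5)
    params = pp.m_step(X, resp, alpha=0.0)
    x = X["x"].to_numpy()
    for k in range(2):
        w = resp[:, k]
        mean_k = (w * x).sum() / w.sum()
        var_k = (w * (x - mean_k) ** 2).sum() / w.sum()
        assert params.means[k, 0] == pytest.approx(mean_k)
        assert params.variances[k, 0] == pytest.approx(var_k)
        for lvl_idx, lvl in enumerate(["a", "b", "c"]):
            freq = w[(X["c"] == lvl).to_numpy()].sum() / w.sum()
            assert params.category_probs[0][k, lvl_idx] == pytest.approx(freq)


def test_m_step_rejects_unnormalized_responsibilities():
    with pytest.raises(ValueError, match="sum to 1"):
        pp.m_step(_cont_frame([0.0, 1.0]), np.array([[0.5, 0.2], [1.0, 0.0]]))


# -- fitting ----------------------------------------------------------------


def test_two_gaussian_groups_recovered():
    rng = np.random.default_rng(0)
    x = np.r_[rng.normal(0, 1, 100), rng.normal(10, 1, 100)]
    X = _cont_frame(x)
    fit = pp.MixedMixture(n_components=2, n_restarts=5, random_state=0).fit(X)
    order = np.argsort(fit.means_[:, 0])
    assert abs(fit.means_[order[0], 0] - x[:100].mean()) < 0.5
    assert abs(fit.means_[order[1], 0] - x[100:].mean()) < 0.5
    assert np.allclose(np.sort(fit.weights_), [0.5, 0.5], atol=0.05)


def test_k1_fit_equals_closed_form_maximum():
    X = _mixed_toy()
    fit = pp.MixedMixture(n_components=1, alpha=0.0, n_restarts=1, random_state=0).fit(X)
    assert fit.converged_
    assert fit.means_[0, 0] == pytest.approx(X["x"].mean(), abs=1e-10)
    assert fit.variances_[0, 0] == pytest.approx(X["x"].var(ddof=0), abs=1e-10)
    assert np.allclose(fit.category_probs_[0][0], [0.4, 0.6, 0.0], atol=1e-10)
    # once at the maximum, the trace is flat
    assert np.allclose(np.diff(fit.loglik_trace_), 0.0, atol=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 3))
def test_em_loglikelihood_trace_is_nondecreasing(seed, k):
    rng = np.random.default_rng(seed)
    n = 40
    X = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "y": rng.normal(2, 3, size=n),
            "c": pd.Categorical(rng.choice(["a", "b"], size=n), categories=["a", "b"]),
        }
    )
    fit = pp.MixedMixture(n_components=k, n_restarts=2, max_iter=60,
                          random_state=seed).fit(X)
    assert np.all(np.diff(fit.loglik_trace_) >= -1e-8)


def test_fewer_rows_than_components_is_fatal():
    with pytest.raises(ValueError, match="cannot support"):
        pp.MixedMixture(n_components=5).fit(_cont_frame([1.0, 2.0]))


def test_affine_equivariance_of_continuous_features():
    rng = np.random.default_rng(1)
    x = np.r_[rng.normal(0, 1, 80), rng.normal(6, 1, 80)]
    X = _cont_frame(x)
    X2 = _cont_frame(3.0 * x + 7.0)
    f1 = pp.MixedMixture(n_components=2, n_restarts=3, random_state=5).fit(X)
    f2 = pp.MixedMixture(n_components=2, n_restarts=3, random_state=5).fit(X2)
    order1, order2 = np.argsort(f1.means_[:, 0]), np.argsort(f2.means_[:, 0])
    assert np.allclose(3.0 * f1.means_[order1, 0] + 7.0, f2.means_[order2, 0], atol=1e-4)
    assert np.allclose(9.0 * f1.variances_[order1, 0], f2.variances_[order2, 0], rtol=1e-3)
    relabel = {o1: o2 for o1, o2 in zip(order1, order2)}
    assert np.array_equal(np.vectorize(relabel.get)(f1.labels_), f2.labels_)


# -- BIC and selection ------------------------------------------------------


def test_bic_closed_form_and_penalty_monotonicity():
    X = _cont_frame(np.random.default_rng(2).normal(size=100))
    fit = pp.MixedMixture(n_components=1, n_restarts=1, random_state=0).fit(X)
    assert fit.n_free_params_ == 2
    assert fit.bic_ == pytest.approx(-2 * fit.loglik_ + 2 * np.log(100))
    assert pp.bic_score(fit.loglik_, 5, 100) > pp.bic_score(fit.loglik_, 2, 100)


def test_free_parameter_count_mixed_two_components():
    """2 components, 1 continuous + 1 three-level categorical:
    (K-1) + K*(2*1 + (3-1)) = 1 + 2*4 = 9 free parameters."""
    X = _mixed_toy()
    fit = pp.MixedMixture(n_components=2, n_restarts=1, random_state=0).fit(X)
    assert fit.n_free_params_ == 9


def test_bic_requires_n_greater_than_one():
    with pytest.raises(ValueError, match="n > 1"):
        pp.bic_score(-10.0, 2, 1)


def test_permutation_of_components_leaves_likelihood_and_bic_unchanged():
    X = _mixed_toy()
    params = pp.m_step(X, np.random.default_rng(3).dirichlet(np.ones(2), size=5))
    perm = [1, 0]
    permuted = pp.MixtureParams(
        weights=params.weights[perm],
        means=params.means[perm],
        variances=params.variances[perm],
        category_probs=[p[perm] for p in params.category_probs],
        continuous_names=params.continuous_names,
        categorical_names=params.categorical_names,
        levels=params.levels,
    )
    _, ll1 = pp.e_step(X, params)
    _, ll2 = pp.e_step(X, permuted)
    assert ll1 == pytest.approx(ll2, abs=1e-10)
    assert permuted.n_free_params == params.n_free_params


def test_select_k_honours_grid_bounds_and_finds_blob_structure():
    rng = np.random.default_rng(6)
    x = np.r_[rng.normal(0, 1, 120), rng.normal(12, 1, 120), rng.normal(24, 1, 120)]
    table = pp.select_k(_cont_frame(x), grid=range(2, 7), seed=1, n_restarts=3)
    assert table.grid == [2, 3, 4, 5, 6]
    assert table.selected_k == 3
    assert not table.no_elbow


def test_select_k_flags_absence_of_structure():
    X = _cont_frame(np.random.default_rng(7).normal(size=150))
    table = pp.select_k(X, grid=range(2, 6), seed=2, n_restarts=2)
    assert table.no_elbow
    assert table.selected_k == 2


# -- assignment -------------------------------------------------------------


def test_assignment_argmax_and_tie_break(fit5000):
    model, prep, _ = fit5000
    labels = pp.assign_clusters(model)
    assert np.array_equal(labels, model.responsibilities_.argmax(axis=1))
    assert len(labels) == len(prep.encoded)
    assert np.bincount(labels, minlength=5).sum() == len(prep.encoded)
    # explicit tie: argmax takes the lower index
    tie = np.array([[0.5, 0.5], [0.1, 0.9]])
    assert tie.argmax(axis=1)[0] == 0


def test_parameter_recovery_on_default_cohort(fit5000, default_config5000):
    """Fitted K=5 weights and component means vs generating truth, after
    optimal (Hungarian) label matching on continuous mean distance."""
    model, prep, truth = fit5000
    config = default_config5000
    cont = [s.name for s in config.continuous]
    true_means = np.array([[s.means[k] for s in config.continuous] for k in range(5)])
    cols = [list(prep.encoded.columns).index(c) for c in cont]
    fitted_means = model.means_[:, cols]
    cost = np.linalg.norm(true_means[:, None, :] - fitted_means[None, :, :], axis=2)
    rows, cols_idx = linear_sum_assignment(cost)
    true_w = np.asarray(config.weights)
    for k, j in zip(rows, cols_idx):
        assert abs(model.weights_[j] - true_w[k]) < 0.03
        for f, spec in enumerate(config.continuous):
            assert abs(fitted_means[j, f] - spec.means[k]) < 0.5 * spec.sds[k]


def test_split_encoded_rejects_missing_categories():
    X = pd.DataFrame({"c": pd.Categorical([None, "a"], categories=["a", "b"])})
    with pytest.raises(ValueError, match="missing"):
        split_encoded(X)
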