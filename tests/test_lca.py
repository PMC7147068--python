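"""EM latent class estimation: likelihood, E/M steps against naive
oracles, parameter recovery, determinism and invariances."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mmclust import LCAParameters, e_step, fit_em, log_likelihood, m_step, simulate_conditions
from mmclust.lca import LCAError


def naive_loglik(params: LCAParameters, y: np.ndarray) -> float:
    """Direct per-patient summation without log-space tricks."""
    total = 0.0
    for row in y:
        s = 0.0
        for k in range(params.K):
            f = params.pi[k]
            for j in range(params.J):
                f *= params.rho[k, j] if row[j] else 1 - params.rho[k, j]
            s += f
        total += np.log(s)
    return total


def test_single_class_single_item_closed_form():
    p = LCAParameters(pi=np.ones(1), rho=np.array([[0.5]]))
    y = np.array([[1], [1], [0], [0]])
    assert log_likelihood(p, y) == pytest.approx(4 * np.log(0.5), abs=1e-12)


def test_degenerate_mixture_equals_component_likelihood():
    rng = np.random.default_rng(0)
    y = (rng.random((20, 4)) < 0.4).astype(int)
    rho0 = rng.uniform(0.2, 0.8, (1, 4))
    p1 = LCAParameters(pi=np.ones(1), rho=rho0)
    p2 = LCAParameters(pi=np.array([1.0, 0.0]), rho=np.vstack([rho0, rng.uniform(0.2, 0.8, (1, 4))]))
    assert log_likelihood(p2, y) == pytest.approx(log_likelihood(p1, y), abs=1e-8)


def test_loglik_matches_naive_oracle():
    rng = np.random.default_rng(1)
    y = (rng.random((6, 3)) < 0.5).astype(int)
    p = LCAParameters(pi=np.array([0.3, 0.7]), rho=rng.uniform(0.1, 0.9, (2, 3)))
    assert log_likelihood(p, y) == pytest.approx(naive_loglik(p, y), abs=1e-10)


def test_loglik_rejects_non_binary_and_mismatched_data():
    p = LCAParameters(pi=np.ones(1), rho=np.array([[0.5, 0.5]]))
    with pytest.raises(LCAError):
        log_likelihood(p, np.array([[0, 2]]))
    with pytest.raises(LCAError):
        log_likelihood(p, np.array([[0, 1, 1]]))


def test_e_step_single_class_posterior_is_one():
    p = LCAParameters(pi=np.ones(1), rho=np.array([[0.3, 0.6]]))
    post = e_step(p, np.array([[0, 1], [1, 1]]))
    assert np.array_equal(post, np.ones((2, 1)))


def test_e_step_symmetry_under_pattern_complement():
    p = LCAParameters(pi=np.array([0.5, 0.5]), rho=np.array([[0.8, 0.8], [0.2, 0.2]]))
    post = e_step(p, np.array([[1, 1], [0, 0]]))
    assert post[0, 0] == pytest.approx(post[1, 1], abs=1e-12)
    assert post[0, 1] == pytest.approx(post[1, 0], abs=1e-12)


def test_e_step_matches_bayes_rule_oracle():
    rng = np.random.default_rng(2)
    y = (rng.random((6, 3)) < 0.5).astype(int)
    p = LCAParameters(pi=np.array([0.4, 0.6]), rho=rng.uniform(0.1, 0.9, (2, 3)))
    post = e_step(p, y)
    for i, row in enumerate(y):
        f = np.array(
            [p.pi[k] * np.prod(np.where(row, p.rho[k], 1 - p.rho[k])) for k in range(2)]
        )
        assert post[i] == pytest.approx(f / f.sum(), abs=1e-12)
    assert post.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-12)


def test_m_step_one_hot_posteriors_give_empirical_prevalences():
    y = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1], [0, 1, 1]])
    post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    p = m_step(post, y)
    assert p.pi == pytest.approx([0.5, 0.5])
    assert p.rho[0] == pytest.approx([1.0, 0.5, 0.0], abs=1e-5)
    assert p.rho[1] == pytest.approx([0.0, 0.5, 1.0], abs=1e-5)


def test_m_step_uniform_posteriors_collapse_to_overall_prevalence():
    rng = np.random.default_rng(3)
    y = (rng.random((30, 4)) < 0.4).astype(int)
    p = m_step(np.full((30, 2), 0.5), y)
    for k in (0, 1):
        assert p.rho[k] == pytest.approx(y.mean(axis=0), abs=1e-6)


def test_m_step_matches_weighted_mean_oracle():
    rng = np.random.default_rng(4)
    y = (rng.random((8, 3)) < 0.5).astype(int)
    post = rng.dirichlet(np.ones(2), size=8)
    p = m_step(post, y)
    assert p.pi == pytest.approx(post.mean(axis=0), abs=1e-12)
    expect = (post.T @ y) / post.sum(axis=0)[:, None]
    assert p.rho == pytest.approx(expect, abs=1e-12)


def test_m_step_reseeds_empty_class_with_warning():
    y = np.array([[0, 1], [1, 0], [1, 1]])
    post = np.column_stack([np.ones(3), np.zeros(3)])
    with pytest.warns(RuntimeWarning, match="empty class"):
        p = m_step(post, y, rng=np.random.default_rng(0))
    assert np.all((p.rho[1] >= 0.05) & (p.rho[1] <= 0.95))


def test_fit_k1_closed_form_column_means():
    rng = np.random.default_rng(5)
    y = (rng.random((40, 6)) < 0.3).astype(int)
    f = fit_em(y, 1, seed=0)
    assert f.params.pi == pytest.approx([1.0])
    assert f.params.rho[0] == pytest.approx(y.mean(axis=0), abs=1e-5)
    assert f.converged


def test_fit_recovers_two_separated_classes(two_class_params):
    y, _ = simulate_conditions(two_class_params, 2000, seed=6)
    f = fit_em(y, 2, n_restarts=20, seed=7)
    cost = np.abs(f.params.rho[:, None, :] - two_class_params.rho[None, :, :]).mean(-1)
    r, c = linear_sum_assignment(cost)
    assert np.abs(f.params.pi[r] - two_class_params.pi[c]).max() < 0.03
    assert cost[r, c].max() < 0.05


def test_fit_is_deterministic_given_seed(two_class_params):
    y, _ = simulate_conditions(two_class_params, 300, seed=8)
    f1 = fit_em(y, 2, n_restarts=5, seed=9)
    f2 = fit_em(y, 2, n_restarts=5, seed=9)
    assert f1.loglik == f2.loglik
    assert np.array_equal(f1.params.pi, f2.params.pi)
    assert np.array_equal(f1.posterior, f2.posterior)


def test_fit_invariant_to_row_permutation(two_class_params):
    y, _ = simulate_conditions(two_class_params, 400, seed=10)
    perm = np.random.default_rng(11).permutation(len(y))
    f1 = fit_em(y, 2, n_restarts=10, seed=12)
    f2 = fit_em(y[perm], 2, n_restarts=10, seed=12)
    assert f1.loglik == pytest.approx(f2.loglik, rel=1e-7)
    assert f1.params.pi == pytest.approx(f2.params.pi, abs=1e-4)
    assert f1.params.rho == pytest.approx(f2.params.rho, abs=1e-3)


def test_classes_sorted_by_descending_pi_and_modal_assignment(two_class_params):
    p = LCAParameters(pi=np.array([0.2, 0.8]),
                      rho=np.vstack([np.full(10, 0.9), np.full(10, 0.1)]))
    y, _ = simulate_conditions(p, 1000, seed=13)
    f = fit_em(y, 2, n_restarts=10, seed=14)
    assert f.params.pi[0] >= f.params.pi[1]
    assert np.array_equal(f.assignment, np.argmax(f.posterior, axis=1))
    assert f.posterior.sum(axis=1) == pytest.approx(np.ones(f.N), abs=1e-8)
    assert f.loglik <= 0


def test_fit_rejects_more_classes_than_rows():
    y = np.array([[0, 1], [1, 0]])
    with pytest.raises(LCAError):
        fit_em(y, 2)


def test_fit_warns_when_k_exceeds_distinct_patterns():
    y = np.array([[0, 1]] * 5 + [[1, 0]] * 5)
    with pytest.warns(RuntimeWarning, match="distinct"):
        fit_em(y, 3, n_restarts=2, seed=0, max_iter=50)
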