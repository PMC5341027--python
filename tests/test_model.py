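"""Model components against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

import ibclust as ib
from ibclust.errors import ConfigError, InputValidationError
from ibclust.model import beta_to_sticks


# ---------------------------------------------------------------------------
# stick breaking


@pytest.mark.parametrize(
    "V,expected",
    [([1.0], [1.0]), ([0.5, 0.5, 1.0], [0.5, 0.25, 0.25])],
)
def test_stick_breaking_closed_form(V, expected):
    np.testing.assert_allclose(ib.stick_breaking_weights(V), expected)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=0, max_size=10))
def test_stick_breaking_telescopes_to_a_simplex(head):
    V = np.array(head + [1.0])
    beta = ib.stick_breaking_weights(V)
    assert abs(beta.sum() - 1.0) < 1e-12
    assert np.all(beta >= 0)


def test_stick_breaking_rejects_bad_sticks():
    with pytest.raises(InputValidationError, match="equal 1"):
        ib.stick_breaking_weights([0.5, 0.9])
    with pytest.raises(InputValidationError, match="0, 1"):
        ib.stick_breaking_weights([1.5, 1.0])


def test_beta_to_sticks_round_trips():
    V = np.array([0.3, 0.8, 0.1, 1.0])
    beta = ib.stick_breaking_weights(V)
    np.testing.assert_allclose(beta_to_sticks(beta), V, atol=1e-12)


# ---------------------------------------------------------------------------
# assignment conditional


def test_assignment_probabilities_direct_normalization():
    p = ib.assignment_probabilities(
        [1, 0], np.array([0.5, 0.5]), np.array([[0.9, 0.1], [0.1, 0.9]])
    )
    np.testing.assert_allclose(p, [0.9, 0.1], atol=1e-12)


def test_assignment_probabilities_reduce_to_prior_without_data():
    beta = np.array([0.3, 0.7])
    psi = np.array([[0.9, 0.1], [0.1, 0.9]])
    np.testing.assert_allclose(
        ib.assignment_probabilities([0, 0], beta, psi), beta, atol=1e-12
    )


def test_assignment_probabilities_single_group():
    p = ib.assignment_probabilities([2, 3], np.array([1.0]), np.array([[0.4, 0.6]]))
    np.testing.assert_allclose(p, [1.0])


def test_sample_assignments_deterministic_cases():
    rng = np.random.default_rng(0)
    counts = ib.CountMatrix([[2, 0], [0, 3]])
    # K=1: everyone in the only group
    z = ib.sample_assignments(counts, np.array([1.0]), np.array([[0.5, 0.5]]), rng)
    assert z.tolist() == [0, 0]
    # orthogonal supports force the matching group
    psi = np.array([[1.0, 0.0], [0.0, 1.0]])
    z = ib.sample_assignments(counts, np.array([0.5, 0.5]), psi, rng)
    assert z.tolist() == [0, 1]


def test_sample_assignments_match_conditional_frequencies():
    """Empirical draw frequencies match the exact conditional within 3 SE."""
    w = np.array([2, 1])
    beta = np.array([0.4, 0.6])
    psi = np.array([[0.8, 0.2], [0.3, 0.7]])
    p = ib.assignment_probabilities(w, beta, psi)
    n = 50_000
    counts = ib.CountMatrix(np.tile(w, (n, 1)))
    z = ib.sample_assignments(counts, beta, psi, np.random.default_rng(1))
    freq = np.bincount(z, minlength=2) / n
    se = np.sqrt(p * (1 - p) / n)
    assert np.all(np.abs(freq - p) <= 3 * se)


# ---------------------------------------------------------------------------
# sticks and profiles conditionals


def test_sample_sticks_posterior_mean_matches_conjugate_update():
    # n=[2,1], alpha=0.1 -> V_1 ~ Beta(3, 1.1), mean 3/4.1
    hyper = ib.Hyperparameters(K=2, alpha=0.1)
    rng = np.random.default_rng(2)
    z = np.array([0, 0, 1])
    draws = np.array([ib.sample_sticks(z, hyper, rng).V[0] for _ in range(20_000)])
    target = 3 / 4.1
    sd = math.sqrt(target * (1 - target) / (4.1 + 1))
    assert abs(draws.mean() - target) <= 4 * sd / math.sqrt(draws.size)
    assert draws.max() <= 1 and draws.min() >= 0


def test_sample_sticks_single_group_is_degenerate():
    state = ib.sample_sticks(np.array([0, 0]), ib.Hyperparameters(K=1), np.random.default_rng(0))
    assert state.V.tolist() == [1.0]
    assert state.beta.tolist() == [1.0]


def test_sample_profiles_posterior_mean_matches_dirichlet_update():
    # one group with column sums [3,1], eps=0.1 -> Dirichlet(3.1, 1.1)
    hyper = ib.Hyperparameters(K=2, epsilon=0.1)
    counts = ib.CountMatrix([[3, 1]])
    z = np.array([0])
    rng = np.random.default_rng(3)
    draws = np.stack([ib.sample_profiles(counts, z, hyper, rng) for _ in range(20_000)])
    occupied = draws[:, 0, :].mean(axis=0)
    np.testing.assert_allclose(occupied, [3.1 / 4.2, 1.1 / 4.2], atol=0.01)
    empty = draws[:, 1, :].mean(axis=0)  # prior Dirichlet(0.1, 0.1): uniform mean
    np.testing.assert_allclose(empty, [0.5, 0.5], atol=0.02)


def test_sample_profiles_single_location_is_degenerate():
    counts = ib.CountMatrix([[4]])
    psi = ib.sample_profiles(counts, np.array([0]), ib.Hyperparameters(K=3), np.random.default_rng(0))
    np.testing.assert_allclose(psi, 1.0)


# ---------------------------------------------------------------------------
# likelihood


def test_log_likelihood_single_component_closed_form():
    counts = ib.CountMatrix([[1, 0]])
    ll = ib.log_likelihood(counts, np.array([1.0]), np.array([[0.25, 0.75]]))
    assert ll == pytest.approx(math.log(0.25), abs=1e-12)


def test_log_likelihood_trivial_single_location():
    counts = ib.CountMatrix([[3], [5]])
    ll = ib.log_likelihood(counts, np.array([1.0]), np.array([[1.0]]))
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_log_likelihood_matches_direct_mixture_sum():
    """Log-space evaluation equals the naive linear-space oracle."""
    rng = np.random.default_rng(4)
    W = rng.integers(0, 6, size=(5, 3))
    W[W.sum(axis=1) == 0, 0] = 1
    counts = ib.CountMatrix(W)
    beta = rng.dirichlet([1.0, 1.0])
    psi = rng.dirichlet([1.0, 1.0, 1.0], size=2)
    direct = 0.0
    for w in W:
        coeff = math.factorial(int(w.sum())) / np.prod([math.factorial(int(x)) for x in w])
        direct += math.log(
            sum(b * coeff * np.prod(p ** w) for b, p in zip(beta, psi))
        )
    assert ib.log_likelihood(counts, beta, psi) == pytest.approx(direct, abs=1e-10)


# ---------------------------------------------------------------------------
# chain driver


def test_gibbs_single_individual_matches_conjugate_posterior():
    # J=1, K=1: psi posterior is Dirichlet(4.1, 1.1) exactly
    counts = ib.CountMatrix([[4, 1]])
    hyper = ib.Hyperparameters(K=1, alpha=0.1, epsilon=0.1)
    fit = ib.run_gibbs(counts, hyper, n_iter=6000, burnin=1000, thin=1, seed=5)
    np.testing.assert_allclose(
        fit.psi_mean()[0], [4.1 / 5.2, 1.1 / 5.2], atol=0.01
    )


def test_gibbs_is_deterministic_given_seed(scenario1_sim):
    kw = dict(n_iter=60, burnin=20, thin=2, seed=17)
    a = ib.run_gibbs(scenario1_sim.counts, **kw)
    b = ib.run_gibbs(scenario1_sim.counts, **kw)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.psi, b.psi)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_array_equal(a.loglik, b.loglik)


def test_gibbs_storage_and_state_invariants():
    counts = ib.CountMatrix([[2, 1], [1, 2], [3, 0]])
    fit = ib.run_gibbs(counts, ib.Hyperparameters(K=3), n_iter=105, burnin=20, thin=7, seed=0)
    assert fit.n_draws == (105 - 20) // 7
    np.testing.assert_allclose(fit.beta.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(fit.psi.sum(axis=2), 1.0, atol=1e-12)
    assert fit.z.min() >= 0 and fit.z.max() < 3
    assert np.all(np.isfinite(fit.loglik))
    assert fit.V[:, -1].tolist() == [1.0] * fit.n_draws


def test_gibbs_rejects_bad_schedule():
    counts = ib.CountMatrix([[1, 1]])
    with pytest.raises(ConfigError):
        ib.run_gibbs(counts, n_iter=10, burnin=10)
    with pytest.raises(ConfigError):
        ib.run_gibbs(counts, n_iter=10, burnin=2, thin=0)


def test_default_hyperparameters():
    hyper = ib.Hyperparameters()
    assert (hyper.K, hyper.alpha, hyper.epsilon) == (25, 0.1, 0.1)


# ---------------------------------------------------------------------------
# relabeling


def _tiny_samples(z, beta, psi):
    z = np.asarray(z, dtype=np.int32)
    S, K = np.asarray(beta).shape
    return ib.PosteriorSamples(
        z=z, V=np.stack([beta_to_sticks(b) for b in np.asarray(beta)]),
        beta=np.asarray(beta, float), psi=np.asarray(psi, float),
        loglik=np.zeros(S), n_iter=S, burnin=0, thin=1, seed=0,
        hyper=ib.Hyperparameters(K=K),
        row_labels=tuple(f"i{j}" for j in range(z.shape[1])),
        col_labels=tuple(f"l{l}" for l in range(np.asarray(psi).shape[2])),
    )


def test_relabel_orders_groups_by_occupancy():
    # occupancies (1, 5, 0) -> old group 1 becomes group 0
    z = [[1, 1, 1, 1, 1, 0]]
    beta = [[0.2, 0.7, 0.1]]
    psi = [[[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]]]
    out = ib.relabel_samples(_tiny_samples(z, beta, psi))
    assert out.z[0].tolist() == [0, 0, 0, 0, 0, 1]
    np.testing.assert_allclose(out.beta[0], [0.7, 0.2, 0.1])
    np.testing.assert_allclose(out.psi[0][0], [0.1, 0.9])


def test_relabel_single_group_is_identity():
    out = ib.relabel_samples(_tiny_samples([[0, 0]], [[1.0]], [[[0.3, 0.7]]]))
    assert out.z[0].tolist() == [0, 0]
    np.testing.assert_allclose(out.psi[0], [[0.3, 0.7]])


def test_relabel_aligns_permuted_duplicate_draws():
    """Two draws identical up to a label swap become bit-identical."""
    base_z = [0, 0, 1]
    base_beta = [0.6, 0.4]
    base_psi = [[0.9, 0.1], [0.2, 0.8]]
    swapped_z = [1, 1, 0]
    out = ib.relabel_samples(
        _tiny_samples(
            [base_z, swapped_z],
            [base_beta, base_beta[::-1]],
            [base_psi, base_psi[::-1]],
        )
    )
    np.testing.assert_array_equal(out.psi[0], out.psi[1])
    np.testing.assert_array_equal(out.beta[0], out.beta[1])
    np.testing.assert_array_equal(out.z[0], out.z[1])


# ---------------------------------------------------------------------------
# conditional refit


def test_conditional_refit_matches_closed_form_dirichlet_posterior():
    counts = ib.CountMatrix([[3, 1], [1, 3], [4, 0]], ("a", "b", "c"), ("x", "y"))
    z = ib.Assignments(np.array([0, 1, 0]), labels=("a", "b", "c"))
    hyper = ib.Hyperparameters(K=3, epsilon=0.1)
    fit = ib.conditional_refit(counts, z, hyper, n_iter=6000, burnin=1000, thin=1, seed=6)
    # group 0 pools rows a and c: counts (7, 1); group 1: (1, 3); group 2 empty
    np.testing.assert_allclose(fit.psi_mean()[0], [7.1 / 8.2, 1.1 / 8.2], atol=0.01)
    np.testing.assert_allclose(fit.psi_mean()[1], [1.1 / 4.2, 3.1 / 4.2], atol=0.01)
    np.testing.assert_allclose(fit.psi_mean()[2], [0.5, 0.5], atol=0.02)
    assert fit.z_frozen and np.all(fit.z == fit.z[0])


def test_conditional_refit_aligns_by_label_and_drops_missing():
    counts2 = ib.CountMatrix([[2, 2], [5, 0]], ("b", "d"), ("x", "y"))
    z = ib.Assignments(np.array([0, 1, 0]), labels=("a", "b", "c"))
    fit = ib.conditional_refit(counts2, z, ib.Hyperparameters(K=2),
                              n_iter=200, burnin=100, thin=1, seed=0)
    assert fit.row_labels == ("b",)
    assert fit.z[0].tolist() == [1]


def test_conditional_refit_requires_overlap():
    counts2 = ib.CountMatrix([[1, 1]], ("zz",), ("x", "y"))
    z = ib.Assignments(np.array([0]), labels=("a",))
    with pytest.raises(InputValidationError, match="no overlap"):
        ib.conditional_refit(counts2, z, n_iter=10, burnin=0, thin=1)


def test_conditional_refit_can_freeze_beta():
    counts = ib.CountMatrix([[3, 1], [1, 3]])
    z = ib.Assignments(np.array([0, 1]))
    fit = ib.conditional_refit(counts, z, ib.Hyperparameters(K=2),
                              n_iter=50, burnin=10, thin=1, seed=0,
                              resample_beta=False)
    np.testing.assert_allclose(fit.beta, 0.5)


# ---------------------------------------------------------------------------
# prior behaviour


def test_prior_occupied_groups_nondecreasing_in_alpha():
    """Larger stick concentration spreads prior mass over more groups."""
    means = [
        ib.prior_occupied_groups(
            ib.Hyperparameters(K=25, alpha=a), n_individuals=100,
            n_draws=2000, seed=13,
        )
        for a in (0.01, 0.1, 1.0, 10.0)
    ]
    assert all(m2 >= m1 for m1, m2 in zip(means, means[1:]))
    assert means[0] < 2 < means[-1]
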