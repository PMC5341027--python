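"""Shared fixtures and the independent enumeration oracle.

Scenario-scale Gibbs fits are session-scoped because several tests read
different summaries off the same posterior; the chains themselves are
deterministic given their seeds.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import betaln, gammaln

import ibclust as ib

# chain schedule used for scenario-scale fits throughout the suite
SCHEDULE = dict(n_iter=3000, burnin=1500, thin=5)


def exact_assignment_posterior(W, K, alpha, epsilon):
    """Exact posterior over assignment vectors by full enumeration.

    Integrates the stick-breaking weights and the Dirichlet profiles out in
    closed form: p(z) is proportional to
    ``prod_{k<K} B(1+n_k, alpha+s_k)/B(1, alpha)`` (moments of the
    truncated stick-breaking prior) times per-group Dirichlet-multinomial
    marginals.  Independent of the sampler: no shared code paths.
    """
    W = np.asarray(W)
    J, L = W.shape
    keys, logs = [], []
    for z in itertools.product(range(K), repeat=J):
        za = np.array(z)
        n = np.bincount(za, minlength=K).astype(float)
        s = n.sum() - np.cumsum(n)
        lp = sum(betaln(1 + n[k], alpha + s[k]) - betaln(1, alpha) for k in range(K - 1))
        for k in range(K):
            c = W[za == k].sum(axis=0)
            lp += gammaln(L * epsilon) - gammaln(L * epsilon + c.sum())
            lp += (gammaln(epsilon + c) - gammaln(epsilon)).sum()
        keys.append(z)
        logs.append(lp)
    logs = np.array(logs)
    p = np.exp(logs - logs.max())
    p /= p.sum()
    return dict(zip(keys, p))


@pytest.fixture(scope="session")
def scenario1_sim():
    return ib.simulate_counts(ib.scenario_preset("scenario1"), seed=5)


@pytest.fixture(scope="session")
def scenario1_fit(scenario1_sim):
    fit = ib.run_gibbs(scenario1_sim.counts, seed=6, **SCHEDULE)
    return ib.relabel_samples(fit)


@pytest.fixture(scope="session")
def scenario2_sim():
    return ib.simulate_counts(ib.scenario_preset("scenario2"), seed=3)


@pytest.fixture(scope="session")
def scenario2_fit(scenario2_sim):
    fit = ib.run_gibbs(scenario2_sim.counts, seed=4, **SCHEDULE)
    return ib.relabel_samples(fit)


@pytest.fixture(scope="session")
def invasion_sims():
    t1 = ib.scenario_preset("invasion_t1")
    t2 = ib.scenario_preset("invasion_t2")
    return ib.simulate_counts(t1, seed=7), ib.simulate_counts(t2, seed=8)


@pytest.fixture(scope="session")
def invasion_fit(invasion_sims):
    sim_t1, _ = invasion_sims
    fit = ib.run_gibbs(sim_t1.counts, seed=9, **SCHEDULE)
    return ib.relabel_samples(fit)


@pytest.fixture(scope="session")
def invasion_refit(invasion_sims, invasion_fit):
    _, sim_t2 = invasion_sims
    z1 = ib.Assignments(invasion_fit.mode_assignments(), labels=invasion_fit.row_labels)
    return ib.conditional_refit(sim_t2.counts, z1, seed=10, **SCHEDULE)
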