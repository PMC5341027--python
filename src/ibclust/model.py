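"""Individual-based clustering: model and blocked Gibbs sampler.

The model clusters individuals by the locations they visit.  Individual
``j`` belongs to latent group ``z_j`` drawn from a categorical distribution
with weights ``beta``; given its group ``k``, its vector of per-location
counts ``w_j`` (with total ``n_j``) is multinomial with probability vector
``psi_k``.  The group weights carry a truncated stick-breaking prior,

    beta_k = V_k * prod_{m<k} (1 - V_m),   V_k ~ Beta(1, alpha),  V_K = 1,

which concentrates mass on few occupied groups so the effective number of
groups is learned from the data rather than fixed; only the maximum ``K``
is pre-specified.  Each profile row ``psi_k`` has a symmetric
Dirichlet(epsilon) prior.  Defaults are K=25, alpha=0.1, epsilon=0.1.

All conditionals are conjugate, so fitting alternates exact block draws of
``psi | z, w``, ``V | z`` and ``z | beta, psi`` (a blocked Gibbs sampler).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import CountMatrix
from .errors import ConfigError, InputValidationError, NumericalError

__all__ = [
    "Hyperparameters",
    "SticksState",
    "Assignments",
    "PosteriorSamples",
    "stick_breaking_weights",
    "beta_to_sticks",
    "assignment_probabilities",
    "sample_assignments",
    "sample_sticks",
    "sample_profiles",
    "log_likelihood",
    "run_gibbs",
    "relabel_samples",
    "conditional_refit",
    "prior_occupied_groups",
]

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300  # psi entries are clipped here before taking logs


@dataclass(frozen=True)
class Hyperparameters:
    """Prior settings: truncation level K, stick concentration alpha,
    per-location Dirichlet concentration epsilon."""

    K: int = 25
    alpha: float = 0.1
    epsilon: float = 0.1

    def __post_init__(self):
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if not self.alpha > 0:
            raise ConfigError("alpha must be > 0")
        if not self.epsilon > 0:
            raise ConfigError("epsilon must be > 0")


@dataclass(frozen=True)
class SticksState:
    """Stick fractions V (with V_K = 1) and the derived group simplex beta."""

    V: np.ndarray
    beta: np.ndarray

    @classmethod
    def from_sticks(cls, V) -> "SticksState":
        return cls(V=np.asarray(V, float), beta=stick_breaking_weights(V))


@dataclass(frozen=True)
class Assignments:
    """Group index per individual (0-based), optionally labelled."""

    z: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        z = np.asarray(self.z)
        if z.ndim != 1 or not np.issubdtype(z.dtype, np.integer):
            raise InputValidationError("assignments must be a 1-d integer vector")
        if np.any(z < 0):
            raise InputValidationError("assignment indices must be nonnegative")
        object.__setattr__(self, "z", z.astype(np.int64))
        if self.labels is not None and len(self.labels) != z.size:
            raise InputValidationError("assignment labels do not match length")


@dataclass(frozen=True)
class PosteriorSamples:
    """Stored post-burn-in draws of (z, V, beta, psi) plus chain metadata."""

    z: np.ndarray          # (S, J)
    V: np.ndarray          # (S, K)
    beta: np.ndarray       # (S, K)
    psi: np.ndarray        # (S, K, L)
    loglik: np.ndarray     # (n_iter,) observed-data log-likelihood trace
    n_iter: int
    burnin: int
    thin: int
    seed: int
    hyper: Hyperparameters
    row_labels: tuple
    col_labels: tuple
    z_frozen: bool = False
    relabeled: bool = False

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.z.shape[1]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def psi_mean(self) -> np.ndarray:
        return self.psi.mean(axis=0)

    def occupancy(self) -> np.ndarray:
        """Posterior mean fraction of individuals in each group."""
        K = self.beta.shape[1]
        frac = np.zeros(K)
        for s in range(self.n_draws):
            frac += np.bincount(self.z[s], minlength=K)
        return frac / (self.n_draws * self.n_individuals)

    def mode_assignments(self) -> np.ndarray:
        """Most frequent group per individual across stored draws."""
        K = self.beta.shape[1]
        counts = np.zeros((self.n_individuals, K), dtype=np.int64)
        for s in range(self.n_draws):
            counts[np.arange(self.n_individuals), self.z[s]] += 1
        return counts.argmax(axis=1)


# ---------------------------------------------------------------------------
# stick-breaking


def stick_breaking_weights(V) -> np.ndarray:
    """Map stick fractions to group probabilities.

    ``beta_k = V_k * prod_{m<k} (1 - V_m)``; the last stick must be exactly
    1 so that the weights telescope to a full simplex.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 1 or V.size < 1:
        raise InputValidationError("V must be a non-empty vector")
    if V[-1] != 1.0:
        raise InputValidationError("last stick fraction must equal 1 exactly")
    if np.any((V < 0) | (V > 1)):
        raise InputValidationError("stick fractions must lie in [0, 1]")
    remaining = np.concatenate(([1.0], np.cumprod(1.0 - V[:-1])))
    return V * remaining


def beta_to_sticks(beta) -> np.ndarray:
    """Invert stick breaking: recover V from a simplex (V_K forced to 1)."""
    beta = np.asarray(beta, dtype=float)
    remaining = 1.0 - np.concatenate(([0.0], np.cumsum(beta[:-1])))
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(remaining > 1e-15, beta / np.maximum(remaining, 1e-15), 0.0)
    V = np.clip(V, 0.0, 1.0)
    V[-1] = 1.0
    return V


# ---------------------------------------------------------------------------
# full conditionals


def _as_beta(sticks) -> np.ndarray:
    if isinstance(sticks, SticksState):
        return sticks.beta
    return np.asarray(sticks, dtype=float)


def _log_weights(W: np.ndarray, beta: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Unnormalised log posterior assignment weights, shape (J, K)."""
    log_psi = np.log(np.clip(psi, _LOG_FLOOR, None))
    return np.log(np.clip(beta, _LOG_FLOOR, None)) + W @ log_psi.T


def assignment_probabilities(w_j, beta, psi) -> np.ndarray:
    """Posterior membership probabilities for one individual.

    ``p_k`` is proportional to ``beta_k * prod_l psi_kl^{w_jl}``, evaluated
    in log space with max-subtraction.
    """
    w_j = np.atleast_2d(np.asarray(w_j, dtype=float))
    beta = _as_beta(beta)
    psi = np.asarray(psi, dtype=float)
    logw = _log_weights(w_j, beta, psi)[0]
    m = logw.max()
    if not np.isfinite(m):
        raise NumericalError("all assignment weights underflowed")
    p = np.exp(logw - m)
    return p / p.sum()


def _sample_categorical_rows(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of unnormalised log weights."""
    m = logw.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(m)):
        raise NumericalError("assignment weights underflowed for some individual")
    p = np.exp(logw - m)
    cdf = np.cumsum(p, axis=1)
    u = rng.random(logw.shape[0]) * cdf[:, -1]
    return (u[:, None] < cdf).argmax(axis=1)


def sample_assignments(
    counts: CountMatrix, sticks, profiles: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Block draw of all group memberships from their exact conditional."""
    beta = _as_beta(sticks)
    psi = np.asarray(profiles, dtype=float)
    if psi.shape[0] != beta.shape[0] or psi.shape[1] != counts.n_locations:
        raise InputValidationError("profile shape inconsistent with counts and beta")
    logw = _log_weights(counts.values.astype(float), beta, psi)
    return _sample_categorical_rows(logw, rng)


def sample_sticks(
    z: np.ndarray, hyper: Hyperparameters, rng: np.random.Generator
) -> SticksState:
    """Conjugate draw of the stick fractions given assignments.

    With group counts ``n_k`` and ``s_k`` the number of individuals in later
    groups, ``V_k ~ Beta(1 + n_k, alpha + s_k)`` for k < K, and ``V_K = 1``.
    """
    z = np.asarray(z)
    if z.size and z.max() >= hyper.K:
        raise InputValidationError("assignment index exceeds K")
    n = np.bincount(z, minlength=hyper.K).astype(float)
    s = n.sum() - np.cumsum(n)
    V = np.ones(hyper.K)
    if hyper.K > 1:
        V[:-1] = rng.beta(1.0 + n[:-1], hyper.alpha + s[:-1])
    return SticksState(V=V, beta=stick_breaking_weights(V))


def sample_profiles(
    counts: CountMatrix,
    z: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw of the visitation-rate rows given assignments.

    Row ``k`` is Dirichlet with parameters ``epsilon + c_kl`` where ``c_kl``
    sums the counts of group-k individuals at location ``l``; empty groups
    draw from the Dirichlet(epsilon) prior.
    """
    z = np.asarray(z)
    if z.size != counts.n_individuals:
        raise InputValidationError("assignment length does not match counts")
    c = np.zeros((hyper.K, counts.n_locations))
    np.add.at(c, z, counts.values.astype(float))
    gam = rng.gamma(hyper.epsilon + c)
    totals = gam.sum(axis=1, keepdims=True)
    # gamma draws with tiny shape can underflow to an all-zero row
    bad = totals[:, 0] <= 0.0
    if np.any(bad):
        gam[bad] = 1.0
        totals = gam.sum(axis=1, keepdims=True)
    return gam / totals


def log_likelihood(counts: CountMatrix, sticks, profiles: np.ndarray) -> float:
    """Observed-data log-likelihood, mixing over groups.

    ``sum_j log sum_k beta_k Multinomial(w_j; n_j, psi_k)``, multinomial
    coefficients included (they are constant in the parameters, so traces
    differ from coefficient-free ones by a constant offset).
    """
    beta = _as_beta(sticks)
    psi = np.asarray(profiles, dtype=float)
    W = counts.values.astype(float)
    logw = _log_weights(W, beta, psi)
    coeff = gammaln(W.sum(axis=1) + 1.0) - gammaln(W + 1.0).sum(axis=1)
    return float(logsumexp(logw, axis=1).sum() + coeff.sum())


# ---------------------------------------------------------------------------
# chain drivers


def _check_schedule(n_iter: int, burnin: int, thin: int) -> None:
    if not (isinstance(n_iter, (int, np.integer)) and isinstance(burnin, (int, np.integer))
            and isinstance(thin, (int, np.integer))):
        raise ConfigError("n_iter, burnin and thin must be integers")
    if not (n_iter > burnin >= 0):
        raise ConfigError(f"need n_iter > burnin >= 0, got {n_iter}, {burnin}")
    if thin < 1:
        raise ConfigError("thin must be >= 1")


def run_gibbs(
    counts: CountMatrix,
    hyper: Hyperparameters | None = None,
    n_iter: int = 10_000,
    burnin: int = 5_000,
    thin: int = 10,
    seed: int = 0,
    progress_every: int | None = None,
) -> PosteriorSamples:
    """Fit the model by blocked Gibbs sampling.

    Assignments start uniformly at random over the K groups; each sweep then
    draws ``psi | z, w``, ``V | z`` and ``z | beta, psi`` in that fixed
    order.  States after ``burnin`` sweeps are stored every ``thin`` sweeps,
    together with a per-sweep observed-data log-likelihood trace.  The run
    is fully reproducible from ``seed``.
    """
    hyper = hyper or Hyperparameters()
    _check_schedule(n_iter, burnin, thin)
    rng = np.random.default_rng(seed)
    J, L = counts.values.shape
    W = counts.values.astype(float)
    coeff = float((gammaln(W.sum(axis=1) + 1.0) - gammaln(W + 1.0).sum(axis=1)).sum())

    z = rng.integers(0, hyper.K, size=J)
    n_store = (n_iter - burnin) // thin
    z_store = np.empty((n_store, J), dtype=np.int32)
    V_store = np.empty((n_store, hyper.K))
    beta_store = np.empty((n_store, hyper.K))
    psi_store = np.empty((n_store, hyper.K, L))
    loglik = np.empty(n_iter)

    s = 0
    for it in range(1, n_iter + 1):
        psi = sample_profiles(counts, z, hyper, rng)
        sticks = sample_sticks(z, hyper, rng)
        logw = _log_weights(W, sticks.beta, psi)
        loglik[it - 1] = logsumexp(logw, axis=1).sum() + coeff
        z = _sample_categorical_rows(logw, rng)
        if it > burnin and (it - burnin) % thin == 0:
            z_store[s] = z
            V_store[s] = sticks.V
            beta_store[s] = sticks.beta
            psi_store[s] = psi
            s += 1
        if progress_every and it % progress_every == 0:
            logger.info("gibbs iteration %d/%d loglik=%.2f", it, n_iter, loglik[it - 1])

    return PosteriorSamples(
        z=z_store, V=V_store, beta=beta_store, psi=psi_store, loglik=loglik,
        n_iter=n_iter, burnin=burnin, thin=thin, seed=int(seed), hyper=hyper,
        row_labels=counts.row_labels, col_labels=counts.col_labels,
    )


def conditional_refit(
    counts_new: CountMatrix,
    z_fixed: Assignments | np.ndarray,
    hyper: Hyperparameters | None = None,
    n_iter: int = 10_000,
    burnin: int = 5_000,
    thin: int = 10,
    seed: int = 0,
    resample_beta: bool = True,
) -> PosteriorSamples:
    """Re-estimate profiles (and weights) on new counts with memberships frozen.

    This is the temporal-change device: group membership from an earlier fit
    is retained while ``psi`` (and by default ``beta``) are re-estimated on
    a later time window's counts.  Individuals present in only one of the
    two inputs are dropped with a warning; with ``resample_beta=False`` the
    weights stay fixed at the occupancy fractions of the frozen assignment.
    """
    hyper = hyper or Hyperparameters()
    _check_schedule(n_iter, burnin, thin)
    if not isinstance(z_fixed, Assignments):
        z_fixed = Assignments(np.asarray(z_fixed))
    if z_fixed.labels is not None:
        by_label = dict(zip(z_fixed.labels, z_fixed.z))
        kept = [r for r in counts_new.row_labels if r in by_label]
        if not kept:
            raise InputValidationError(
                "no overlap between new counts and frozen assignments"
            )
        dropped_new = counts_new.n_individuals - len(kept)
        dropped_old = len(z_fixed.z) - len(kept)
        if dropped_new or dropped_old:
            logger.warning(
                "conditional refit: dropped %d individuals absent from the frozen "
                "assignment and %d absent from the new counts", dropped_new, dropped_old,
            )
        counts_new = counts_new.subset_rows(kept)
        z = np.asarray([by_label[r] for r in kept], dtype=np.int64)
    else:
        if len(z_fixed.z) != counts_new.n_individuals:
            raise InputValidationError(
                "unlabelled frozen assignment must match counts length"
            )
        z = z_fixed.z
    if z.max() >= hyper.K:
        raise InputValidationError("frozen assignment index exceeds K")

    rng = np.random.default_rng(seed)
    J, L = counts_new.values.shape
    W = counts_new.values.astype(float)
    coeff = float((gammaln(W.sum(axis=1) + 1.0) - gammaln(W + 1.0).sum(axis=1)).sum())
    n = np.bincount(z, minlength=hyper.K).astype(float)
    fixed_beta = n / n.sum()
    fixed_sticks = SticksState(V=beta_to_sticks(fixed_beta), beta=fixed_beta)

    n_store = (n_iter - burnin) // thin
    z_store = np.tile(z.astype(np.int32), (n_store, 1))
    V_store = np.empty((n_store, hyper.K))
    beta_store = np.empty((n_store, hyper.K))
    psi_store = np.empty((n_store, hyper.K, L))
    loglik = np.empty(n_iter)

    s = 0
    for it in range(1, n_iter + 1):
        psi = sample_profiles(counts_new, z, hyper, rng)
        sticks = sample_sticks(z, hyper, rng) if resample_beta else fixed_sticks
        # complete-data log-likelihood of the frozen assignment
        log_psi = np.log(np.clip(psi, _LOG_FLOOR, None))
        loglik[it - 1] = float((W * log_psi[z]).sum()) + coeff
        if it > burnin and (it - burnin) % thin == 0:
            V_store[s] = sticks.V
            beta_store[s] = sticks.beta
            psi_store[s] = psi
            s += 1

    return PosteriorSamples(
        z=z_store, V=V_store, beta=beta_store, psi=psi_store, loglik=loglik,
        n_iter=n_iter, burnin=burnin, thin=thin, seed=int(seed), hyper=hyper,
        row_labels=counts_new.row_labels, col_labels=counts_new.col_labels,
        z_frozen=True,
    )


# ---------------------------------------------------------------------------
# relabeling


def _greedy_match(dist: np.ndarray) -> np.ndarray:
    """Greedy assignment on a square distance matrix.

    Returns ``perm`` with ``perm[target] = source``: repeatedly takes the
    globally smallest remaining (source, target) distance.
    """
    K = dist.shape[0]
    perm = np.full(K, -1)
    used_src = np.zeros(K, bool)
    used_tgt = np.zeros(K, bool)
    order = np.argsort(dist, axis=None, kind="stable")
    filled = 0
    for flat in order:
        a, b = divmod(int(flat), K)
        if used_src[a] or used_tgt[b]:
            continue
        perm[b] = a
        used_src[a] = True
        used_tgt[b] = True
        filled += 1
        if filled == K:
            break
    return perm


def relabel_samples(samples: PosteriorSamples) -> PosteriorSamples:
    """Resolve label switching across stored draws.

    Within each draw, groups are re-indexed by decreasing occupancy (ties
    keep their original order).  Draws after the first are then greedily
    aligned to the running mean profile matrix by smallest total variation
    distance, so group ``k`` refers to the same mixture component in every
    stored draw.
    """
    if samples.n_draws == 0:
        raise InputValidationError("cannot relabel an empty sample set")
    S, K = samples.beta.shape
    z = np.empty_like(samples.z)
    beta = np.empty_like(samples.beta)
    V = np.empty_like(samples.V)
    psi = np.empty_like(samples.psi)
    running = None
    for s in range(S):
        n = np.bincount(samples.z[s], minlength=K)
        order = np.argsort(-n, kind="stable")  # new index i <- old group order[i]
        p = samples.psi[s][order]
        b = samples.beta[s][order]
        zz = _invert_perm(order)[samples.z[s]]
        if running is not None:
            perm = _greedy_match(0.5 * np.abs(p[:, None, :] - running[None, :, :]).sum(-1))
            p = p[perm]
            b = b[perm]
            zz = _invert_perm(perm)[zz]
        psi[s] = p
        beta[s] = b
        V[s] = beta_to_sticks(b)
        z[s] = zz
        running = p.copy() if running is None else (running * s + p) / (s + 1)
    return replace(samples, z=z, V=V, beta=beta, psi=psi, relabeled=True)


def _invert_perm(perm: np.ndarray) -> np.ndarray:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return inv


# ---------------------------------------------------------------------------
# prior diagnostics


def prior_occupied_groups(
    hyper: Hyperparameters, n_individuals: int, n_draws: int = 10_000, seed: int = 0
) -> float:
    """Prior-predictive mean number of occupied groups.

    Simulates ``beta`` from the truncated stick-breaking prior and ``z``
    from the implied categorical for ``n_individuals`` individuals; returns
    the average number of distinct groups used.  Increasing ``alpha`` makes
    the sticks shorter, spreading mass over more groups.
    """
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_draws):
        V = np.ones(hyper.K)
        if hyper.K > 1:
            V[:-1] = rng.beta(1.0, hyper.alpha, size=hyper.K - 1)
        beta = stick_breaking_weights(V)
        z = rng.choice(hyper.K, size=n_individuals, p=beta)
        total += np.unique(z).size
    return total / n_draws
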