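"""Latent class analysis for binary condition indicators.

The model: each patient belongs to one of K unobserved classes with prior
(mixing) probabilities ``pi``; given class k, the J binary condition flags
are independent Bernoulli draws with item-response probabilities
``rho[k, j]``.  The observed-data log-likelihood is

    l = sum_i log sum_k pi[k] * prod_j rho[k,j]^y_ij (1-rho[k,j])^(1-y_ij)

maximised by expectation-maximisation (EM) with multiple random restarts.
Patients are allocated to their modal (highest-posterior) class.

Implementation notes
--------------------
* All likelihood computations are in log space with log-sum-exp over
  classes, so extreme item-response probabilities cannot underflow.
* ``rho`` is clamped to ``[RHO_EPS, 1 - RHO_EPS]`` to avoid log(0) at the
  boundary of the parameter space.
* ``fit_em`` collapses duplicate response patterns to unique rows with
  multiplicities; the weighted EM updates are exact and typically much
  faster when J is small relative to N.
* Classes are relabelled in descending mixing-proportion order after
  fitting so that cluster identities are stable across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

RHO_EPS = 1e-6


class LCAError(ValueError):
    """Invalid parameters or data for the latent class model."""


@dataclass
class LCAParameters:
    """Mixing proportions and per-class condition probabilities.

    pi : (K,) mixing proportions, non-negative, summing to 1.
    rho : (K, J) item-response probabilities, clamped to [eps, 1-eps].
    """

    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.pi.ndim != 1 or self.pi.size == 0:
            raise LCAError("pi must be a non-empty 1-d vector")
        if np.any(self.pi < 0):
            raise LCAError("pi entries must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise LCAError(f"pi must sum to 1 (got {self.pi.sum()!r})")
        if self.rho.shape[0] != self.pi.size:
            raise LCAError("rho must have one row per class")
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise LCAError("rho entries must lie in [0, 1]")
        self.rho = np.clip(self.rho, RHO_EPS, 1.0 - RHO_EPS)

    @property
    def K(self) -> int:
        return self.pi.size

    @property
    def J(self) -> int:
        return self.rho.shape[1]


@dataclass
class LCAFit:
    """A fitted latent class model with posteriors and modal assignments."""

    params: LCAParameters
    loglik: float
    posterior: np.ndarray  # (N, K)
    assignment: np.ndarray  # (N,) modal class labels
    converged: bool
    n_iterations: int
    n_restarts_used: int
    seed: int | None
    N: int

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def n_params(self) -> int:
        """Free parameters: (K-1) mixing + K*J item-response."""
        return (self.params.K - 1) + self.params.K * self.params.J

    def to_dict(self, condition_registry: list[str] | None = None) -> dict:
        d = {
            "K": int(self.params.K),
            "pi": self.params.pi.tolist(),
            "rho": self.params.rho.tolist(),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "N": int(self.N),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "n_restarts_used": int(self.n_restarts_used),
            "seed": self.seed,
        }
        if condition_registry is not None:
            d["condition_registry"] = list(condition_registry)
        return d

    def save_json(self, path, condition_registry=None, extra: dict | None = None):
        d = self.to_dict(condition_registry)
        if extra:
            d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _validate_data(data: np.ndarray, params: LCAParameters | None = None) -> np.ndarray:
    y = np.asarray(data)
    if y.ndim != 2:
        raise LCAError(f"data must be 2-d (N x J), got ndim={y.ndim}")
    vals = np.unique(y)
    if not np.isin(vals, (0, 1)).all():
        raise LCAError(f"data must be binary 0/1; found values {vals[:10]}")
    if params is not None and y.shape[1] != params.J:
        raise LCAError(
            f"data has J={y.shape[1]} conditions but parameters have J={params.J}"
        )
    return y.astype(np.float64, copy=False)


def _log_component_density(params: LCAParameters, y: np.ndarray) -> np.ndarray:
    """(N, K) matrix of log pi_k + log f_k(y_i)."""
    log_rho = np.log(params.rho)  # (K, J)
    log_1m = np.log1p(-params.rho)
    # y @ log_rho.T + (1-y) @ log_1m.T, expanded to avoid allocating (1-y)
    ll = y @ (log_rho - log_1m).T + log_1m.sum(axis=1)
    return ll + np.log(params.pi)


def log_likelihood(params: LCAParameters, data: np.ndarray) -> float:
    """Total log-likelihood of binary data under the latent class model."""
    y = _validate_data(data, params)
    return float(logsumexp(_log_component_density(params, y), axis=1).sum())


def e_step(params: LCAParameters, data: np.ndarray) -> np.ndarray:
    """Posterior class-membership probabilities p_ik (rows on the simplex)."""
    y = _validate_data(data, params)
    lp = _log_component_density(params, y)
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)


def m_step(
    posterior: np.ndarray,
    data: np.ndarray,
    rng: np.random.Generator | None = None,
) -> LCAParameters:
    """Maximising update: pi = mean posterior, rho = weighted prevalence.

    A class with zero posterior mass has no defined item-response row; its
    rho is re-seeded uniformly at random (warning emitted) so EM can escape.
    """
    p = np.asarray(posterior, dtype=float)
    y = _validate_data(data)
    if p.shape[0] != y.shape[0]:
        raise LCAError("posterior and data row counts differ")
    mass = p.sum(axis=0)  # (K,)
    pi = mass / p.shape[0]
    dead = mass <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} empty class(es) in M step; re-seeding rho",
            RuntimeWarning,
            stacklevel=2,
        )
        if rng is None:
            rng = np.random.default_rng()
        mass = np.where(dead, 1.0, mass)
    rho = (p.T @ y) / mass[:, None]
    if dead.any():
        rho[dead] = rng.uniform(0.05, 0.95, size=(int(dead.sum()), y.shape[1]))
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum()
    return LCAParameters(pi=pi, rho=rho)


def _weighted_em_run(
    uniq: np.ndarray,
    w: np.ndarray,
    init: LCAParameters,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
):
    """One EM run on unique patterns with multiplicities. Returns
    (params, loglik, n_iter, converged, trace)."""
    params = init
    n = w.sum()
    prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _log_component_density(params, uniq)  # (U, K)
        row_ll = logsumexp(lp, axis=1)
        ll = float(w @ row_ll)
        trace.append(ll)
        if np.isfinite(prev):
            denom = max(abs(prev), 1.0)
            if ll < prev - 1e-9 * denom:
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev} -> {ll} at iter {it}"
                )
            if (ll - prev) / denom < tol:
                converged = True
                break
        prev = ll
        post = np.exp(lp - row_ll[:, None])  # (U, K)
        wp = post * w[:, None]
        mass = wp.sum(axis=0)
        dead = mass <= 0
        pi = mass / n
        if dead.any():
            mass = np.where(dead, 1.0, mass)
        rho = (wp.T @ uniq) / mass[:, None]
        if dead.any():
            rho[dead] = rng.uniform(0.05, 0.95, size=(int(dead.sum()), uniq.shape[1]))
            pi = np.clip(pi, 1e-12, None)
            pi /= pi.sum()
        params = LCAParameters(pi=pi, rho=rho)
    return params, trace[-1], it, converged, trace


def _random_init(K: int, J: int, rng: np.random.Generator) -> LCAParameters:
    pi = rng.dirichlet(np.ones(K))
    rho = rng.uniform(0.05, 0.95, size=(K, J))
    return LCAParameters(pi=pi, rho=rho)


def fit_em(
    data: np.ndarray,
    K: int,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
    extra_inits: list[LCAParameters] | None = None,
) -> LCAFit:
    """Fit a K-class model by EM with random restarts.

    Restarts draw pi ~ Dirichlet(1,...,1) and rho ~ Uniform(0.05, 0.95);
    the restart with the highest final log-likelihood wins. Convergence is
    declared when the relative log-likelihood change drops below ``tol``.
    Classes are relabelled in descending pi order; modal assignment breaks
    ties toward the lowest class index.

    ``extra_inits`` prepends deterministic initialisations (used e.g. to
    warm-start a (K+1)-class fit from a fitted K-class model).
    """
    y = _validate_data(data)
    N, J = y.shape
    if K < 1:
        raise LCAError("K must be >= 1")
    if N <= K:
        raise LCAError(f"need more observations than classes (N={N}, K={K})")

    uniq, inverse, counts = np.unique(y, axis=0, return_inverse=True, return_counts=True)
    if K > uniq.shape[0]:
        warnings.warn(
            f"K={K} exceeds the {uniq.shape[0]} distinct response patterns; "
            "the model is likely unidentifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    w = counts.astype(float)

    rng = np.random.default_rng(seed)
    inits: list[LCAParameters] = list(extra_inits or [])
    if K == 1:
        # closed form: single class, rho = column means
        inits = [LCAParameters(pi=np.ones(1), rho=y.mean(axis=0, keepdims=True))]
        n_runs = 1
    else:
        n_runs = len(inits) + n_restarts
        inits += [_random_init(K, J, rng) for _ in range(n_restarts)]

    best = None
    for init in inits:
        if init.J != J or init.K != K:
            raise LCAError("extra initialisation has wrong dimensions")
        params, ll, n_it, conv, _ = _weighted_em_run(uniq, w, init, max_iter, tol, rng)
        if best is None or ll > best[1]:
            best = (params, ll, n_it, conv)

    params, ll, n_it, conv = best
    order = np.argsort(-params.pi, kind="stable")
    params = LCAParameters(pi=params.pi[order], rho=params.rho[order])
    post_u = e_step(params, uniq)
    posterior = post_u[inverse]
    assignment = np.argmax(posterior, axis=1)
    return LCAFit(
        params=params,
        loglik=ll,
        posterior=posterior,
        assignment=assignment,
        converged=conv,
        n_iterations=n_it,
        n_restarts_used=n_runs,
        seed=seed,
        N=N,
    )
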