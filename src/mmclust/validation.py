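"""Hold-out stability assessment.

The clustering is refit on the held-out split with the number of classes
fixed to the training solution, and each test cluster is matched to a
training cluster under two independent criteria:

* smallest Jensen-Shannon distance (base-2, so bounded by 1) between the
  disease-prevalence profiles normalised to probability distributions, and
* highest Pearson correlation between the raw prevalence profiles.

Matching is per test cluster (many-to-one is allowed: the smaller test set
may not reproduce every training cluster).  Agreement of the two criteria,
and the similarity of the relative-entropy classification quality across
splits, are the stability evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .lca import LCAFit, fit_em
from .profiling import prevalence_profile
from .selection import relative_entropy


class ValidationError(ValueError):
    pass


def jsd(p, q) -> float:
    """Jensen-Shannon distance between two non-negative profiles.

    Profiles are normalised to sum 1; the divergence uses base-2
    logarithms (D = H(M) - (H(P)+H(Q))/2 with M the midpoint), and the
    distance is its square root, so it is symmetric, lies in [0, 1], and
    is 0 iff the normalised profiles coincide.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("profiles must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("profiles must be non-negative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValidationError("profiles must have positive sum")
    d = float(jensenshannon(p, q, base=2))
    return 0.0 if np.isnan(d) else d  # identical profiles can yield nan


def profile_correlation(p, q) -> float:
    """Pearson correlation between two raw prevalence profiles; NaN (with a
    warning) when either profile is constant."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.size < 2:
        raise ValidationError("profiles must share a length of at least 2")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        warnings.warn("constant profile: correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(pearsonr(p, q).statistic)


@dataclass
class MatchResult:
    """Train/test cluster correspondence under the two criteria."""

    jsd_matrix: np.ndarray  # (n_train, n_test)
    corr_matrix: np.ndarray
    jsd_match: dict[int, int]  # test cluster -> train cluster (argmin JSD)
    corr_match: dict[int, int]  # test cluster -> train cluster (argmax corr)
    agreement: dict[int, bool]
    entropy_train: float | None = None
    entropy_test: float | None = None

    def to_dict(self) -> dict:
        return {
            "jsd_matrix": self.jsd_matrix.tolist(),
            "corr_matrix": self.corr_matrix.tolist(),
            "jsd_match": {str(k): v for k, v in self.jsd_match.items()},
            "corr_match": {str(k): v for k, v in self.corr_match.items()},
            "agreement": {str(k): bool(v) for k, v in self.agreement.items()},
            "entropy_train": self.entropy_train,
            "entropy_test": self.entropy_test,
            "jsd_normalisation": "profiles normalised to sum 1; base-2 logs",
            "correlation_scale": "raw (un-normalised) prevalences",
        }


def match_clusters(train_profiles, test_profiles) -> MatchResult:
    """Match every test cluster to a training cluster.

    ``train_profiles``/``test_profiles``: 2-d arrays (clusters x J) of
    within-cluster prevalences on a shared condition registry.  Each test
    cluster independently takes the argmin-JSD and argmax-correlation
    training partner (ties toward the lowest training index).
    """
    tr = np.atleast_2d(np.asarray(train_profiles, dtype=float))
    te = np.atleast_2d(np.asarray(test_profiles, dtype=float))
    if tr.shape[1] != te.shape[1]:
        raise ValidationError(
            f"condition registries differ: J={tr.shape[1]} vs J={te.shape[1]}"
        )
    nt, ns = tr.shape[0], te.shape[0]
    jm = np.empty((nt, ns))
    cm = np.empty((nt, ns))
    for i in range(nt):
        for j in range(ns):
            jm[i, j] = jsd(tr[i], te[j])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cm[i, j] = profile_correlation(tr[i], te[j])
    jsd_match = {j: int(np.argmin(jm[:, j])) for j in range(ns)}
    with np.errstate(invalid="ignore"):
        corr_match = {j: int(np.nanargmax(cm[:, j])) for j in range(ns)}
    agreement = {j: jsd_match[j] == corr_match[j] for j in range(ns)}
    return MatchResult(jsd_matrix=jm, corr_matrix=cm, jsd_match=jsd_match,
                       corr_match=corr_match, agreement=agreement)


def replicate_on_test(
    train_fit: LCAFit,
    train_data: np.ndarray,
    test_data: np.ndarray,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[LCAFit, MatchResult]:
    """Refit on the held-out data at the training K and match the clusters.

    Profiles on both sides are modal-assignment within-cluster prevalences;
    the relative entropies of both fits are recorded for the
    classification-quality consistency check.
    """
    K = train_fit.params.K
    test_data = np.asarray(test_data)
    if test_data.shape[0] < 5 * K:
        warnings.warn(
            f"test split ({test_data.shape[0]} rows) is small for K={K}",
            RuntimeWarning,
            stacklevel=2,
        )
    test_fit = fit_em(test_data, K, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed)
    tr_within, _, _ = prevalence_profile(train_fit.assignment, train_data)
    te_within, _, _ = prevalence_profile(test_fit.assignment, test_data)
    tr_mat = np.vstack([tr_within[k] for k in sorted(tr_within)])
    te_mat = np.vstack([te_within[k] for k in sorted(te_within)])
    match = match_clusters(tr_mat, te_mat)
    match.entropy_train = relative_entropy(train_fit)
    match.entropy_test = relative_entropy(test_fit)
    return test_fit, match
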