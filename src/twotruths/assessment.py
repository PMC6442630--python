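"""Clustering agreement and embedding-comparison theory.

Two complementary yardsticks quantify which block structure each spectral
embedding recovers:

* the adjusted Rand index (ARI), a chance-corrected pair-counting
  agreement between two partitions, with permutation-test significance;
* Chernoff information between the block-conditional Gaussian limits of
  the embedded coordinates.  For two Gaussians F1 = N(mu1, Sigma1),
  F2 = N(mu2, Sigma2) and Sigma_t = t Sigma1 + (1-t) Sigma2,

      h(t) = t(1-t)/2 (mu1-mu2)' Sigma_t^{-1} (mu1-mu2)
             + 1/2 log( |Sigma_t| / (|Sigma1|^t |Sigma2|^{1-t}) ),

  and the Chernoff information is sup_{t in (0,1)} h(t): the exponential
  rate at which the Bayes error of distinguishing the blocks decays.  The
  Chernoff ratio rho = rho_A / rho_L (minimum pairwise Chernoff
  information under the ASE limit over that under the LSE limit) is > 1
  when adjacency embedding separates the blocks at a better rate and < 1
  when Laplacian embedding does.

Block-conditional limit parameters are estimated empirically: several
graphs are sampled at large n, embedded, Procrustes-aligned on their block
means, pooled, and summarized by per-block sample means and covariances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .gmm import Clustering
from .sbm import SBMParams, sample_sbm
from .embedding import spectral_embed

__all__ = [
    "GaussianComponent",
    "ChernoffResult",
    "ChernoffRatioResult",
    "GroupingResult",
    "MixtureKLResult",
    "ari",
    "ari_permutation_test",
    "chernoff_h",
    "chernoff_information",
    "limit_gmm_params",
    "chernoff_ratio_sbm",
    "gaussian_kl",
    "mixture_kl_numeric",
    "best_two_grouping",
]


# ---------------------------------------------------------------------------
# Adjusted Rand index


def _as_labels(c: Union[Clustering, np.ndarray, Sequence]) -> np.ndarray:
    if isinstance(c, Clustering):
        return c.labels
    return np.asarray(c)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def ari(c1, c2) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Pair-counting form: with contingency table N, row sums a_i and column
    sums b_j,

        ARI = (sum_ij C(N_ij,2) - E) / (M - E),
        E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
        M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.

    1 means identical partitions, 0 is the chance level.  In the
    degenerate M == E case the value is 1 if the partitions induce the
    same pair relations and 0 otherwise.
    """
    l1, l2 = _as_labels(c1), _as_labels(c2)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("partitions must be 1-D of equal length")
    n = len(l1)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, i1 = np.unique(l1, return_inverse=True)
    _, i2 = np.unique(l2, return_inverse=True)
    k1, k2 = i1.max() + 1, i2.max() + 1
    N = np.bincount(i1 * k2 + i2, minlength=k1 * k2).reshape(k1, k2)
    a = N.sum(axis=1)
    b = N.sum(axis=0)
    index = _comb2(N).sum()
    E = _comb2(a).sum() * _comb2(b).sum() / _comb2(np.array([n]))[0]
    M = 0.5 * (_comb2(a).sum() + _comb2(b).sum())
    if abs(M - E) < 1e-12:
        # both partitions pairwise-trivial (all-together or all-apart)
        return 1.0 if np.array_equal(np.sort(a), np.sort(b)) else 0.0
    return float((index - E) / (M - E))


def ari_permutation_test(
    c1, c2, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for the observed ARI.

    The labels of the second partition are shuffled uniformly across items;
    p = (1 + #{ARI_perm >= ARI_obs}) / (1 + n_perm) (add-one rule, so p is
    never exactly zero).
    """
    l1, l2 = _as_labels(c1), _as_labels(c2)
    obs = ari(l1, l2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if ari(l1, rng.permutation(l2)) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Chernoff information


@dataclass(frozen=True)
class GaussianComponent:
    """A weighted multivariate normal N(mu, sigma)."""

    mu: np.ndarray
    sigma: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sig = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sig)
        if sig.shape != (len(mu), len(mu)):
            raise ValueError("sigma must be d x d")
        if not np.allclose(sig, sig.T):
            raise ValueError("sigma must be symmetric")
        _chol_or_raise(sig)
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("weight must be in (0, 1]")

    @property
    def d(self) -> int:
        return len(self.mu)


def _chol_or_raise(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive-definite") from exc


def _logdet(S: np.ndarray) -> float:
    L = _chol_or_raise(S)
    return 2.0 * float(np.log(np.diag(L)).sum())


@dataclass(frozen=True)
class ChernoffResult:
    value: float
    t_star: float


def chernoff_h(t: float, F1: GaussianComponent, F2: GaussianComponent) -> float:
    """The Chernoff exponent integrand h(t; F1, F2) for Gaussians."""
    if not (0.0 < t < 1.0):
        raise ValueError("t must lie in (0, 1)")
    dmu = F1.mu - F2.mu
    St = t * F1.sigma + (1.0 - t) * F2.sigma
    L = _chol_or_raise(St)
    sol = np.linalg.solve(L, dmu)
    quad = float(sol @ sol)
    logdet_t = 2.0 * float(np.log(np.diag(L)).sum())
    return (
        0.5 * t * (1.0 - t) * quad
        + 0.5 * (logdet_t - t * _logdet(F1.sigma) - (1.0 - t) * _logdet(F2.sigma))
    )


def chernoff_information(
    F1: GaussianComponent, F2: GaussianComponent, tol: float = 1e-8
) -> ChernoffResult:
    """sup over t in (0,1) of h(t): dense grid scan then local refinement."""
    ts = np.arange(1e-3, 1.0, 1e-3)
    hs = np.array([chernoff_h(t, F1, F2) for t in ts])
    i = int(np.argmax(hs))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, len(ts) - 1)]
    res = minimize_scalar(
        lambda t: -chernoff_h(t, F1, F2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    t_star = float(res.x)
    value = float(-res.fun)
    if hs[i] > value:  # refinement should never lose to the grid
        value, t_star = float(hs[i]), float(ts[i])
    return ChernoffResult(value=max(value, 0.0), t_star=t_star)


# ---------------------------------------------------------------------------
# Empirical block-conditional limit parameters and the Chernoff ratio


def limit_gmm_params(
    params: SBMParams,
    method: str,
    d: int,
    n: int = 4000,
    n_graphs: int = 5,
    seed: int = 0,
) -> list[GaussianComponent]:
    """Estimate the per-block Gaussian limits of a spectral embedding.

    Samples ``n_graphs`` SBM graphs of size ``n`` with known memberships,
    embeds each at dimension ``d``, aligns every embedding to the first by
    the orthogonal Procrustes rotation of its block means (the embedding is
    identified only up to an orthogonal transform), pools the vertices and
    returns one weighted component per block: the pooled within-block
    sample mean and covariance, weighted by pi.
    """
    rng = np.random.default_rng(seed)
    K = params.K
    pooled: list[list[np.ndarray]] = [[] for _ in range(K)]
    ref_means: Optional[np.ndarray] = None
    for _ in range(n_graphs):
        g, z = sample_sbm(params, n, seed=rng, block_sizes="multinomial")
        emb = spectral_embed(g, method, d, seed=int(rng.integers(2**31)))
        X = emb.X
        means = np.stack([X[z == k].mean(axis=0) for k in range(K)])
        if ref_means is None:
            ref_means = means
        else:
            R, _ = orthogonal_procrustes(means, ref_means)
            X = X @ R
        for k in range(K):
            pooled[k].append(X[z == k])
    comps = []
    for k in range(K):
        Xk = np.concatenate(pooled[k], axis=0)
        comps.append(
            GaussianComponent(
                mu=Xk.mean(axis=0),
                sigma=np.cov(Xk, rowvar=False)
                + 1e-12 * np.eye(Xk.shape[1]),
                weight=float(params.pi[k]),
            )
        )
    return comps


@dataclass(frozen=True)
class ChernoffRatioResult:
    """rho_A, rho_L and their ratio rho = rho_A / rho_L for an SBM."""

    rho_A: float
    rho_L: float
    rho: float
    pairs_A: dict
    pairs_L: dict
    meta: dict = field(default_factory=dict)


def _min_pairwise_chernoff(
    comps: Sequence[GaussianComponent],
) -> tuple[float, dict]:
    details = {}
    for i, j in itertools.combinations(range(len(comps)), 2):
        res = chernoff_information(comps[i], comps[j])
        details[(i, j)] = res
    worst = min(details.values(), key=lambda r: r.value)
    return worst.value, details


def chernoff_ratio_sbm(
    params: SBMParams,
    d: Optional[int] = None,
    n: int = 4000,
    n_graphs: int = 5,
    seed: int = 0,
) -> ChernoffRatioResult:
    """Chernoff ratio rho = rho_A / rho_L for an SBM.

    rho_A (rho_L) is the minimum over block pairs of the Chernoff
    information between the blocks' ASE (LSE) limit components, estimated
    empirically at matched n from the same seed stream.
    """
    if params.K < 2:
        raise ValueError("need at least 2 blocks")
    if d is None:
        d = params.rank_B
    comps_A = limit_gmm_params(params, "ASE", d, n=n, n_graphs=n_graphs, seed=seed)
    comps_L = limit_gmm_params(params, "LSE", d, n=n, n_graphs=n_graphs, seed=seed)
    rho_A, pairs_A = _min_pairwise_chernoff(comps_A)
    rho_L, pairs_L = _min_pairwise_chernoff(comps_L)
    return ChernoffRatioResult(
        rho_A=rho_A,
        rho_L=rho_L,
        rho=rho_A / rho_L,
        pairs_A=pairs_A,
        pairs_L=pairs_L,
        meta={"mode": "empirical", "n": n, "n_graphs": n_graphs, "seed": seed, "d": d},
    )


# ---------------------------------------------------------------------------
# Kullback–Leibler divergences and the best two-grouping analysis


def gaussian_kl(F1: GaussianComponent, F2: GaussianComponent) -> float:
    """Closed-form KL(F1 || F2) between multivariate normals."""
    if F1.d != F2.d:
        raise ValueError("dimension mismatch")
    d = F1.d
    S2inv_S1 = np.linalg.solve(F2.sigma, F1.sigma)
    dmu = F2.mu - F1.mu
    quad = float(dmu @ np.linalg.solve(F2.sigma, dmu))
    return 0.5 * (
        float(np.trace(S2inv_S1)) + quad - d + _logdet(F2.sigma) - _logdet(F1.sigma)
    )


@dataclass(frozen=True)
class MixtureKLResult:
    value: float
    se: float
    n_samples: int


def _mixture_logpdf(comps: Sequence[GaussianComponent], X: np.ndarray) -> np.ndarray:
    w = np.array([c.weight for c in comps], dtype=float)
    w = w / w.sum()
    parts = np.empty((len(X), len(comps)))
    for k, c in enumerate(comps):
        diff = X - c.mu
        L = _chol_or_raise(c.sigma)
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        parts[:, k] = (
            np.log(w[k]) - 0.5 * (c.d * np.log(2 * np.pi) + logdet + maha)
        )
    return logsumexp(parts, axis=1)


def _sample_mixture(
    comps: Sequence[GaussianComponent], n: int, rng: np.random.Generator
) -> np.ndarray:
    w = np.array([c.weight for c in comps], dtype=float)
    w = w / w.sum()
    counts = rng.multinomial(n, w)
    draws = []
    for c, m in zip(comps, counts):
        if m:
            draws.append(rng.multivariate_normal(c.mu, c.sigma, size=m))
    return np.concatenate(draws, axis=0)


def mixture_kl_numeric(
    P: Sequence[GaussianComponent],
    Q: Sequence[GaussianComponent],
    n_samples: int = 100_000,
    seed: int = 0,
) -> MixtureKLResult:
    """Monte-Carlo KL(P || Q) between Gaussian mixtures.

    Samples from P and averages log p - log q; the value is clamped at 0
    from below and reported with its standard error.
    """
    rng = np.random.default_rng(seed)
    X = _sample_mixture(P, n_samples, rng)
    diff = _mixture_logpdf(P, X) - _mixture_logpdf(Q, X)
    val = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(len(diff)))
    return MixtureKLResult(value=max(val, 0.0), se=se, n_samples=n_samples)


@dataclass(frozen=True)
class GroupingResult:
    """Divergences over bipartitions of four components into two clusters."""

    partitions: list
    divergences: list
    best: tuple


def _bipartitions_of_four() -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    out = []
    items = (0, 1, 2, 3)
    for r in (1, 2):
        for cell in itertools.combinations(items, r):
            rest = tuple(i for i in items if i not in cell)
            if r == 2 and cell > rest:
                continue  # each 2-2 split once
            out.append((cell, rest))
    return out


def best_two_grouping(
    components: Sequence[GaussianComponent],
    mode: str = "ordered-kl",
    seed: int = 0,
    n_samples: int = 100_000,
) -> GroupingResult:
    """Find the bipartition of four Gaussians maximizing between-cell KL.

    Each cell of a bipartition becomes a weight-renormalized mixture and
    the cells are compared by Monte-Carlo KL.  ``ordered-kl`` evaluates the
    four 1-vs-3 splits once (first cell as the KL reference) and the three
    2-vs-2 splits in both directions — ten evaluations; ``symmetrized-kl``
    evaluates the seven unordered bipartitions with the symmetrized KL.
    The best grouping is the partition achieving the largest divergence.
    """
    if len(components) != 4:
        raise ValueError("exactly 4 components required")
    rng = np.random.default_rng(seed)
    partitions = []
    divergences = []
    for cell1, cell2 in _bipartitions_of_four():
        P = [components[i] for i in cell1]
        Q = [components[i] for i in cell2]
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        if mode == "ordered-kl":
            partitions.append((cell1, cell2))
            divergences.append(mixture_kl_numeric(P, Q, n_samples, seed=s1).value)
            if len(cell1) == 2:  # 2-2 splits in both directions
                partitions.append((cell2, cell1))
                divergences.append(
                    mixture_kl_numeric(Q, P, n_samples, seed=s2).value
                )
        elif mode == "symmetrized-kl":
            partitions.append((cell1, cell2))
            kl1 = mixture_kl_numeric(P, Q, n_samples, seed=s1).value
            kl2 = mixture_kl_numeric(Q, P, n_samples, seed=s2).value
            divergences.append(0.5 * (kl1 + kl2))
        else:
            raise ValueError("mode must be 'ordered-kl' or 'symmetrized-kl'")
    best = partitions[int(np.argmax(divergences))]
    best = tuple(sorted((tuple(sorted(best[0])), tuple(sorted(best[1])))))
    return GroupingResult(partitions=partitions, divergences=divergences, best=best)
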