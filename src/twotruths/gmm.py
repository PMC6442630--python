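"""Gaussian-mixture clustering of embedded vertices with BIC choice of K.

Spectral embedding limit theory makes the embedded vertices of a K-block
SBM approximately a K-component Gaussian mixture with full (block-specific)
covariances, so clustering is maximum-likelihood EM over unconstrained
Gaussian mixtures.  The number of components is chosen by maximizing the
penalized likelihood 2*loglik - dim(theta_K)*ln(n), with
dim(theta_K) = (K-1) + K*d + K*d(d+1)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "GMMFit",
    "Clustering",
    "fit_gmm",
    "em_loglik_trace",
    "select_k_bic",
    "assign_clusters",
]


@dataclass(frozen=True)
class GMMFit:
    """Fitted Gaussian mixture: parameters, total log-likelihood and BIC."""

    K: int
    weights: np.ndarray
    means: np.ndarray  # K x d
    covariances: np.ndarray  # K x d x d, full
    loglik: float  # total (summed over the n observations)
    n: int
    d: int

    @property
    def theta_dim(self) -> int:
        K, d = self.K, self.d
        return (K - 1) + K * d + K * d * (d + 1) // 2

    @property
    def bic_value(self) -> float:
        """Penalized likelihood 2*loglik - theta_dim*ln(n); larger is better."""
        return 2.0 * self.loglik - self.theta_dim * np.log(self.n)


@dataclass(frozen=True)
class Clustering:
    """Hard partition of items into clusters 0..K-1 (every index occupied)."""

    labels: np.ndarray
    K: int

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", lab)
        occupied = np.unique(lab)
        if not np.array_equal(occupied, np.arange(self.K)):
            raise ValueError("labels must use every index in 0..K-1")

    def __len__(self) -> int:
        return len(self.labels)


def _reg_covar(X: np.ndarray) -> float:
    """Covariance floor 1e-6 * trace(cov(X)) / d, bounded away from zero."""
    d = X.shape[1]
    tr = float(np.trace(np.atleast_2d(np.cov(X, rowvar=False))))
    return max(1e-6 * tr / d, 1e-12)


def fit_gmm(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> GMMFit:
    """Maximum-likelihood EM fit of a K-component full-covariance mixture.

    Best of ``n_init`` k-means++-seeded initializations by log-likelihood;
    a data-scaled diagonal floor keeps near-degenerate components
    invertible.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n <= K:
        raise ValueError("need more observations than mixture components")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        tol=tol,
        max_iter=max_iter,
        reg_covar=_reg_covar(X),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    loglik = float(gm.score(X) * n)
    return GMMFit(
        K=K,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        loglik=loglik,
        n=n,
        d=d,
    )


def em_loglik_trace(
    X: np.ndarray, K: int, seed: int = 0, max_iter: int = 100, tol: float = 1e-8
) -> np.ndarray:
    """Per-iteration total log-likelihood of a single EM run.

    Steps EM one iteration at a time (warm-started) so the monotone ascent
    of the likelihood can be inspected directly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=1,
        init_params="k-means++",
        max_iter=1,
        warm_start=True,
        tol=0.0,
        reg_covar=_reg_covar(X),
        random_state=seed,
    )
    trace = []
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        trace.append(float(gm.score(X) * n))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return np.asarray(trace)


def select_k_bic(
    X: np.ndarray,
    K_range: Iterable[int] = range(1, 51),
    seed: int = 0,
    n_init: int = 5,
) -> tuple[int, dict[int, GMMFit]]:
    """Fit mixtures over a K range; return the BIC argmax and all fits.

    Ties break toward smaller K; a K whose fit fails is skipped with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    fits: dict[int, GMMFit] = {}
    for K in K_range:
        try:
            fits[K] = fit_gmm(X, K, seed=seed, n_init=n_init)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"GMM fit failed for K={K}: {exc}")
    if not fits:
        raise RuntimeError("every mixture fit failed")
    ks = sorted(fits)
    bics = np.array([fits[K].bic_value for K in ks])
    K_hat = ks[int(np.argmax(bics))]
    return K_hat, fits


def _component_log_densities(fit: GMMFit, X: np.ndarray) -> np.ndarray:
    """n x K matrix of log(weight_k) + log N(x | mu_k, Sigma_k)."""
    n, d = X.shape
    out = np.empty((n, fit.K))
    for k in range(fit.K):
        diff = X - fit.means[k]
        L = np.linalg.cholesky(fit.covariances[k])
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = (
            np.log(fit.weights[k])
            - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        )
    return out


def assign_clusters(fit: GMMFit, X: np.ndarray) -> Clustering:
    """MAP hard assignment under the fitted posterior.

    Ties go to the lower component index; components left empty are
    removed and the labels compacted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != fit.d:
        raise ValueError("data dimension does not match the fit")
    labels = np.argmax(_component_log_densities(fit, X), axis=1)
    occupied = np.unique(labels)
    remap = np.full(fit.K, -1, dtype=np.int64)
    remap[occupied] = np.arange(len(occupied))
    return Clustering(labels=remap[labels], K=len(occupied))
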