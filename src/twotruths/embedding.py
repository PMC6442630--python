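"""Adjacency and Laplacian spectral embedding with scree-based dimension choice.

Both embeddings use the scaled top eigenvectors of a symmetric matrix: the
adjacency A itself (ASE) or the normalized Laplacian
L(A) = D^{-1/2} A D^{-1/2} (LSE).  The top d eigenpairs are selected by
eigenvalue magnitude and each vertex is mapped to the corresponding row of
X = U_d |S_d|^{1/2}.

The embedding dimension can be chosen automatically from the scree of
eigenvalue magnitudes via the profile-likelihood singular-value-threshold
criterion: the split maximizing a two-group Gaussian profile likelihood
with pooled variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .graph import Graph

__all__ = [
    "Embedding",
    "SpectrumInfo",
    "normalized_laplacian",
    "spectral_embed",
    "embed_matrix",
    "profile_likelihood_svt",
    "embed_auto",
]

_DENSE_CUTOFF = 200  # below this, a full dense eigendecomposition is cheaper


@dataclass
class Embedding:
    """n x d matrix of scaled spectral coordinates plus provenance."""

    X: np.ndarray
    eigenvalues: np.ndarray  # signed, ordered by descending magnitude
    method: str  # "ASE" or "LSE"
    d: int
    spectrum: Optional[np.ndarray] = None  # full magnitudes used for d selection
    d_hat: Optional[int] = None


@dataclass(frozen=True)
class SpectrumInfo:
    """Ordered (descending) eigenvalue magnitudes of A or L(A)."""

    values: np.ndarray
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if (np.diff(v) > 1e-12).any() or (v < -1e-12).any():
            raise ValueError("spectrum values must be nonincreasing and nonnegative")


def normalized_laplacian(g: Graph) -> sp.csr_matrix:
    """L = D^{-1/2} A D^{-1/2}; requires every vertex to have degree >= 1."""
    deg = g.degrees()
    if (deg == 0).any():
        raise ValueError(
            "graph has zero-degree vertices; extract the largest connected "
            "component before Laplacian embedding"
        )
    dinv = 1.0 / np.sqrt(deg.astype(float))
    Dinv = sp.diags(dinv)
    return sp.csr_matrix(Dinv @ g.adjacency.astype(float) @ Dinv)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive (first on ties)."""
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def _top_eigenpairs(
    M: Union[np.ndarray, sp.spmatrix], k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric matrix, by eigenvalue magnitude.

    Uses a sparse Lanczos solver with a seeded start vector for large
    problems and a dense eigendecomposition for small ones (or k close
    to n, where Lanczos is unreliable).
    """
    n = M.shape[0]
    if k < 1 or k > n - 1:
        raise ValueError("need 1 <= k <= n-1")
    if n <= _DENSE_CUTOFF or k > (n - 2) // 2 or not sp.issparse(M):
        A = M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)
        w, V = np.linalg.eigh(A)
    else:
        v0 = np.random.default_rng(seed).standard_normal(n)
        w, V = eigsh(M.astype(float), k=k, which="LM", v0=v0)
    order = np.argsort(-np.abs(w), kind="stable")[:k]
    return w[order], _fix_signs(V[:, order].copy())


def embed_matrix(
    M: Union[np.ndarray, sp.spmatrix], d: int, method: str = "ASE", seed: int = 0
) -> Embedding:
    """Spectral embedding X = U_d |S_d|^{1/2} of an arbitrary symmetric matrix.

    Useful for embedding expectation matrices P = Z B Z^T or composite
    weighted adjacencies directly.
    """
    w, V = _top_eigenpairs(M, d, seed=seed)
    X = V * np.sqrt(np.abs(w))
    return Embedding(X=X, eigenvalues=w, method=method, d=d)


def spectral_embed(g: Graph, method: str, d: int, seed: int = 0) -> Embedding:
    """Embed a graph at a fixed dimension via ASE or LSE."""
    method = method.upper()
    if method == "ASE":
        M: Union[np.ndarray, sp.spmatrix] = g.adjacency.astype(float)
    elif method == "LSE":
        M = normalized_laplacian(g)
    else:
        raise ValueError("method must be 'ASE' or 'LSE'")
    if not (1 <= d <= g.n - 1):
        raise ValueError("need 1 <= d <= n-1")
    emb = embed_matrix(M, d, method=method, seed=seed)
    return emb


# ---------------------------------------------------------------------------
# Profile-likelihood singular value thresholding


def _split_loglik(v: np.ndarray, d: int) -> float:
    """Profile log-likelihood of splitting v into v[:d] and v[d:].

    Both groups are modeled as Gaussians with distinct means and a pooled
    common variance (maximum-likelihood plug-in).  A zero pooled variance
    (both groups constant) fits perfectly: +inf.
    """
    g1, g2 = v[:d], v[d:]
    m = len(v)
    ss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    sigma2 = ss / m
    if sigma2 <= np.finfo(float).tiny:
        return np.inf
    return -0.5 * m * (np.log(2 * np.pi * sigma2) + 1.0)


def _one_elbow(v: np.ndarray) -> int:
    lls = np.array([_split_loglik(v, d) for d in range(1, len(v))])
    return int(np.argmax(lls)) + 1  # argmax ties break toward smaller d


def profile_likelihood_svt(
    s: Union[SpectrumInfo, np.ndarray],
    max_d: Optional[int] = None,
    elbow: int = 1,
) -> int:
    """Choose the embedding dimension from a scree of eigenvalue magnitudes.

    For each candidate split d the leading d values and the remaining
    values (through ``max_d``) are modeled as two Gaussians with a pooled
    variance; d-hat maximizes the profile likelihood, ties toward smaller
    d.  With ``elbow > 1`` the procedure recurses on the tail beyond the
    previous elbow, returning the cumulative index.
    """
    v = s.values if isinstance(s, SpectrumInfo) else np.asarray(s, dtype=float)
    if max_d is None:
        max_d = len(v)
    if max_d > len(v):
        raise ValueError("max_d exceeds the number of spectrum values")
    v = v[:max_d]
    if len(v) < 3:
        raise ValueError("need at least 3 spectrum values")
    if np.ptp(v) <= np.finfo(float).tiny:
        raise ValueError("all spectrum values identical: no elbow exists")
    if elbow < 1:
        raise ValueError("elbow must be >= 1")
    offset = 0
    for _ in range(elbow):
        tail = v[offset:]
        if len(tail) < 2:
            raise ValueError("elbow index exceeds the available splits")
        offset += _one_elbow(tail)
    return offset


def embed_auto(
    g: Graph,
    method: str,
    max_d: Optional[int] = None,
    elbow: int = 1,
    seed: int = 0,
) -> Embedding:
    """Embed at the profile-likelihood-selected dimension.

    Computes the top ``max_d`` (default min(100, n-2)) eigenpairs once,
    selects d-hat from their magnitudes, and truncates.  The scree and
    d-hat are kept on the result for provenance.
    """
    if max_d is None:
        max_d = min(100, g.n - 2)
    max_d = min(max_d, g.n - 2)
    method = method.upper()
    M = g.adjacency.astype(float) if method == "ASE" else normalized_laplacian(g)
    w, V = _top_eigenpairs(M, max_d, seed=seed)
    mags = np.abs(w)
    d_hat = profile_likelihood_svt(mags, max_d=max_d, elbow=elbow)
    X = V[:, :d_hat] * np.sqrt(mags[:d_hat])
    return Embedding(
        X=X,
        eigenvalues=w[:d_hat],
        method=method,
        d=d_hat,
        spectrum=mags,
        d_hat=d_hat,
    )
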