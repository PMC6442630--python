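"""Stochastic block model parameterization, sampling and block projections.

The stochastic block model (SBM) is parameterized by a block membership
probability vector ``pi`` on the unit simplex and a symmetric K x K block
connectivity probability matrix ``B``: conditional on memberships ``z``,
each dyad (i < j) is an independent Bernoulli(B[z_i, z_j]) edge.

The four-block "two-truths" specialization orders its blocks
(LG, LW, RG, RW) — left/right hemisphere crossed with gray/white tissue —
so that collapsing by hemisphere yields an affinity two-block model
(a ≈ c ≫ b) while collapsing by tissue yields a core–periphery model (one
block much denser than both the other block and the cross density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .graph import Graph, VertexLabels

__all__ = [
    "SBMParams",
    "TwoTruthsParams",
    "BlockProjection",
    "ProjectionCoords",
    "StructureClass",
    "sample_sbm",
    "membership_labels",
    "default_two_truths_params",
    "project_to_blocks",
    "collapse_membership",
    "collapse_params",
    "two_block_coords",
    "classify_structure",
    "validate_two_truths",
]

BLOCK_NAMES = ("LG", "LW", "RG", "RW")


@dataclass(frozen=True)
class SBMParams:
    """(K, pi, B) for a stochastic block model."""

    pi: np.ndarray
    B: np.ndarray
    block_names: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "B", B)
        if pi.ndim != 1 or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be a strictly positive simplex vector")
        K = len(pi)
        if B.shape != (K, K):
            raise ValueError("B must be K x K")
        if not np.allclose(B, B.T):
            raise ValueError("B must be symmetric")
        if (B < 0).any() or (B > 1).any():
            raise ValueError("B entries must lie in [0, 1]")
        if self.block_names is not None and len(self.block_names) != K:
            raise ValueError("block_names length must equal K")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def rank_B(self) -> int:
        return int(np.linalg.matrix_rank(self.B))

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "B": self.B.tolist(),
            "block_names": list(self.block_names) if self.block_names else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SBMParams":
        names = tuple(d["block_names"]) if d.get("block_names") else None
        return cls(pi=np.asarray(d["pi"]), B=np.asarray(d["B"]), block_names=names)


@dataclass(frozen=True)
class TwoTruthsParams:
    """Four-block SBM with blocks ordered (LG, LW, RG, RW).

    ``hemisphere`` and ``tissue`` map each block index 0..3 to its level on
    the corresponding binary track.
    """

    base: SBMParams
    hemisphere: tuple[str, ...] = ("Left", "Left", "Right", "Right")
    tissue: tuple[str, ...] = ("Gray", "White", "Gray", "White")

    def __post_init__(self):
        if self.base.K != 4:
            raise ValueError("two-truths model requires K=4")
        if len(self.hemisphere) != 4 or len(self.tissue) != 4:
            raise ValueError("label tracks must map all four blocks")

    def track_map(self, track: str) -> tuple[str, ...]:
        if track == "hemisphere":
            return self.hemisphere
        if track == "tissue":
            return self.tissue
        raise ValueError("track must be 'hemisphere' or 'tissue'")


def default_two_truths_params() -> TwoTruthsParams:
    """The default four-block two-truths model.

    pi = [0.28, 0.22, 0.28, 0.22] over (LG, LW, RG, RW).  The connectivity
    matrix emulates a composite connectome: gray matter connects almost
    exclusively within its own hemisphere (strong lateralization of the
    sparse blocks), while white matter is a dense core that also couples
    heavily across hemispheres (callosal connectivity), so its
    lateralization is weak.  Consequently the hemisphere collapse is an
    affinity two-block model, the tissue collapse is core–periphery, and
    at d = K = 2 Laplacian embedding recovers the hemisphere bipartition
    while adjacency embedding recovers the tissue bipartition.
    """
    B = np.array(
        [
            [0.020, 0.045, 0.002, 0.005],
            [0.045, 0.130, 0.005, 0.115],
            [0.002, 0.005, 0.020, 0.045],
            [0.005, 0.115, 0.045, 0.130],
        ]
    )
    base = SBMParams(
        pi=np.array([0.28, 0.22, 0.28, 0.22]), B=B, block_names=BLOCK_NAMES
    )
    return TwoTruthsParams(base=base)


# ---------------------------------------------------------------------------
# Sampling


def _draw_memberships(
    pi: np.ndarray,
    n: int,
    rng: np.random.Generator,
    block_sizes: str,
    max_retries: int = 100,
) -> np.ndarray:
    K = len(pi)
    if block_sizes == "multinomial":
        for _ in range(max_retries):
            z = rng.choice(K, size=n, p=pi)
            if len(np.unique(z)) == K:
                return z
        raise ValueError(
            f"multinomial membership draw left a block empty in {max_retries} tries"
        )
    if block_sizes == "proportional-fixed":
        counts = np.floor(n * pi).astype(int)
        # largest-remainder rounding to make counts sum to n
        rem = n * pi - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
        if (counts == 0).any():
            raise ValueError("fixed proportional sizing leaves a block empty")
        return np.repeat(np.arange(K), counts)
    raise ValueError("block_sizes must be 'multinomial' or 'proportional-fixed'")


def sample_sbm(
    params: SBMParams,
    n: int,
    seed: Union[int, np.random.Generator] = 0,
    block_sizes: str = "multinomial",
) -> tuple[Graph, np.ndarray]:
    """Sample a graph from an SBM.

    Memberships are drawn multinomial(pi) (resampled, up to 100 tries, if a
    block comes up empty) or fixed at the rounded proportions; each dyad
    i < j is then an independent Bernoulli(B[z_i, z_j]).

    Returns
    -------
    (Graph, z) : the sampled graph and the true block memberships.
    """
    if n < params.K:
        raise ValueError("n must be at least the number of blocks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = _draw_memberships(params.pi, n, rng, block_sizes)

    # Row-chunked upper-triangular Bernoulli thresholding keeps peak memory
    # modest for n in the thousands.
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    chunk = 2048
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        P = params.B[np.ix_(z[start:stop], z)]
        U = rng.random((stop - start, n))
        hit = U < P
        # keep strictly upper-triangular part (global indices)
        ri, rj = np.nonzero(hit)
        ri = ri + start
        keep = rj > ri
        rows_i.append(ri[keep])
        rows_j.append(rj[keep])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    data = np.ones(len(i), dtype=np.int8)
    A = sp.coo_matrix((data, (i, j)), shape=(n, n)).tocsr()
    A = A + A.T
    return Graph(n=n, adjacency=A), z


def membership_labels(tt: TwoTruthsParams, z: np.ndarray) -> VertexLabels:
    """Map sampled block indices to hemisphere/tissue label tracks."""
    hemi = np.asarray(tt.hemisphere, dtype=object)[z]
    tiss = np.asarray(tt.tissue, dtype=object)[z]
    return VertexLabels(hemisphere=hemi, tissue=tiss)


def sample_two_truths(
    tt: TwoTruthsParams,
    n: int,
    seed: Union[int, np.random.Generator] = 0,
    block_sizes: str = "multinomial",
) -> tuple[Graph, np.ndarray]:
    """Sample from the four-block model, attaching both label tracks."""
    g, z = sample_sbm(tt.base, n, seed=seed, block_sizes=block_sizes)
    g.labels = membership_labels(tt, z)
    return g, z


# ---------------------------------------------------------------------------
# A priori projections


@dataclass(frozen=True)
class BlockProjection:
    """Plug-in block density estimates for a known membership."""

    levels: tuple
    B_hat: np.ndarray
    pi_hat: np.ndarray
    edge_counts: np.ndarray
    dyad_counts: np.ndarray


def project_to_blocks(g: Graph, membership: np.ndarray) -> BlockProjection:
    """Estimate (pi, B) by projecting a graph onto known block memberships.

    ``B_hat[k, l]`` is edges(k, l) / dyads(k, l), where within-block dyad
    counts are n_k (n_k - 1) / 2.  Blocks with fewer than two vertices have
    an undefined within-block density, reported as NaN with a warning.
    """
    membership = np.asarray(membership)
    if len(membership) != g.n:
        raise ValueError("membership length must equal vertex count")
    levels, codes = np.unique(membership, return_inverse=True)
    Kp = len(levels)
    counts = np.bincount(codes, minlength=Kp)
    Z = sp.csr_matrix(
        (np.ones(g.n), (np.arange(g.n), codes)), shape=(g.n, Kp)
    )
    M = np.asarray((Z.T @ g.adjacency @ Z).todense(), dtype=float)
    edge_counts = M.copy()
    edge_counts[np.diag_indices(Kp)] /= 2.0  # within edges double-counted
    dyads = np.outer(counts, counts).astype(float)
    dyads[np.diag_indices(Kp)] = counts * (counts - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        B_hat = edge_counts / dyads
    if (counts < 2).any():
        warnings.warn(
            "block(s) with < 2 vertices: within-block density undefined (NaN)"
        )
    return BlockProjection(
        levels=tuple(levels),
        B_hat=B_hat,
        pi_hat=counts / g.n,
        edge_counts=edge_counts,
        dyad_counts=dyads,
    )


def collapse_membership(labels: VertexLabels, track: str) -> np.ndarray:
    """Per-vertex two-level membership for one track of the label pair."""
    if track == "hemisphere":
        return labels.hemisphere
    if track == "tissue":
        return labels.tissue
    raise ValueError("track must be 'hemisphere' or 'tissue'")


def collapse_params(tt: TwoTruthsParams, track: str) -> SBMParams:
    """Exact two-block aggregation of the four-block model along one track.

    Merged densities are pi-weighted dyad averages,
    ``B2[u, v] = sum_{k in Gu, l in Gv} pi_k pi_l B[k, l] / (pi_Gu pi_Gv)``
    (ordered double sums, so within-group diagonal terms carry weight
    pi_k^2), which preserves the expected edge density exactly.
    """
    tmap = np.asarray(tt.track_map(track), dtype=object)
    levels = sorted(set(tmap))
    pi, B = tt.base.pi, tt.base.B
    K2 = len(levels)
    pi2 = np.zeros(K2)
    B2 = np.zeros((K2, K2))
    groups = [np.flatnonzero(tmap == lev) for lev in levels]
    for u, gu in enumerate(groups):
        pi2[u] = pi[gu].sum()
        for v, gv in enumerate(groups):
            w = np.outer(pi[gu], pi[gv])
            B2[u, v] = (w * B[np.ix_(gu, gv)]).sum() / w.sum()
    return SBMParams(pi=pi2, B=B2, block_names=tuple(levels))


# ---------------------------------------------------------------------------
# Two-block coordinates and structure taxonomy


@dataclass(frozen=True)
class ProjectionCoords:
    """(x, y) = (min(a,c)/max(a,c), b/max(a,c)) for a two-block B=[a,b;b,c]."""

    a: float
    b: float
    c: float
    x: float
    y: float


def two_block_coords(a: float, b: float, c: float) -> ProjectionCoords:
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    m = max(a, c)
    if m <= 0:
        raise ValueError("max(a, c) must be positive")
    return ProjectionCoords(a=a, b=b, c=c, x=min(a, c) / m, y=b / m)


StructureClass = str  # one of "affinity", "core-periphery", "neither"


def classify_structure(
    a: float, b: float, c: float, margin: float = 2.0
) -> StructureClass:
    """Classify a two-block B=[a,b;b,c] by its dominance pattern.

    Affinity means both within-block densities dominate the between-block
    density (min(a,c) >= margin*b); core–periphery means one block dominates
    both the other densities (max(a,c) >= margin*max(b, min(a,c))).
    Affinity is checked first.
    """
    if margin < 1.0:
        raise ValueError("margin must be >= 1")
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if min(a, c) >= margin * b:
        return "affinity"
    if max(a, c) >= margin * max(b, min(a, c)):
        return "core-periphery"
    return "neither"


@dataclass(frozen=True)
class TwoTruthsReport:
    """Result of checking that a four-block model exhibits two truths."""

    tracks: dict
    passed: bool


def validate_two_truths(
    tt: TwoTruthsParams,
    margin: float = 2.0,
    chernoff_n: int = 2000,
    chernoff_graphs: int = 2,
    seed: int = 0,
) -> TwoTruthsReport:
    """Check the two-truths property of a four-block model.

    Passes iff the hemisphere collapse is affinity with Chernoff ratio
    rho < 1 (LSE preferred) and the tissue collapse is core–periphery with
    rho > 1 (ASE preferred).  Chernoff ratios are estimated empirically on
    the collapsed two-block models.
    """
    from .assessment import chernoff_ratio_sbm

    tracks = {}
    ok = {}
    for track, want_class, want_rho in (
        ("hemisphere", "affinity", "lt1"),
        ("tissue", "core-periphery", "gt1"),
    ):
        p2 = collapse_params(tt, track)
        a, b, c = p2.B[0, 0], p2.B[0, 1], p2.B[1, 1]
        coords = two_block_coords(a, b, c)
        cls = classify_structure(a, b, c, margin=margin)
        ratio = chernoff_ratio_sbm(
            p2, d=2, n=chernoff_n, n_graphs=chernoff_graphs, seed=seed
        )
        rho_ok = ratio.rho < 1.0 if want_rho == "lt1" else ratio.rho > 1.0
        ok[track] = (cls == want_class) and rho_ok
        tracks[track] = {
            "a": a,
            "b": b,
            "c": c,
            "coords": coords,
            "structure": cls,
            "chernoff": ratio,
        }
    return TwoTruthsReport(tracks=tracks, passed=bool(ok["hemisphere"] and ok["tissue"]))
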