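"""End-to-end orchestration of the two-truths analysis.

Pieces:

* ``spectral_cluster_graph`` — GMM composed with ASE or LSE on one graph,
  with automatic or fixed choices of the embedding dimension d and the
  number of clusters K;
* ``two_truths_experiment`` — the Monte-Carlo study: sample graphs from
  the four-block two-truths SBM, cluster each with both embeddings at
  d = K = 2, and score each clustering against both binary truths
  (hemisphere and tissue) by ARI;
* ``eda_projection_points`` — the exploratory two-block projection map for
  a collection of labeled graphs, plotting each graph twice at
  (x, y) = (min(a,c)/max(a,c), b/max(a,c));
* ``chernoff_map`` — the Chernoff-ratio background over that coordinate
  plane, with the rho = 1 contour separating the region where adjacency
  embedding is preferred from where Laplacian embedding is.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import sbm as _sbm
from .assessment import ari, chernoff_ratio_sbm
from .embedding import embed_auto, spectral_embed
from .gmm import Clustering, assign_clusters, fit_gmm, select_k_bic
from .graph import Graph, largest_connected_component
from .sbm import (
    SBMParams,
    TwoTruthsParams,
    collapse_membership,
    classify_structure,
    default_two_truths_params,
    project_to_blocks,
    sample_two_truths,
    two_block_coords,
    validate_two_truths,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "MapGrid",
    "spectral_cluster_graph",
    "two_truths_experiment",
    "eda_projection_points",
    "chernoff_map",
    "delta_ari_summary",
]


@dataclass
class ExperimentConfig:
    """Configuration of the Monte-Carlo two-truths experiment."""

    tt_params: TwoTruthsParams = field(default_factory=default_two_truths_params)
    n: int = 4000
    n_reps: int = 50
    d: Union[int, str] = 2  # embedding dimension, or "auto"
    K: Union[int, str] = 2  # number of clusters, or "auto"
    seed: int = 0
    ari_threshold: float = 0.95
    max_d: int = 50  # scree depth when d == "auto"
    k_max: int = 10  # BIC range when K == "auto"
    validate: bool = True

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.ari_threshold < 1.0):
            raise ValueError("ari_threshold must be in (0, 1)")


def spectral_cluster_graph(
    g: Graph,
    method: str,
    d: Union[int, str] = "auto",
    K: Union[int, str] = "auto",
    seed: int = 0,
    max_d: int = 100,
    k_max: int = 50,
) -> tuple[Clustering, dict]:
    """GMM o {ASE, LSE}: embed, fit a Gaussian mixture, MAP-assign.

    Non-connected input is reduced to its largest connected component with
    a warning (the diagnostics carry the index map).  Deterministic given
    (graph, seed).
    """
    diagnostics: dict = {"method": method.upper()}
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(g.adjacency, directed=False)
    if n_comp > 1:
        warnings.warn("graph not connected: clustering its largest component")
        g, index_map = largest_connected_component(g)
        diagnostics["lcc_index_map"] = index_map
    if d == "auto":
        emb = embed_auto(g, method, max_d=max_d, seed=seed)
    else:
        emb = spectral_embed(g, method, int(d), seed=seed)
    diagnostics["d"] = emb.d
    diagnostics["eigenvalues"] = emb.eigenvalues
    if emb.spectrum is not None:
        diagnostics["spectrum"] = emb.spectrum
    if K == "auto":
        K_hat, fits = select_k_bic(emb.X, K_range=range(1, k_max + 1), seed=seed)
        fit = fits[K_hat]
        diagnostics["bic_trace"] = {k: f.bic_value for k, f in fits.items()}
    else:
        fit = fit_gmm(emb.X, int(K), seed=seed)
    diagnostics["K"] = fit.K
    clustering = assign_clusters(fit, emb.X)
    return clustering, diagnostics


@dataclass
class ExperimentResult:
    """Per-replicate ARIs and the derived summary of the experiment."""

    replicates: pd.DataFrame
    summary: dict
    config: ExperimentConfig
    n_failed: int = 0


def two_truths_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the Monte-Carlo two-truths experiment.

    Per replicate: sample a graph from the four-block model, run
    GMM o LSE and GMM o ASE, and compute ARI against the hemisphere and
    tissue truths.  The summary reports the fraction of replicates in
    which each method finds each truth above ``ari_threshold``, the mean
    delta-ARI coordinates and their quadrant fractions.
    """
    if cfg.validate:
        report = validate_two_truths(cfg.tt_params, seed=cfg.seed)
        if not report.passed:
            warnings.warn(
                "tt_params failed the two-truths validation; proceeding anyway"
            )
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    n_failed = 0
    for rep, child in enumerate(ss.spawn(cfg.n_reps)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            rows.append(_run_replicate(cfg, rep, rep_seed))
        except Exception as exc:
            warnings.warn(f"replicate {rep} failed: {exc}")
            n_failed += 1
    df = pd.DataFrame(rows)
    summary = _summarize(df, cfg) if len(df) else {}
    summary["n_failed"] = n_failed
    return ExperimentResult(replicates=df, summary=summary, config=cfg, n_failed=n_failed)


def _run_replicate(cfg: ExperimentConfig, rep: int, seed: int) -> dict:
    g, _ = sample_two_truths(cfg.tt_params, cfg.n, seed=seed)
    g, index_map = largest_connected_component(g)
    truth_h = collapse_membership(g.labels, "hemisphere")
    truth_t = collapse_membership(g.labels, "tissue")
    row: dict = {"rep": rep, "seed": seed, "n_lcc": g.n}
    for method in ("LSE", "ASE"):
        clus, diag = spectral_cluster_graph(
            g, method, d=cfg.d, K=cfg.K, seed=seed,
            max_d=cfg.max_d, k_max=cfg.k_max,
        )
        m = method.lower()
        row[f"ari_{m}_hemisphere"] = ari(clus.labels, truth_h)
        row[f"ari_{m}_tissue"] = ari(clus.labels, truth_t)
        row[f"d_{m}"] = diag["d"]
        row[f"K_{m}"] = diag["K"]
    row["x_rep"] = row["ari_lse_hemisphere"] - row["ari_lse_tissue"]
    row["y_rep"] = row["ari_ase_hemisphere"] - row["ari_ase_tissue"]
    return row


def _summarize(df: pd.DataFrame, cfg: ExperimentConfig) -> dict:
    thr = cfg.ari_threshold
    quads = _quadrant_fractions(df)
    return {
        "n_reps": len(df),
        "frac_lse_hemisphere": float((df["ari_lse_hemisphere"] > thr).mean()),
        "frac_ase_tissue": float((df["ari_ase_tissue"] > thr).mean()),
        "frac_lse_tissue": float((df["ari_lse_tissue"] > thr).mean()),
        "frac_ase_hemisphere": float((df["ari_ase_hemisphere"] > thr).mean()),
        "mean_x": float(df["x_rep"].mean()),
        "mean_y": float(df["y_rep"].mean()),
        "quadrant_fractions": quads,
    }


def _quadrant_fractions(df: pd.DataFrame) -> dict:
    x, y = df["x_rep"].to_numpy(), df["y_rep"].to_numpy()
    return {
        "(+,+)": float(((x > 0) & (y > 0)).mean()),
        "(+,-)": float(((x > 0) & (y < 0)).mean()),
        "(-,+)": float(((x < 0) & (y > 0)).mean()),
        "(-,-)": float(((x < 0) & (y < 0)).mean()),
    }


def delta_ari_summary(result: ExperimentResult) -> tuple[pd.DataFrame, dict]:
    """Per-replicate delta-ARI coordinates and their quadrant fractions.

    x = ARI(LSE, hemisphere) - ARI(LSE, tissue) and
    y = ARI(ASE, hemisphere) - ARI(ASE, tissue); a replicate in the (+,-)
    quadrant is one where LSE identified the hemisphere truth better and
    ASE the tissue truth better.
    """
    if result.replicates.empty:
        raise ValueError("no replicates to summarize")
    table = result.replicates[["rep", "x_rep", "y_rep"]].copy()
    quads = _quadrant_fractions(result.replicates)
    quads["mean_x"] = float(table["x_rep"].mean())
    quads["mean_y"] = float(table["y_rep"].mean())
    return table, quads


# ---------------------------------------------------------------------------
# EDA projections


def eda_projection_points(graphs: Sequence[Graph], margin: float = 2.0) -> pd.DataFrame:
    """Two-block projection coordinates for a collection of labeled graphs.

    Each graph contributes one point per track: project onto the two-block
    model of that track, convert the fitted [a, b; b, c] to
    (x, y) = (min(a,c)/max(a,c), b/max(a,c)) and classify the structure.
    """
    rows = []
    for gid, g in enumerate(graphs):
        if g.labels is None:
            raise ValueError(f"graph {gid} has no vertex labels")
        for track in ("hemisphere", "tissue"):
            proj = project_to_blocks(g, collapse_membership(g.labels, track))
            if proj.B_hat.shape != (2, 2) or np.isnan(proj.B_hat).any():
                warnings.warn(f"graph {gid}, track {track}: projection undefined")
                continue
            a, b, c = proj.B_hat[0, 0], proj.B_hat[0, 1], proj.B_hat[1, 1]
            coords = two_block_coords(a, b, c)
            rows.append(
                {
                    "graph": gid,
                    "track": track,
                    "a": a,
                    "b": b,
                    "c": c,
                    "x": coords.x,
                    "y": coords.y,
                    "structure": classify_structure(a, b, c, margin=margin),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chernoff-ratio map


@dataclass
class MapGrid:
    """Chernoff-ratio surface over the two-block coordinate plane.

    Cell (x, y) corresponds to B = [s, s*y; s*y, s*x] with pi fixed, so
    max(a, c) = s and the coordinates recover (x, y) exactly.  ``rho`` is
    the estimated Chernoff ratio per cell (NaN where estimation failed)
    and ``contours`` the rho = 1 level curves in (x, y) coordinates.  The
    y = x diagonal is the rank-1 submodel boundary (B singular there).
    """

    xs: np.ndarray
    ys: np.ndarray
    rho: np.ndarray  # shape (len(ys), len(xs))
    contours: list
    s: float
    pi: tuple
    meta: dict


def chernoff_map(
    resolution: int = 26,
    s: float = 0.1,
    pi: tuple = (0.5, 0.5),
    n: int = 1000,
    n_graphs: int = 1,
    seed: int = 0,
) -> MapGrid:
    """Estimate the Chernoff-ratio background over (x, y) in (0, 1]^2."""
    if resolution < 5:
        raise ValueError("resolution must be >= 5")
    if not (0.0 < s <= 1.0):
        raise ValueError("s must be in (0, 1]")
    xs = np.linspace(1.0 / resolution, 1.0, resolution)
    ys = np.linspace(1.0 / resolution, 1.0, resolution)
    rho = np.full((resolution, resolution), np.nan)
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(resolution * resolution) % (2**31)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            B = np.array([[s, s * y], [s * y, s * x]])
            params = SBMParams(pi=np.asarray(pi), B=B)
            try:
                res = chernoff_ratio_sbm(
                    params, d=2, n=n, n_graphs=n_graphs,
                    seed=int(seeds[iy * resolution + ix]),
                )
                rho[iy, ix] = res.rho
            except Exception as exc:
                warnings.warn(f"map cell ({x:.3f},{y:.3f}) failed: {exc}")
    contours = _rho_contours(xs, ys, rho)
    return MapGrid(
        xs=xs, ys=ys, rho=rho, contours=contours, s=s, pi=tuple(pi),
        meta={"n": n, "n_graphs": n_graphs, "seed": seed},
    )


def _rho_contours(xs: np.ndarray, ys: np.ndarray, rho: np.ndarray) -> list:
    """rho = 1 level curves, linearly interpolated to (x, y) coordinates."""
    from skimage import measure

    filled = np.where(np.isnan(rho), 1.0, rho)
    out = []
    for c in measure.find_contours(filled, 1.0):
        # c[:, 0] indexes ys, c[:, 1] indexes xs
        cx = np.interp(c[:, 1], np.arange(len(xs)), xs)
        cy = np.interp(c[:, 0], np.arange(len(ys)), ys)
        out.append(np.column_stack([cx, cy]))
    return out
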