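"""Pseudospatial ordering of cells and smooth per-gene expression profiles.

Cells are placed on a 1-D axis s in [0, 1] running from the typical-ependymal
(dorsal) end at s = 0 to the beta2-tanycyte (ventral) end at s = 1. The axis
is the rank-normalized first principal component (or first diffusion
component) of the top-variance gene space, oriented by anchor gene sets.
Per-gene profiles are least-squares cubic B-spline fits of normalized
expression on s, evaluated on a shared grid, raw and standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from ._errors import DegenerateInputError, ParameterError


@dataclass
class PseudospaceAssignment:
    s: pd.Series  # per cell, in [0, 1]
    anchors: dict
    method: str
    flipped: bool


@dataclass
class FittedProfileSet:
    """Per-gene fitted curves on a shared pseudospace grid.

    ``curves`` holds the raw spline fits (genes x grid); ``z`` the grid-
    standardized curves for the non-constant genes; ``sd`` the per-gene
    standard deviation of the fitted curve over the grid.
    """

    grid: np.ndarray
    curves: pd.DataFrame
    z: pd.DataFrame
    sd: pd.Series
    constant_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def order_cells(adata: ad.AnnData, anchors: dict,
                n_top_genes: int = 1000, method: str = "pca",
                orientation_tol: float = 1e-3) -> PseudospaceAssignment:
    """Order cells along the principal expression axis, anchored anatomically.

    ``anchors`` maps ``start_genes`` (high at s = 0) and ``end_genes`` (high at
    s = 1) to gene-name lists. The raw axis score is rank-normalized, so any
    strictly increasing transform of the score leaves s unchanged; swapping
    the anchor roles maps s to 1 - s exactly.
    """
    if adata.n_obs < 100:
        raise DegenerateInputError(f"need >= 100 cells to order, got {adata.n_obs}")
    start = [g for g in anchors.get("start_genes", []) if g in adata.var_names]
    end = [g for g in anchors.get("end_genes", []) if g in adata.var_names]
    if not start or not end:
        raise ParameterError("anchor gene lists must be non-empty and present in the matrix")

    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    var = X.var(axis=0)
    if np.all(var < 1e-12):
        raise DegenerateInputError("all genes constant; no axis signal")
    top = np.argsort(var)[::-1][: min(n_top_genes, X.shape[1])]
    Xt = X[:, top]
    Xt = Xt - Xt.mean(axis=0)
    if method == "pca":
        score = PCA(n_components=1, svd_solver="arpack", random_state=0).fit_transform(Xt)[:, 0]
    elif method == "diffusion":
        score = _diffusion_component(Xt)
    else:
        raise ParameterError(f"unknown ordering method {method!r}")

    s = _rank01(score)
    # orient: cells rich in start anchors must sit at low s
    w_start = X[:, [adata.var_names.get_loc(g) for g in start]].mean(axis=1)
    w_end = X[:, [adata.var_names.get_loc(g) for g in end]].mean(axis=1)
    m_start = float(np.average(s, weights=w_start)) if w_start.sum() > 0 else np.nan
    m_end = float(np.average(s, weights=w_end)) if w_end.sum() > 0 else np.nan
    if not np.isfinite(m_start) or not np.isfinite(m_end) or abs(m_end - m_start) < orientation_tol:
        raise DegenerateInputError(
            "anchor genes do not disambiguate orientation "
            f"(start mean s={m_start:.4f}, end mean s={m_end:.4f}); "
            "pass a manual orientation flag or different anchors")
    flipped = m_start > m_end
    if flipped:
        s = _rank01(-score)
    return PseudospaceAssignment(
        s=pd.Series(s, index=adata.obs_names, name="s"),
        anchors={"start_genes": start, "end_genes": end},
        method=method, flipped=flipped)


def _rank01(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average")
    return (r - 1.0) / (len(r) - 1.0)


def _diffusion_component(X: np.ndarray, n_neighbors: int = 15) -> np.ndarray:
    """First non-trivial eigenvector of a Gaussian-kernel diffusion operator."""
    from sklearn.neighbors import kneighbors_graph
    from scipy.sparse.linalg import eigsh

    D = kneighbors_graph(X, n_neighbors=n_neighbors, mode="distance")
    sigma = D.data.mean()
    W = D.copy()
    W.data = np.exp(-(W.data ** 2) / (2 * sigma ** 2))
    W = 0.5 * (W + W.T)
    d = np.asarray(W.sum(axis=1)).ravel()
    Dinv = sp.diags(1.0 / np.sqrt(np.maximum(d, 1e-12)))
    M = Dinv @ W @ Dinv
    vals, vecs = eigsh(M, k=2, which="LA")
    order = np.argsort(vals)[::-1]
    return vecs[:, order[1]]


def _bspline_design(x: np.ndarray, df: int, span: tuple[float, float],
                    degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of ``df`` cubic B-spline basis functions with internal
    knots at quantiles of x; returns (matrix, full knot vector)."""
    n_internal = df - (degree + 1)
    if n_internal > 0:
        qs = np.linspace(0, 1, n_internal + 2)[1:-1]
        internal = np.quantile(x, qs)
    else:
        internal = np.array([])
    lo, hi = span
    t = np.concatenate([[lo] * (degree + 1), internal, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    return B, t


def fit_profiles(adata: ad.AnnData, ps: PseudospaceAssignment,
                 G: int = 100, df: int = 6, genes: list[str] | None = None,
                 constant_sd: float = 1e-8,
                 span: tuple[float, float] = (0.0, 1.0)) -> FittedProfileSet:
    """Least-squares cubic B-spline fit of each gene's normalized expression on s.

    All genes share one design matrix, so the fit is a single linear solve.
    Genes whose fitted curve has sd < ``constant_sd`` over the grid are
    flagged constant and excluded from the standardized set.
    """
    if G < 20:
        raise ParameterError(f"G={G} too coarse; need >= 20 grid points")
    if df < 4:
        raise ParameterError(f"df={df}; cubic fits need df >= 4")
    s = ps.s.loc[adata.obs_names].to_numpy()
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    names = list(adata.var_names)
    if genes is not None:
        idx = [names.index(g) for g in genes]
        X = X[:, idx]
        names = list(genes)

    B, t = _bspline_design(s, df, span)
    grid = np.linspace(span[0], span[1], G)
    Bg = BSpline.design_matrix(grid, t, 3).toarray()
    coef, *_ = np.linalg.lstsq(B, X, rcond=None)
    fitted = (Bg @ coef).T  # genes x grid

    curves = pd.DataFrame(fitted, index=names, columns=np.round(grid, 6))
    sd = curves.std(axis=1, ddof=0)
    constant = sd.index[sd < constant_sd].tolist()
    nz = curves.drop(index=constant)
    z = nz.sub(nz.mean(axis=1), axis=0).div(sd.drop(index=constant), axis=0)
    return FittedProfileSet(grid=grid, curves=curves, z=z, sd=sd,
                            constant_genes=constant,
                            params={"G": G, "df": df})
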