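"""Specific-vs-shared marker classification by membership correlation.

Each gene's normalized expression vector is correlated with binary indicator
vectors of every candidate population subset (1 for cells in the subset, 0
otherwise). Positive, significant correlations (BH-adjusted p < alpha across
the full gene x subset family) are candidates; the gene is assigned to the
candidate subset maximizing score = r * w, where w is the equal-weight mean
of per-population mean expression within the subset. Singleton winners are
"specific" markers, larger subsets "shared" markers, and a subset joining
the two axis ends captures U-shaped profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class MembershipDesign:
    populations: list[str]
    subsets: list[tuple[str, ...]]
    indicators: np.ndarray  # cells x subsets, {0,1}
    cell_population: pd.Series

    @property
    def subset_labels(self) -> list[str]:
        return ["|".join(s) for s in self.subsets]


def make_design(adata: ad.AnnData, populations: list[str] | None = None,
                max_size: int | None = None) -> MembershipDesign:
    """Enumerate all non-empty proper subsets of the population list (30 for 5
    populations, including non-contiguous ones such as the two axis ends) and
    build their cell-indicator vectors."""
    cell_pop = adata.obs["population"].astype(str)
    if populations is None:
        populations = [p for p in
                       (adata.obs["population"].cat.categories
                        if hasattr(adata.obs["population"], "cat") else sorted(cell_pop.unique()))
                       if p in set(cell_pop)]
    max_size = max_size or len(populations) - 1
    subsets = [tuple(c) for size in range(1, max_size + 1)
               for c in combinations(populations, size)]
    onehot = np.stack([(cell_pop == p).to_numpy(float) for p in populations], axis=1)
    pop_index = {p: i for i, p in enumerate(populations)}
    ind = np.stack([onehot[:, [pop_index[p] for p in s]].sum(axis=1) for s in subsets], axis=1)
    return MembershipDesign(populations=list(populations), subsets=subsets,
                            indicators=ind, cell_population=cell_pop)


def _pearson_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between X (n x p) and Y (n x q) -> p x q."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Yc) / np.outer(sx, sy)
    R[~np.isfinite(R)] = np.nan
    return R


def correlate_memberships(adata: ad.AnnData, design: MembershipDesign,
                          alpha: float = 0.01, min_cells: int = 3) -> pd.DataFrame:
    """Pearson r and two-sided p for every (gene, subset); BH across the whole
    family; keep candidates with r > 0 and p_adj < alpha."""
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    n = X.shape[0]
    ok = design.indicators.sum(axis=0) >= min_cells
    for lab, keep in zip(design.subset_labels, ok):
        if not keep:
            log.warning("subset %s has < %d cells; skipped", lab, min_cells)
    ind = design.indicators[:, ok]
    labels = [l for l, k in zip(design.subset_labels, ok) if k]

    R = _pearson_matrix(X, ind)
    # two-sided p via the exact beta distribution of r^2 under the null
    ab = (n - 2) / 2.0
    with np.errstate(invalid="ignore"):
        P = 2 * beta_dist.sf((1 + np.abs(R)) / 2, ab, ab)
    valid = np.isfinite(R)
    genes = np.repeat(list(adata.var_names), len(labels))
    subs = np.tile(labels, adata.n_vars)
    df = pd.DataFrame({"gene": genes, "subset": subs,
                       "r": R.ravel(), "p": P.ravel(),
                       "valid": valid.ravel()})
    df = df[df["valid"]].drop(columns="valid")
    if len(df) == 0:
        df["p_adj"] = pd.Series(dtype=float)
        return df.reset_index(drop=True)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[(df["r"] > 0) & (df["p_adj"] < alpha)].reset_index(drop=True)


def assign_markers(candidates: pd.DataFrame, adata: ad.AnnData,
                   design: MembershipDesign,
                   weighting: str = "population") -> pd.DataFrame:
    """Score candidates (score = r * w) and assign each gene its argmax subset.

    ``weighting='population'`` sets w to the equal-weight mean of per-population
    mean expression over the subset's populations; ``'cell'`` uses the plain
    mean over the subset's cells. Ties break toward the smaller subset, then
    lexicographically. Genes with no passing candidate are absent (callers
    may treat them as "unclassified").
    """
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    pop_means = {}
    for p in design.populations:
        mask = (design.cell_population == p).to_numpy()
        pop_means[p] = X[mask].mean(axis=0) if mask.any() else np.zeros(X.shape[1])
    gene_idx = {g: i for i, g in enumerate(adata.var_names)}

    cand = candidates.copy()
    w = np.empty(len(cand))
    for j, (g, lab) in enumerate(zip(cand["gene"], cand["subset"])):
        pops = lab.split("|")
        gi = gene_idx[g]
        if weighting == "population":
            w[j] = float(np.mean([pop_means[p][gi] for p in pops]))
        elif weighting == "cell":
            mask = design.cell_population.isin(pops).to_numpy()
            w[j] = float(X[mask, gi].mean())
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    cand["w"] = w
    cand["score"] = cand["r"] * cand["w"]
    cand["subset_size"] = cand["subset"].str.count(r"\|") + 1

    cand = cand.sort_values(["gene", "score", "subset_size", "subset"],
                            ascending=[True, False, True, True], kind="mergesort")
    best = cand.groupby("gene", sort=True).head(1).set_index("gene")
    n_cand = candidates.groupby("gene").size()
    best["n_candidates"] = n_cand.reindex(best.index)
    return best[["subset", "r", "p_adj", "w", "score", "subset_size", "n_candidates"]]


def summarize_specific_vs_shared(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of assigned genes per subset and per subset size (1 = specific)."""
    if len(table) == 0:
        return pd.DataFrame(columns=["subset", "subset_size", "n_genes", "class"])
    counts = (table.groupby(["subset", "subset_size"]).size()
              .rename("n_genes").reset_index())
    counts["class"] = np.where(counts["subset_size"] == 1, "specific", "shared")
    return counts.sort_values(["subset_size", "subset"]).reset_index(drop=True)
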