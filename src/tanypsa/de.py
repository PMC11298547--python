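"""Stratified pseudobulk differential expression and temporal trajectories.

Cells of each (population, condition) stratum are randomly split into
``n_reps`` pseudo-replicates of near-equal size and their UMI counts summed,
turning single cells into replicate-level count libraries. Differential
expression between two conditions within a population is then tested with a
negative-binomial Wald test at the DESeq2 contract level: median-of-ratios
size factors, per-gene method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, and a Wald test on the condition coefficient of a
log-link NB GLM. Genes significant across the fed->12h->24h course are
classified into temporal trajectory families (I = net up at 24 h, D = net
down, T = transient) with a six-way shape sub-index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError, ParameterError


@dataclass
class PseudobulkTable:
    """Summed counts per (population, condition, replicate).

    ``counts`` rows are indexed by a (population, condition, replicate)
    MultiIndex; ``cells`` maps each row to the obs names it aggregates (kept
    so downstream stages, e.g. communication scoring, can reuse the same
    replicate structure).
    """

    counts: pd.DataFrame
    n_cells: pd.Series
    cells: dict[tuple[str, str, int], list[str]]
    n_reps: int
    seed: int


def make_pseudoreplicates(adata: ad.AnnData, n_reps: int = 4,
                          seed: int = 0) -> PseudobulkTable:
    """Random, cluster-stratified partition into pseudo-replicates.

    Within each (population, condition) stratum cells are shuffled and split
    into ``n_reps`` groups whose sizes differ by at most one; counts are
    summed per group. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = sp.csr_matrix(X)
    pops = adata.obs["population"].astype(str)
    conds = adata.obs["condition"].astype(str)
    rows = {}
    n_cells = {}
    cells = {}
    for pop in sorted(pops.unique()):
        for cond in sorted(conds.unique()):
            idx = np.flatnonzero((pops == pop).to_numpy() & (conds == cond).to_numpy())
            if len(idx) == 0:
                continue
            if len(idx) < n_reps:
                raise ConfigError(
                    f"stratum (population={pop}, condition={cond}) has "
                    f"{len(idx)} cells < n_reps={n_reps}")
            perm = rng.permutation(idx)
            for r, part in enumerate(np.array_split(perm, n_reps)):
                key = (pop, cond, r)
                rows[key] = np.asarray(X[part].sum(axis=0)).ravel()
                n_cells[key] = len(part)
                cells[key] = adata.obs_names[part].tolist()
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=adata.var_names)
    counts.index = pd.MultiIndex.from_tuples(counts.index,
                                             names=["population", "condition", "replicate"])
    return PseudobulkTable(counts=counts,
                           n_cells=pd.Series(n_cells).rename("n_cells"),
                           cells=cells, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# NB Wald test

def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq2-style size factors; falls back to library-size ratios when no
    gene is expressed in every sample."""
    logc = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan, dtype=float))
    every = np.all(counts > 0, axis=0)
    if every.sum() >= 1:
        loggeo = logc[:, every].mean(axis=0)
        sf = np.exp(np.median(logc[:, every] - loggeo, axis=1))
    else:
        lib = counts.sum(axis=1).astype(float)
        sf = lib / np.exp(np.mean(np.log(lib)))
    return sf


def _moment_dispersions(counts: np.ndarray, sf: np.ndarray,
                        x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments NB dispersion from within-condition variability.

    Pooling the variance within each design group keeps real fold changes
    out of the dispersion estimate.
    """
    q = counts / sf[:, None]
    mu = q.mean(axis=0)
    groups = [q[x == g] for g in np.unique(x)]
    dof = sum(len(g) - 1 for g in groups)
    v = sum((len(g) - 1) * g.var(axis=0, ddof=1) for g in groups) / dof
    xi = np.mean(1.0 / sf)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = (v - xi * mu) / mu ** 2
    return mu, disp


def _fit_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Parametric dispersion trend a0 + a1/mu.

    Fitted to all finite moment estimates, including the non-positive ones:
    excluding them would bias the trend upward when true dispersion is small
    (the moment estimator is roughly unbiased but very noisy at few
    replicates, so negatives are informative).
    """
    ok = np.isfinite(disp) & (mu > 0)
    if ok.sum() < 10:
        med = float(np.nanmedian(np.clip(disp, 1e-6, None))) if np.isfinite(disp).any() else 0.1
        return max(med, 1e-6), 0.0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(A, disp[ok], rcond=None)
    a0 = max(float(coef[0]), 1e-6)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def _shrink_dispersions(mu: np.ndarray, disp: np.ndarray,
                        a0: float, a1: float, weight: float = 0.5) -> np.ndarray:
    trend = a0 + a1 / np.maximum(mu, 1e-8)
    disp = np.where(np.isfinite(disp) & (disp > 0), disp, trend)
    out = np.exp((1 - weight) * np.log(disp) + weight * np.log(trend))
    return np.clip(out, 1e-8, 10.0)


def _nb_irls(counts: np.ndarray, sf: np.ndarray, x: np.ndarray,
             disp: np.ndarray, n_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for per-gene NB GLMs log mu = log sf + b0 + b1 x.

    Returns (b0, b1, se_b1). ``x`` is the 0/1 condition indicator.
    """
    m, G = counts.shape
    X = np.column_stack([np.ones(m), x])
    off = np.log(sf)
    q = counts / sf[:, None]
    b0 = np.log(np.maximum(q.mean(axis=0), 1e-8))
    b1 = np.zeros(G)
    for _ in range(n_iter):
        eta = off[:, None] + b0[None, :] + np.outer(x, b1)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + disp[None, :] * mu)
        z = (counts - mu) / mu
        # normal equations per gene: (X^T W X) delta = X^T W (z * ... )
        s00 = W.sum(axis=0)
        s01 = (W * x[:, None]).sum(axis=0)
        s11 = (W * (x ** 2)[:, None]).sum(axis=0)
        g0 = (W * z).sum(axis=0)
        g1 = (W * z * x[:, None]).sum(axis=0)
        det = s00 * s11 - s01 ** 2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        d0 = np.nan_to_num(np.clip(d0, -5, 5))
        d1 = np.nan_to_num(np.clip(d1, -5, 5))
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < tol:
            break
    eta = np.clip(off[:, None] + b0[None, :] + np.outer(x, b1), -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + disp[None, :] * mu)
    s00 = W.sum(axis=0)
    s01 = (W * x[:, None]).sum(axis=0)
    s11 = (W * (x ** 2)[:, None]).sum(axis=0)
    det = s00 * s11 - s01 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b1 = np.sqrt(s00 / det)
    return b0, b1, se_b1


def pseudobulk_de(pb: PseudobulkTable, contrast: tuple[str, str],
                  population: str, use_t: bool = False) -> pd.DataFrame:
    """NB Wald test of ``contrast = (condition, reference)`` within a population.

    log2FoldChange is condition over reference. The Wald statistic uses the
    normal reference by default: the trended dispersion borrows strength
    across all genes, so the per-gene variance behaves as known rather than
    estimated at few replicates. ``use_t=True`` switches to a t reference
    with (samples - 2) df for a more conservative test.
    """
    cond, ref = contrast
    sub = pb.counts.xs(population, level="population", drop_level=True)
    available = set(sub.index.get_level_values("condition"))
    for c in (cond, ref):
        if c not in available:
            raise ConfigError(f"condition {c!r} absent from pseudobulk table")
    sub = sub[sub.index.get_level_values("condition").isin([cond, ref])]
    x = (sub.index.get_level_values("condition") == cond).astype(float)
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ConfigError("need >= 2 replicates per condition")
    counts = sub.to_numpy(dtype=float)
    genes = sub.columns
    nonzero = counts.sum(axis=0) > 0
    counts_nz = counts[:, nonzero]

    sf = median_of_ratios(counts_nz)
    mu, disp_raw = _moment_dispersions(counts_nz, sf, x)
    a0, a1 = _fit_trend(mu, disp_raw)
    disp = _shrink_dispersions(mu, disp_raw, a0, a1)
    b0, b1, se = _nb_irls(counts_nz, sf, x, disp)

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = b1 / se
    if use_t:
        pval = 2 * stats.t.sf(np.abs(wald), df=len(x) - 2)
    else:
        pval = 2 * stats.norm.sf(np.abs(wald))
    pval = np.where(np.isfinite(wald), pval, np.nan)

    res = pd.DataFrame(index=genes[nonzero])
    res["baseMean"] = (counts_nz / sf[:, None]).mean(axis=0)
    res["log2FoldChange"] = b1 / np.log(2)
    res["lfcSE"] = se / np.log(2)
    res["stat"] = wald
    res["pvalue"] = pval
    padj = np.full(len(res), np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        padj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
    res["padj"] = padj
    res.attrs["contrast"] = (cond, ref)
    res.attrs["population"] = population
    res.attrs["size_factors"] = sf
    return res


def de_burden(results_by_population: dict[str, pd.DataFrame],
              adata: ad.AnnData, alpha: float = 0.05) -> pd.DataFrame:
    """Normalized DE burden: significant genes divided by the median number of
    detected genes per cell of the population; also the fraction down."""
    if "detected_genes" in adata.obs:
        detected = adata.obs["detected_genes"].to_numpy()
    else:
        X = adata.layers["counts"] if "counts" in adata.layers else adata.X
        detected = np.asarray((sp.csr_matrix(X) > 0).sum(axis=1)).ravel()
    pops = adata.obs["population"].astype(str)
    rows = []
    for pop, res in results_by_population.items():
        sig = res[res["padj"] < alpha]
        med = float(np.median(detected[(pops == pop).to_numpy()]))
        n_de = len(sig)
        n_down = int((sig["log2FoldChange"] < 0).sum())
        rows.append({"population": pop, "n_de": n_de, "n_down": n_down,
                     "median_detected": med,
                     "burden": n_de / med if med > 0 else np.nan,
                     "frac_down": n_down / n_de if n_de else 0.0})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# temporal trajectory classes

FAMILY_UP, FAMILY_DOWN, FAMILY_TRANSIENT = "I", "D", "T"


def _sign(lfc: float, padj: float, alpha: float) -> int:
    if np.isfinite(padj) and padj < alpha:
        return 1 if lfc > 0 else -1
    return 0


def _subindex(family: str, s12: int, s2412: int) -> tuple[int, bool]:
    """Shape sub-index from the (12h-vs-fed, 24h-vs-12h) significance signs.

    Convention (documented in the methods note): 1 = both steps significant in
    the family direction; 4 = early step only; 2 = late step only; 3 = neither
    step individually (gradual); 5 = significant decrease at 12 h; 6 =
    significant increase at 12 h with reversal. Combinations a family cannot
    produce map to the nearest shape with a warning flag.
    """
    m = {"I": 1, "D": -1}.get(family, 0)
    if (s12, s2412) == (1, -1):
        return 6, False
    if (s12, s2412) == (-1, 1):
        return 5, False
    if s12 == 0 and s2412 == 0:
        return 3, False
    if m != 0:
        if s12 == m and s2412 == m:
            return 1, False
        if s12 == m and s2412 == 0:
            return 4, False
        if s12 == 0 and s2412 == m:
            return 2, False
        # contradictory for this family
        if s12 == -m:
            return (5 if m == 1 else 6), True
        return 2, True
    # transient family: net ns at 24 h
    if s12 == 1:
        return 6, False
    if s12 == -1:
        return 5, False
    return 2, True


def classify_trajectories(de_12_vs_fed: pd.DataFrame, de_24_vs_fed: pd.DataFrame,
                          de_24_vs_12: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Assign each gene a temporal trajectory label (e.g. "I1", "T6").

    Family from the 24h-vs-fed endpoint (up -> I, down -> D, not significant
    but significant at 12 h -> T); sub-index from the two step signs. Genes
    not significant in any contrast are unlabeled (absent from the result).
    """
    genes = de_12_vs_fed.index.intersection(de_24_vs_fed.index).intersection(de_24_vs_12.index)
    rows = []
    for g in genes:
        s12 = _sign(de_12_vs_fed.at[g, "log2FoldChange"], de_12_vs_fed.at[g, "padj"], alpha)
        s24 = _sign(de_24_vs_fed.at[g, "log2FoldChange"], de_24_vs_fed.at[g, "padj"], alpha)
        s2412 = _sign(de_24_vs_12.at[g, "log2FoldChange"], de_24_vs_12.at[g, "padj"], alpha)
        if s24 == 1:
            family = FAMILY_UP
        elif s24 == -1:
            family = FAMILY_DOWN
        elif s12 != 0 or s2412 != 0:
            family = FAMILY_TRANSIENT
        else:
            continue
        idx, warn = _subindex(family, s12, s2412)
        rows.append({"gene": g, "family": family, "subindex": idx,
                     "label": f"{family}{idx}", "warn": warn,
                     "s12": s12, "s24": s24, "s2412": s2412})
    out = pd.DataFrame(rows, columns=["gene", "family", "subindex", "label",
                                      "warn", "s12", "s24", "s2412"])
    return out.set_index("gene") if len(out) else out


def simulate_null_pseudobulk(n_genes: int = 2000, n_reps: int = 4,
                             mean_depth: float = 2e5, dispersion: float = 0.01,
                             lfc: float = 0.0, frac_de: float = 0.0,
                             seed: int = 0) -> tuple[PseudobulkTable, np.ndarray]:
    """NB pseudobulk counts for two conditions with optional planted fold
    changes; returns the table and the boolean planted-DE mask. Used by the
    calibration and power checks of the Wald test.

    Default dispersion 0.01 reflects pseudo-replicate libraries: random
    splits of one cell pool are near-multinomial, so replicate-level counts
    sit just above Poisson.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(50), sigma=1.5, size=n_genes)
    de_mask = np.zeros(n_genes, dtype=bool)
    if frac_de > 0:
        de_mask[: int(n_genes * frac_de)] = True
    rows = {}
    cells = {}
    for ci, cond in enumerate(["fed", "fasting24h"]):
        mult = np.where(de_mask & (ci == 1), 2.0 ** lfc, 1.0)
        for r in range(n_reps):
            depth_factor = rng.lognormal(0, 0.15)
            mu = base * mult
            mu = mu / mu.sum() * mean_depth * depth_factor
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
            rows[("all", cond, r)] = rng.poisson(lam).astype(float)
            cells[("all", cond, r)] = []
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"g{i:04d}" for i in range(n_genes)])
    counts.index = pd.MultiIndex.from_tuples(counts.index,
                                             names=["population", "condition", "replicate"])
    pb = PseudobulkTable(counts=counts, n_cells=pd.Series(dtype=int),
                         cells=cells, n_reps=n_reps, seed=seed)
    return pb, de_mask
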