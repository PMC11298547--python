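"""Unsupervised pseudospatial patterns, transition scores and split regions,
plus differential pseudospatial analysis (DPSA) across conditions.

Standardized per-gene curves are clustered into patterns (k-means, k chosen
by silhouette); patterns with too few member genes are dropped. For each
retained pattern's consensus curve, on-off switches are threshold-gated zero
crossings: a switch is marked where the curve crosses zero with the flanking
local extrema reaching at least -t and +t. Summing the binary switch
matrices over patterns gives a transition score per grid point; local maxima
of the threshold-aggregated, smoothed score are the "split regions" that
segment the axis into populations.

DPSA compares each gene's fed curve with its curve in another condition via
Pearson correlation and a center-of-mass displacement, calling a
dorso->ventral (toward larger s) or ventro->dorsal shift when the profile
changed and the displacement exceeds a dead-band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from ._errors import DegenerateInputError
from .pseudospace import FittedProfileSet

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class PatternSet:
    grid: np.ndarray
    members: dict[int, list[str]]  # pattern id -> gene names
    consensus: pd.DataFrame  # patterns x grid, standardized
    min_genes: int
    k_selected: int
    params: dict = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.members)


@dataclass
class TransitionProfile:
    grid: np.ndarray
    thresholds: tuple[float, ...]
    switch: dict[float, pd.DataFrame]  # threshold -> patterns x grid binary
    scores: pd.DataFrame  # grid x thresholds (column per threshold)


@dataclass
class SplitRegions:
    positions: list[float]  # s values of called boundaries
    indices: list[int]
    heights: list[float]
    params: dict = field(default_factory=dict)


def cluster_patterns(profiles: FittedProfileSet, k_range=range(5, 41),
                     min_genes: int = 50, seed: int = 0,
                     restandardize: bool = True,
                     min_sd: float = 0.1) -> PatternSet:
    """k-means on standardized curves; k maximizes mean silhouette over
    ``k_range``; clusters with <= ``min_genes`` members are dropped.

    Genes whose fitted curve moves less than ``min_sd`` (sd over the grid, in
    normalized-expression units) carry no axis signal — their standardized
    curves are pure noise — and are excluded before clustering.
    """
    Z = profiles.z.loc[profiles.sd.reindex(profiles.z.index) >= min_sd]
    if Z.shape[0] == 0:
        raise DegenerateInputError("no non-constant genes to cluster")
    X = Z.to_numpy()
    ks = [k for k in k_range if 2 <= k < X.shape[0]]
    if not ks:
        raise DegenerateInputError(f"no feasible k in k_range for {X.shape[0]} genes")
    best = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
        sil = silhouette_score(X, km.labels_) if k > 1 else -1.0
        if best is None or sil > best[0]:
            best = (sil, k, km.labels_)
    _, k_sel, labels = best

    members: dict[int, list[str]] = {}
    consensus_rows = {}
    pid = 0
    for lab in range(k_sel):
        genes = Z.index[labels == lab].tolist()
        if len(genes) <= min_genes:
            continue
        members[pid] = genes
        c = X[labels == lab].mean(axis=0)
        if restandardize:
            sd = c.std()
            c = (c - c.mean()) / sd if sd > 0 else c - c.mean()
        consensus_rows[pid] = c
        pid += 1
    consensus = pd.DataFrame.from_dict(consensus_rows, orient="index",
                                       columns=Z.columns)
    return PatternSet(grid=profiles.grid, members=members, consensus=consensus,
                      min_genes=min_genes, k_selected=k_sel,
                      params={"k_range": [min(ks), max(ks)], "seed": seed})


def _local_extrema_segments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each position, value of the preceding and following local extremum.

    Endpoints count as extrema. "Local extremum" is taken on the sequence of
    sign-of-slope changes; plateaus are traversed.
    """
    n = len(y)
    dy = np.diff(y)
    ext = [0]
    for i in range(1, n - 1):
        left = dy[i - 1]
        right = dy[i]
        if left == 0:
            continue
        if right == 0:
            # look ahead to next nonzero slope
            j = i
            while j < n - 1 and dy[j] == 0:
                j += 1
            right = dy[j] if j < n - 1 else 0
        if left * right < 0:
            ext.append(i)
    ext.append(n - 1)
    ext = np.array(sorted(set(ext)))
    prev_ext = np.empty(n)
    next_ext = np.empty(n)
    for i in range(n):
        prev_ext[i] = y[ext[ext <= i][-1]] if np.any(ext <= i) else y[0]
        ahead = ext[ext >= i]
        next_ext[i] = y[ahead[0]] if len(ahead) else y[-1]
    return prev_ext, next_ext


def switch_points(curve: np.ndarray, threshold: float) -> np.ndarray:
    """Binary vector marking threshold-gated zero crossings of a standardized
    curve: grid point g is 1 when the curve crosses zero between g-1 and g and
    the flanking local extrema reach -threshold and +threshold (either order)."""
    n = len(curve)
    out = np.zeros(n, dtype=int)
    prev_ext, next_ext = _local_extrema_segments(curve)
    for g in range(1, n):
        a, b = curve[g - 1], curve[g]
        if a == 0 and b == 0:
            continue
        crosses = (a < 0 <= b) or (a > 0 >= b)
        if not crosses:
            continue
        lo_before = prev_ext[g - 1]
        hi_after = next_ext[g]
        up_ok = lo_before <= -threshold and hi_after >= threshold
        down_ok = lo_before >= threshold and hi_after <= -threshold
        if up_ok or down_ok:
            out[g] = 1
    return out


def transition_scores(ps: PatternSet,
                      thresholds=DEFAULT_THRESHOLDS) -> TransitionProfile:
    """Per-threshold binary switch matrices over patterns and their column sums."""
    thresholds = tuple(thresholds)
    switch = {}
    scores = {}
    for t in thresholds:
        if ps.n_patterns == 0:
            mat = pd.DataFrame(np.zeros((0, len(ps.grid)), dtype=int),
                               columns=ps.consensus.columns if len(ps.consensus) else None)
        else:
            rows = {pid: switch_points(ps.consensus.loc[pid].to_numpy(), t)
                    for pid in ps.consensus.index}
            mat = pd.DataFrame.from_dict(rows, orient="index",
                                         columns=ps.consensus.columns)
        switch[t] = mat
        scores[t] = mat.sum(axis=0).to_numpy() if len(mat) else np.zeros(len(ps.grid), dtype=int)
    score_df = pd.DataFrame(scores, index=np.round(ps.grid, 6))
    return TransitionProfile(grid=ps.grid, thresholds=thresholds,
                             switch=switch, scores=score_df)


def call_split_regions(tp: TransitionProfile, window: int = 5,
                       min_frac: float = 0.5) -> SplitRegions:
    """Aggregate scores over thresholds, smooth with a centered moving average,
    and report local maxima of height >= min_frac * global max; maxima closer
    than ``window`` grid points merge into the higher one."""
    total = tp.scores.sum(axis=1).to_numpy().astype(float)
    if total.max() <= 0:
        return SplitRegions(positions=[], indices=[], heights=[],
                            params={"window": window, "min_frac": min_frac})
    kernel = np.ones(window) / window
    sm = np.convolve(total, kernel, mode="same")
    gmax = sm.max()
    n = len(sm)
    cand = [i for i in range(n)
            if sm[i] >= min_frac * gmax
            and sm[i] >= (sm[i - 1] if i > 0 else -np.inf)
            and sm[i] >= (sm[i + 1] if i < n - 1 else -np.inf)]
    # collapse plateaus and merge close maxima to the higher one
    merged: list[int] = []
    for i in sorted(cand, key=lambda j: (-sm[j], j)):
        if all(abs(i - j) > window for j in merged):
            merged.append(i)
    # refine each peak to the raw-score centroid nearby (smoothing spreads a
    # sharp switch over the window; the raw score pins its location)
    refined = []
    for i in merged:
        lo, hi = max(0, i - window), min(n, i + window + 1)
        seg = total[lo:hi]
        if seg.sum() > 0:
            j = lo + int(round(float(np.arange(lo, hi) @ seg / seg.sum()) - lo))
        else:
            j = i
        refined.append(j)
    merged = sorted(set(refined))
    return SplitRegions(positions=[float(tp.grid[i]) for i in merged],
                        indices=merged,
                        heights=[float(sm[i]) for i in merged],
                        params={"window": window, "min_frac": min_frac})


# ---------------------------------------------------------------------------
# DPSA

def center_of_mass(curve: np.ndarray, grid: np.ndarray) -> float:
    """Expression-weighted mean axis position, negative values clipped to 0."""
    w = np.maximum(np.asarray(curve, dtype=float), 0.0)
    tot = w.sum()
    if tot <= 0:
        return float("nan")
    return float((grid * w).sum() / tot)


def compare_conditions(profiles_by_condition: dict[str, FittedProfileSet],
                       baseline: str = "fed", alpha: float = 0.05,
                       delta: float = 0.05, r_min: float = 0.8,
                       patterns: PatternSet | None = None) -> pd.DataFrame:
    """Per gene and condition: correlation of fed vs condition curve, center-of-
    mass displacement, and a shift-direction call.

    A gene is flagged ``changed`` when the fed-vs-condition correlation fails
    significance at ``alpha`` (BH across genes) or r < ``r_min``. Direction is
    dorso->ventral for displacement > +delta on a changed gene, ventro->dorsal
    for < -delta, otherwise none.
    """
    if baseline not in profiles_by_condition:
        raise KeyError(f"baseline condition {baseline!r} missing")
    base = profiles_by_condition[baseline]
    grid = base.grid
    rows = []
    for cond, prof in profiles_by_condition.items():
        if cond == baseline:
            continue
        if not np.allclose(prof.grid, grid):
            raise ValueError("conditions must share the pseudospace grid")
        shared = base.curves.index.intersection(prof.curves.index)
        missing = base.curves.index.difference(shared)
        if len(missing):
            log.warning("%d genes missing in condition %s; skipped", len(missing), cond)
        A = base.curves.loc[shared].to_numpy()
        B = prof.curves.loc[shared].to_numpy()
        r = _rowwise_pearson(A, B)
        n = len(grid)
        ab = (n - 2) / 2.0
        with np.errstate(invalid="ignore"):
            p = 2 * beta_dist.sf((1 + np.abs(r)) / 2, ab, ab)
        p = np.where(np.isfinite(r), p, 1.0)
        c_base = np.array([center_of_mass(a, grid) for a in A])
        c_cond = np.array([center_of_mass(b, grid) for b in B])
        dc = c_cond - c_base
        df = pd.DataFrame({"gene": shared, "condition": cond, "r": r, "p": p,
                           "com_fed": c_base, "com_cond": c_cond, "delta_com": dc})
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["p_adj"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    changed = (out["p_adj"] >= alpha) | (out["r"] < r_min) | ~np.isfinite(out["r"])
    out["changed"] = changed
    direction = np.where(changed & (out["delta_com"] > delta), "dorso->ventral",
                         np.where(changed & (out["delta_com"] < -delta),
                                  "ventro->dorsal", "none"))
    out["direction"] = direction

    if patterns is not None and patterns.n_patterns > 0:
        out["pattern"] = out["gene"].map(
            {g: pid for pid, genes in patterns.members.items() for g in genes})
    return out


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac ** 2).sum(axis=1) * (Bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r
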