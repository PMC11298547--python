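"""Ligand-receptor communication scoring between cell populations.

For each annotated ligand-receptor pair, the communication score from a
sender to a receiver population is the mean ligand expression over sender
cells times the receptor summary over receiver cells (geometric mean of
subunit means for multi-subunit receptors). For single-subunit receptors
this equals the mean over all sender x receiver cell pairs of the expression
product. Scores computed per pseudo-replicate feed a one-way ANOVA across
feeding conditions; DeltaScore is the mean score change of a fasting
condition relative to fed, and category summaries report the fraction of
significantly up/down pairs per signaling class.
"""

from __future__ import annotations

import importlib.resources
import logging
import re

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import f_oneway
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError, FormatError
from .de import PseudobulkTable

log = logging.getLogger(__name__)

CATEGORIES = ("Secreted Signaling", "ECM-Receptor", "Cell-Cell Contact")
_SUBUNIT_SEP = re.compile(r"[_&]")


def bundled_lr_db_path():
    """Path to the packaged 30-pair toy ligand-receptor database."""
    return importlib.resources.files("tanypsa") / "data" / "lr_toy.csv"


def read_lr_db(path) -> pd.DataFrame:
    """Parse a CellChat-style ligand-receptor table (CSV or TSV).

    Expected columns: ligand, receptor (subunits joined by "_" or "&"),
    annotation (one of the three signaling categories), pathway.
    """
    import os
    if hasattr(path, "open") and not isinstance(path, (str, os.PathLike)):
        with path.open() as fh:  # importlib.resources Traversable
            df = pd.read_csv(fh, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"ligand", "receptor", "annotation"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"LR database must have columns ligand, receptor, annotation[, pathway]; "
            f"got {list(df.columns)}")
    if "pathway" not in df.columns:
        df["pathway"] = ""
    cat_norm = {c.lower(): c for c in CATEGORIES}
    bad = [a for a in df["annotation"] if str(a).strip().lower() not in cat_norm]
    if bad:
        raise FormatError(
            f"unknown LR categories {sorted(set(map(str, bad)))}; expected one of {CATEGORIES}")
    out = pd.DataFrame({
        "ligand": df["ligand"].str.strip(),
        "receptor": df["receptor"].str.strip(),
        "receptor_subunits": [tuple(_SUBUNIT_SEP.split(r.strip())) for r in df["receptor"]],
        "category": [cat_norm[str(a).strip().lower()] for a in df["annotation"]],
        "pathway": df["pathway"],
    })
    out.index = pd.Index(out["ligand"] + "-" + out["receptor"], name="pair")
    if out.index.duplicated().any():
        raise FormatError(f"duplicate LR pair ids: {out.index[out.index.duplicated()].tolist()}")
    if (out["ligand"] == "").any() or any(s == ("",) for s in out["receptor_subunits"]):
        raise FormatError("empty ligand or receptor gene name in LR database")
    return out


def communication_scores(adata: ad.AnnData, db: pd.DataFrame,
                         sender: str, receiver: str,
                         pb: PseudobulkTable) -> pd.DataFrame:
    """Per (pair, condition, replicate) communication scores.

    Replicates reuse the stratified pseudo-replicate cell partition ``pb``.
    Pairs whose ligand or any receptor subunit is absent from the matrix are
    skipped with a log message.
    """
    X = adata.X if not sp.issparse(adata.X) else adata.X.tocsc()
    gene_idx = {g: i for i, g in enumerate(adata.var_names)}
    obs_idx = {c: i for i, c in enumerate(adata.obs_names)}
    conditions = sorted({k[1] for k in pb.cells})
    rows = []
    for pair in db.itertuples():
        lig = pair.ligand
        subs = pair.receptor_subunits
        if lig not in gene_idx or any(s not in gene_idx for s in subs):
            log.info("pair %s skipped: gene absent from matrix", pair.Index)
            continue
        for cond in conditions:
            for r in range(pb.n_reps):
                s_cells = [obs_idx[c] for c in pb.cells.get((sender, cond, r), [])
                           if c in obs_idx]
                r_cells = [obs_idx[c] for c in pb.cells.get((receiver, cond, r), [])
                           if c in obs_idx]
                if not s_cells or not r_cells:
                    continue
                lbar = _mean_expr(X, s_cells, gene_idx[lig])
                sub_means = np.array([_mean_expr(X, r_cells, gene_idx[s]) for s in subs])
                rbar = float(np.exp(np.mean(np.log(sub_means)))) if np.all(sub_means > 0) else 0.0
                rows.append({"pair": pair.Index, "sender": sender, "receiver": receiver,
                             "condition": cond, "replicate": r,
                             "score": lbar * rbar, "category": pair.category,
                             "pathway": pair.pathway})
    return pd.DataFrame(rows)


def _mean_expr(X, cell_idx, gene_i) -> float:
    col = X[cell_idx, gene_i]
    if sp.issparse(col):
        return float(col.mean())
    return float(np.mean(col))


def pair_score(sender_expr: np.ndarray, receiver_expr: np.ndarray) -> float:
    """Single-pair score: mean(ligand over senders) * mean(receptor over
    receivers) — equal to the mean of all pairwise expression products."""
    return float(np.mean(sender_expr) * np.mean(receiver_expr))


def condition_anova(scores: pd.DataFrame, baseline: str = "fed",
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across conditions on replicate scores per (pair, sender,
    receiver); BH adjustment across pairs; DeltaScore per non-fed condition."""
    conditions = sorted(scores["condition"].unique())
    if len(conditions) < 2:
        raise ConfigError("condition_anova needs >= 2 conditions")
    rows = []
    for (pair, snd, rcv), grp in scores.groupby(["pair", "sender", "receiver"], sort=True):
        groups = [grp.loc[grp["condition"] == c, "score"].to_numpy() for c in conditions]
        if any(len(g) < 2 for g in groups):
            F, p = np.nan, np.nan
        elif all(np.allclose(g, groups[0][0]) for g in groups):
            F, p = 0.0, 1.0  # identical scores: no variance anywhere
        else:
            F, p = f_oneway(*groups)
            if not np.isfinite(F):
                F, p = 0.0, 1.0
        mean_base = grp.loc[grp["condition"] == baseline, "score"].mean()
        row = {"pair": pair, "sender": snd, "receiver": rcv, "F": F, "p": p,
               "category": grp["category"].iloc[0]}
        for c in conditions:
            mc = grp.loc[grp["condition"] == c, "score"].mean()
            row[f"score_{c}"] = mc
            if c != baseline:
                row[f"delta_{c}"] = mc - mean_base
        rows.append(row)
    out = pd.DataFrame(rows).set_index(["pair", "sender", "receiver"])
    ok = np.isfinite(out["p"])
    out["p_adj"] = np.nan
    out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out.attrs["baseline"] = baseline
    out.attrs["alpha"] = alpha
    return out


def category_summary(anova: pd.DataFrame, condition: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Among significant pairs, % up- and down-regulated (DeltaScore sign)
    per sender and signaling category for the given condition vs baseline."""
    delta_col = f"delta_{condition}"
    if delta_col not in anova.columns:
        raise ConfigError(f"no DeltaScore column for condition {condition!r}")
    rows = []
    senders = anova.index.get_level_values("sender").unique()
    for snd in senders:
        sub = anova.xs(snd, level="sender")
        for cat in CATEGORIES:
            pairs = sub[sub["category"] == cat]
            sig = pairs[pairs["p_adj"] < alpha]
            n = len(sig)
            up = int((sig[delta_col] > 0).sum())
            down = int((sig[delta_col] < 0).sum())
            rows.append({"sender": snd, "category": cat, "n_sig": n,
                         "pct_up": 100.0 * up / n if n else 0.0,
                         "pct_down": 100.0 * down / n if n else 0.0})
    return pd.DataFrame(rows)
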