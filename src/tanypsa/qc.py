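"""Cell quality control and total-count log normalization.

Two filters are applied: a mitochondrial-fraction outlier rule (a cell is
removed when its mito fraction exceeds the population median by more than
``mad_k`` scaled median absolute deviations, upper tail only) and a minimum
detected-genes rule (default 200). Normalization is per-cell total-count
scaling followed by log1p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ._errors import DegenerateInputError

log = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826  # scales MAD to the sd of a normal


@dataclass
class QCReport:
    n_cells_in: int
    n_removed_mito: int
    n_removed_mingenes: int
    mito_rule_applied: bool
    mito_threshold: float | None
    flags: pd.DataFrame  # per input cell: removed, reasons
    params: dict = field(default_factory=dict)

    @property
    def n_cells_out(self) -> int:
        return self.n_cells_in - int(self.flags["removed"].sum())

    def summary(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_removed_mito": self.n_removed_mito,
            "n_removed_mingenes": self.n_removed_mingenes,
            "mito_rule_applied": self.mito_rule_applied,
            "mito_threshold": self.mito_threshold,
            "params": self.params,
        }


def qc_filter(adata: ad.AnnData, mito_gene_prefix: str = "mt-",
              min_genes: int = 200, mad_k: float = 3.0) -> tuple[ad.AnnData, QCReport]:
    """Remove mito-fraction outliers and cells with too few detected genes.

    The mito cut is one-sided (upper tail): a bimodal mito distribution in
    stressed tissue makes low fractions unremarkable. With MAD = 0 (all cells
    identical) the mito rule removes nothing. The cut is iterated to a fixed
    point — median and MAD recomputed on the surviving cells until no further
    cell exceeds the threshold — which makes the filter idempotent.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()

    mito_mask = np.array([g.lower().startswith(mito_gene_prefix.lower())
                          for g in adata.var_names])
    reasons = [[] for _ in range(adata.n_obs)]
    mito_threshold = None
    mito_rule_applied = bool(mito_mask.any())
    if mito_rule_applied:
        with np.errstate(invalid="ignore"):
            mito_frac = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() / np.maximum(totals, 1)
        keep = np.ones(adata.n_obs, dtype=bool)
        for _ in range(100):  # fixed-point iteration; converges in a few rounds
            med = float(np.median(mito_frac[keep]))
            mad = float(np.median(np.abs(mito_frac[keep] - med))) * MAD_CONSISTENCY
            mito_threshold = med + mad_k * mad
            new_keep = keep & (mito_frac <= mito_threshold)
            if (new_keep == keep).all():
                break
            keep = new_keep
        for i in np.flatnonzero(~keep):
            reasons[i].append("mito")
        adata = adata.copy()
        adata.obs["mito_frac"] = mito_frac
    else:
        log.warning("no genes match mito prefix %r; mito rule skipped", mito_gene_prefix)

    for i in np.flatnonzero(detected < min_genes):
        reasons[i].append("min_genes")

    removed = np.array([len(r) > 0 for r in reasons])
    flags = pd.DataFrame({
        "removed": removed,
        "reasons": [",".join(r) for r in reasons],
        "detected_genes": detected,
        "total_counts": totals,
    }, index=adata.obs_names)
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_removed_mito=int(sum("mito" in r for r in reasons)),
        n_removed_mingenes=int(sum("min_genes" in r for r in reasons)),
        mito_rule_applied=mito_rule_applied,
        mito_threshold=mito_threshold,
        flags=flags,
        params={"mito_gene_prefix": mito_gene_prefix, "min_genes": min_genes, "mad_k": mad_k},
    )
    out = adata[~removed].copy()
    out.obs["detected_genes"] = detected[~removed]
    return out, report


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log1p(count / cell_total * scale); stores size factors in obs['size_factor'].

    The result is dense in ``layers['lognorm']``-free form: X becomes the
    normalized matrix and raw counts are kept in ``layers['counts']``.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise DegenerateInputError(
            f"{int((totals <= 0).sum())} cells have zero total counts; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    X = adata.X.tocsr(copy=True).astype(float)
    sf = totals / scale
    X.data /= np.repeat(sf, np.diff(X.indptr))
    X.data = np.log1p(X.data)
    out.X = X
    out.obs["size_factor"] = sf
    return out
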