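"""End-to-end orchestration: simulate -> qc -> pseudospace -> markers ->
patterns (+DPSA) -> de (+trajectories) -> ccc, driven by one config.

Every stage writes its interchange files (TSV/JSON/MatrixMarket) into the
run directory, and ``run_all`` records a manifest with the effective
parameters, seeds and SHA-256 hashes of every output, so a re-run with the
same config is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ccc as ccc_mod
from . import de as de_mod
from . import io as io_mod
from . import markers as mk
from . import patterns as pat
from . import pseudospace as psp
from . import qc as qc_mod
from . import simulate as sim
from ._errors import ConfigError

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "pseudospace", "markers", "patterns",
              "dpsa", "de", "trajectories", "ccc")


@dataclass
class RunConfig:
    outdir: str = "tanypsa_run"
    seed: int = 0
    input_dir: str | None = None  # read instead of simulating
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    qc: dict = field(default_factory=lambda: {
        "mito_prefix": "mt-", "min_genes": 200, "mad_k": 3.0, "scale": 1e4})
    pseudospace: dict = field(default_factory=lambda: {
        "G": 100, "df": 6, "n_top_genes": 1000, "method": "pca",
        "anchors": None})  # None -> derive from planted specific genes
    markers: dict = field(default_factory=lambda: {"alpha": 0.01})
    patterns: dict = field(default_factory=lambda: {
        "min_genes": 50, "k_min": 5, "k_max": 40,
        "thresholds": [0.1, 0.2, 0.3, 0.4, 0.5],
        "window": 5, "min_frac": 0.5})
    dpsa: dict = field(default_factory=lambda: {
        "alpha": 0.05, "delta": 0.05, "r_min": 0.8, "baseline": "fed"})
    de: dict = field(default_factory=lambda: {"n_reps": 4, "alpha": 0.05})
    ccc: dict = field(default_factory=lambda: {
        "lr_db": None, "senders": ["alpha2", "beta2"], "receiver": "Epen",
        "alpha": 0.05})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown RunConfig field {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, dict) and isinstance(v, dict):
                cur.update(v)
            else:
                setattr(cfg, k, v)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> str:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def default_anchor_genes(adata) -> dict:
    """Anchor genes from planted metadata: specific markers of the first and
    last population along the axis."""
    var = adata.var
    if "program" not in var or "subset" not in var:
        raise ConfigError(
            "pseudospace.anchors not set and the dataset carries no planted "
            "program metadata to derive them from")
    pops = list(adata.obs["population"].cat.categories)
    start = var.index[(var["program"] == "specific") & (var["subset"] == pops[0])].tolist()
    end = var.index[(var["program"] == "specific") & (var["subset"] == pops[-1])].tolist()
    if not start or not end:
        raise ConfigError("could not derive anchor genes from planted metadata")
    return {"start_genes": start[:20], "end_genes": end[:20]}


def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and return the manifest dict."""
    os.makedirs(cfg.outdir, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {},
                      "outputs": {}}
    on = {s: cfg.stages.get(s, True) for s in ALL_STAGES}

    # pre-flight
    if on["ccc"] and cfg.ccc.get("lr_db") is not None \
            and not os.path.exists(cfg.ccc["lr_db"]):
        raise ConfigError(f"ccc.lr_db path {cfg.ccc['lr_db']!r} does not exist")
    if cfg.input_dir is None and not on["simulate"]:
        raise ConfigError("either enable the simulate stage or set input_dir")

    def record(stage, **outputs):
        manifest["stages"][stage] = "done"
        for name, path in outputs.items():
            manifest["outputs"][f"{stage}/{name}"] = _sha256(path)

    # --- simulate / load
    if cfg.input_dir is not None:
        adata = io_mod.read_dataset(cfg.input_dir)
        gt = None
        manifest["stages"]["simulate"] = "skipped (input_dir)"
    else:
        simcfg = sim.default_config(seed=cfg.seed, **cfg.sim)
        adata, gt = sim.generate_dataset(simcfg)
        d = os.path.join(cfg.outdir, "dataset")
        io_mod.write_dataset(adata, d)
        gt.to_json(os.path.join(d, "ground_truth.json"))
        record("simulate", matrix=os.path.join(d, "matrix.mtx"),
               cells=os.path.join(d, "cells.tsv"),
               ground_truth=os.path.join(d, "ground_truth.json"))

    # --- qc + normalize
    if on["qc"]:
        filtered, report = qc_mod.qc_filter(
            adata, mito_gene_prefix=cfg.qc["mito_prefix"],
            min_genes=cfg.qc["min_genes"], mad_k=cfg.qc["mad_k"])
        norm = qc_mod.normalize(filtered, scale=cfg.qc["scale"])
        p_tsv = _write_tsv(report.flags, os.path.join(cfg.outdir, "qc_flags.tsv"))
        p_json = os.path.join(cfg.outdir, "qc_summary.json")
        with open(p_json, "w") as fh:
            json.dump(report.summary(), fh, indent=1, sort_keys=True)
        record("qc", flags=p_tsv, summary=p_json)
    else:
        norm = qc_mod.normalize(adata, scale=cfg.qc["scale"])
        manifest["stages"]["qc"] = "skipped"

    # --- pseudospace
    ps = profiles = None
    if on["pseudospace"]:
        anchors = cfg.pseudospace["anchors"] or default_anchor_genes(norm)
        ps = psp.order_cells(norm, anchors,
                             n_top_genes=cfg.pseudospace["n_top_genes"],
                             method=cfg.pseudospace["method"])
        profiles = psp.fit_profiles(norm, ps, G=cfg.pseudospace["G"],
                                    df=cfg.pseudospace["df"])
        _write_tsv(ps.s.to_frame(), os.path.join(cfg.outdir, "pseudospace.tsv"))
        _write_tsv(profiles.curves, os.path.join(cfg.outdir, "profiles.tsv"))
        record("pseudospace",
               s=os.path.join(cfg.outdir, "pseudospace.tsv"),
               profiles=os.path.join(cfg.outdir, "profiles.tsv"))
    else:
        manifest["stages"]["pseudospace"] = "skipped"

    # --- markers
    if on["markers"]:
        design = mk.make_design(norm)
        cand = mk.correlate_memberships(norm, design, alpha=cfg.markers["alpha"])
        table = mk.assign_markers(cand, norm, design)
        summary = mk.summarize_specific_vs_shared(table)
        _write_tsv(table, os.path.join(cfg.outdir, "markers.tsv"))
        _write_tsv(summary, os.path.join(cfg.outdir, "markers_summary.tsv"), index=False)
        record("markers", table=os.path.join(cfg.outdir, "markers.tsv"),
               summary=os.path.join(cfg.outdir, "markers_summary.tsv"))
    else:
        manifest["stages"]["markers"] = "skipped"

    # --- patterns + split regions
    patterns_set = None
    if on["patterns"]:
        if profiles is None:
            raise ConfigError("patterns stage requires the pseudospace stage")
        pcfg = cfg.patterns
        patterns_set = pat.cluster_patterns(
            profiles, k_range=range(pcfg["k_min"], pcfg["k_max"] + 1),
            min_genes=pcfg["min_genes"], seed=cfg.seed)
        tp = pat.transition_scores(patterns_set, thresholds=pcfg["thresholds"])
        regions = pat.call_split_regions(tp, window=pcfg["window"],
                                         min_frac=pcfg["min_frac"])
        _write_tsv(tp.scores, os.path.join(cfg.outdir, "transition_scores.tsv"))
        with open(os.path.join(cfg.outdir, "split_regions.json"), "w") as fh:
            json.dump({"positions": regions.positions, "heights": regions.heights,
                       "params": regions.params}, fh, indent=1, sort_keys=True)
        record("patterns",
               scores=os.path.join(cfg.outdir, "transition_scores.tsv"),
               split_regions=os.path.join(cfg.outdir, "split_regions.json"))
    else:
        manifest["stages"]["patterns"] = "skipped"

    # --- DPSA
    if on["dpsa"]:
        if ps is None:
            raise ConfigError("dpsa stage requires the pseudospace stage")
        by_cond = {}
        for cond in norm.obs["condition"].cat.categories:
            subset = norm[norm.obs["condition"] == cond]
            by_cond[cond] = psp.fit_profiles(subset, ps, G=cfg.pseudospace["G"],
                                             df=cfg.pseudospace["df"])
        shifts = pat.compare_conditions(
            by_cond, baseline=cfg.dpsa["baseline"], alpha=cfg.dpsa["alpha"],
            delta=cfg.dpsa["delta"], r_min=cfg.dpsa["r_min"],
            patterns=patterns_set)
        _write_tsv(shifts, os.path.join(cfg.outdir, "dpsa.tsv"), index=False)
        record("dpsa", shifts=os.path.join(cfg.outdir, "dpsa.tsv"))
    else:
        manifest["stages"]["dpsa"] = "skipped"

    # --- DE + trajectories
    pb = None
    if on["de"]:
        pb = de_mod.make_pseudoreplicates(norm, n_reps=cfg.de["n_reps"],
                                          seed=cfg.seed)
        conds = list(norm.obs["condition"].cat.categories)
        baseline = conds[0]
        results: dict[str, dict[str, pd.DataFrame]] = {}
        for pop in norm.obs["population"].cat.categories:
            results[pop] = {}
            for cond in conds[1:]:
                res = de_mod.pseudobulk_de(pb, (cond, baseline), pop)
                results[pop][f"{cond}_vs_{baseline}"] = res
                _write_tsv(res, os.path.join(
                    cfg.outdir, f"de_{pop}_{cond}_vs_{baseline}.tsv"))
            if len(conds) >= 3:
                res = de_mod.pseudobulk_de(pb, (conds[2], conds[1]), pop)
                results[pop][f"{conds[2]}_vs_{conds[1]}"] = res
        burden_input = {p: results[p][f"{conds[-1]}_vs_{baseline}"] for p in results}
        burden = de_mod.de_burden(burden_input, norm, alpha=cfg.de["alpha"])
        _write_tsv(burden, os.path.join(cfg.outdir, "de_burden.tsv"))
        record("de", burden=os.path.join(cfg.outdir, "de_burden.tsv"))

        if on["trajectories"] and len(conds) >= 3:
            frames = []
            for pop in results:
                tr = de_mod.classify_trajectories(
                    results[pop][f"{conds[1]}_vs_{baseline}"],
                    results[pop][f"{conds[2]}_vs_{baseline}"],
                    results[pop][f"{conds[2]}_vs_{conds[1]}"],
                    alpha=cfg.de["alpha"])
                if len(tr):
                    tr = tr.assign(population=pop)
                    frames.append(tr)
            traj = pd.concat(frames) if frames else pd.DataFrame()
            _write_tsv(traj, os.path.join(cfg.outdir, "trajectories.tsv"))
            record("trajectories", table=os.path.join(cfg.outdir, "trajectories.tsv"))
        elif not on["trajectories"]:
            manifest["stages"]["trajectories"] = "skipped"
    else:
        manifest["stages"]["de"] = "skipped"
        manifest["stages"]["trajectories"] = "skipped"

    # --- communication scores
    if on["ccc"]:
        if pb is None:
            raise ConfigError("ccc stage requires the de stage (replicate structure)")
        db_path = cfg.ccc.get("lr_db") or ccc_mod.bundled_lr_db_path()
        db = ccc_mod.read_lr_db(db_path)
        frames = []
        for snd in cfg.ccc["senders"]:
            frames.append(ccc_mod.communication_scores(
                norm, db, sender=snd, receiver=cfg.ccc["receiver"], pb=pb))
        scores = pd.concat(frames, ignore_index=True)
        anova = ccc_mod.condition_anova(scores, alpha=cfg.ccc["alpha"])
        conds = [c for c in norm.obs["condition"].cat.categories][1:]
        summaries = pd.concat(
            [ccc_mod.category_summary(anova, c, alpha=cfg.ccc["alpha"]).assign(condition=c)
             for c in conds], ignore_index=True)
        _write_tsv(anova, os.path.join(cfg.outdir, "ccc_anova.tsv"))
        _write_tsv(summaries, os.path.join(cfg.outdir, "ccc_categories.tsv"), index=False)
        record("ccc", anova=os.path.join(cfg.outdir, "ccc_anova.tsv"),
               categories=os.path.join(cfg.outdir, "ccc_categories.tsv"))
    else:
        manifest["stages"]["ccc"] = "skipped"

    mpath = os.path.join(cfg.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
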