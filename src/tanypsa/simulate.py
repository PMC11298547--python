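"""Synthetic UMI count datasets with planted pseudospatial structure.

Emulates a third-ventricle-like design: ~5 cell populations ordered along a
latent dorso-ventral axis s in [0, 1], genes following population-specific
bumps, shared gradients, U-shapes or condition-dependent shifted profiles,
negative-binomial UMI noise with log-normal library-size variation, three
feeding conditions, and planted ligand-receptor (LR) amplitude changes
between a sender and a receiver population.

Every downstream stage of the pipeline is testable against the ground truth
this module returns alongside the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import ConfigError

CONDITIONS = ("fed", "fasting12h", "fasting24h")
DEFAULT_POPULATIONS = (
    ("Epen", 0.30, (0.00, 0.30)),
    ("alpha1", 0.15, (0.30, 0.45)),
    ("alpha2", 0.20, (0.45, 0.65)),
    ("beta1", 0.15, (0.65, 0.80)),
    ("beta2", 0.20, (0.80, 1.00)),
)

PROGRAM_KINDS = ("specific", "gradient_up", "gradient_down", "u_shape", "shifted", "flat")


@dataclass(frozen=True)
class Population:
    name: str
    fraction: float
    interval: tuple[float, float]


@dataclass(frozen=True)
class GeneProgram:
    """A family of genes sharing one planted pseudospatial profile shape.

    ``shift_per_condition`` applies only to ``kind='shifted'``: a signed axis
    displacement of the fed profile in each non-fed condition (positive =
    dorso->ventral, toward larger s).
    """

    kind: str
    n_genes: int
    populations: tuple[str, ...] = ()
    amplitude: float = 1.0
    shift_per_condition: dict[str, float] = field(default_factory=dict)
    center: float = 0.5  # logistic midpoint for gradient kinds
    rate: float = 0.1  # logistic steepness for gradient kinds


@dataclass(frozen=True)
class LREffect:
    """A planted ligand-receptor pair with per-condition ligand amplitude."""

    pair_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]
    sender: str
    receiver: str
    amplitude_per_condition: dict[str, float]


@dataclass
class SimConfig:
    n_cells_per_condition: int = 1500
    conditions: tuple[str, ...] = CONDITIONS
    populations: tuple[Population, ...] = tuple(
        Population(n, f, iv) for n, f, iv in DEFAULT_POPULATIONS
    )
    n_genes: int = 2000
    gene_programs: tuple[GeneProgram, ...] = ()
    mean_depth: float = 5000.0
    nb_dispersion: float = 0.3
    depth_sigma: float = 0.3
    baseline: float = 0.1
    lr_pairs: tuple[LREffect, ...] = ()
    n_mito_genes: int = 10
    frac_damaged: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth: per-cell axis position, per-gene program, per-LR direction."""

    cell_s: np.ndarray
    gene_program: pd.DataFrame  # index gene, columns: kind, subset, shift_12h/24h-style
    lr_direction: dict[str, dict[str, int]]  # pair_id -> condition -> sign vs fed
    boundaries: tuple[float, ...]  # population interval boundaries in (0, 1)

    def to_json(self, path) -> None:
        obj = {
            "cell_s": self.cell_s.tolist(),
            "gene_program": self.gene_program.reset_index().to_dict(orient="list"),
            "lr_direction": self.lr_direction,
            "boundaries": list(self.boundaries),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


# ---------------------------------------------------------------------------
# planted profile curves

def raised_cosine(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth bump supported on [lo, hi], peaking at the midpoint with height 1."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    width = hi - lo
    inside = (s >= lo) & (s <= hi)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[inside] - lo) / width))
    return out


def plateau(s: np.ndarray, lo: float, hi: float, edge_frac: float = 0.2) -> np.ndarray:
    """Flat-top bump: 1 across [lo, hi] with raised-cosine shoulders taking up
    ``edge_frac`` of the interval width at each end. Used for planted LR genes,
    whose replicate-level summaries should not be dominated by within-
    population profile variance."""
    s = np.asarray(s, dtype=float)
    w = (hi - lo) * edge_frac
    out = np.zeros_like(s)
    core = (s >= lo + w) & (s <= hi - w)
    out[core] = 1.0
    left = (s >= lo) & (s < lo + w)
    out[left] = 0.5 * (1 - np.cos(np.pi * (s[left] - lo) / w))
    right = (s > hi - w) & (s <= hi)
    out[right] = 0.5 * (1 - np.cos(np.pi * (hi - s[right]) / w))
    return out


def logistic_ramp(s: np.ndarray, up: bool = True, center: float = 0.5, rate: float = 0.1) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    z = 1.0 / (1.0 + np.exp(-(s - center) / rate))
    return z if up else 1.0 - z


def program_curve(kind: str, s: np.ndarray, intervals: dict[str, tuple[float, float]],
                  populations: Sequence[str], shift: float = 0.0,
                  axis_ends: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.3), (0.8, 1.0)),
                  center: float = 0.5, rate: float = 0.1) -> np.ndarray:
    """Evaluate a program's planted profile at axis positions ``s``.

    ``shift`` translates the profile along the axis (clipped at [0, 1], no wrap).
    ``axis_ends`` gives the two end-population intervals carrying the U-shape bumps.
    """
    s = np.asarray(s, dtype=float)
    if shift != 0.0:
        s = np.clip(s - shift, 0.0, 1.0)
    if kind == "specific":
        lo, hi = intervals[populations[0]]
        return raised_cosine(s, lo, hi)
    if kind == "gradient_up":
        return logistic_ramp(s, up=True, center=center, rate=rate)
    if kind == "gradient_down":
        return logistic_ramp(s, up=False, center=center, rate=rate)
    if kind == "u_shape":
        return raised_cosine(s, *axis_ends[0]) + raised_cosine(s, *axis_ends[1])
    if kind == "shifted":
        # asymmetric bump so the center of mass tracks the translation cleanly
        return raised_cosine(s, 0.2, 0.55)
    if kind == "flat":
        return np.ones_like(s)
    raise ConfigError(f"gene_programs: unknown program kind {kind!r}")


# ---------------------------------------------------------------------------
# defaults

def default_gene_programs(populations: Sequence[Population]) -> tuple[GeneProgram, ...]:
    """The default planted design: 50 specific genes per population, shared
    gradients both ways, U-shape genes high at both axis ends, and shifted
    genes moving dorso->ventral (+) or ventro->dorsal (-) under fasting."""
    progs = [GeneProgram("specific", 50, (p.name,), amplitude=6.0) for p in populations]
    progs += [
        GeneProgram("gradient_up", 150, amplitude=4.0),
        GeneProgram("gradient_down", 150, amplitude=4.0),
        GeneProgram("u_shape", 60, amplitude=6.0),
        GeneProgram("shifted", 60, amplitude=6.0,
                    shift_per_condition={"fasting12h": 0.1, "fasting24h": 0.2}),
        GeneProgram("shifted", 40, amplitude=6.0,
                    shift_per_condition={"fasting12h": -0.1, "fasting24h": -0.2}),
    ]
    return tuple(progs)


def default_lr_effects() -> tuple[LREffect, ...]:
    """Planted LR rewiring mirroring the fasting design: secreted-signaling
    pairs lose amplitude at 24 h, ECM-receptor pairs double, and cell-cell
    contact pairs from the ventral sender increase."""
    from .ccc import bundled_lr_db_path, read_lr_db

    db = read_lr_db(bundled_lr_db_path())
    amp = {
        "Secreted Signaling": {"fed": 1.0, "fasting12h": 0.7, "fasting24h": 0.5},
        "ECM-Receptor": {"fed": 1.0, "fasting12h": 1.4, "fasting24h": 2.0},
        "Cell-Cell Contact": {"fed": 1.0, "fasting12h": 1.3, "fasting24h": 1.8},
    }
    effects = []
    for row in db.itertuples():
        sender = "beta2" if row.category == "Cell-Cell Contact" else "alpha2"
        effects.append(LREffect(
            pair_id=row.Index,
            ligand=row.ligand,
            receptor_subunits=tuple(row.receptor_subunits),
            sender=sender,
            receiver="Epen",
            amplitude_per_condition=dict(amp[row.category]),
        ))
    return tuple(effects)


def boundary_config(seed: int = 0, boundaries: tuple[float, float] = (0.33, 0.66),
                    n_cells_per_condition: int = 400, n_genes: int = 1000) -> SimConfig:
    """Three populations with expression programs switching on/off exactly at
    the two population boundaries: the planted design for split-region
    recovery. Genes are steep logistic ramps centered on each boundary, so
    every pattern's on-off transition happens there."""
    b1, b2 = boundaries
    pops = (
        Population("Epen", b1, (0.0, b1)),
        Population("alpha", b2 - b1, (b1, b2)),
        Population("beta2", 1.0 - b2, (b2, 1.0)),
    )
    progs = tuple(
        GeneProgram(kind, 100, amplitude=5.0, center=c, rate=0.04)
        for c in boundaries for kind in ("gradient_up", "gradient_down")
    )
    return SimConfig(
        n_cells_per_condition=n_cells_per_condition, populations=pops,
        n_genes=n_genes, gene_programs=progs, lr_pairs=(), n_mito_genes=0,
        frac_damaged=0.0, seed=seed)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    pops = tuple(Population(n, f, iv) for n, f, iv in DEFAULT_POPULATIONS)
    cfg = SimConfig(
        populations=pops,
        gene_programs=default_gene_programs(pops),
        lr_pairs=default_lr_effects(),
        frac_damaged=0.02,
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigError(f"unknown SimConfig field {k!r}")
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# validation

def validate_config(cfg: SimConfig) -> None:
    fracs = [p.fraction for p in cfg.populations]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError(f"populations: fractions sum to {sum(fracs)}, expected 1")
    prev_hi = 0.0
    for p in cfg.populations:
        lo, hi = p.interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"populations: interval {p.interval} of {p.name} not within [0,1]")
        if abs(lo - prev_hi) > 1e-9:
            raise ConfigError(
                f"populations: interval of {p.name} starts at {lo}, expected {prev_hi} "
                "(intervals must be ordered, disjoint and cover [0,1])")
        prev_hi = hi
    if abs(prev_hi - 1.0) > 1e-9:
        raise ConfigError("populations: intervals do not cover [0,1]")
    pop_names = {p.name for p in cfg.populations}
    n_prog = 0
    for gp in cfg.gene_programs:
        if gp.kind not in PROGRAM_KINDS:
            raise ConfigError(f"gene_programs: unknown kind {gp.kind!r}")
        if gp.amplitude < 0:
            raise ConfigError(f"gene_programs: amplitude {gp.amplitude} < 0")
        if gp.kind == "specific" and len(gp.populations) != 1:
            raise ConfigError("gene_programs: specific program must name exactly one population")
        for nm in gp.populations:
            if nm not in pop_names:
                raise ConfigError(f"gene_programs: unknown population {nm!r}")
        for cond, sh in gp.shift_per_condition.items():
            if not -1.0 <= sh <= 1.0:
                raise ConfigError(f"gene_programs: shift {sh} for {cond} outside [-1,1]")
        n_prog += gp.n_genes
    n_lr_genes = len({g for e in cfg.lr_pairs for g in (e.ligand, *e.receptor_subunits)})
    if cfg.n_genes < n_prog + n_lr_genes + cfg.n_mito_genes:
        raise ConfigError(
            f"n_genes: {cfg.n_genes} smaller than total program genes "
            f"({n_prog} program + {n_lr_genes} LR + {cfg.n_mito_genes} mito)")
    if cfg.nb_dispersion < 0:
        raise ConfigError(f"nb_dispersion: {cfg.nb_dispersion} must be >= 0")


# ---------------------------------------------------------------------------
# generation

def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with NB2 variance mu + d*mu^2.

    dispersion -> 0 degenerates to Poisson.
    """
    if dispersion < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_dataset(cfg: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a cells x genes UMI matrix from the planted design.

    Counts are NB(mean = depth_c * p_gc, dispersion) where p_gc is the cell's
    normalized intensity under the gene's program curve evaluated at its true
    axis position. Identical config and seed give bit-identical output.
    """
    validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    intervals = {p.name: p.interval for p in cfg.populations}
    pop_names = [p.name for p in cfg.populations]
    fracs = np.array([p.fraction for p in cfg.populations])

    # --- cells: condition blocks, iid population draw, uniform s in interval
    n_per = cfg.n_cells_per_condition
    n_cells = n_per * len(cfg.conditions)
    condition = np.repeat(list(cfg.conditions), n_per)
    pop_idx = rng.choice(len(pop_names), size=n_cells, p=fracs)
    lo = np.array([intervals[pop_names[i]][0] for i in pop_idx])
    hi = np.array([intervals[pop_names[i]][1] for i in pop_idx])
    s = lo + rng.uniform(size=n_cells) * (hi - lo)
    population = np.array(pop_names, dtype=object)[pop_idx]

    # --- genes: program genes, LR genes, mito genes, flat filler
    gene_names: list[str] = []
    gene_kind: list[str] = []
    gene_subset: list[str] = []
    curves = []  # per gene: dict condition -> intensity over cells (lazily via shift)

    def add_gene(name, kind, subset, curve_by_cond):
        gene_names.append(name)
        gene_kind.append(kind)
        gene_subset.append(subset)
        curves.append(curve_by_cond)

    shift_label: list[dict[str, float]] = []
    axis_ends = (cfg.populations[0].interval, cfg.populations[-1].interval)
    end_subset = f"{cfg.populations[0].name}|{cfg.populations[-1].name}"
    for gi, gp in enumerate(cfg.gene_programs):
        for j in range(gp.n_genes):
            name = f"{gp.kind}_{gi}_{j:03d}"
            by_cond = {}
            for cond in cfg.conditions:
                sh = gp.shift_per_condition.get(cond, 0.0) if gp.kind == "shifted" else 0.0
                by_cond[cond] = gp.amplitude * program_curve(
                    gp.kind, s, intervals, gp.populations, shift=sh,
                    axis_ends=axis_ends, center=gp.center, rate=gp.rate)
            subset = "|".join(gp.populations) if gp.populations else (
                end_subset if gp.kind == "u_shape" else "")
            add_gene(name, gp.kind, subset, by_cond)
            shift_label.append(dict(gp.shift_per_condition) if gp.kind == "shifted" else {})

    # LR genes: ligand expressed by the sender (amplitude scaled per condition),
    # receptor subunits expressed by the receiver at constant amplitude.
    lr_gene_curves: dict[str, dict[str, np.ndarray]] = {}
    lr_gene_meta: dict[str, tuple[str, str]] = {}
    for eff in cfg.lr_pairs:
        l_lo, l_hi = intervals[eff.sender]
        lig_base = 6.0 * plateau(s, l_lo, l_hi)
        by_cond = {c: eff.amplitude_per_condition.get(c, 1.0) * lig_base for c in cfg.conditions}
        if eff.ligand in lr_gene_curves:  # ligand shared across pairs: keep first plant
            pass
        else:
            lr_gene_curves[eff.ligand] = by_cond
            lr_gene_meta[eff.ligand] = ("lr_ligand", eff.sender)
        r_lo, r_hi = intervals[eff.receiver]
        rec_base = 6.0 * plateau(s, r_lo, r_hi)
        for sub in eff.receptor_subunits:
            if sub not in lr_gene_curves:
                lr_gene_curves[sub] = {c: rec_base for c in cfg.conditions}
                lr_gene_meta[sub] = ("lr_receptor", eff.receiver)
    for gname, by_cond in lr_gene_curves.items():
        kind, popn = lr_gene_meta[gname]
        add_gene(gname, kind, popn, by_cond)
        shift_label.append({})

    for j in range(cfg.n_mito_genes):
        add_gene(f"mt-gene{j}", "mito", "",
                 {c: 0.5 * np.ones_like(s) for c in cfg.conditions})
        shift_label.append({})

    n_fill = cfg.n_genes - len(gene_names)
    for j in range(n_fill):
        add_gene(f"flatfill_{j:04d}", "flat", "",
                 {c: np.ones_like(s) for c in cfg.conditions})
        shift_label.append({})

    # --- intensity matrix (cells x genes), per-cell normalized to probabilities
    n_genes = len(gene_names)
    E = np.empty((n_cells, n_genes))
    cond_masks = {c: condition == c for c in cfg.conditions}
    for g in range(n_genes):
        col = np.empty(n_cells)
        for c, mask in cond_masks.items():
            col[mask] = curves[g][c][mask]
        E[:, g] = col
    E += cfg.baseline

    # damaged cells: mitochondrial load boosted, or depth collapsed (QC targets)
    damaged_mito = np.zeros(n_cells, dtype=bool)
    damaged_depth = np.zeros(n_cells, dtype=bool)
    if cfg.frac_damaged > 0:
        dmg = rng.uniform(size=n_cells) < cfg.frac_damaged
        half = rng.uniform(size=n_cells) < 0.5
        damaged_mito = dmg & half
        damaged_depth = dmg & ~half
        mito_cols = [i for i, n in enumerate(gene_names) if n.startswith("mt-")]
        if mito_cols:
            row_tot = E[damaged_mito].sum(axis=1)
            E[np.ix_(damaged_mito, mito_cols)] += (
                0.8 * row_tot[:, None] / len(mito_cols))

    P = E / E.sum(axis=1, keepdims=True)
    depth = rng.lognormal(mean=np.log(cfg.mean_depth), sigma=cfg.depth_sigma, size=n_cells)
    depth[damaged_depth] *= 0.03
    mu = depth[:, None] * P
    counts = _sample_counts(rng, mu, cfg.nb_dispersion)

    obs = pd.DataFrame({
        "condition": pd.Categorical(condition, categories=list(cfg.conditions)),
        "population": pd.Categorical(population, categories=pop_names),
        "true_s": s,
    }, index=[f"cell_{i:05d}" for i in range(n_cells)])
    var = pd.DataFrame({"program": gene_kind, "subset": gene_subset}, index=gene_names)
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["sim_config"] = _config_summary(cfg)

    shifts = pd.DataFrame(shift_label, index=gene_names).fillna(0.0)
    gt_genes = var.copy()
    for c in cfg.conditions[1:]:
        gt_genes[f"shift_{c}"] = shifts[c] if c in shifts.columns else 0.0
    lr_dir = {
        eff.pair_id: {
            c: int(np.sign(eff.amplitude_per_condition.get(c, 1.0)
                           - eff.amplitude_per_condition.get("fed", 1.0)))
            for c in cfg.conditions if c != "fed"
        } for eff in cfg.lr_pairs
    }
    boundaries = tuple(p.interval[1] for p in cfg.populations[:-1])
    gt = GroundTruth(cell_s=s, gene_program=gt_genes, lr_direction=lr_dir,
                     boundaries=boundaries)
    return adata, gt


def _config_summary(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["populations"] = [[p.name, p.fraction, list(p.interval)] for p in cfg.populations]
    d["gene_programs"] = [asdict(gp) for gp in cfg.gene_programs]
    d["lr_pairs"] = [asdict(e) for e in cfg.lr_pairs]
    return d
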