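"""Synthetic generator: determinism, planted-signal fidelity, validation, IO."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

import tanypsa as tp
from tanypsa import FormatError
from tanypsa.simulate import (GeneProgram, Population, SimConfig,
                              generate_dataset, validate_config)


def _tiny_config(**kw):
    pops = (Population("A", 0.5, (0.0, 0.5)), Population("B", 0.5, (0.5, 1.0)))
    defaults = dict(n_cells_per_condition=100, conditions=("fed",),
                    populations=pops, n_genes=20,
                    gene_programs=(GeneProgram("gradient_up", 5, amplitude=3.0),),
                    n_mito_genes=0, frac_damaged=0.0, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_bit_identical():
    cfg = _tiny_config(seed=7)
    a1, _ = generate_dataset(cfg)
    a2, _ = generate_dataset(cfg)
    assert (a1.X != a2.X).nnz == 0
    assert (a1.obs["true_s"] == a2.obs["true_s"]).all()


def test_low_noise_gradient_is_monotone():
    # NB dispersion -> 0 at huge depth: normalized expression of a ramp gene
    # must track the true axis position almost perfectly
    cfg = _tiny_config(n_cells_per_condition=300, mean_depth=1e6,
                       nb_dispersion=0.0, depth_sigma=0.0, seed=1)
    adata, gt = generate_dataset(cfg)
    g = [i for i, p in enumerate(adata.var["program"]) if p == "gradient_up"][0]
    expr = adata.X[:, g].toarray().ravel() / np.asarray(adata.X.sum(axis=1)).ravel()
    rho = spearmanr(expr, gt.cell_s).statistic
    assert rho >= 0.99


def test_population_sizes_binomial():
    cfg = _tiny_config(n_cells_per_condition=1000, seed=3)
    adata, _ = generate_dataset(cfg)
    n_a = (adata.obs["population"] == "A").sum()
    lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5)
    assert lo <= n_a <= hi


def test_every_cell_position_inside_population_interval():
    cfg = _tiny_config(seed=2)
    adata, gt = generate_dataset(cfg)
    for pop, (lo, hi) in (("A", (0.0, 0.5)), ("B", (0.5, 1.0))):
        s = gt.cell_s[(adata.obs["population"] == pop).to_numpy()]
        assert np.all((s >= lo) & (s <= hi))


@pytest.mark.parametrize("mutate, field", [
    (dict(populations=(Population("A", 0.6, (0.0, 0.5)),
                       Population("B", 0.5, (0.5, 1.0)))), "fractions"),
    (dict(populations=(Population("A", 0.5, (0.0, 0.4)),
                       Population("B", 0.5, (0.5, 1.0)))), "intervals"),
    (dict(n_genes=3), "n_genes"),
    (dict(gene_programs=(GeneProgram("specific", 5, ("A", "B")),)), "specific"),
    (dict(gene_programs=(GeneProgram("shifted", 5,
                                     shift_per_condition={"fed": 2.0}),)), "shift"),
])
def test_invalid_config_rejected(mutate, field):
    cfg = _tiny_config(**mutate)
    with pytest.raises(tp.ConfigError):
        validate_config(cfg)


def test_program_fidelity_low_noise():
    """Each planted gene's empirical profile correlates with its planted curve."""
    from tanypsa.simulate import program_curve
    cfg = tp.default_config(seed=1, n_cells_per_condition=400, n_genes=1200,
                            mean_depth=5e4, nb_dispersion=0.01, depth_sigma=0.0,
                            frac_damaged=0.0)
    adata, gt = generate_dataset(cfg)
    fed = adata[adata.obs["condition"] == "fed"]
    s = fed.obs["true_s"].to_numpy()
    intervals = {p.name: p.interval for p in cfg.populations}
    X = fed.X.toarray() / np.asarray(fed.X.sum(axis=1))
    rng = np.random.default_rng(0)
    ok = 0
    checked = 0
    for kind, pops in (("specific", ("alpha2",)), ("gradient_up", ()),
                       ("u_shape", ())):
        genes = np.flatnonzero(
            (fed.var["program"] == kind).to_numpy()
            & (fed.var["subset"].isin(["|".join(pops)]) if pops else True))
        for g in rng.choice(genes, size=5, replace=False):
            planted = program_curve(kind, s, intervals, list(pops),
                                    axis_ends=((0.0, 0.3), (0.8, 1.0)))
            r = np.corrcoef(X[:, g], planted)[0, 1]
            checked += 1
            ok += abs(r) >= 0.95
    assert checked == 15 and ok == 15


def test_shift_fidelity_center_of_mass():
    """Expression-weighted mean of s moves by the configured displacement."""
    cfg = tp.default_config(seed=1, n_cells_per_condition=800, n_genes=1200,
                            mean_depth=1e5, nb_dispersion=0.01, depth_sigma=0.0,
                            frac_damaged=0.0)
    adata, gt = generate_dataset(cfg)
    shifted = gt.gene_program.query("program == 'shifted' and shift_fasting24h > 0")
    gi = [adata.var_names.get_loc(g) for g in shifted.index[:10]]
    coms = {}
    for cond in ("fed", "fasting24h"):
        sub = adata[adata.obs["condition"] == cond]
        X = sub.X.toarray()[:, gi]
        s = sub.obs["true_s"].to_numpy()
        coms[cond] = (X * s[:, None]).sum(axis=0) / X.sum(axis=0)
    observed = coms["fasting24h"] - coms["fed"]
    # the planted translation clips at the axis edge, so compare against the
    # planted curves' own center-of-mass displacement
    from tanypsa.simulate import program_curve
    grid = np.linspace(0, 1, 2001)
    c_fed = program_curve("shifted", grid, {}, [])
    c_24 = program_curve("shifted", grid, {}, [], shift=0.2)
    expected = (grid * c_24).sum() / c_24.sum() - (grid * c_fed).sum() / c_fed.sum()
    assert np.all(np.abs(observed - expected) <= 0.02)


def test_roundtrip_write_read(tmp_path, small_dataset):
    adata, _ = small_dataset
    sub = adata[:50, :100].copy()
    tp.write_dataset(sub, tmp_path / "ds")
    back = tp.read_dataset(tmp_path / "ds")
    assert (back.X != sub.X).nnz == 0
    assert list(back.obs_names) == list(sub.obs_names)
    assert list(back.var_names) == list(sub.var_names)
    assert (back.obs["condition"].astype(str) == sub.obs["condition"].astype(str)).all()
    assert (back.obs["population"].astype(str) == sub.obs["population"].astype(str)).all()


def test_mtx_cellranger_orientation(tmp_path):
    import anndata as ad
    import pandas as pd
    import scipy.sparse as sp
    X = sp.csr_matrix(np.array([[1, 0, 2], [0, 3, 0]]))  # 2 cells x 3 genes
    a = ad.AnnData(X=X, obs=pd.DataFrame(index=["c1", "c2"]),
                   var=pd.DataFrame(index=["g1", "g2", "g3"]))
    tp.write_dataset(a, tmp_path / "toy")
    header = None
    with open(tmp_path / "toy" / "matrix.mtx") as fh:
        for line in fh:
            if not line.startswith("%"):
                header = line.split()
                break
    assert header[:2] == ["3", "2"]  # genes as rows, cells as columns


def test_barcode_count_mismatch_raises(tmp_path, small_dataset):
    adata, _ = small_dataset
    tp.write_dataset(adata[:30, :50], tmp_path / "bad")
    bc = tmp_path / "bad" / "barcodes.tsv"
    lines = bc.read_text().splitlines()
    bc.write_text("\n".join(lines[:-1]) + "\n")
    # metadata must stay consistent with barcodes to reach the dimension check
    (tmp_path / "bad" / "cells.tsv").unlink()
    with pytest.raises(FormatError):
        tp.read_dataset(tmp_path / "bad")
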