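"""Pseudobulk construction, NB Wald test, DE burden, trajectory classes."""

import numpy as np
import pandas as pd
import pytest

import tanypsa as tp
from tanypsa.de import (classify_trajectories, median_of_ratios,
                        simulate_null_pseudobulk)


@pytest.fixture(scope="module")
def small_pb(small_norm):
    norm, _ = small_norm
    return tp.make_pseudoreplicates(norm, n_reps=4, seed=1)


def test_pseudobulk_conserves_counts(small_norm, small_pb):
    norm, _ = small_norm
    counts = norm.layers["counts"]
    for pop in norm.obs["population"].cat.categories:
        for cond in norm.obs["condition"].cat.categories:
            mask = ((norm.obs["population"] == pop)
                    & (norm.obs["condition"] == cond)).to_numpy()
            direct = np.asarray(counts[mask].sum(axis=0)).ravel()
            via_pb = small_pb.counts.loc[(pop, cond)].sum(axis=0).to_numpy()
            np.testing.assert_array_equal(direct, via_pb)


def test_replicate_sizes_differ_by_at_most_one(small_pb):
    sizes = small_pb.n_cells
    for (pop, cond), grp in sizes.groupby(level=[0, 1]):
        assert grp.max() - grp.min() <= 1


def test_nine_cells_split_3222(small_norm):
    norm, _ = small_norm
    sub = norm[:9].copy()
    sub.obs["population"] = pd.Categorical(["P"] * 9)
    sub.obs["condition"] = pd.Categorical(["fed"] * 9)
    pb = tp.make_pseudoreplicates(sub, n_reps=4, seed=0)
    assert sorted(pb.n_cells.tolist(), reverse=True) == [3, 2, 2, 2]


def test_pseudoreplicates_deterministic(small_norm):
    norm, _ = small_norm
    a = tp.make_pseudoreplicates(norm, seed=5)
    b = tp.make_pseudoreplicates(norm, seed=5)
    assert a.cells == b.cells


def test_too_small_stratum_names_it(small_norm):
    norm, _ = small_norm
    sub = norm[:3].copy()
    sub.obs["population"] = pd.Categorical(["tiny"] * 3)
    sub.obs["condition"] = pd.Categorical(["fed"] * 3)
    with pytest.raises(tp.ConfigError, match="tiny"):
        tp.make_pseudoreplicates(sub, n_reps=4)


def test_equal_libraries_unit_size_factors():
    counts = np.tile(np.array([10.0, 20.0, 5.0, 40.0]), (6, 1))
    np.testing.assert_allclose(median_of_ratios(counts), 1.0, atol=1e-12)


def test_identical_conditions_null_identity():
    rng = np.random.default_rng(0)
    row = rng.poisson(30, size=200).astype(float)
    counts = pd.DataFrame(np.tile(row, (8, 1)),
                          columns=[f"g{i}" for i in range(200)])
    counts.index = pd.MultiIndex.from_tuples(
        [("all", c, r) for c in ("fed", "fast") for r in range(4)],
        names=["population", "condition", "replicate"])
    from tanypsa.de import PseudobulkTable
    table = PseudobulkTable(counts=counts, n_cells=pd.Series(dtype=int),
                            cells={}, n_reps=4, seed=0)
    res = tp.pseudobulk_de(table, ("fast", "fed"), "all")
    np.testing.assert_allclose(res["log2FoldChange"], 0.0, atol=1e-9)
    assert (res["padj"].fillna(1.0) >= 0.999).all()


def test_label_swap_negates_lfc():
    pb, _ = simulate_null_pseudobulk(n_genes=300, lfc=1.0, frac_de=0.2, seed=3)
    fwd = tp.pseudobulk_de(pb, ("fasting24h", "fed"), "all")
    rev = tp.pseudobulk_de(pb, ("fed", "fasting24h"), "all")
    np.testing.assert_allclose(fwd["log2FoldChange"],
                               -rev["log2FoldChange"], atol=1e-6)
    np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-9)


def test_absent_condition_errors():
    pb, _ = simulate_null_pseudobulk(n_genes=50, seed=0)
    with pytest.raises(tp.ConfigError):
        tp.pseudobulk_de(pb, ("nope", "fed"), "all")


def test_deseq2_oracle_agreement(tmp_path):
    """Independent oracle: DESeq2 (R) on one simulated pseudobulk table.

    The NB Wald test re-implements DESeq2's contract, not its numerics, so
    agreement is checked on fold-change estimates and significance ranking
    rather than exact p-values.
    """
    import shutil
    import subprocess
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    pb, mask = simulate_null_pseudobulk(n_genes=400, lfc=1.0, frac_de=0.15, seed=7)
    res = tp.pseudobulk_de(pb, ("fasting24h", "fed"), "all")
    counts = pb.counts.xs("all", level="population")
    mat = counts.T.astype(int)
    mat.columns = [f"{c}_{r}" for c, r in counts.index]
    mat.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = tmp_path / "deseq.R"
    script.write_text(f"""
suppressMessages(library(DESeq2))
m <- as.matrix(read.delim("{tmp_path}/counts.tsv", row.names=1))
cond <- factor(sub("_[0-9]+$", "", colnames(m)), levels=c("fed","fasting24h"))
dds <- DESeqDataSetFromMatrix(m, DataFrame(cond), ~cond)
dds <- DESeq(dds, quiet=TRUE)
r <- results(dds, contrast=c("cond","fasting24h","fed"))
write.csv(as.data.frame(r), "{tmp_path}/deseq_out.csv")
""")
    proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                          timeout=300)
    if proc.returncode != 0:
        pytest.skip(f"DESeq2 unavailable: {proc.stderr[-300:]}")
    ref = pd.read_csv(tmp_path / "deseq_out.csv", index_col=0)
    common = res.index.intersection(ref.index)
    ours = res.loc[common]
    theirs = ref.loc[common]
    ok = theirs["baseMean"] >= 10
    # fold changes agree closely on well-measured genes
    np.testing.assert_allclose(ours.loc[ok, "log2FoldChange"],
                               theirs.loc[ok, "log2FoldChange"], atol=0.25)
    # significance calls agree on the vast majority of genes
    a = (ours.loc[ok, "padj"] < 0.05).fillna(False)
    b = (theirs.loc[ok, "padj"] < 0.05).fillna(False)
    assert (a == b).mean() >= 0.9


def test_burden_arithmetic(small_norm):
    norm, _ = small_norm
    pop = norm.obs["population"].cat.categories[0]
    res = pd.DataFrame({"padj": [0.01] * 100 + [0.5] * 50,
                        "log2FoldChange": [1.0] * 60 + [-1.0] * 40 + [0.0] * 50})
    burden = tp.de_burden({pop: res}, norm)
    med = np.median(norm.obs.loc[norm.obs["population"] == pop, "detected_genes"])
    assert burden.loc[pop, "burden"] == pytest.approx(100 / med)
    assert burden.loc[pop, "frac_down"] == pytest.approx(0.4)
    zero = tp.de_burden({pop: res[res["padj"] > 0.1]}, norm)
    assert zero.loc[pop, "burden"] == 0.0


def _mk_res(genes, lfc, padj):
    return pd.DataFrame({"log2FoldChange": lfc, "padj": padj}, index=genes)


def test_trajectory_monotone_up_is_I1():
    g = ["a"]
    tr = classify_trajectories(_mk_res(g, [1.0], [0.01]),
                               _mk_res(g, [2.0], [0.01]),
                               _mk_res(g, [1.0], [0.01]))
    assert tr.loc["a", "label"] == "I1"


def test_trajectory_transient_up_is_T6():
    g = ["a"]
    tr = classify_trajectories(_mk_res(g, [1.0], [0.01]),   # up at 12h
                               _mk_res(g, [0.1], [0.60]),   # ns at 24h vs fed
                               _mk_res(g, [-1.0], [0.01]))  # down 24 vs 12
    assert tr.loc["a", "label"] == "T6"


def test_trajectory_all_ns_unlabeled():
    g = ["a"]
    tr = classify_trajectories(_mk_res(g, [0.1], [0.9]),
                               _mk_res(g, [0.1], [0.9]),
                               _mk_res(g, [0.1], [0.9]))
    assert len(tr) == 0


@pytest.mark.parametrize("s12,s24,s2412,label", [
    ((1.0, 0.01), (2.0, 0.01), (1.0, 0.01), "I1"),   # up, up: continuous
    ((1.0, 0.01), (1.0, 0.01), (0.1, 0.9), "I4"),    # early up, sustained
    ((0.1, 0.9), (1.0, 0.01), (1.0, 0.01), "I2"),    # late up
    ((0.1, 0.9), (1.0, 0.01), (0.1, 0.9), "I3"),     # gradual net up
    ((-1.0, 0.01), (1.0, 0.01), (2.0, 0.01), "I5"),  # dip at 12h then up
    ((1.0, 0.01), (1.0, 0.01), (-0.5, 0.01), "I6"),  # spike at 12h, net up
    ((-1.0, 0.01), (-2.0, 0.01), (-1.0, 0.01), "D1"),
    ((-1.0, 0.01), (0.0, 0.9), (1.0, 0.01), "T5"),
])
def test_trajectory_lookup_semantics(s12, s24, s2412, label):
    g = ["a"]
    tr = classify_trajectories(_mk_res(g, [s12[0]], [s12[1]]),
                               _mk_res(g, [s24[0]], [s24[1]]),
                               _mk_res(g, [s2412[0]], [s2412[1]]))
    assert tr.loc["a", "label"] == label
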