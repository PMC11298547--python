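"""Pattern clustering, transition scores, split regions, and DPSA shifts."""

import numpy as np
import pandas as pd
import pytest

import tanypsa as tp
from tanypsa.patterns import (SplitRegions, TransitionProfile, center_of_mass,
                              switch_points, transition_scores)
from tanypsa.pseudospace import FittedProfileSet


def _profiles(curves: dict, grid=None) -> FittedProfileSet:
    grid = grid if grid is not None else np.linspace(0, 1, len(next(iter(curves.values()))))
    df = pd.DataFrame({k: np.asarray(v, float) for k, v in curves.items()}).T
    df.columns = np.round(grid, 6)
    sd = df.std(axis=1, ddof=0)
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return FittedProfileSet(grid=grid, curves=df, z=z, sd=sd, constant_genes=[])


def _pattern_set(consensus: dict, grid=None):
    from tanypsa.patterns import PatternSet
    grid = grid if grid is not None else np.linspace(0, 1, len(next(iter(consensus.values()))))
    df = pd.DataFrame({k: np.asarray(v, float) for k, v in consensus.items()}).T
    df.columns = np.round(grid, 6)
    return PatternSet(grid=grid, members={k: [f"gene{k}"] for k in consensus},
                      consensus=df, min_genes=0, k_selected=len(consensus))


# ---------------------------------------------------------------------------
# switch detection

def brute_force_switches(curve, t):
    """Independent oracle: enumerate zero crossings, then gate each on the
    nearest local extrema (endpoints included) reaching -t and +t."""
    curve = np.asarray(curve, float)
    n = len(curve)
    # local extrema by exhaustive check
    ext = [0, n - 1]
    for i in range(1, n - 1):
        left = curve[:i + 1]
        right = curve[i:]
        if (curve[i] >= max(left[-2], right[1]) and
                (curve[i] > left[-2] or curve[i] > right[1])):
            ext.append(i)
        if (curve[i] <= min(left[-2], right[1]) and
                (curve[i] < left[-2] or curve[i] < right[1])):
            ext.append(i)
    ext = sorted(set(ext))
    out = np.zeros(n, dtype=int)
    for g in range(1, n):
        a, b = curve[g - 1], curve[g]
        if not ((a < 0 <= b) or (a > 0 >= b)):
            continue
        before = [e for e in ext if e <= g - 1]
        after = [e for e in ext if e >= g]
        lo = curve[before[-1]] if before else curve[0]
        hi = curve[after[0]] if after else curve[-1]
        if (lo <= -t and hi >= t) or (lo >= t and hi <= -t):
            out[g] = 1
    return out


def test_step_curve_single_switch_all_thresholds():
    curve = np.array([-1.0] * 5 + [1.0] * 5)
    for t in (0.1, 0.2, 0.3, 0.4, 0.5):
        sw = switch_points(curve, t)
        assert sw.sum() == 1 and sw[5] == 1


def test_small_amplitude_side_blocks_switch():
    # crosses zero but the negative extremum only reaches -0.2
    curve = np.array([-0.2, -0.1, 0.1, 0.5, 1.0])
    assert switch_points(curve, 0.1).sum() == 1
    assert switch_points(curve, 0.3).sum() == 0


def test_monotone_curve_without_crossing_has_no_switch():
    curve = np.linspace(0.2, 1.0, 10)
    for t in (0.1, 0.5):
        assert switch_points(curve, t).sum() == 0


@pytest.mark.parametrize("seed", range(10))
def test_switch_oracle_on_random_curves(seed):
    rng = np.random.default_rng(seed)
    curve = rng.normal(0, 1, 10)
    for t in (0.1, 0.3, 0.5):
        np.testing.assert_array_equal(switch_points(curve, t),
                                      brute_force_switches(curve, t))


def test_two_patterns_switching_together_score_two():
    step = [-1.0] * 5 + [1.0] * 5
    ps = _pattern_set({0: step, 1: [-v for v in step]})
    tp_ = transition_scores(ps, thresholds=(0.5,))
    assert tp_.scores.iloc[5, 0] == 2
    assert tp_.scores.drop(tp_.scores.index[5]).to_numpy().sum() == 0


def test_transition_scores_invariant_to_pattern_order():
    step = [-1.0] * 5 + [1.0] * 5
    ramp = np.linspace(-1, 1, 10)
    a = transition_scores(_pattern_set({0: step, 1: ramp})).scores
    b = transition_scores(_pattern_set({0: ramp, 1: step})).scores
    np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


# ---------------------------------------------------------------------------
# split regions

def test_single_switch_yields_single_region():
    step = [-1.0] * 10 + [1.0] * 10
    tp_ = transition_scores(_pattern_set({0: step}))
    reg = tp.call_split_regions(tp_)
    assert len(reg.positions) == 1
    assert reg.indices[0] == 10


def test_flat_profile_yields_empty_regions():
    tp_ = transition_scores(_pattern_set({0: np.full(20, 0.4)}))
    reg = tp.call_split_regions(tp_)
    assert reg.positions == []


def test_axis_reversal_mirrors_regions():
    rng = np.random.default_rng(3)
    curves = {i: np.cumsum(rng.normal(0, 1, 30)) for i in range(3)}
    curves = {i: (c - c.mean()) / c.std() for i, c in curves.items()}
    fwd = tp.call_split_regions(transition_scores(_pattern_set(curves)))
    rev = tp.call_split_regions(transition_scores(
        _pattern_set({i: c[::-1] for i, c in curves.items()})))
    n = 30
    mirrored = sorted(n - 1 - i for i in fwd.indices)
    got = sorted(rev.indices)
    assert len(mirrored) == len(got)
    # crossings are recorded on the right edge of the crossing interval, so
    # mirroring is exact up to one grid step
    assert all(abs(a - b) <= 1 for a, b in zip(mirrored, got))


def test_min_genes_filter_drops_small_archetype():
    """Archetypes with <= min_genes members yield no retained pattern."""
    rng = np.random.default_rng(0)
    grid = np.linspace(0, 1, 40)
    curves = {}
    for i in range(70):
        curves[f"up{i}"] = 1 / (1 + np.exp(-(grid - 0.5) / 0.05)) + rng.normal(0, 0.02, 40)
    for i in range(70):
        curves[f"down{i}"] = 1 / (1 + np.exp((grid - 0.5) / 0.05)) + rng.normal(0, 0.02, 40)
    for i in range(30):
        curves[f"bump{i}"] = np.exp(-(grid - 0.5) ** 2 / 0.01) + rng.normal(0, 0.02, 40)
    prof = _profiles(curves, grid)
    ps = tp.cluster_patterns(prof, k_range=range(2, 7), min_genes=50, seed=0)
    assert ps.n_patterns == 2
    members = {frozenset(g.rstrip("0123456789") for g in genes)
               for genes in ps.members.values()}
    assert members == {frozenset({"up"}), frozenset({"down"})}


def test_clustering_deterministic(default_profiles):
    a = tp.cluster_patterns(default_profiles, k_range=range(5, 16), seed=1)
    b = tp.cluster_patterns(default_profiles, k_range=range(5, 16), seed=1)
    assert a.k_selected == b.k_selected
    assert {k: v for k, v in a.members.items()} == {k: v for k, v in b.members.items()}


# ---------------------------------------------------------------------------
# DPSA

def test_identical_curves_direction_none():
    grid = np.linspace(0, 1, 50)
    bump = np.exp(-(grid - 0.4) ** 2 / 0.02)
    prof = _profiles({"g": bump}, grid)
    out = tp.compare_conditions({"fed": prof, "fasting24h": prof})
    row = out.iloc[0]
    assert row["r"] == pytest.approx(1.0, abs=1e-12)
    assert row["delta_com"] == pytest.approx(0.0, abs=1e-12)
    assert row["direction"] == "none"


def test_translated_asymmetric_bump_com_displacement():
    """Closed form: translating a profile by +0.2 moves its center of mass by
    +0.2 (up to edge clipping of the sampled grid)."""
    grid = np.linspace(0, 1, 200)
    asym = np.where((grid > 0.1) & (grid < 0.5),
                    np.sin(np.pi * (grid - 0.1) / 0.4) ** 2 * (grid - 0.1), 0.0)
    shifted = np.where((grid > 0.3) & (grid < 0.7),
                       np.sin(np.pi * (grid - 0.3) / 0.4) ** 2 * (grid - 0.3), 0.0)
    dc = center_of_mass(shifted, grid) - center_of_mass(asym, grid)
    assert dc == pytest.approx(0.2, abs=0.03)
    out = tp.compare_conditions({"fed": _profiles({"g": asym}, grid),
                                 "fasting24h": _profiles({"g": shifted}, grid)})
    assert out.iloc[0]["direction"] == "dorso->ventral"


@pytest.fixture(scope="module")
def dpsa_calls(default_norm, default_pseudospace):
    norm, gt = default_norm
    by_cond = {}
    for cond in norm.obs["condition"].cat.categories:
        sub = norm[norm.obs["condition"] == cond]
        by_cond[cond] = tp.fit_profiles(sub, default_pseudospace)
    out = tp.compare_conditions(by_cond)
    return out[out["condition"] == "fasting24h"].set_index("gene"), gt


def test_planted_shifts_called_with_direction(dpsa_calls):
    calls, gt = dpsa_calls
    prog = gt.gene_program
    dv = prog.query("program == 'shifted' and shift_fasting24h > 0").index
    vd = prog.query("program == 'shifted' and shift_fasting24h < 0").index
    dv_rate = (calls.reindex(dv)["direction"] == "dorso->ventral").mean()
    vd_rate = (calls.reindex(vd)["direction"] == "ventro->dorsal").mean()
    assert dv_rate >= 0.9
    assert vd_rate >= 0.9


def test_flat_genes_rarely_called(dpsa_calls):
    calls, gt = dpsa_calls
    flat = gt.gene_program.query("program == 'flat'").index
    false_rate = (calls.reindex(flat)["direction"] != "none").mean()
    assert false_rate <= 0.05


def test_split_regions_recover_planted_boundaries():
    from tanypsa.simulate import boundary_config, generate_dataset
    cfg = boundary_config(seed=1)
    adata, gt = generate_dataset(cfg)
    norm = tp.normalize(adata)
    down = [g for g in norm.var_names if g.startswith("gradient_down_1")][:20]
    up = [g for g in norm.var_names if g.startswith("gradient_up_2")][:20]
    ps = tp.order_cells(norm, {"start_genes": down, "end_genes": up})
    prof = tp.fit_profiles(norm, ps, df=8)
    pats = tp.cluster_patterns(prof, k_range=range(2, 11), seed=1)
    regions = tp.call_split_regions(tp.transition_scores(pats), window=10)
    assert len(regions.positions) == 2
    for found, true in zip(sorted(regions.positions), gt.boundaries):
        assert abs(found - true) <= 0.05
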