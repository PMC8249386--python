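"""Guide assignment, cell QC, pseudotime, pseudobulk profiles, and DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_cell_dataset, make_uniform_library
from sctile.library import ResidueSpan, cut_codon
from sctile.scan import kernel_smooth
from sctile.singlecell import (
    CellDataset,
    PseudobulkMatrix,
    PseudotimeTable,
    assign_guides,
    compute_qc,
    group_de,
    normalize_log,
    position_correlation,
    pseudobulk_profiles,
    pseudotime_residue_track,
    qc_cells,
    residue_pc1,
    signature_pseudotime,
    single_assignment_rate,
)
from sctile.simulate import SimConfig, simulate_library, simulate_sc


def _tiny_ds(expr_rows, umi_rows, genes, guides, **flags):
    cells = [f"c{i}" for i in range(len(expr_rows))]
    return make_cell_dataset(
        pd.DataFrame(expr_rows, index=cells, columns=genes),
        pd.DataFrame(umi_rows, index=cells, columns=guides),
        **flags,
    )


def test_assign_guides_single_and_multi():
    ds = _tiny_ds(
        [[5, 5]] * 4,
        [[10, 0], [10, 7], [0, 0], [2, 2]],
        genes=["g1", "g2"],
        guides=["G1", "G2"],
    )
    out = assign_guides(ds, min_umi=3)
    assert out.loc["c0", "guide_status"] == "single"
    assert out.loc["c0", "assigned_guide"] == "G1"
    assert out.loc["c1", "guide_status"] == "multi"
    assert out.loc["c2", "guide_status"] == "none"
    assert out.loc["c3", "guide_status"] == "none"  # sub-threshold UMIs


def test_single_assignment_rate_from_totals():
    assert single_assignment_rate(4362, 4943) == pytest.approx(88.2, abs=0.05)


def test_planted_multiplet_rate_recovered():
    cfg = SimConfig(seed=51)
    lib, _ = simulate_library(cfg)
    ds, ledger = simulate_sc(cfg, lib)
    out = assign_guides(ds)
    recovered = (out["guide_status"] == "multi").mean()
    assert recovered == pytest.approx(ledger["multiplet_fraction"], abs=1e-12)
    # and the realized fraction sits inside the binomial 95% CI of 8%
    se = np.sqrt(0.08 * 0.92 / cfg.n_cells)
    assert abs(recovered - 0.08) <= 1.96 * se


def test_qc_thresholds_on_constructed_cells():
    genes = [f"g{i}" for i in range(300)] + ["mt-1"]
    ok = [1] * 250 + [0] * 50 + [10]  # 251 genes, ~4% mito
    few = [1] * 150 + [0] * 150 + [1]  # 151 genes detected
    mito = [1] * 250 + [0] * 50 + [35]  # 12% mito reads
    ds = _tiny_ds(
        [ok, few, mito],
        [[10], [10], [10]],
        genes=genes,
        guides=["G1"],
        mito=["mt-1"],
    )
    qc = compute_qc(ds)
    assert qc["status"].tolist() == ["pass", "fail_genes", "fail_mito"]
    kept = qc_cells(ds, qc)
    assert list(kept.expr.index) == ["c0"]
    assert kept.cell_guide.tolist() == ["G1"]


def test_all_cells_failing_reports_tally():
    ds = _tiny_ds(
        [[1] * 10], [[0]], genes=[f"g{i}" for i in range(10)], guides=["G1"]
    )
    qc = compute_qc(ds)
    with pytest.raises(ValueError, match="fail"):
        qc_cells(ds, qc)


def test_simulated_qc_labels_recovered_exactly():
    cfg = SimConfig(seed=52)
    lib, _ = simulate_library(cfg)
    ds, ledger = simulate_sc(cfg, lib)
    qc = compute_qc(ds)
    assert (qc["status"] == ledger["qc_status"]).all()


def test_qc_pass_set_invariant_to_cell_order():
    cfg = SimConfig(seed=53, n_cells=400)
    lib, _ = simulate_library(cfg)
    ds, _ = simulate_sc(cfg, lib)
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.expr.index)
    shuffled = CellDataset(
        expr=ds.expr.loc[perm],
        guide_umi=ds.guide_umi.loc[perm],
        gene_meta=ds.gene_meta,
    )
    a = set(compute_qc(ds).query("status == 'pass'").index)
    b = set(compute_qc(shuffled).query("status == 'pass'").index)
    assert a == b


def test_normalize_log_forced_value_and_scale_invariance():
    genes = ["a", "b"]
    ds = _tiny_ds([[10, 0], [3, 7]], [[5], [5]], genes=genes, guides=["G1"])
    norm = normalize_log(ds)
    assert norm.loc["c0", "a"] == pytest.approx(np.log1p(10_000))
    doubled = _tiny_ds([[20, 0], [3, 7]], [[5], [5]], genes=genes, guides=["G1"])
    assert np.allclose(normalize_log(doubled).loc["c0"], norm.loc["c0"])


def test_normalize_log_matches_two_line_reference():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 40, size=(20, 30))
    x[:, 0] += 1  # no zero-count cells
    genes = [f"g{i}" for i in range(30)]
    ds = _tiny_ds(x, np.ones((20, 1)), genes=genes, guides=["G1"])
    # independent two-line reference
    ref = np.log1p(x / x.sum(axis=1, keepdims=True) * 1e4)
    assert np.max(np.abs(normalize_log(ds).to_numpy() - ref)) < 1e-12


def test_zero_count_cell_is_an_error():
    ds = _tiny_ds([[0, 0]], [[5]], genes=["a", "b"], guides=["G1"])
    with pytest.raises(ValueError, match="zero-count"):
        normalize_log(ds)


def _archetype_ds():
    """Six pure leukemia-profile cells and six pure differentiated cells."""
    genes = ["s_up", "s_down", "Cd11b", "Meis1", "filler"]
    leukemia_cell = [0, 10, 0, 10, 5]
    differentiated = [10, 0, 10, 0, 5]
    rows = [leukemia_cell] * 6 + [differentiated] * 6
    umi = [[10]] * 12
    ds = _tiny_ds(
        rows,
        umi,
        genes=genes,
        guides=["G1"],
        signature=["s_up", "s_down"],
        diff=["Cd11b"],
        leukemia=["Meis1"],
    )
    return CellDataset(
        expr=ds.expr,
        guide_umi=ds.guide_umi,
        gene_meta=ds.gene_meta,
        cell_guide=pd.Series("G1", index=ds.expr.index),
    )


def test_pseudotime_archetypes_at_zero_and_one():
    pt = signature_pseudotime(_archetype_ds())
    assert np.allclose(pt.tau.iloc[:6], 0.0, atol=1e-12)
    assert np.allclose(pt.tau.iloc[6:], 1.0, atol=1e-12)


def test_pseudotime_orientation_flips_against_leukemia_markers():
    ds = _archetype_ds()
    meta = ds.gene_meta.copy()
    meta.loc["Cd11b", "diff_marker"] = False  # only leukemia markers left
    ds2 = CellDataset(ds.expr, ds.guide_umi, meta, cell_guide=ds.cell_guide)
    pt = signature_pseudotime(ds2)
    assert np.allclose(pt.tau.iloc[:6], 0.0, atol=1e-12)
    assert np.allclose(pt.tau.iloc[6:], 1.0, atol=1e-12)


def test_pseudotime_identical_cells_is_degenerate():
    genes = ["s1", "s2", "Cd11b"]
    rows = [[5, 5, 1]] * 12
    ds = _tiny_ds(
        rows, [[10]] * 12, genes=genes, guides=["G1"], signature=["s1", "s2"],
        diff=["Cd11b"],
    )
    ds = CellDataset(
        ds.expr, ds.guide_umi, ds.gene_meta,
        cell_guide=pd.Series("G1", index=ds.expr.index),
    )
    with pytest.raises(ValueError, match="degenerate"):
        signature_pseudotime(ds)


def test_external_pseudotime_is_respected():
    ds = _archetype_ds()
    tau = pd.Series(np.linspace(0, 1, 12), index=ds.expr.index)
    pt = signature_pseudotime(ds, external_tau=tau)
    assert np.allclose(pt.tau, tau)


def test_pseudotime_recovers_latent_differentiation():
    cfg = SimConfig(seed=54)
    lib, _ = simulate_library(cfg)
    ds, ledger = simulate_sc(cfg, lib)
    kept = qc_cells(ds, compute_qc(ds))
    pt = signature_pseudotime(kept)
    rho = sps.spearmanr(pt.tau, ledger["tau"].loc[kept.expr.index]).statistic
    assert rho >= 0.8


def test_null_effect_guide_medians_indistinguishable():
    """With no planted differentiation effect, neg-control guides and guides
    in a non-essential region have statistically indistinguishable
    pseudotime medians (pooled over seeded replicates)."""
    neutral = ResidueSpan(901, 1500)
    control_meds, neutral_meds = [], []
    for seed in range(20):
        cfg = SimConfig(seed=60 + seed, n_cells=1200, sc_effect_size=0.0)
        lib, _ = simulate_library(cfg)
        ds, _ = simulate_sc(cfg, lib)
        kept = qc_cells(ds, compute_qc(ds))
        pt = signature_pseudotime(kept)
        neg_ids = {g.guide_id for g in lib.neg_controls}
        neutral_ids = {
            g.guide_id for g in lib.tiling if cut_codon(g) in neutral
        }
        med = pt.per_guide_median
        control_meds += list(med[med.index.isin(neg_ids)])
        neutral_meds += list(med[med.index.isin(neutral_ids)])
    p = sps.mannwhitneyu(control_meds, neutral_meds).pvalue
    assert p > 0.01


def test_pseudotime_track_flat_for_constant_medians(toy_lib):
    med = pd.Series(0.5, index=[g.guide_id for g in toy_lib.tiling])
    pt = PseudotimeTable(tau=pd.Series(dtype=float), per_guide_median=med)
    track = pseudotime_residue_track(pt, toy_lib)
    assert np.allclose(track.scores, 0.5)


def test_pseudotime_track_equals_nadaraya_watson_oracle(
    toy_lib, smoothing_oracle
):
    rng = np.random.default_rng(5)
    ids = [g.guide_id for g in toy_lib.tiling][::2]  # gaps from dropped guides
    med = pd.Series(rng.uniform(size=len(ids)), index=ids)
    pt = PseudotimeTable(tau=pd.Series(dtype=float), per_guide_median=med)
    track = pseudotime_residue_track(pt, toy_lib, bandwidth_nt=7.0)
    assert np.max(np.abs(track.scores - smoothing_oracle(toy_lib, med, 7.0))) < 1e-10


def test_pseudotime_track_elevated_in_shifting_window():
    cfg = SimConfig(seed=55)
    lib, _ = simulate_library(cfg)
    ds, _ = simulate_sc(cfg, lib)
    kept = qc_cells(ds, compute_qc(ds))
    track = pseudotime_residue_track(signature_pseudotime(kept), lib)
    s = track.to_series()
    inside = s.loc[127:332].mean()
    control_region = s.loc[901:1500].mean()
    assert inside - control_region >= 0.2


def _guide_cells_ds(toy_lib, gene_by_span, n_per_guide=4, seed=0):
    """Cells per tiling guide; listed genes are high only for guides whose
    cut codon falls in their span."""
    rng = np.random.default_rng(seed)
    rows, umis, cells, owner = [], [], [], []
    genes = list(gene_by_span) + ["base1", "base2"]
    for g in toy_lib.tiling:
        for k in range(n_per_guide):
            row = []
            for gene in gene_by_span:
                span = gene_by_span[gene]
                hot = cut_codon(g) in span
                row.append(rng.poisson(30 if hot else 3))
            row += [rng.poisson(20), rng.poisson(20)]
            rows.append(row)
            cells.append(f"{g.guide_id}_{k}")
            owner.append(g.guide_id)
    expr = pd.DataFrame(rows, index=cells, columns=genes)
    umi = pd.DataFrame(
        0, index=cells, columns=[g.guide_id for g in toy_lib.guides]
    )
    ds = make_cell_dataset(expr, umi, signature=list(gene_by_span) + ["base1"])
    return CellDataset(
        ds.expr, ds.guide_umi, ds.gene_meta,
        cell_guide=pd.Series(owner, index=cells),
    )


def test_pseudobulk_constant_gene_gives_constant_column(toy_lib):
    ds = _guide_cells_ds(toy_lib, {"flat": ResidueSpan(1, 50)})
    # make 'flat' identical for every cell
    ds.expr["flat"] = 10
    ds.expr["base1"] = 10
    ds.expr["base2"] = 10
    pm = pseudobulk_profiles(ds, toy_lib)
    col = pm.profile["flat"].to_numpy()
    assert np.allclose(col, col[0])


def test_pseudobulk_localized_gene_peaks_in_its_span(toy_lib):
    span = ResidueSpan(10, 20)
    ds = _guide_cells_ds(toy_lib, {"hot": span})
    pm = pseudobulk_profiles(ds, toy_lib)
    peak = int(pm.profile["hot"].idxmax())
    assert peak in span


def test_pseudobulk_columns_match_per_gene_smoothing(toy_lib):
    ds = _guide_cells_ds(
        toy_lib, {"hot": ResidueSpan(10, 20), "cold": ResidueSpan(30, 45)}
    )
    pm = pseudobulk_profiles(ds, toy_lib)
    norm = normalize_log(ds)
    means = norm.groupby(ds.cell_guide).mean()
    for gene in pm.profile.columns:
        ref = kernel_smooth(means[gene], toy_lib, bandwidth_nt=pm.bandwidth_nt)
        assert np.allclose(pm.profile[gene].to_numpy(), ref.scores, atol=1e-10)


def _pm(matrix, residues=None):
    mat = np.asarray(matrix, dtype=float)
    idx = residues or list(range(1, len(mat) + 1))
    return PseudobulkMatrix(
        profile=pd.DataFrame(mat, index=idx, columns=[f"g{i}" for i in range(mat.shape[1])]),
        bandwidth_nt=3.0,
    )


def test_position_correlation_duplicated_rows():
    pm = _pm([[1.0, 2.0, 5.0], [1.0, 2.0, 5.0], [4.0, 1.0, 0.0]])
    r = position_correlation(pm).r
    assert r.loc[1, 2] == pytest.approx(1.0)
    assert r.loc[1, 1] == 1.0
    assert np.allclose(r, r.T)


def test_position_correlation_antipattern_rows():
    pm = _pm([[1.0, -1.0, 2.0], [-1.0, 1.0, -2.0]])
    r = position_correlation(pm).r
    assert r.loc[1, 2] == pytest.approx(-1.0)


def test_position_correlation_zero_variance_row_missing():
    # after gene-centering, the middle row is exactly zero -> undefined
    pm = _pm([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [3.0, 4.0, 7.0]])
    r = position_correlation(pm).r
    assert r.loc[2].isna().all()
    assert not np.isnan(r.loc[1, 3])


def test_position_correlation_needs_two_genes():
    with pytest.raises(ValueError, match="genes"):
        position_correlation(_pm([[1.0], [2.0]]))


def test_residue_pc1_rank_one_recovers_pattern():
    u = np.array([0.0, 1.0, 2.0, 5.0, 3.0])
    v = np.array([1.0, -2.0, 0.5])
    pm = _pm(np.outer(u, v))
    track = residue_pc1(pm)
    r = np.corrcoef(track.scores, u)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_residue_pc1_orientation_invariant_to_column_sign_flip():
    rng = np.random.default_rng(11)
    mat = rng.normal(size=(30, 5))
    orient = rng.normal(size=30)
    a = residue_pc1(_pm(mat), orient_track=orient)
    b = residue_pc1(_pm(-mat), orient_track=orient)
    assert np.allclose(a.scores, b.scores, atol=1e-8)


def test_residue_pc1_separates_planted_region():
    cfg = SimConfig(seed=56)
    lib, _ = simulate_library(cfg)
    ds, _ = simulate_sc(cfg, lib)
    kept = qc_cells(ds, compute_qc(ds))
    pt_track = pseudotime_residue_track(signature_pseudotime(kept), lib)
    pm = pseudobulk_profiles(kept, lib)
    track = residue_pc1(pm, orient_track=pt_track)
    region = track.scores[126:332]
    neutral = track.scores[900:1500]
    pooled_sd = np.sqrt((region.var() + neutral.var()) / 2)
    assert (region.mean() - neutral.mean()) / pooled_sd >= 2.0


def test_group_de_identical_groups_no_calls(toy_lib):
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(30)]
    block = rng.poisson(8, size=(12, 30))
    guides_a = [g.guide_id for g in toy_lib.tiling if cut_codon(g) <= 12]
    cells, owners = [], []
    for k in range(12):
        cells += [f"a{k}", f"n{k}"]
        owners += [guides_a[k], toy_lib.neg_controls[0].guide_id]
    expr = pd.DataFrame(
        np.repeat(block, 2, axis=0), index=cells, columns=genes
    )
    umi = pd.DataFrame(0, index=cells, columns=[g.guide_id for g in toy_lib.guides])
    ds = make_cell_dataset(expr, umi)
    ds = CellDataset(ds.expr, ds.guide_umi, ds.gene_meta,
                     cell_guide=pd.Series(owners, index=cells))
    out = group_de(ds, toy_lib, ResidueSpan(1, 12))
    assert np.allclose(out["mean_diff"], 0.0)
    assert not out["significant"].any()


def test_group_de_calibration_on_planted_shift(toy_lib):
    """A +1 log-unit shift in 30 genes is called with high power while null
    genes stay below the FDR threshold (aggregated over seeds)."""
    shifted = [f"s{i}" for i in range(30)]
    nulls = [f"n{i}" for i in range(170)]
    genes = shifted + nulls
    region_guides = [g.guide_id for g in toy_lib.tiling if cut_codon(g) <= 10]
    neg = toy_lib.neg_controls[0].guide_id
    n_hits, n_false = [], 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        # shifted genes are a small slice of total counts so that depth
        # normalization does not push a compositional shift into the nulls
        base = np.concatenate(
            [rng.lognormal(0.0, 0.3, size=30), rng.lognormal(2.3, 0.4, size=170)]
        )
        cells, owners, rows = [], [], []
        for k in range(60):
            lam = base.copy()
            owner = region_guides[k % len(region_guides)]
            lam[:30] *= np.e  # +1 natural-log unit in region cells
            rows.append(rng.poisson(lam))
            cells.append(f"a{seed}_{k}")
            owners.append(owner)
        for k in range(60):
            rows.append(rng.poisson(base))
            cells.append(f"r{seed}_{k}")
            owners.append(neg)
        expr = pd.DataFrame(rows, index=cells, columns=genes)
        umi = pd.DataFrame(0, index=cells, columns=[g.guide_id for g in toy_lib.guides])
        ds = make_cell_dataset(expr, umi)
        ds = CellDataset(ds.expr, ds.guide_umi, ds.gene_meta,
                         cell_guide=pd.Series(owners, index=cells))
        out = group_de(ds, toy_lib, ResidueSpan(1, 10))
        n_hits.append(int(out.loc[shifted, "significant"].sum()))
        n_false += int(out.loc[nulls, "significant"].sum())
    assert min(n_hits) >= 27
    assert n_false / (20 * 170) <= 0.05


def test_group_de_undersized_group_is_error(toy_lib):
    ds = _guide_cells_ds(toy_lib, {"hot": ResidueSpan(10, 20)}, n_per_guide=1)
    with pytest.raises(ValueError, match="cells"):
        group_de(ds, toy_lib, ResidueSpan(1, 50))  # no neg-control cells


def test_shared_effect_regions_correlate_in_de_estimates():
    cfg = SimConfig(seed=57)
    lib, _ = simulate_library(cfg)
    ds, _ = simulate_sc(cfg, lib)
    kept = qc_cells(ds, compute_qc(ds))
    de_a = group_de(kept, lib, ResidueSpan(127, 332))
    de_b = group_de(kept, lib, ResidueSpan(460, 555))
    r = np.corrcoef(de_a["mean_diff"], de_b["mean_diff"])[0, 1]
    assert r >= 0.9
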