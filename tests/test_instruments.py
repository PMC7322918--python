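"""Overlap, mQTL filtering, clumping, iterative instrument building, REML."""

import numpy as np
import pandas as pd
import pytest

from epimediate import (LdMatrix, SharedRegion, build_instrument, clump_snps,
                        filter_mqtls, instrument_effects, overlap_dmrs,
                        reml_meta_dmr_effect)


def _dmr_row(chrom, start, end, cpgs, p_adj=1e-4):
    return {"chrom": chrom, "start": start, "end": end, "n_cpg": len(cpgs),
            "cpgs": ",".join(cpgs), "estimate": 0.02, "se": 0.005,
            "p": 1e-6, "p_adj": p_adj}


def _ewas_for(cpgs, pvals, pos0=1000):
    return pd.DataFrame({"cpg": cpgs, "chrom": "chr1",
                         "pos": pos0 + 100 * np.arange(len(cpgs)),
                         "estimate": 0.02, "se": 0.005, "p": pvals,
                         "n": 400, "status": "ok"})


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_disjoint_intervals_do_not_overlap():
    exp = pd.DataFrame([_dmr_row("chr1", 1000, 2000, ["a", "b"])])
    sur = pd.DataFrame([_dmr_row("chr1", 5000, 6000, ["c", "d"])])
    ewas = _ewas_for(["a", "b"], [1e-8, 1e-6])
    assert overlap_dmrs(exp, sur, ewas) == []


def test_partial_overlap_keeps_shared_cpgs():
    exp = pd.DataFrame([_dmr_row("chr1", 1000, 2000, ["a", "b", "c"])])
    sur = pd.DataFrame([_dmr_row("chr1", 1500, 2500, ["b", "c", "d"])])
    ewas = _ewas_for(["a", "b", "c"], [1e-6, 1e-9, 1e-7])
    shared = overlap_dmrs(exp, sur, ewas)
    assert len(shared) == 1
    assert shared[0].shared_cpgs == ["b", "c"]
    assert shared[0].sentinel == "b"  # lowest exposure-EWAS P


def test_identical_region_full_membership_and_min_p_sentinel():
    cpgs = ["a", "b", "c"]
    exp = pd.DataFrame([_dmr_row("chr1", 1000, 1200, cpgs)])
    ewas = _ewas_for(cpgs, [1e-4, 1e-4, 1e-10])
    shared = overlap_dmrs(exp, exp.copy(), ewas)
    assert shared[0].shared_cpgs == cpgs
    assert shared[0].sentinel == "c"


def test_overlap_requires_adjusted_significance():
    exp = pd.DataFrame([_dmr_row("chr1", 1000, 2000, ["a", "b"], p_adj=0.5)])
    sur = pd.DataFrame([_dmr_row("chr1", 1000, 2000, ["a", "b"])])
    ewas = _ewas_for(["a", "b"], [1e-8, 1e-6])
    assert overlap_dmrs(exp, sur, ewas) == []


# ---------------------------------------------------------------------------
# mQTL filtering
# ---------------------------------------------------------------------------

def _mqtl(snp, cpg, p=1e-10, eaf=0.3, beta=0.05, se=0.005):
    return {"snp": snp, "cpg": cpg, "effect_allele": "A",
            "other_allele": "G", "eaf": eaf, "beta": beta, "se": se, "p": p}


def test_filter_boundaries_are_strict():
    mq = pd.DataFrame([
        _mqtl("rs1", "a", eaf=0.95),           # MAF exactly 0.05 -> out
        _mqtl("rs2", "a", p=5e-8),             # P exactly 5e-8 -> out
        _mqtl("rs3", "a", eaf=0.051),          # just inside
        _mqtl("rs4", "b"),                     # wrong CpG
    ])
    out = filter_mqtls(mq, ["a"])
    assert list(out["snp"]) == ["rs3"]


def test_filter_empty_table():
    out = filter_mqtls(pd.DataFrame(columns=list(_mqtl("x", "y"))), ["a"])
    assert len(out) == 0


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _ld(snps, r):
    return LdMatrix(r=pd.DataFrame(r, index=snps, columns=snps))


def test_single_snp_kept():
    ld = _ld(["rs1"], np.eye(1))
    assert clump_snps(pd.DataFrame({"snp": ["rs1"], "p": [1e-9]}), ld) \
        == ["rs1"]


def test_correlated_pair_keeps_lowest_p():
    r = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
    ld = _ld(["rsA", "rsB"], r)
    stats_ = pd.DataFrame({"snp": ["rsA", "rsB"], "p": [1e-10, 1e-9]})
    assert clump_snps(stats_, ld) == ["rsA"]


def test_independent_snps_all_kept():
    ld = _ld(["rs1", "rs2", "rs3"], np.eye(3))
    stats_ = pd.DataFrame({"snp": ["rs3", "rs1", "rs2"],
                           "p": [1e-8, 1e-9, 1e-7]})
    assert set(clump_snps(stats_, ld)) == {"rs1", "rs2", "rs3"}
    assert clump_snps(stats_, ld)[0] == "rs1"  # selection order by P


def test_missing_snp_in_ld_fails_by_name():
    ld = _ld(["rs1"], np.eye(1))
    with pytest.raises(ValueError, match="rs2"):
        clump_snps(pd.DataFrame({"snp": ["rs1", "rs2"], "p": [1e-9, 1e-9]}),
                   ld)


def test_clump_ties_broken_lexicographically():
    r = np.eye(2)
    ld = _ld(["rsB", "rsA"], r)
    stats_ = pd.DataFrame({"snp": ["rsB", "rsA"], "p": [1e-9, 1e-9]})
    assert clump_snps(stats_, ld) == ["rsA", "rsB"]


# ---------------------------------------------------------------------------
# iterative instrument building
# ---------------------------------------------------------------------------

def _shared(cpgs, sentinel):
    row = pd.Series(_dmr_row("chr1", 1000, 1000 + 100 * len(cpgs), cpgs))
    return SharedRegion(exposure="smoking", exposure_dmr=row,
                        survival_dmr=row, shared_cpgs=cpgs, sentinel=sentinel)


def test_single_cpg_region_is_filter_then_clump():
    mq = pd.DataFrame([_mqtl("rs1", "a", p=1e-12), _mqtl("rs2", "a", p=1e-9),
                       _mqtl("rs3", "a", p=1e-3)])
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.5
    ld = _ld(["rs1", "rs2", "rs3"], r)
    ewas = _ewas_for(["a"], [1e-8])
    trail = build_instrument(_shared(["a"], "a"), mq, ld, ewas)
    # rs3 fails P filter; rs2 clumped away against rs1 (r^2 = 0.25)
    assert list(trail["snp"]) == ["rs1"]
    assert set(trail["source_cpg"]) == {"a"}


def test_snp_of_later_cpg_already_used_is_excluded():
    mq = pd.DataFrame([
        _mqtl("rs1", "a", p=1e-12),
        _mqtl("rs1", "b", p=1e-10),   # rs1 proxies both CpGs
        _mqtl("rs2", "b", p=1e-9),
    ])
    ld = _ld(["rs1", "rs2"], np.eye(2))
    ewas = _ewas_for(["a", "b"], [1e-9, 1e-6])  # a is the sentinel
    trail = build_instrument(_shared(["a", "b"], "a"), mq, ld, ewas)
    trail = trail.set_index("snp")
    assert trail.loc["rs1", "source_cpg"] == "a"  # only via the sentinel step
    assert trail.loc["rs2", "source_cpg"] == "b"


def test_worked_two_cpg_four_snp_toy_matches_manual_trace():
    # step a (sentinel): rs1 (1e-12) kept, rs2 pruned (r^2 0.25 with rs1),
    #   rs4 kept (independent); step b: rs3 is b-only, kept.
    mq = pd.DataFrame([
        _mqtl("rs1", "a", p=1e-12), _mqtl("rs2", "a", p=1e-10),
        _mqtl("rs4", "a", p=1e-9), _mqtl("rs3", "b", p=1e-11),
        _mqtl("rs1", "b", p=1e-8 / 2),
    ])
    snps = ["rs1", "rs2", "rs3", "rs4"]
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 0.5
    ld = _ld(snps, r)
    ewas = _ewas_for(["a", "b"], [1e-9, 1e-6])
    trail = build_instrument(_shared(["a", "b"], "a"), mq, ld, ewas)
    assert list(trail["snp"]) == ["rs1", "rs4", "rs3"]
    assert list(trail["source_cpg"]) == ["a", "a", "b"]


def test_build_instrument_row_order_invariance(rng):
    mq = pd.DataFrame([
        _mqtl("rs1", "a", p=1e-12), _mqtl("rs2", "a", p=1e-10),
        _mqtl("rs4", "a", p=1e-9), _mqtl("rs3", "b", p=1e-11),
        _mqtl("rs1", "b", p=1e-9),
    ])
    snps = ["rs1", "rs2", "rs3", "rs4"]
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 0.5
    ld = _ld(snps, r)
    ewas = _ewas_for(["a", "b"], [1e-9, 1e-6])
    ref = build_instrument(_shared(["a", "b"], "a"), mq, ld, ewas)
    for _ in range(5):
        perm = mq.sample(frac=1.0, random_state=int(rng.integers(1e6)))
        out = build_instrument(_shared(["a", "b"], "a"), perm, ld, ewas)
        pd.testing.assert_frame_equal(ref, out)


def test_empty_instrument_flagged_not_fatal():
    mq = pd.DataFrame([_mqtl("rs1", "a", p=1e-3)])  # fails P filter
    ld = _ld(["rs1"], np.eye(1))
    ewas = _ewas_for(["a"], [1e-8])
    trail = build_instrument(_shared(["a"], "a"), mq, ld, ewas)
    assert len(trail) == 0


# ---------------------------------------------------------------------------
# REML meta-analysis to the DMR-level effect
# ---------------------------------------------------------------------------

def test_reml_single_cpg_degenerates():
    mu, se, tau2 = reml_meta_dmr_effect([0.08], [0.02])
    assert (mu, se, tau2) == (0.08, 0.02, 0.0)


def test_reml_identical_effects_closed_form():
    mu, se, tau2 = reml_meta_dmr_effect([0.1, 0.1], [0.02, 0.02], np.eye(2))
    assert mu == pytest.approx(0.1, abs=1e-10)
    assert se == pytest.approx(0.02 / np.sqrt(2), rel=1e-8)
    assert tau2 == pytest.approx(0.0, abs=1e-8)


def _grid_reml(y, s, R, grid_max=0.05, step=1e-6):
    """Independent tau^2 grid search oracle."""
    y, s = np.asarray(y, float), np.asarray(s, float)
    V = np.outer(s, s) * R
    one = np.ones(len(y))
    best = (None, -np.inf)
    for tau2 in np.arange(0.0, grid_max, step):
        sigma = V + tau2 * np.eye(len(y))
        si = np.linalg.inv(sigma)
        denom = one @ si @ one
        mu = (one @ si @ y) / denom
        r = y - mu
        ll = -0.5 * (np.linalg.slogdet(sigma)[1] + np.log(denom)
                     + r @ si @ r)
        if ll > best[1]:
            best = (tau2, ll)
    tau2 = best[0]
    sigma = V + tau2 * np.eye(len(y))
    si = np.linalg.inv(sigma)
    denom = one @ si @ one
    return (one @ si @ y) / denom, denom ** -0.5, tau2


def test_reml_matches_grid_search_oracle():
    y = [0.08, 0.12]
    s = [0.02, 0.03]
    R = np.array([[1.0, 0.6], [0.6, 1.0]])
    mu, se, tau2 = reml_meta_dmr_effect(y, s, R)
    mu_g, se_g, tau2_g = _grid_reml(y, s, R, grid_max=0.01, step=1e-6)
    assert abs(mu - mu_g) < 1e-6
    assert abs(tau2 - tau2_g) < 2e-6


def test_reml_scale_equivariance():
    y = [0.05, 0.09, 0.07]
    s = [0.01, 0.02, 0.015]
    R = np.full((3, 3), 0.4)
    np.fill_diagonal(R, 1.0)
    mu1, se1, _ = reml_meta_dmr_effect(y, s, R)
    c = 3.7
    mu2, se2, _ = reml_meta_dmr_effect(list(np.array(y) * c),
                                       list(np.array(s) * c), R)
    assert mu2 == pytest.approx(c * mu1, rel=1e-6)
    assert se2 == pytest.approx(c * se1, rel=1e-6)


def test_reml_zero_tau_reduces_to_gls():
    y = np.array([0.1, 0.1001, 0.0999])
    s = np.array([0.02, 0.02, 0.02])
    R = np.eye(3)
    mu, se, tau2 = reml_meta_dmr_effect(list(y), list(s), R)
    assert tau2 == 0.0
    w = 1.0 / s ** 2
    assert mu == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-10)
    assert se == pytest.approx(np.sum(w) ** -0.5, rel=1e-10)


def test_reml_rejects_bad_input():
    with pytest.raises(ValueError):
        reml_meta_dmr_effect([], [])
    with pytest.raises(ValueError):
        reml_meta_dmr_effect([0.1], [0.0])


def test_dmr_level_effect_recovers_common_truth():
    """Equal per-CpG cis effects: beta_GP within +-2 se_GP for >= 95% of SNPs."""
    from epimediate import SimulationConfig, simulate_reference_panel
    from epimediate.dmr import residual_cpg_correlation
    from epimediate.pipeline import mqtl_summary_from_panel
    cfg = SimulationConfig(
        n_panel=2000, n_cohort=10, n_cpg=10, n_region=1,
        n_snp_per_region=8, n_cpg_per_region=5, ld_decay=0.4,
        exposure_effects={"smoking": (0.0,), "alcohol": (0.0,),
                          "hpv16_e6": (0.0,)},
        mediation_loghr=(0.0,), n_batch=1, batch_effect_sd=0.0, seed=99)
    panel, truth = simulate_reference_panel(cfg)
    mqtls = mqtl_summary_from_panel(panel, truth)
    members = truth.member_cpgs(0)
    filtered = filter_mqtls(mqtls, members)
    R = residual_cpg_correlation(panel.methylation, members)
    ld = LdMatrix.from_dosages(panel.dosage)
    proxying = [s for s in truth.snps.index if s in set(filtered["snp"])]
    trail = pd.DataFrame({"snp": proxying,
                          "source_cpg": members[0], "step": 0})
    inst = instrument_effects(_shared_from_truth(truth, members), trail,
                              filtered, R)
    tab = inst.table.set_index("snp")
    hits = 0
    for snp in tab.index:
        # marginal truth includes LD-borrowed effects from neighbours
        region_snps = truth.snps
        dos = panel.dosage[region_snps.index].to_numpy()
        target = panel.dosage[snp].to_numpy()
        tc = target - target.mean()
        marginal = (tc @ (dos - dos.mean(0)) / (tc @ tc)) \
            @ region_snps["cis_effect"].to_numpy()
        # small additive slack absorbs the logistic-map linearisation error
        if abs(tab.loc[snp, "beta_gp"] - marginal) \
                <= 2.0 * tab.loc[snp, "se_gp"] + 0.003:
            hits += 1
    assert hits / len(tab) >= 0.95


def _shared_from_truth(truth, members):
    row = truth.regions.loc[0]
    dmr_row = pd.Series({"chrom": row["chrom"], "start": row["start"],
                         "end": row["end"], "cpgs": ",".join(members)})
    return SharedRegion(exposure="smoking", exposure_dmr=dmr_row,
                        survival_dmr=dmr_row, shared_cpgs=members,
                        sentinel=members[0])


def test_clump_contract_on_synthetic_panel():
    """Every per-CpG clump satisfies max pairwise r^2 < 0.01."""
    from epimediate import simulate_reference_panel
    from epimediate.pipeline import mqtl_summary_from_panel
    from epimediate.scenarios import mr_scenario_config
    cfg = mr_scenario_config(n_panel=1500, seed=55)
    panel, truth = simulate_reference_panel(cfg)
    mqtls = mqtl_summary_from_panel(panel, truth)
    members = truth.member_cpgs(0)
    ld = LdMatrix.from_dosages(panel.dosage)
    ewas_stub = _ewas_for(members, np.linspace(1e-9, 1e-5, len(members)))
    trail = build_instrument(_shared_from_truth(truth, members), mqtls, ld,
                             ewas_stub)
    for _, grp in trail.groupby("source_cpg"):
        snps = list(grp["snp"])
        if len(snps) > 1:
            sub = ld.submatrix(snps).to_numpy() ** 2
            np.fill_diagonal(sub, 0.0)
            assert sub.max() < 0.01
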