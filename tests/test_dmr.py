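"""DMR calling: candidate scan, GLS combination, Sidak, brute force."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimediate import (CandidateRegion, call_dmrs, find_candidate_regions,
                        region_statistic, residual_cpg_correlation,
                        run_linear_ewas, sidak_adjust)
from epimediate.dmr import dmr_table_to_bed

from conftest import make_methylation


def _ewas_frame(pos, est, p, chrom="chr1"):
    return pd.DataFrame({
        "cpg": [f"cg{i:03d}" for i in range(len(pos))],
        "chrom": chrom, "pos": pos, "estimate": est,
        "se": np.full(len(pos), 0.01), "p": p, "n": 100, "status": "ok"})


# ---------------------------------------------------------------------------
# candidate scan
# ---------------------------------------------------------------------------

def test_alternating_signs_yield_no_candidates():
    k = 8
    tab = _ewas_frame(100 * np.arange(k), [0.02 * (-1) ** i for i in range(k)],
                      np.full(k, 0.01))
    assert find_candidate_regions(tab) == []


def test_three_qualifying_cpgs_form_one_candidate():
    pos = [1000, 1100, 1200, 1300, 1400]
    p = [0.5, 0.01, 0.01, 0.01, 0.5]
    est = [0.02] * 5
    cands = find_candidate_regions(_ewas_frame(pos, est, p))
    assert len(cands) == 1
    assert cands[0].cpgs == ["cg001", "cg002", "cg003"]
    assert (cands[0].start, cands[0].end) == (1100, 1300)


def test_gap_boundary_is_strict():
    tab = _ewas_frame([1000, 1501], [0.02, 0.02], [0.01, 0.01])
    assert find_candidate_regions(tab, max_gap=500) == []
    tab2 = _ewas_frame([1000, 1500], [0.02, 0.02], [0.01, 0.01])
    assert len(find_candidate_regions(tab2, max_gap=500)) == 1


def test_unannotated_cpgs_rejected():
    tab = _ewas_frame([1000, 1100], [0.02, 0.02], [0.01, 0.01])
    tab.loc[1, "pos"] = np.nan
    with pytest.raises(ValueError, match="cg001"):
        find_candidate_regions(tab)


# ---------------------------------------------------------------------------
# GLS region statistic
# ---------------------------------------------------------------------------

def _region(cpgs, pos):
    return CandidateRegion(chrom="chr1", start=pos[0], end=pos[-1],
                           cpgs=cpgs)


def test_two_cpgs_closed_forms():
    tab = _ewas_frame([1000, 1100], [0.02, 0.02], [0.01, 0.01])
    tab["se"] = 0.008
    region = _region(["cg000", "cg001"], [1000, 1100])
    R0 = pd.DataFrame(np.eye(2), index=region.cpgs, columns=region.cpgs)
    rec = region_statistic(region, tab, R0)
    assert rec.estimate == pytest.approx(0.02, rel=1e-12)
    assert rec.se == pytest.approx(0.008 / np.sqrt(2), rel=1e-12)
    R1 = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=region.cpgs,
                      columns=region.cpgs)
    rec1 = region_statistic(region, tab, R1)
    # perfectly correlated CpGs add no information
    assert rec1.se == pytest.approx(0.008, rel=1e-4)


def test_three_cpg_gls_matches_hand_algebra():
    b = np.array([0.02, 0.03, 0.025])
    s = np.array([0.01, 0.01, 0.012])
    R = np.full((3, 3), 0.5)
    np.fill_diagonal(R, 1.0)
    tab = _ewas_frame([1000, 1100, 1200], b, [0.01] * 3)
    tab["se"] = s
    region = _region(["cg000", "cg001", "cg002"], [1000, 1100, 1200])
    Rdf = pd.DataFrame(R, index=region.cpgs, columns=region.cpgs)
    rec = region_statistic(region, tab, Rdf)
    V = np.outer(s, s) * R
    Vi = np.linalg.inv(V)
    one = np.ones(3)
    expect_est = (one @ Vi @ b) / (one @ Vi @ one)
    expect_se = (one @ Vi @ one) ** -0.5
    assert rec.estimate == pytest.approx(expect_est, abs=1e-10)
    assert rec.se == pytest.approx(expect_se, abs=1e-10)


def test_identity_correlation_equals_inverse_variance_meta(rng):
    for _ in range(10):
        k = rng.integers(2, 6)
        b = rng.normal(0, 0.05, k)
        s = rng.uniform(0.005, 0.03, k)
        pos = 1000 + 100 * np.arange(k)
        tab = _ewas_frame(pos, b, np.full(k, 0.01))
        tab["se"] = s
        region = _region(list(tab["cpg"]), list(pos))
        Rdf = pd.DataFrame(np.eye(k), index=region.cpgs, columns=region.cpgs)
        rec = region_statistic(region, tab, Rdf)
        w = 1.0 / s ** 2
        assert rec.estimate == pytest.approx(np.sum(w * b) / np.sum(w),
                                             abs=1e-12)
        assert rec.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)


def test_adding_independent_identical_cpg_never_hurts(rng):
    for _ in range(20):
        k = int(rng.integers(2, 5))
        b0 = float(rng.normal(0, 0.05))
        s = rng.uniform(0.005, 0.03, k + 1)
        R = np.eye(k + 1)
        sub = R[:k, :k]
        pos = list(1000 + 100 * np.arange(k + 1))
        tab = _ewas_frame(pos, np.full(k + 1, b0), np.full(k + 1, 0.01))
        tab["se"] = s
        small = _region(list(tab["cpg"][:k]), pos[:k])
        big = _region(list(tab["cpg"]), pos)
        Rs = pd.DataFrame(sub, index=small.cpgs, columns=small.cpgs)
        Rb = pd.DataFrame(R, index=big.cpgs, columns=big.cpgs)
        assert region_statistic(big, tab, Rb).se \
            <= region_statistic(small, tab, Rs).se + 1e-12


# ---------------------------------------------------------------------------
# Sidak
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, t, expected", [
    (0.01, 1, 0.01),
    (0.01, 5, 1.0 - 0.99 ** 5),   # 0.0490099501
    (1.0, 17, 1.0),
])
def test_sidak_values(p, t, expected):
    assert sidak_adjust(p, t) == pytest.approx(expected, rel=1e-12)


def test_sidak_monotone_and_bounded(rng):
    for _ in range(50):
        p = float(rng.uniform(1e-12, 1.0))
        t = int(rng.integers(1, 1000))
        adj = sidak_adjust(p, t)
        assert p <= adj <= 1.0


# ---------------------------------------------------------------------------
# full caller vs brute force
# ---------------------------------------------------------------------------

def _brute_force_dmrs(ewas, M, p_enter=0.05, max_gap=500, max_window=20):
    """Independent enumeration: candidates, windows, GLS via explicit inv."""
    rows = [], 0
    tab = ewas.sort_values(["chrom", "pos"]).reset_index(drop=True)
    # multiplicity universe: every gap-connected window, counted directly
    windows = 0
    for _, sub in tab.groupby("chrom"):
        run = 1
        blocks = []
        pos = sorted(sub["pos"])
        for a, b in zip(pos, pos[1:]):
            if b - a <= max_gap:
                run += 1
            else:
                blocks.append(run)
                run = 1
        blocks.append(run)
        for bsize in blocks:
            for length in range(2, min(bsize, max_window) + 1):
                windows += bsize - length + 1
    rows = []
    runs, current = [], []
    for _, row in tab.iterrows():
        ok = row["p"] < p_enter
        if not ok:
            if len(current) >= 2:
                runs.append(current)
            current = []
            continue
        if current and (row["pos"] - current[-1]["pos"] > max_gap
                        or np.sign(row["estimate"])
                        != np.sign(current[-1]["estimate"])
                        or row["chrom"] != current[-1]["chrom"]):
            if len(current) >= 2:
                runs.append(current)
            current = []
        current.append(row)
    if len(current) >= 2:
        runs.append(current)
    best = []
    for run in runs:
        cpgs = [r["cpg"] for r in run]
        Y = M.beta[cpgs].to_numpy()
        Yc = Y - Y.mean(axis=0)
        R = np.corrcoef(Yc, rowvar=False)
        cand_best = None
        for i in range(len(run) - 1):
            for j in range(i + 2, min(len(run), i + max_window) + 1):
                b = np.array([r["estimate"] for r in run[i:j]])
                s = np.array([r["se"] for r in run[i:j]])
                V = np.outer(s, s) * R[i:j, i:j]
                Vi = np.linalg.inv(V)
                one = np.ones(j - i)
                est = (one @ Vi @ b) / (one @ Vi @ one)
                se = (one @ Vi @ one) ** -0.5
                p = 2 * stats.norm.sf(abs(est / se))
                if cand_best is None or p < cand_best[4]:
                    cand_best = (run[i]["pos"], run[j - 1]["pos"],
                                 cpgs[i:j], est, p)
        best.append(cand_best)
    for start, end, cpgs, est, p in best:
        rows.append({"start": start, "end": end, "cpgs": ",".join(cpgs),
                     "estimate": est, "p": p,
                     "p_adj": 1.0 - (1.0 - p) ** max(windows, 1)})
    return pd.DataFrame(rows)


def test_call_dmrs_matches_brute_force(rng):
    n, m = 150, 6
    beta = np.clip(0.5 + 0.05 * rng.normal(size=(n, m)), 0, 1)
    shift = np.repeat([0.0, 1.0], [n - 60, 60])
    beta[:, 1:4] = np.clip(beta[:, 1:4] + 0.04 * shift[:, None], 0, 1)
    M = make_methylation(beta)
    ewas = run_linear_ewas(M, pd.Series(shift, index=M.sample_ids))
    out = call_dmrs(ewas, M)
    brute = _brute_force_dmrs(ewas, M)
    assert len(out) == len(brute)
    if len(out):
        o = out.sort_values("start").reset_index(drop=True)
        b = brute.sort_values("start").reset_index(drop=True)
        assert list(o["cpgs"]) == list(b["cpgs"])
        assert np.allclose(o["estimate"], b["estimate"], atol=1e-10)
        assert np.allclose(o["p_adj"], b["p_adj"], rtol=1e-8)


def test_call_dmrs_empty_when_no_candidates(rng):
    beta = np.clip(0.5 + 0.05 * rng.normal(size=(80, 5)), 0, 1)
    M = make_methylation(beta)
    ewas = run_linear_ewas(M, pd.Series(rng.normal(size=80),
                                        index=M.sample_ids))
    ewas["p"] = 0.9  # force no candidates
    out = call_dmrs(ewas, M)
    assert len(out) == 0


def test_single_window_sidak_is_identity(rng):
    # exactly one gap-connected pair in the annotation -> T = 1 -> p_adj = p
    from epimediate import MethylationMatrix
    beta = np.clip(0.5 + 0.03 * rng.normal(size=(120, 4)), 0, 1)
    group = np.repeat([0.0, 1.0], 60)
    beta[:, 1:3] = np.clip(beta[:, 1:3] + 0.05 * group[:, None], 0, 1)
    cpgs = [f"cg{i:04d}" for i in range(4)]
    df = pd.DataFrame(beta, columns=cpgs,
                      index=[f"S{i:04d}" for i in range(120)])
    ann = pd.DataFrame({"chrom": "chr1",
                        "pos": [1000, 50_000, 50_100, 99_000]}, index=cpgs)
    ann.index.name = "cpg"
    M = MethylationMatrix(beta=df, annotation=ann)
    ewas = run_linear_ewas(M, pd.Series(group, index=M.sample_ids))
    out = call_dmrs(ewas, M)
    assert len(out) == 1
    assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0], rel=1e-9)


def test_null_dmr_calibration():
    """Exposure-free simulations: Sidak keeps the family-wise rate near 5%."""
    rng = np.random.default_rng(606)
    n_sig = n_tot = 0
    for rep in range(50):
        n, m = 200, 120
        beta = np.clip(0.5 + 0.04 * rng.normal(size=(n, m)), 0, 1)
        M = make_methylation(beta)
        x = pd.Series(rng.normal(size=n), index=M.sample_ids)
        out = call_dmrs(run_linear_ewas(M, x), M)
        n_tot += len(out)
        n_sig += int((out["p_adj"] < 0.05).sum())
    assert n_tot > 0
    assert n_sig / n_tot <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tot)


def test_bed_export_converts_coordinates():
    dmrs = pd.DataFrame({"chrom": ["chr2"], "start": [220325443],
                         "end": [220326041], "n_cpg": [5], "cpgs": ["a,b"],
                         "estimate": [0.02], "se": [0.005], "z": [4.0],
                         "p": [1e-5], "p_adj": [1e-3]})
    bed = dmr_table_to_bed(dmrs)
    assert bed["start"].iloc[0] == 220325442  # 0-based half-open
    assert bed["end"].iloc[0] == 220326041


def test_residual_correlation_removes_covariate_structure(rng):
    n = 300
    age = rng.normal(60, 8, n)
    common = 0.002 * (age - 60.0)
    beta = np.clip(0.5 + common[:, None] + 0.01 * rng.normal(size=(n, 3)),
                   0, 1)
    M = make_methylation(beta)
    cov = pd.DataFrame({"age": age}, index=M.sample_ids)
    raw = residual_cpg_correlation(M, list(M.beta.columns))
    adj = residual_cpg_correlation(M, list(M.beta.columns), cov)
    assert raw.iloc[0, 1] > 0.4          # age drives shared variance
    assert abs(adj.iloc[0, 1]) < 0.15    # gone after residualising
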