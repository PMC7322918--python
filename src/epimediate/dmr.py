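"""Differentially methylated region calling from EWAS summary statistics.

Candidate regions are maximal runs of nearby CpGs (gap <= ``max_gap`` bp)
whose single-site estimates share a sign and reach nominal P < ``p_enter``.
Each contiguous sub-window of length >= 2 is scored by inverse-variance
generalised least squares using the CpG-CpG correlation of
covariate-residualised methylation (V = diag(s) R diag(s)), the best
sub-window per candidate is kept, and a Sidak correction over the total
number of sub-windows evaluated genome-wide controls multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import MethylationMatrix, SurrogateVariableSet, _as_design

__all__ = [
    "CandidateRegion",
    "DmrRecord",
    "find_candidate_regions",
    "residual_cpg_correlation",
    "region_statistic",
    "call_dmrs",
    "sidak_adjust",
    "dmr_table_to_bed",
]

DMR_COLUMNS = ["chrom", "start", "end", "n_cpg", "cpgs",
               "estimate", "se", "z", "p", "p_adj"]


@dataclass
class CandidateRegion:
    """A contiguous run of qualifying CpGs (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    cpgs: list[str]

    def __post_init__(self):
        if len(self.cpgs) < 2:
            raise ValueError("a region needs more than one CpG")
        if self.end < self.start:
            raise ValueError("end precedes start")


@dataclass
class DmrRecord:
    chrom: str
    start: int
    end: int
    cpgs: list[str]
    estimate: float
    se: float
    z: float
    p: float
    p_adj: float | None = None

    @property
    def n_cpg(self) -> int:
        return len(self.cpgs)


def sidak_adjust(p: float, t: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^T over T tests."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if t < 1:
        raise ValueError("T must be >= 1")
    # -expm1(T log1p(-p)) is exact for tiny p where 1-(1-p)**T underflows
    if p == 1.0:
        return 1.0
    adj = -np.expm1(t * np.log1p(-p))
    return float(min(max(adj, np.nextafter(0, 1)), 1.0))


def find_candidate_regions(ewas: pd.DataFrame,
                           p_enter: float = 0.05,
                           max_gap: int = 500) -> list[CandidateRegion]:
    """Maximal same-sign low-P runs; singletons are discarded."""
    required = {"cpg", "chrom", "pos", "estimate", "p"}
    if not required.issubset(ewas.columns):
        raise ValueError(f"EWAS table lacks columns {required - set(ewas.columns)}")
    unannotated = ewas.loc[ewas["pos"].isna() | ewas["chrom"].isna(), "cpg"]
    if len(unannotated):
        raise ValueError(f"unannotated CpGs: {list(unannotated)[:10]}")
    regions: list[CandidateRegion] = []
    for chrom, sub in ewas.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        run: list[tuple[str, int, float]] = []

        def flush():
            if len(run) >= 2:
                regions.append(CandidateRegion(
                    chrom=str(chrom), start=run[0][1], end=run[-1][1],
                    cpgs=[c for c, _, _ in run]))
            run.clear()

        for _, row in sub.iterrows():
            qualifies = row["p"] < p_enter and np.isfinite(row["estimate"])
            if not qualifies:
                flush()
                continue
            sign = np.sign(row["estimate"])
            if run and (row["pos"] - run[-1][1] > max_gap or sign != run[-1][2]):
                flush()
            run.append((row["cpg"], int(row["pos"]), sign))
        flush()
    return regions


def residual_cpg_correlation(M: MethylationMatrix,
                             cpgs: list[str],
                             covariates: pd.DataFrame | None = None,
                             svs: SurrogateVariableSet | None = None) -> pd.DataFrame:
    """Pearson correlation of covariate-residualised methylation."""
    Y = M.beta[cpgs].to_numpy(dtype=float)
    X, _ = _as_design(covariates, svs, Y.shape[0])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = np.corrcoef((Y - X @ coef), rowvar=False)
    R = np.atleast_2d(R)
    return pd.DataFrame(R, index=cpgs, columns=cpgs)


def _gls_combine(b: np.ndarray, s: np.ndarray, R: np.ndarray,
                 ridge: float = 1e-6) -> tuple[float, float]:
    V = np.outer(s, s) * R
    one = np.ones(len(b))
    for attempt in (0.0, ridge):
        try:
            Vr = V + attempt * np.diag(s ** 2)
            c = np.linalg.cholesky(Vr)
            w = np.linalg.solve(c.T, np.linalg.solve(c, one))
            denom = one @ w
            est = float((w @ b) / denom)
            return est, float(denom ** -0.5)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "region covariance singular even after ridge repair")


def region_statistic(region: CandidateRegion,
                     ewas: pd.DataFrame,
                     R: pd.DataFrame) -> DmrRecord:
    """Inverse-variance GLS combination of the member CpG estimates."""
    sub = ewas.set_index("cpg").loc[region.cpgs]
    missing = [c for c in region.cpgs if c not in R.index]
    if missing:
        raise ValueError(f"CpGs absent from the correlation matrix: {missing}")
    b = sub["estimate"].to_numpy(dtype=float)
    s = sub["se"].to_numpy(dtype=float)
    Rm = R.loc[region.cpgs, region.cpgs].to_numpy(dtype=float)
    est, se = _gls_combine(b, s, Rm)
    z = est / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    return DmrRecord(chrom=region.chrom, start=region.start, end=region.end,
                     cpgs=list(region.cpgs), estimate=est, se=se, z=z, p=p)


def count_scan_windows(ewas: pd.DataFrame, max_gap: int = 500,
                       max_window: int = 20) -> int:
    """Number of contiguous sub-windows the genome-wide scan ranges over.

    Every run of consecutive CpGs with inter-CpG gaps <= ``max_gap``
    contributes all its length-2..``max_window`` contiguous sub-windows,
    whatever their P-values — the multiplicity universe must count the
    windows the scan *could* have selected, not only those surviving the
    candidate filter, or the Sidak correction inherits the selection bias
    of the P < p_enter entry rule.
    """
    total = 0
    for _, sub in ewas.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        breaks = np.where(np.diff(pos) > max_gap)[0]
        sizes = np.diff(np.concatenate([[0], breaks + 1, [len(pos)]]))
        for b in sizes:
            top = min(int(b), max_window)
            for length in range(2, top + 1):
                total += int(b) - length + 1
    return total


def call_dmrs(ewas: pd.DataFrame,
              M: MethylationMatrix,
              covariates: pd.DataFrame | None = None,
              svs: SurrogateVariableSet | None = None,
              p_enter: float = 0.05,
              max_gap: int = 500,
              alpha: float = 0.05,
              max_window: int = 20) -> pd.DataFrame:
    """Full DMR scan: candidates -> best sub-window -> Sidak adjustment.

    The Sidak universe T counts every gap-connected sub-window of the
    annotation (:func:`count_scan_windows`), so family-wise control holds
    by the union bound and T is reproducible from the run itself.
    """
    candidates = find_candidate_regions(ewas, p_enter=p_enter, max_gap=max_gap)
    total_windows = count_scan_windows(ewas, max_gap=max_gap,
                                       max_window=max_window)
    best: list[DmrRecord] = []
    ann = ewas.set_index("cpg")
    for cand in candidates:
        R = residual_cpg_correlation(M, cand.cpgs, covariates, svs)
        cand_best: DmrRecord | None = None
        k = len(cand.cpgs)
        for i in range(k - 1):
            for j in range(i + 2, min(k, i + max_window) + 1):
                sub_cpgs = cand.cpgs[i:j]
                window = CandidateRegion(
                    chrom=cand.chrom,
                    start=int(ann.loc[sub_cpgs[0], "pos"]),
                    end=int(ann.loc[sub_cpgs[-1], "pos"]),
                    cpgs=sub_cpgs)
                rec = region_statistic(window, ewas, R)
                if cand_best is None or rec.p < cand_best.p:
                    cand_best = rec
        if cand_best is not None:
            best.append(cand_best)
    rows = []
    for rec in best:
        rec.p_adj = sidak_adjust(rec.p, max(total_windows, 1))
        rows.append({"chrom": rec.chrom, "start": rec.start, "end": rec.end,
                     "n_cpg": rec.n_cpg, "cpgs": ",".join(rec.cpgs),
                     "estimate": rec.estimate, "se": rec.se, "z": rec.z,
                     "p": rec.p, "p_adj": rec.p_adj})
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    if len(out):
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def dmr_table_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6 export: 1-based inclusive -> 0-based half-open intervals."""
    return pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["start"].astype(int) - 1,
        "end": dmrs["end"].astype(int),
        "name": ["dmr_%d" % i for i in range(len(dmrs))],
        "score": np.minimum(1000, (-10.0 * np.log10(
            np.clip(dmrs["p_adj"].to_numpy(dtype=float), 1e-100, 1.0))).astype(int)),
        "strand": ".",
    })
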