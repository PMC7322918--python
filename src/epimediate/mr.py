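"""Two-sample Mendelian randomization of DMR methylation on survival.

Per-SNP Wald ratios beta_GD / beta_GP (delta-method SEs) are combined by
inverse-variance weighting generalised to correlated instruments: GLS of
the SNP-survival effects on the SNP-methylation effects through the
origin with error covariance Omega_ij = seGD_i seGD_j rho_ij, where rho is
the signed, allele-aligned SNP correlation matrix.  MR-Egger adds a free
intercept (the directional-pleiotropy test) after orienting every
instrument to a positive exposure effect.  A closed-form power
calculation on the log-OR scale completes the module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet, LdMatrix

__all__ = [
    "Z_95",
    "MrEstimate",
    "MrInput",
    "wald_ratio",
    "ivw_correlated",
    "egger_correlated",
    "harmonise",
    "mr_region",
    "mr_power",
]

Z_95 = 1.959964

MR_COLUMNS = ["region", "layout", "method", "n_snp", "beta", "se", "hr",
              "ci_low", "ci_high", "p", "intercept", "intercept_se",
              "intercept_ci_low", "intercept_ci_high", "intercept_p"]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class MrEstimate:
    """One causal estimate: log hazard per unit average-DMR methylation."""

    method: str
    n_snp: int
    beta: float
    se: float
    p: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - Z_95 * self.se)),
                float(np.exp(self.beta + Z_95 * self.se)))

    @property
    def intercept_ci95(self) -> tuple[float, float] | None:
        if self.intercept is None:
            return None
        return (self.intercept - Z_95 * self.intercept_se,
                self.intercept + Z_95 * self.intercept_se)


@dataclass
class MrInput:
    """Allele-harmonised per-SNP effect vectors plus the LD matrix."""

    snps: list[str]
    bgp: np.ndarray
    segp: np.ndarray
    bgd: np.ndarray
    segd: np.ndarray
    rho: np.ndarray
    log: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        k = len(self.snps)
        for name in ("bgp", "segp", "bgd", "segd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per SNP")
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (k, k):
            raise ValueError("rho must be k x k")
        if k == 0:
            raise ValueError("at least one SNP is required")

    @property
    def n_snp(self) -> int:
        return len(self.snps)


def _normal_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))


def wald_ratio(bgd: float, segd: float, bgp: float, segp: float,
               second_order: bool = True) -> MrEstimate:
    """Single-instrument ratio estimate beta_GD / beta_GP.

    The delta-method variance is seGD^2/bGP^2 + bGD^2 seGP^2 / bGP^4
    (second order); ``second_order=False`` drops the exposure-uncertainty
    term, the convention under which IVW weights are exact.
    """
    if bgp == 0:
        raise ValueError("beta_GP is zero: weak-instrument degenerate")
    beta = bgd / bgp
    var = segd ** 2 / bgp ** 2
    if second_order:
        var += bgd ** 2 * segp ** 2 / bgp ** 4
    se = float(np.sqrt(var))
    return MrEstimate(method="wald", n_snp=1, beta=float(beta), se=se,
                      p=_normal_p(beta / se))


def _omega(segd: np.ndarray, rho: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    omega = np.outer(segd, segd) * rho
    try:
        np.linalg.cholesky(omega)
        return omega
    except np.linalg.LinAlgError:
        omega = omega + ridge * np.diag(segd ** 2)
        np.linalg.cholesky(omega)  # raises if still singular
        return omega


def ivw_correlated(inp: MrInput) -> MrEstimate:
    """Correlation-adjusted IVW: origin-constrained GLS of bGD on bGP."""
    if inp.n_snp == 1:
        return wald_ratio(inp.bgd[0], inp.segd[0], inp.bgp[0], inp.segp[0],
                          second_order=False)
    omega = _omega(inp.segd, inp.rho)
    x = inp.bgp
    wy = np.linalg.solve(omega, inp.bgd)
    wx = np.linalg.solve(omega, x)
    denom = float(x @ wx)
    beta = float(x @ wy) / denom
    se = denom ** -0.5
    return MrEstimate(method="ivw", n_snp=inp.n_snp, beta=beta, se=se,
                      p=_normal_p(beta / se))


def egger_correlated(inp: MrInput, constrain_intercept: bool = False) -> MrEstimate:
    """Correlation-adjusted MR-Egger: GLS with design [1, bGP].

    Instruments are oriented so every beta_GP >= 0 (flipping beta_GD and
    the corresponding rows/columns of rho jointly).  The slope is the
    causal estimate; the intercept with its CI and P is the
    directional-pleiotropy test.  ``constrain_intercept`` pins the
    intercept at zero (then the slope equals IVW; internal check mode).
    """
    if inp.n_snp < 3 and not constrain_intercept:
        raise ValueError("MR-Egger needs >= 3 instruments")
    sign = np.where(inp.bgp < 0, -1.0, 1.0)
    x = inp.bgp * sign
    y = inp.bgd * sign
    rho = inp.rho * np.outer(sign, sign)
    omega = _omega(inp.segd, rho)
    if constrain_intercept:
        X = x[:, None]
    else:
        X = np.column_stack([np.ones(inp.n_snp), x])
    wX = np.linalg.solve(omega, X)
    xtwx = X.T @ wX
    coef = np.linalg.solve(xtwx, wX.T @ y)
    cov = np.linalg.inv(xtwx)
    if constrain_intercept:
        beta, se = float(coef[0]), float(np.sqrt(cov[0, 0]))
        return MrEstimate(method="egger_constrained", n_snp=inp.n_snp,
                          beta=beta, se=se, p=_normal_p(beta / se))
    beta, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    b0, se0 = float(coef[0]), float(np.sqrt(cov[0, 0]))
    return MrEstimate(method="egger", n_snp=inp.n_snp, beta=beta, se=se,
                      p=_normal_p(beta / se), intercept=b0, intercept_se=se0,
                      intercept_p=_normal_p(b0 / se0))


# ---------------------------------------------------------------------------
# harmonisation and per-region analysis
# ---------------------------------------------------------------------------

def harmonise(instrument_table: pd.DataFrame,
              snp_survival: pd.DataFrame,
              ld: LdMatrix,
              palindromic_maf: float = 0.42) -> MrInput | None:
    """Align the survival effects to the instrument's effect alleles.

    Survival rows whose effect allele matches the instrument's other
    allele are sign-flipped; incompatible alleles are dropped and logged;
    palindromic SNPs with MAF > ``palindromic_maf`` are dropped (strand
    ambiguity unresolvable from summary data).  Returns None when nothing
    survives.
    """
    surv = snp_survival.set_index("snp")
    snps, bgp, segp, bgd, segd, log = [], [], [], [], [], []
    for _, row in instrument_table.iterrows():
        snp = row["snp"]
        if snp not in surv.index:
            log.append(f"{snp}: absent from survival GWAS, dropped")
            continue
        srow = surv.loc[snp]
        if srow.get("status", "ok") != "ok" or not np.isfinite(srow["loghr"]):
            log.append(f"{snp}: unusable survival estimate, dropped")
            continue
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        sea = str(srow["effect_allele"])
        maf = min(float(row["eaf"]), 1.0 - float(row["eaf"]))
        if frozenset((ea, oa)) in _PALINDROMIC and maf > palindromic_maf:
            log.append(f"{snp}: palindromic with MAF {maf:.2f}, dropped")
            continue
        if sea == ea or sea == ".":
            flip = 1.0
        elif sea == oa:
            flip = -1.0
            log.append(f"{snp}: survival effect allele flipped")
        else:
            log.append(f"{snp}: incompatible alleles {sea} vs {ea}/{oa}, dropped")
            continue
        snps.append(snp)
        bgp.append(float(row["beta_gp"]))
        segp.append(float(row["se_gp"]))
        bgd.append(flip * float(srow["loghr"]))
        segd.append(float(srow["se"]))
    if not snps:
        return None
    rho = ld.submatrix(snps).to_numpy(dtype=float)
    return MrInput(snps=snps, bgp=np.array(bgp), segp=np.array(segp),
                   bgd=np.array(bgd), segd=np.array(segd), rho=rho, log=log)


def _estimate_row(region: str, layout: str, est: MrEstimate) -> dict:
    lo, hi = est.ci95
    row = {"region": region, "layout": layout, "method": est.method,
           "n_snp": est.n_snp, "beta": est.beta, "se": est.se, "hr": est.hr,
           "ci_low": lo, "ci_high": hi, "p": est.p,
           "intercept": np.nan, "intercept_se": np.nan,
           "intercept_ci_low": np.nan, "intercept_ci_high": np.nan,
           "intercept_p": np.nan}
    if est.intercept is not None:
        ilo, ihi = est.intercept_ci95
        row.update(intercept=est.intercept, intercept_se=est.intercept_se,
                   intercept_ci_low=ilo, intercept_ci_high=ihi,
                   intercept_p=est.intercept_p)
    return row


def _subset_input(inp: MrInput, keep: list[str]) -> MrInput:
    idx = [inp.snps.index(s) for s in keep]
    return MrInput(snps=keep, bgp=inp.bgp[idx], segp=inp.segp[idx],
                   bgd=inp.bgd[idx], segd=inp.segd[idx],
                   rho=inp.rho[np.ix_(idx, idx)], log=list(inp.log))


def mr_region(instrument: InstrumentSet,
              snp_survival: pd.DataFrame,
              ld: LdMatrix) -> pd.DataFrame:
    """Per-region MR layouts: all DMR CpGs, plus sentinel-CpG sensitivity.

    The full instrument is analysed by IVW (Wald if a single SNP) with
    MR-Egger added when >= 3 SNPs survive harmonisation.  The sentinel
    layout re-instruments using only the sentinel CpG's own mQTL effects.
    """
    region = instrument.region.name
    rows: list[dict] = []
    if instrument.empty:
        return pd.DataFrame(rows, columns=MR_COLUMNS)
    inp = harmonise(instrument.table, snp_survival, ld)
    if inp is None:
        return pd.DataFrame(rows, columns=MR_COLUMNS)
    if inp.n_snp == 1:
        est = wald_ratio(inp.bgd[0], inp.segd[0], inp.bgp[0], inp.segp[0])
        rows.append(_estimate_row(region, "all_dmr_cpgs", est))
    else:
        rows.append(_estimate_row(region, "all_dmr_cpgs", ivw_correlated(inp)))
        if inp.n_snp >= 3:
            rows.append(_estimate_row(region, "all_dmr_cpgs",
                                      egger_correlated(inp)))
    # sentinel sensitivity: SNPs proxying the sentinel CpG, with the
    # sentinel CpG's own mQTL effect as beta_GP
    sentinel = instrument.region.sentinel
    sent_recs = instrument.mqtls[instrument.mqtls["cpg"] == sentinel]
    sent_recs = sent_recs[sent_recs["snp"].isin(inp.snps)].drop_duplicates("snp")
    if len(sent_recs):
        sent_table = sent_recs.rename(columns={"beta": "beta_gp", "se": "se_gp"})
        sub = harmonise(sent_table, snp_survival, ld)
        if sub is not None:
            if sub.n_snp == 1:
                est = wald_ratio(sub.bgd[0], sub.segd[0], sub.bgp[0], sub.segp[0])
            else:
                est = ivw_correlated(sub)
            rows.append(_estimate_row(region, "sentinel", est))
    return pd.DataFrame(rows, columns=MR_COLUMNS)


def per_snp_table(inp: MrInput, region: str) -> pd.DataFrame:
    """Forest-plot-ready per-SNP Wald ratios."""
    rows = []
    for i, snp in enumerate(inp.snps):
        est = wald_ratio(inp.bgd[i], inp.segd[i], inp.bgp[i], inp.segp[i])
        lo, hi = est.ci95
        rows.append({"region": region, "snp": snp, "beta": est.beta,
                     "se": est.se, "hr": est.hr, "ci_low": lo, "ci_high": hi,
                     "p": est.p})
    return pd.DataFrame(rows)


def mr_power(n: int, r2: float, or_grid, alpha: float = 0.05) -> pd.DataFrame:
    """Asymptotic two-sided MR power on the log-OR scale.

    power = Phi(sqrt(n r2) |log OR| - z) + Phi(-sqrt(n r2) |log OR| - z)
    with z the 1 - alpha/2 normal quantile.  With r2 the variance in the
    exposure explained by the strongest single instrument this is a lower
    bound on the power of the combined-instrument analysis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < r2 <= 1.0):
        raise ValueError("r2 must lie in (0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    ors = np.atleast_1d(np.asarray(or_grid, dtype=float))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = np.sqrt(n * r2) * np.abs(np.log(ors))
    power = stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z)
    return pd.DataFrame({"odds_ratio": ors, "r2": r2, "n": n,
                         "alpha": alpha, "power": power})
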