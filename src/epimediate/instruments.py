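"""DMR overlap and genetic-instrument construction from mQTL summaries.

Exposure DMRs that intersect a survival DMR on the same chromosome define
shared regions.  For each shared region, instruments are built from mQTL
summary statistics by iterative per-CpG LD clumping: starting at the
sentinel CpG (lowest exposure-EWAS P), each subsequent CpG contributes
only mQTLs not already genome-wide significant for an earlier CpG, clumped
at r^2 < 0.01 within the step.  Each selected SNP's per-CpG effects are
then combined into one effect on average DMR methylation (beta_GP) by a
REML random-effects meta-analysis that accounts for the CpG-CpG
correlation of the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SharedRegion",
    "LdMatrix",
    "InstrumentSet",
    "overlap_dmrs",
    "filter_mqtls",
    "clump_snps",
    "build_instrument",
    "reml_meta_dmr_effect",
    "instrument_effects",
]

MQTL_COLUMNS = ["snp", "cpg", "effect_allele", "other_allele",
                "eaf", "beta", "se", "p"]

GENOME_WIDE_P = 5e-8


@dataclass
class SharedRegion:
    """An exposure DMR paired with an overlapping survival DMR."""

    exposure: str
    exposure_dmr: pd.Series
    survival_dmr: pd.Series
    shared_cpgs: list[str]
    sentinel: str

    def __post_init__(self):
        if not self.shared_cpgs:
            raise ValueError("shared CpG set must be non-empty")
        if self.sentinel not in self.shared_cpgs:
            raise ValueError("sentinel must be one of the shared CpGs")

    @property
    def name(self) -> str:
        d = self.exposure_dmr
        return f"{d['chrom']}:{int(d['start'])}-{int(d['end'])}"


@dataclass
class LdMatrix:
    """Signed, effect-allele-aligned SNP correlation matrix."""

    r: pd.DataFrame
    provenance: str = "unknown"

    def __post_init__(self):
        vals = self.r.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have a unit diagonal")
        if np.nanmax(np.abs(vals)) > 1.0 + 1e-8:
            raise ValueError("LD entries must lie in [-1, 1]")

    @classmethod
    def from_dosages(cls, dosage: pd.DataFrame, provenance: str = "panel") -> "LdMatrix":
        r = np.corrcoef(dosage.to_numpy(dtype=float), rowvar=False)
        r = np.atleast_2d(r)
        np.fill_diagonal(r, 1.0)
        return cls(r=pd.DataFrame(r, index=dosage.columns, columns=dosage.columns),
                   provenance=provenance)

    def submatrix(self, snps: list[str]) -> pd.DataFrame:
        missing = [s for s in snps if s not in self.r.index]
        if missing:
            raise ValueError(f"SNPs absent from the LD matrix: {missing}")
        return self.r.loc[snps, snps]


@dataclass
class InstrumentSet:
    """Selected mQTL SNPs for one shared region, with DMR-level effects.

    ``table`` rows: snp, effect_allele, other_allele, eaf, beta_gp, se_gp,
    tau2, n_cpg, cpg_trail, source_cpg.  ``mqtls`` keeps the filtered
    per-CpG records backing the set (needed for the sentinel sensitivity
    analysis downstream).
    """

    region: SharedRegion
    table: pd.DataFrame
    mqtls: pd.DataFrame

    def __post_init__(self):
        if len(self.table):
            if not np.isfinite(self.table["beta_gp"].to_numpy(dtype=float)).all():
                raise ValueError("beta_gp must be finite")
            if (self.table["se_gp"].to_numpy(dtype=float) <= 0).any():
                raise ValueError("se_gp must be positive")

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


def overlap_dmrs(exposure_dmrs: pd.DataFrame,
                 survival_dmrs: pd.DataFrame,
                 exposure_ewas: pd.DataFrame,
                 exposure: str = "exposure",
                 alpha: float = 0.05) -> list[SharedRegion]:
    """Pair exposure DMRs with intersecting survival DMRs.

    Both tables are restricted to Sidak-adjusted P < ``alpha``.  Shared
    CpGs are the intersection of the member lists (positional order
    preserved); the sentinel is the shared CpG with the lowest
    exposure-EWAS P, ties broken by genomic position.
    """
    def _sig(df):
        return df[df["p_adj"] < alpha] if "p_adj" in df.columns else df

    exp_sig, surv_sig = _sig(exposure_dmrs), _sig(survival_dmrs)
    pmap = exposure_ewas.set_index("cpg")
    shared: list[SharedRegion] = []
    for _, erow in exp_sig.iterrows():
        for _, srow in surv_sig.iterrows():
            if erow["chrom"] != srow["chrom"]:
                continue
            if erow["end"] < srow["start"] or srow["end"] < erow["start"]:
                continue
            e_cpgs = str(erow["cpgs"]).split(",")
            s_cpgs = set(str(srow["cpgs"]).split(","))
            common = [c for c in e_cpgs if c in s_cpgs]
            if not common:
                continue
            sentinel = min(common, key=lambda c: (pmap.loc[c, "p"],
                                                  pmap.loc[c, "pos"]))
            shared.append(SharedRegion(exposure=exposure,
                                       exposure_dmr=erow, survival_dmr=srow,
                                       shared_cpgs=common, sentinel=sentinel))
    return shared


def filter_mqtls(mqtls: pd.DataFrame,
                 cpgs: list[str],
                 maf_min: float = 0.05,
                 p_max: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Restrict to the region's CpGs with MAF > maf_min and P < p_max.

    Both inequalities are strict; MAF = min(eaf, 1 - eaf).
    """
    sub = mqtls[mqtls["cpg"].isin(set(cpgs))].copy()
    if not len(sub):
        return sub
    eaf = sub["eaf"].to_numpy(dtype=float)
    # round away float representation noise so eaf 0.95 gives MAF 0.05 exactly
    maf = np.round(np.minimum(eaf, 1.0 - eaf), 12)
    keep = (maf > maf_min) & (sub["p"].to_numpy(dtype=float) < p_max)
    return sub[keep].reset_index(drop=True)


def clump_snps(snp_stats: pd.DataFrame,
               ld: LdMatrix,
               r2_max: float = 0.01) -> list[str]:
    """Greedy LD clumping: keep the lowest-P SNP, discard r^2 >= r2_max.

    P-ties are broken lexicographically by SNP id, so the output is a
    deterministic function of the input set.
    """
    stats_ = snp_stats.drop_duplicates("snp")
    order = stats_.sort_values(["p", "snp"], kind="stable")["snp"].tolist()
    r = ld.submatrix(order).to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(order)}
    kept: list[str] = []
    alive = set(order)
    for snp in order:
        if snp not in alive:
            continue
        kept.append(snp)
        alive.discard(snp)
        i = pos[snp]
        for other in list(alive):
            if r[i, pos[other]] ** 2 >= r2_max:
                alive.discard(other)
    return kept


def build_instrument(region: SharedRegion,
                     mqtls: pd.DataFrame,
                     ld: LdMatrix,
                     exposure_ewas: pd.DataFrame,
                     r2_max: float = 0.01,
                     maf_min: float = 0.05,
                     p_max: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Iterative per-CpG clumping over the shared CpGs.

    CpGs are visited in ascending exposure-EWAS P starting at the
    sentinel.  At each step, the CpG's filtered mQTLs whose SNPs are not
    already genome-wide significant for an earlier CpG are clumped at
    ``r2_max`` and appended.  Returns the selection trail (snp,
    source_cpg, step) deduplicated by SNP id.
    """
    filtered = filter_mqtls(mqtls, region.shared_cpgs, maf_min, p_max)
    pmap = exposure_ewas.set_index("cpg")
    ordered = sorted(region.shared_cpgs,
                     key=lambda c: (pmap.loc[c, "p"], pmap.loc[c, "pos"], c))
    if ordered and ordered[0] != region.sentinel:
        # the sentinel is defined by the same ranking; enforce it anyway
        ordered.remove(region.sentinel)
        ordered.insert(0, region.sentinel)
    rows = []
    selected: set[str] = set()
    for step, cpg in enumerate(ordered):
        earlier = set(ordered[:step])
        assoc_earlier = set(filtered.loc[filtered["cpg"].isin(earlier), "snp"])
        cand = filtered[(filtered["cpg"] == cpg)
                        & ~filtered["snp"].isin(assoc_earlier)]
        if not len(cand):
            continue
        kept = clump_snps(cand[["snp", "p"]], ld, r2_max=r2_max)
        for snp in kept:
            if snp not in selected:
                selected.add(snp)
                rows.append({"snp": snp, "source_cpg": cpg, "step": step})
    return pd.DataFrame(rows, columns=["snp", "source_cpg", "step"])


def _restricted_loglik(tau2: float, y: np.ndarray, V: np.ndarray) -> float:
    sigma = V + tau2 * np.eye(len(y))
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    one = np.ones(len(y))
    si_one = np.linalg.solve(c.T, np.linalg.solve(c, one))
    si_y = np.linalg.solve(c.T, np.linalg.solve(c, y))
    denom = one @ si_one
    mu = (one @ si_y) / denom
    resid = y - mu
    si_r = np.linalg.solve(c.T, np.linalg.solve(c, resid))
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return -0.5 * (logdet + np.log(denom) + resid @ si_r)


def reml_meta_dmr_effect(betas, ses, R=None,
                         ridge: float = 1e-6) -> tuple[float, float, float]:
    """REML meta-analysis of one SNP's per-CpG effects.

    Model: y = mu 1 + eps, eps ~ N(0, V + tau^2 I) with
    V = diag(se) R diag(se).  Returns (beta_GP, se_GP, tau2); a single
    CpG degenerates to (beta, se, 0).
    """
    y = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("at least one CpG effect is required")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    if y.size == 1:
        return float(y[0]), float(s[0]), 0.0
    Rm = np.eye(y.size) if R is None else np.asarray(R, dtype=float)
    V = np.outer(s, s) * Rm
    if not np.isfinite(_restricted_loglik(0.0, y, V)):
        V = V + ridge * np.diag(s ** 2)
        if not np.isfinite(_restricted_loglik(0.0, y, V)):
            raise np.linalg.LinAlgError(
                "CpG covariance not positive definite after ridge repair")
    ub = max(10.0 * float(np.var(y)) + float(np.max(s) ** 2), 1e-8)
    res = optimize.minimize_scalar(lambda t: -_restricted_loglik(t, y, V),
                                   bounds=(0.0, ub), method="bounded",
                                   options={"xatol": 1e-10})
    tau2 = float(res.x)
    # snap to the boundary when the optimum is effectively zero
    if tau2 < 1e-10 or -_restricted_loglik(0.0, y, V) <= res.fun + 1e-12:
        tau2 = 0.0
    sigma = V + tau2 * np.eye(y.size)
    one = np.ones(y.size)
    w = np.linalg.solve(sigma, one)
    denom = one @ w
    mu = float((w @ y) / denom)
    return mu, float(denom ** -0.5), tau2


def instrument_effects(region: SharedRegion,
                       trail: pd.DataFrame,
                       filtered_mqtls: pd.DataFrame,
                       cpg_correlation: pd.DataFrame) -> InstrumentSet:
    """REML-combine each selected SNP's per-CpG effects into beta_GP."""
    rows = []
    for _, sel in trail.iterrows():
        snp = sel["snp"]
        recs = filtered_mqtls[filtered_mqtls["snp"] == snp]
        recs = recs.drop_duplicates("cpg").set_index("cpg")
        cpgs = [c for c in region.shared_cpgs if c in recs.index]
        R = cpg_correlation.loc[cpgs, cpgs].to_numpy(dtype=float)
        mu, se, tau2 = reml_meta_dmr_effect(
            recs.loc[cpgs, "beta"].to_numpy(dtype=float),
            recs.loc[cpgs, "se"].to_numpy(dtype=float), R)
        first = recs.loc[cpgs[0]]
        rows.append({
            "snp": snp,
            "effect_allele": first["effect_allele"],
            "other_allele": first["other_allele"],
            "eaf": float(first["eaf"]),
            "beta_gp": mu, "se_gp": se, "tau2": tau2,
            "n_cpg": len(cpgs), "cpg_trail": ";".join(cpgs),
            "source_cpg": sel["source_cpg"],
        })
    table = pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele",
                                        "eaf", "beta_gp", "se_gp", "tau2",
                                        "n_cpg", "cpg_trail", "source_cpg"])
    return InstrumentSet(region=region, table=table, mqtls=filtered_mqtls)
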