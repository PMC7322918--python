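"""Per-CpG association engines and surrogate-variable estimation.

Three engines share one summary-statistics currency (one row per CpG/SNP:
estimate, SE, P, N, status):

* linear EWAS — OLS of methylation beta values on an exposure with
  covariates (age, sex, other prognostic factors, surrogate variables);
* Cox EWAS — partial-likelihood log hazard per unit beta, model 1
  (age + sex + SVs) or model 2 (additionally the three prognostic factors);
* SNP survival GWAS — additive-dosage Cox per SNP with age + sex.

Surrogate variables are estimated by a two-step residual procedure:
residualise every CpG on the model covariates, pick the number of
components K by permutation parallel analysis of the residual eigenvalues,
and return the first K left singular vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .coxfit import CoxPartial

__all__ = [
    "MethylationMatrix",
    "SurrogateVariableSet",
    "MultipleTestingConfig",
    "SUGGESTIVE_P",
    "beta_to_m_values",
    "estimate_surrogate_variables",
    "run_linear_ewas",
    "run_cox_ewas",
    "run_snp_survival_gwas",
    "bonferroni_threshold",
    "sv_sensitivity",
]

#: suggestive evidence threshold (family-wise 0.05 for the 450K panel)
SUGGESTIVE_P = 2.4e-7

EWAS_COLUMNS = ["cpg", "chrom", "pos", "estimate", "se", "p", "n", "status"]


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta values plus per-CpG genomic annotation."""

    beta: pd.DataFrame
    annotation: pd.DataFrame  # index: cpg; columns: chrom, pos (1-based)

    def __post_init__(self):
        vals = self.beta.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.beta.columns.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"CpGs without annotation: {sorted(missing)[:5]}")
        if self.annotation["pos"].isna().any():
            bad = self.annotation.index[self.annotation["pos"].isna()]
            raise ValueError(f"CpGs with missing positions: {list(bad)[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    def sorted_cpgs(self) -> pd.Index:
        ann = self.annotation.loc[self.beta.columns]
        return ann.sort_values(["chrom", "pos"]).index


def beta_to_m_values(beta, eps: float = 1e-6) -> np.ndarray:
    """M-value transform log2(b / (1 - b)), clipped away from the bounds."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


@dataclass
class SurrogateVariableSet:
    """K orthonormal surrogate-variable scores per sample."""

    sv: np.ndarray  # samples x K
    k: int
    n_perm: int
    seed: int | None = None

    def __post_init__(self):
        if self.k != self.sv.shape[1]:
            raise ValueError("K does not match the score matrix")
        if self.k:
            gram = self.sv.T @ self.sv
            if np.max(np.abs(gram - np.diag(np.diag(gram)))) > 1e-8:
                raise ValueError("surrogate variables must be orthogonal")


@dataclass
class MultipleTestingConfig:
    alpha: float = 0.05
    m: int = 862491
    suggestive_p: float = SUGGESTIVE_P

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def bonferroni_threshold(cfg: MultipleTestingConfig | None = None, *,
                         alpha: float | None = None, m: int | None = None,
                         truncate: bool = True) -> float:
    """Family-wise threshold alpha/m.

    By default the mantissa is truncated to one decimal place, matching the
    display convention under which 0.05/862491 is reported as 5.7e-8.
    """
    if cfg is None:
        cfg = MultipleTestingConfig(alpha=0.05 if alpha is None else alpha,
                                    m=862491 if m is None else m)
    t = cfg.alpha / cfg.m
    if not truncate:
        return t
    exponent = int(np.floor(np.log10(t)))
    mantissa = t / 10.0 ** exponent
    mantissa = np.floor(mantissa * 10.0 + 1e-9) / 10.0
    return float(mantissa * 10.0 ** exponent)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _as_design(covariates: pd.DataFrame | None,
               svs: SurrogateVariableSet | None,
               n: int) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates + SVs, with column names for error messages."""
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate rows do not match sample count")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    if svs is not None and svs.k:
        for j in range(svs.k):
            cols.append(svs.sv[:, j])
            names.append(f"sv{j + 1}")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]):
    if X.shape[0] < X.shape[1]:
        raise ValueError("more covariates than samples")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the pivoted QR diagonal
        _, r, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * diag[0]] or [names[piv[-1]]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

def estimate_surrogate_variables(M: MethylationMatrix,
                                 model_covariates: pd.DataFrame | None = None,
                                 n_perm: int = 25,
                                 seed: int = 0,
                                 level: float = 0.05) -> SurrogateVariableSet:
    """Two-step residual SVA with permutation parallel analysis.

    Each CpG is residualised on the model covariates; K is the number of
    leading residual eigenvalues exceeding the (1 - level) quantile of the
    corresponding eigenvalues of column-permuted residuals.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    Y = M.beta.to_numpy(dtype=float)
    n = Y.shape[0]
    X, names = _as_design(model_covariates, None, n)
    _check_full_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef
    s = np.linalg.svd(R, compute_uv=False)
    kmax = len(s)
    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, kmax))
    Rp = np.empty_like(R)
    for b in range(n_perm):
        for j in range(R.shape[1]):
            Rp[:, j] = R[rng.permutation(n), j]
        perm[b] = np.linalg.svd(Rp, compute_uv=False)
    thresh = np.quantile(perm, 1.0 - level, axis=0)
    k = 0
    while k < kmax and s[k] > thresh[k]:
        k += 1
    U, _, _ = np.linalg.svd(R, full_matrices=False)
    return SurrogateVariableSet(sv=U[:, :k].copy(), k=k, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# linear EWAS
# ---------------------------------------------------------------------------

def run_linear_ewas(M: MethylationMatrix,
                    exposure: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    svs: SurrogateVariableSet | None = None) -> pd.DataFrame:
    """OLS of each CpG's beta value on the exposure with covariates.

    Returns one row per CpG: beta-scale slope, naive SE, two-sided t
    P-value (df = n - p), and the slope restated in percentage points.
    """
    e = exposure.loc[M.sample_ids].to_numpy(dtype=float)
    n = len(e)
    if np.ptp(e) == 0:
        raise ValueError("constant exposure: slope is unidentified")
    base, names = _as_design(covariates, svs, n)
    X = np.column_stack([e, base])
    names = ["exposure"] + names
    _check_full_rank(X, names)
    Y = M.beta.to_numpy(dtype=float)
    p = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    est = coef[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=df)
    ann = M.annotation.loc[M.beta.columns]
    out = pd.DataFrame({
        "cpg": M.beta.columns,
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "estimate": est,
        "se": se,
        "p": np.clip(pval, np.nextafter(0, 1), 1.0),
        "n": n,
        "status": "ok",
    })
    out["estimate_pct"] = 100.0 * out["estimate"]
    return out


# ---------------------------------------------------------------------------
# Cox EWAS and SNP survival GWAS
# ---------------------------------------------------------------------------

def _cox_scan(first_columns: pd.DataFrame, base: np.ndarray,
              partial: CoxPartial) -> tuple[np.ndarray, np.ndarray, list[str]]:
    n_var = first_columns.shape[1]
    est = np.full(n_var, np.nan)
    se = np.full(n_var, np.nan)
    status = []
    vals = first_columns.to_numpy(dtype=float)
    for i in range(n_var):
        x = vals[:, i]
        if np.ptp(x) == 0:
            status.append("monomorphic")
            continue
        fit = partial.fit(np.column_stack([x, base]))
        if fit.converged and np.isfinite(fit.se[0]):
            est[i] = fit.beta[0]
            se[i] = fit.se[0]
            status.append("ok")
        else:
            status.append("nonconverged")
    return est, se, status


def run_cox_ewas(M: MethylationMatrix,
                 survival_days: pd.Series,
                 event: pd.Series,
                 covariates: pd.DataFrame | None = None,
                 svs: SurrogateVariableSet | None = None,
                 model: int = 1,
                 exposures: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cox EWAS: log hazard per unit beta, Wald SE and normal P per CpG.

    Model 1 adjusts for the supplied covariates (age, sex) and SVs;
    model 2 additionally requires the three prognostic factors in
    ``exposures``.  Non-convergent fits are flagged, not dropped.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    t = survival_days.loc[M.sample_ids].to_numpy(dtype=float)
    d = event.loc[M.sample_ids].to_numpy()
    if d.sum() == 0:
        raise ValueError("no events: survival EWAS is degenerate")
    if d.sum() < 10:
        raise ValueError("fewer than 10 events: survival EWAS unreliable")
    cov = covariates
    if model == 2:
        if exposures is None or exposures.shape[1] < 3:
            raise ValueError("model 2 requires the three prognostic factors")
        cov = exposures if cov is None else pd.concat(
            [cov, exposures.loc[cov.index]], axis=1)
    base, names = _as_design(cov, svs, len(t))
    base = base[:, 1:]  # Cox partial likelihood has no intercept
    partial = CoxPartial(t, d)
    est, se, status = _cox_scan(M.beta, base, partial)
    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(est / se))
    ann = M.annotation.loc[M.beta.columns]
    return pd.DataFrame({
        "cpg": M.beta.columns,
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "estimate": est,
        "se": se,
        "p": pval,
        "n": len(t),
        "status": status,
    })


def run_snp_survival_gwas(dosage: pd.DataFrame,
                          survival_days: pd.Series,
                          event: pd.Series,
                          age: pd.Series,
                          sex: pd.Series,
                          effect_alleles: pd.Series | None = None) -> pd.DataFrame:
    """Additive-dosage Cox per SNP, adjusting for age and sex.

    Monomorphic SNPs yield flagged rows with missing estimates so the MR
    stage sees explicit missingness.
    """
    vals = dosage.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    idx = dosage.index
    t = survival_days.loc[idx].to_numpy(dtype=float)
    d = event.loc[idx].to_numpy()
    if d.sum() < 10:
        raise ValueError("fewer than 10 events: SNP survival GWAS unreliable")
    base = np.column_stack([age.loc[idx].to_numpy(dtype=float),
                            sex.loc[idx].to_numpy(dtype=float)])
    partial = CoxPartial(t, d)
    est, se, status = _cox_scan(dosage, base, partial)
    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(est / se))
    if effect_alleles is None:
        ea = ["." for _ in dosage.columns]
    else:
        ea = [str(effect_alleles.get(s, ".")) for s in dosage.columns]
    return pd.DataFrame({
        "snp": dosage.columns,
        "effect_allele": ea,
        "loghr": est,
        "se": se,
        "p": pval,
        "n_events": int(d.sum()),
        "status": status,
    })


# ---------------------------------------------------------------------------
# SV sensitivity
# ---------------------------------------------------------------------------

def sv_sensitivity(svs: SurrogateVariableSet,
                   covariate: pd.Series | np.ndarray) -> dict:
    """Per-SV Pearson correlation with a covariate plus the joint R-squared.

    Returns a dict with a per-SV table, the joint R^2 of the covariate
    regressed on all SVs, and the SVs with nominal P < 0.05.
    """
    y = np.asarray(covariate, dtype=float)
    if len(y) != svs.sv.shape[0]:
        raise ValueError("covariate length does not match sample count")
    if np.ptp(y) == 0:
        raise ValueError("constant covariate")
    rows = []
    for j in range(svs.k):
        r, p = stats.pearsonr(svs.sv[:, j], y)
        rows.append((f"sv{j + 1}", r, p))
    table = pd.DataFrame(rows, columns=["sv", "r", "p"])
    if svs.k == 0:
        r2 = 0.0
    else:
        X = np.column_stack([np.ones(len(y)), svs.sv])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2 = float(1.0 - (resid ** 2).sum() / tss)
    flagged = list(table.loc[table["p"] < 0.05, "sv"])
    return {"per_sv": table, "joint_r2": r2, "flagged": flagged}
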