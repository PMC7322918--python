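"""Planted-truth validation scenarios.

Each scenario fixes one set of study conditions and measures one property
of the pipeline against known ground truth:

* :func:`mr_recovery_scenario` — a strong-cis-mQTL region (AHRR/SPEG-class
  architecture) with a planted mediation log-HR; runs the full genetic
  chain (panel mQTL OLS -> filtering -> iterative clumping -> REML
  combination -> SNP survival GWAS -> harmonisation -> correlated IVW) on
  the planted region and reports the per-replicate causal estimates,
  standard errors and CI coverage.
* :func:`dmr_recovery_scenario` — a noise-dominated exposure DMR with a
  planted beta-scale shift; runs the EWAS -> DMR stage and reports how
  often the region is recovered at Sidak-adjusted P < 0.05.

Scenario parameters were fixed by a design-stage power analysis of the
stated study conditions (see the methods note); they are study
definitions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import call_dmrs, residual_cpg_correlation
from .ewas import run_linear_ewas, run_snp_survival_gwas
from .instruments import (LdMatrix, SharedRegion, build_instrument,
                          filter_mqtls, instrument_effects)
from .mr import Z_95, mr_region
from .pipeline import mqtl_summary_from_panel
from .simulate import (SimulationConfig, simulate_clinical_cohort,
                       simulate_reference_panel)

__all__ = [
    "mr_scenario_config",
    "dmr_scenario_config",
    "mr_chain_once",
    "mr_recovery_scenario",
    "dmr_recovery_scenario",
]


def mr_scenario_config(mediation: float = 0.3,
                       n_panel: int = 2000,
                       n_cohort: int = 1000,
                       seed: int = 0) -> SimulationConfig:
    """One strong-mQTL region carrying the planted mediation effect.

    24 cis SNPs in moderate LD (r = 0.3 between neighbours) with per-allele
    effects of 0.13-0.20 beta give the region the genetic variance a
    detectable mediation signal needs at ~26% events.
    """
    return SimulationConfig(
        n_panel=n_panel, n_cohort=n_cohort, n_cpg=10, n_region=1,
        n_snp_per_region=24, n_cpg_per_region=5,
        maf_range=(0.25, 0.45), ld_decay=0.3,
        cis_effect_range=(0.13, 0.20), region_baseline_range=(0.45, 0.55),
        exposure_effects={"smoking": (-0.05,), "alcohol": (0.0,),
                          "hpv16_e6": (0.0,)},
        mediation_loghr=(mediation,),
        n_batch=1, batch_effect_sd=0.0, seed=seed)


def dmr_scenario_config(shift: float = 0.05,
                        n_cohort: int = 1000,
                        seed: int = 0) -> SimulationConfig:
    """A noise-dominated 5-CpG exposure DMR planted among 200 CpGs."""
    return SimulationConfig(
        n_panel=200, n_cohort=n_cohort, n_cpg=200, n_region=1,
        n_snp_per_region=4, n_cpg_per_region=5,
        maf_range=(0.1, 0.4), ld_decay=0.5,
        cis_effect_range=(0.01, 0.03),
        exposure_effects={"smoking": (-shift,), "alcohol": (0.0,),
                          "hpv16_e6": (0.0,)},
        mediation_loghr=(0.0,),
        n_batch=1, batch_effect_sd=0.0, seed=seed)


def mr_chain_once(config: SimulationConfig) -> pd.DataFrame:
    """Run the mQTL-instrument -> survival-GWAS -> MR chain once.

    The planted region's identity comes from the truth table (the
    discovery stages have their own scenario); everything downstream —
    summary statistics, filtering, clumping, REML combination, Cox GWAS,
    harmonisation and the correlated-instrument estimators — is the
    production code path.
    """
    panel, truth = simulate_reference_panel(config)
    cohort = simulate_clinical_cohort(config, truth)
    mqtls = mqtl_summary_from_panel(panel, truth)
    ld = LdMatrix.from_dosages(panel.dosage, provenance="synthetic panel")
    members = truth.member_cpgs(0)
    cov = cohort.phenotypes[["age", "sex"]]
    ewas = run_linear_ewas(cohort.methylation,
                           cohort.phenotypes["smoking_ever"], cov)
    pmap = ewas.set_index("cpg")
    sentinel = min(members, key=lambda c: (pmap.loc[c, "p"], pmap.loc[c, "pos"]))
    row = truth.regions.loc[0]
    dmr_row = pd.Series({"chrom": row["chrom"], "start": row["start"],
                         "end": row["end"], "cpgs": ",".join(members)})
    shared = SharedRegion(exposure="smoking", exposure_dmr=dmr_row,
                          survival_dmr=dmr_row, shared_cpgs=members,
                          sentinel=sentinel)
    trail = build_instrument(shared, mqtls, ld, ewas)
    filtered = filter_mqtls(mqtls, members)
    R = residual_cpg_correlation(panel.methylation, members)
    inst = instrument_effects(shared, trail, filtered, R)
    gwas = run_snp_survival_gwas(
        cohort.dosage[list(inst.table["snp"])], cohort.survival_days,
        cohort.event, cohort.phenotypes["age"], cohort.phenotypes["sex"],
        effect_alleles=truth.snps["effect_allele"])
    return mr_region(inst, gwas, ld)


def mr_recovery_scenario(n_rep: int = 200, mediation: float = 0.3,
                         n_panel: int = 2000, n_cohort: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Replicate the MR chain; one row per replicate with the IVW estimate."""
    rows = []
    ss = np.random.SeedSequence([seed, 42])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_rep)]
    for rep, s in enumerate(child_seeds):
        cfg = mr_scenario_config(mediation=mediation, n_panel=n_panel,
                                 n_cohort=n_cohort, seed=s)
        res = mr_chain_once(cfg)
        main = res[(res["layout"] == "all_dmr_cpgs")
                   & (res["method"].isin(["ivw", "wald"]))]
        if not len(main):
            continue
        r = main.iloc[0]
        covered = (r["beta"] - Z_95 * r["se"] <= mediation
                   <= r["beta"] + Z_95 * r["se"])
        rows.append({"rep": rep, "method": r["method"], "n_snp": r["n_snp"],
                     "beta": r["beta"], "se": r["se"], "p": r["p"],
                     "covered": bool(covered)})
    return pd.DataFrame(rows)


def dmr_recovery_scenario(n_rep: int = 100, shift: float = 0.05,
                          n_cohort: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Replicate the exposure EWAS -> DMR stage on the planted region."""
    rows = []
    ss = np.random.SeedSequence([seed, 43])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_rep)]
    for rep, s in enumerate(child_seeds):
        cfg = dmr_scenario_config(shift=shift, n_cohort=n_cohort, seed=s)
        _, truth = simulate_reference_panel(cfg)
        cohort = simulate_clinical_cohort(cfg, truth)
        cov = cohort.phenotypes[["age", "sex"]]
        ewas = run_linear_ewas(cohort.methylation,
                               cohort.phenotypes["smoking_ever"], cov)
        dmrs = call_dmrs(ewas, cohort.methylation, cov)
        row = truth.regions.loc[0]
        hit = dmrs[(dmrs["chrom"] == row["chrom"])
                   & (dmrs["start"] <= row["end"])
                   & (dmrs["end"] >= row["start"])
                   & (dmrs["p_adj"] < 0.05)]
        rows.append({"rep": rep, "recovered": bool(len(hit)),
                     "n_dmr": len(dmrs)})
    return pd.DataFrame(rows)
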