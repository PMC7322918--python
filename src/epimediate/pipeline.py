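"""End-to-end orchestration: simulate -> EWAS -> DMR -> instruments -> MR.

One :func:`run_pipeline` call executes the stages in dependency order on a
synthetic panel + cohort, writes every interchange table under the output
directory, and emits a run manifest (config hash, seeds, per-file
checksums, stage counts).  A stage failure halts downstream stages; the
manifest still records the failure point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as eio
from .dmr import call_dmrs, dmr_table_to_bed, residual_cpg_correlation
from .ewas import (bonferroni_threshold, estimate_surrogate_variables,
                   run_cox_ewas, run_linear_ewas, run_snp_survival_gwas)
from .instruments import (LdMatrix, build_instrument, filter_mqtls,
                          instrument_effects, overlap_dmrs)
from .mr import MR_COLUMNS, mr_power, mr_region
from .simulate import (EXPOSURES, CohortData, SimulationConfig, TruthTable,
                       simulate_clinical_cohort, simulate_reference_panel)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "mqtl_summary_from_panel"]


@dataclass
class PipelineConfig:
    """Thresholds, toggles and paths for one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    p_enter: float = 0.05
    max_gap: int = 500
    maf_min: float = 0.05
    p_max: float = 5e-8
    r2_max: float = 0.01
    alpha_dmr: float = 0.05
    alpha: float = 0.05
    run_sva: bool = True
    run_model2: bool = True
    sva_n_perm: int = 25
    power_r2_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    power_or_grid: tuple[float, ...] = (1.1, 1.2, 1.3, 1.5, 2.0, 3.0)
    out_dir: str = "pipeline_out"
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in (("p_enter", 0, 1), ("maf_min", 0, 0.5),
                             ("p_max", 0, 1), ("r2_max", 0, 1),
                             ("alpha_dmr", 0, 1), ("alpha", 0, 1)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        # one seed governs every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("maf_range", "mediation_loghr", "cis_effect_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "exposure_effects" in sim:
                sim["exposure_effects"] = {k: tuple(v) for k, v in
                                           sim["exposure_effects"].items()}
            sim = SimulationConfig(**sim)
        for key in ("power_r2_grid", "power_or_grid"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash the science, not the destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True, default=str) + "\n",
                        encoding="utf-8")
        return path


def mqtl_summary_from_panel(panel: CohortData, truth: TruthTable) -> pd.DataFrame:
    """Per-region OLS mQTL summary statistics from the reference panel.

    For every (region SNP, member CpG) pair: simple-regression slope of
    beta on dosage, its SE, two-sided t P-value and the effect-allele
    frequency observed in the panel.
    """
    rows = []
    n = len(panel.dosage)
    for r in truth.regions.index:
        snps = truth.snps[truth.snps["region"] == r]
        cpgs = truth.member_cpgs(int(r))
        D = panel.dosage[snps.index].to_numpy(dtype=float)
        Y = panel.methylation.beta[cpgs].to_numpy(dtype=float)
        Dc = D - D.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        var_d = (Dc ** 2).sum(axis=0)
        for j, snp in enumerate(snps.index):
            if var_d[j] == 0:
                continue
            slope = (Dc[:, j] @ Yc) / var_d[j]
            resid = Yc - np.outer(Dc[:, j], slope)
            sigma2 = (resid ** 2).sum(axis=0) / (n - 2)
            se = np.sqrt(sigma2 / var_d[j])
            tval = slope / se
            pval = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
            eaf = float(D[:, j].mean() / 2.0)
            for k, cpg in enumerate(cpgs):
                rows.append({
                    "snp": snp, "cpg": cpg,
                    "effect_allele": snps.loc[snp, "effect_allele"],
                    "other_allele": snps.loc[snp, "other_allele"],
                    "eaf": eaf, "beta": slope[k], "se": se[k],
                    "p": max(pval[k], np.nextafter(0, 1)),
                })
    return pd.DataFrame(rows, columns=eio.SCHEMAS["mqtl"].keys())


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full analysis chain on a synthetic panel + cohort."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed,
                           started=time.time())
    manifest.thresholds = {
        "p_enter": cfg.p_enter, "max_gap": cfg.max_gap,
        "maf_min": cfg.maf_min, "p_max": cfg.p_max, "r2_max": cfg.r2_max,
        "alpha_dmr": cfg.alpha_dmr, "alpha": cfg.alpha,
        "bonferroni_default": bonferroni_threshold(),
    }

    def _emit(name: str, writer, df, columns=None):
        path = out / name
        if columns is None:
            writer(df, path)
        else:
            writer(df, path, columns)
        manifest.checksums[name] = eio.sha256sum(path)

    stage = "simulate"
    try:
        panel, truth = simulate_reference_panel(cfg.sim)
        cohort = simulate_clinical_cohort(cfg.sim, truth)
        manifest.counts["event_fraction"] = cohort.event_fraction
        manifest.counts["n_panel"] = len(panel.dosage)
        manifest.counts["n_cohort"] = len(cohort.dosage)
        _emit("cohort_dosage.tsv", eio.write_matrix, cohort.dosage)
        _emit("cohort_methylation.tsv", eio.write_matrix, cohort.methylation.beta)
        pheno = cohort.phenotypes.copy()
        pheno["survival_days"] = cohort.survival_days
        pheno["event"] = cohort.event
        _emit("cohort_phenotypes.tsv", eio.write_matrix, pheno)
        ann = truth.annotation.reset_index()
        _emit("cpg_annotation.tsv", eio.write_table, ann)
        truth_out = truth.snps.reset_index()
        _emit("truth_snps.tsv", eio.write_table, truth_out)
        _emit("truth_regions.tsv", eio.write_table, truth.regions.reset_index())
        manifest.stages_completed.append(stage)

        stage = "sva"
        base_cov = cohort.phenotypes[["age", "sex"]]
        svs = None
        if cfg.run_sva:
            # the SVA model must carry every variable of interest so the
            # surrogate variables stay orthogonal to the planned contrasts
            sva_model = cohort.phenotypes[
                ["age", "sex", "smoking_ever", "alcohol_units", "hpv16_e6_pos"]]
            svs = estimate_surrogate_variables(
                cohort.methylation, sva_model, n_perm=cfg.sva_n_perm,
                seed=cfg.seed)
            manifest.counts["n_surrogate_variables"] = svs.k
        manifest.stages_completed.append(stage)

        stage = "ewas"
        exp_cols = {"smoking": "smoking_ever", "alcohol": "alcohol_units",
                    "hpv16_e6": "hpv16_e6_pos"}
        ewas_tables: dict[str, pd.DataFrame] = {}
        for e in EXPOSURES:
            others = [exp_cols[o] for o in EXPOSURES if o != e]
            cov = cohort.phenotypes[["age", "sex"] + others]
            tab = run_linear_ewas(cohort.methylation,
                                  cohort.phenotypes[exp_cols[e]], cov, svs)
            ewas_tables[e] = tab
            _emit(f"ewas_{e}.tsv", eio.write_table, tab,
                  list(eio.SCHEMAS["ewas"].keys()))
        manifest.counts["n_cpg_tested"] = len(next(iter(ewas_tables.values())))
        manifest.stages_completed.append(stage)

        stage = "ewas_survival"
        surv1 = run_cox_ewas(cohort.methylation, cohort.survival_days,
                             cohort.event, base_cov, svs, model=1)
        ewas_tables["survival_model1"] = surv1
        _emit("ewas_survival_model1.tsv", eio.write_table, surv1,
              list(eio.SCHEMAS["ewas"].keys()))
        if cfg.run_model2:
            expos = cohort.phenotypes[list(exp_cols.values())]
            surv2 = run_cox_ewas(cohort.methylation, cohort.survival_days,
                                 cohort.event, base_cov, svs, model=2,
                                 exposures=expos)
            _emit("ewas_survival_model2.tsv", eio.write_table, surv2,
                  list(eio.SCHEMAS["ewas"].keys()))
        manifest.stages_completed.append(stage)

        stage = "dmr"
        dmr_tables: dict[str, pd.DataFrame] = {}
        for name, tab in ewas_tables.items():
            cov = base_cov  # correlation structure uses the shared covariates
            dmrs = call_dmrs(tab, cohort.methylation, cov, svs,
                             p_enter=cfg.p_enter, max_gap=cfg.max_gap,
                             alpha=cfg.alpha_dmr)
            dmr_tables[name] = dmrs
            _emit(f"dmr_{name}.tsv", eio.write_table, dmrs,
                  list(eio.SCHEMAS["dmr"].keys()))
            if len(dmrs):
                _emit(f"dmr_{name}.bed", eio.write_bed, dmr_table_to_bed(dmrs))
        manifest.counts["n_dmr"] = {k: int((v["p_adj"] < cfg.alpha_dmr).sum())
                                    for k, v in dmr_tables.items()}
        manifest.stages_completed.append(stage)

        stage = "overlap"
        shared = []
        for e in EXPOSURES:
            shared.extend(overlap_dmrs(dmr_tables[e],
                                       dmr_tables["survival_model1"],
                                       ewas_tables[e], exposure=e,
                                       alpha=cfg.alpha_dmr))
        manifest.counts["n_shared_regions"] = len(shared)
        manifest.counts["n_shared_cpgs"] = int(
            sum(len(s.shared_cpgs) for s in shared))
        manifest.stages_completed.append(stage)

        stage = "mqtl"
        mqtls = mqtl_summary_from_panel(panel, truth)
        _emit("mqtl_summary.tsv", eio.write_table, mqtls)
        ld = LdMatrix.from_dosages(panel.dosage, provenance="synthetic panel")
        _emit("ld_matrix.tsv", eio.write_ld_matrix, ld.r)
        manifest.stages_completed.append(stage)

        stage = "instruments"
        instrument_sets = []
        inst_rows = []
        for s in shared:
            trail = build_instrument(s, mqtls, ld, ewas_tables[s.exposure],
                                     r2_max=cfg.r2_max, maf_min=cfg.maf_min,
                                     p_max=cfg.p_max)
            filtered = filter_mqtls(mqtls, s.shared_cpgs, cfg.maf_min, cfg.p_max)
            if not len(trail):
                continue
            R = residual_cpg_correlation(cohort.methylation, s.shared_cpgs,
                                         base_cov, svs)
            inst = instrument_effects(s, trail, filtered, R)
            instrument_sets.append(inst)
            tab = inst.table.copy()
            tab.insert(0, "region", inst.region.name)
            inst_rows.append(tab)
        if inst_rows:
            inst_table = pd.concat(inst_rows, ignore_index=True)
        else:
            inst_table = pd.DataFrame(columns=list(eio.SCHEMAS["instrument"]))
        _emit("instruments.tsv", eio.write_table, inst_table,
              list(eio.SCHEMAS["instrument"].keys()))
        manifest.counts["n_instrument_snps"] = int(len(inst_table))
        manifest.stages_completed.append(stage)

        stage = "snp_survival"
        inst_snps = sorted(set(inst_table["snp"])) if len(inst_table) else []
        if inst_snps:
            gwas = run_snp_survival_gwas(
                cohort.dosage[inst_snps], cohort.survival_days, cohort.event,
                cohort.phenotypes["age"], cohort.phenotypes["sex"],
                effect_alleles=truth.snps["effect_allele"])
        else:
            gwas = pd.DataFrame(columns=list(eio.SCHEMAS["snp_survival"]))
        _emit("snp_survival.tsv", eio.write_table, gwas,
              list(eio.SCHEMAS["snp_survival"].keys()))
        manifest.stages_completed.append(stage)

        stage = "mr"
        mr_rows = [mr_region(inst, gwas, ld) for inst in instrument_sets]
        mr_table = (pd.concat(mr_rows, ignore_index=True) if mr_rows
                    else pd.DataFrame(columns=MR_COLUMNS))
        _emit("mr_results.tsv", eio.write_table, mr_table)
        power_rows = [mr_power(cfg.sim.n_cohort, r2, cfg.power_or_grid,
                               cfg.alpha) for r2 in cfg.power_r2_grid]
        _emit("mr_power.tsv", eio.write_table,
              pd.concat(power_rows, ignore_index=True))
        manifest.counts["n_mr_estimates"] = int(len(mr_table))
        manifest.stages_completed.append(stage)
    except Exception as exc:  # manifest records partial failure, then re-raise
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.finished = time.time()
        manifest.write(out / "run_manifest.json")
        raise
    manifest.finished = time.time()
    manifest.write(out / "run_manifest.json")
    return manifest
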