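"""Synthetic reference panel and clinical cohort with known mediation.

Emulates the study design the pipeline targets: whole-blood EPIC-like
methylation in an oropharyngeal-cancer cohort (~73% ever smokers, ~26%
deaths by administrative censoring at ~2.75 years), a separate unrelated
reference panel for cis-mQTL discovery, spatially clustered
exposure-associated methylation regions, and a planted causal path
genotype -> regional methylation -> survival hazard whose strength
(``mediation_loghr``, log hazard per unit average-DMR beta) is the
quantity the downstream Mendelian-randomization stage must recover.

Genetic layer: per region, haplotypes follow a Markov "copy" chain so the
signed correlation between adjacent SNPs equals ``ld_decay`` exactly in
expectation (and decays as ``ld_decay**|i-j|``); SNPs within a region share
one minor-allele frequency drawn from ``maf_range``.  Methylation: effects
are stated on the beta scale, applied on the logit scale through the local
slope at each CpG's baseline, with Gaussian logit-scale noise, then mapped
back through the logistic function — values stay strictly inside (0, 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ewas import MethylationMatrix

__all__ = [
    "EXPOSURES",
    "SimulationConfig",
    "QuestionnaireRecord",
    "TruthTable",
    "CohortData",
    "simulate_reference_panel",
    "simulate_clinical_cohort",
    "derive_smoking_status",
    "derive_alcohol_units",
    "cigarette_equivalents_per_day",
    "classify_hpv_serostatus",
    "HPV16_E6_MFI_CUTOFF",
    "CIGAR_CIGARETTE_EQUIVALENTS",
]

EXPOSURES = ("smoking", "alcohol", "hpv16_e6")

#: one cigar counts as this many cigarettes when computing daily equivalents
CIGAR_CIGARETTE_EQUIVALENTS = 4.0

#: HPV16 E6 median-fluorescence-intensity seropositivity cut-off (inclusive)
HPV16_E6_MFI_CUTOFF = 1000.0

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel + cohort.

    Defaults mirror the target cohort: 409 patients, ~26% deaths by the
    administrative censoring day 1005 (~2.75 years), ~73% ever smokers,
    ~74% drinkers with median ~22.5 units/week, ~67% HPV16 E6 seropositive.
    """

    n_panel: int = 2000
    n_cohort: int = 409
    n_cpg: int = 2000
    n_region: int = 4
    n_snp_per_region: int = 8
    n_cpg_per_region: int = 5
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_decay: float = 0.8
    # per-exposure, per-region methylation shift on the beta scale, per unit
    # of the exposure variable (ever-smoking 0/1, alcohol units/week,
    # HPV16 E6 seropositivity 0/1)
    exposure_effects: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "smoking": (-0.05, 0.05, 0.0, 0.0),
            "alcohol": (0.0, 0.0, -0.001, 0.0),
            "hpv16_e6": (0.0, 0.0, 0.0, -0.02),
        }
    )
    # log hazard per unit average beta across each region's member CpGs
    # (1.4/unit beta ~ hazard ratio 1.28 per M-value unit at a CpG near 50%
    # methylation, a strong prognostic locus)
    mediation_loghr: tuple[float, ...] = (1.4, 0.0, 0.0, 0.0)
    # optional direct (non-mediated) exposure effects on the log hazard
    direct_exposure_loghr: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 3.0e-4
    censor_day: float = 1005.0
    n_batch: int = 2
    batch_effect_sd: float = 0.01
    batch_affected_frac: float = 0.3
    noise_sd: float = 0.03
    cis_effect_range: tuple[float, float] = (0.02, 0.05)
    region_baseline_range: tuple[float, float] = (0.35, 0.65)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_panel", "n_cohort", "n_cpg", "n_region",
                     "n_snp_per_region", "n_cpg_per_region", "n_batch"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ValueError("ld_decay must lie in [0, 1]")
        if self.censor_day <= 0:
            raise ValueError("censor_day must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_cpg < self.n_region * self.n_cpg_per_region:
            raise ValueError("n_cpg smaller than the planted region CpGs")
        if self.n_cpg_per_region < 2:
            raise ValueError("regions need >= 2 member CpGs")
        for exp, effects in self.exposure_effects.items():
            if exp not in EXPOSURES:
                raise ValueError(f"unknown exposure {exp!r}")
            if len(effects) != self.n_region:
                raise ValueError(f"exposure_effects[{exp!r}] must list one "
                                 f"shift per region ({self.n_region})")
        if len(self.mediation_loghr) != self.n_region:
            raise ValueError("mediation_loghr must list one value per region")
        blo, bhi = self.region_baseline_range
        if not (0.0 < blo <= bhi < 1.0):
            raise ValueError("region_baseline_range must lie within (0, 1)")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class QuestionnaireRecord:
    """Raw tobacco/alcohol/HPV questionnaire answers for one participant."""

    cigarettes_per_day: float = 0.0
    handrolled_per_day: float = 0.0
    cigars_per_day: float = 0.0
    smokeless_per_day: float = 0.0
    years_smoked: float = 0.0
    lifetime_cigarettes: float = 0.0
    wine_units: float = 0.0
    spirit_units: float = 0.0
    beer_units: float = 0.0
    hpv16_e6_mfi: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


@dataclass
class TruthTable:
    """Full generative ground truth shared by panel and cohort.

    ``regions``: per-region chrom/start/end, planted exposure shifts and
    mediation log-HR.  ``region_cpgs``: member CpGs in positional order.
    ``snps``: per-SNP region, MAF, alleles and the (common across member
    CpGs) cis effect on the beta scale per effect allele.
    """

    regions: pd.DataFrame
    region_cpgs: pd.DataFrame
    snps: pd.DataFrame
    cpg_baseline: pd.Series
    annotation: pd.DataFrame

    def __post_init__(self):
        counts = self.region_cpgs.groupby("region").size()
        if (counts < 2).any():
            raise ValueError("every planted region must list >= 2 CpGs")
        for df in (self.regions, self.snps):
            num = df.select_dtypes("number")
            if not np.isfinite(num.to_numpy(dtype=float)).all():
                raise ValueError("truth values must be finite")

    def member_cpgs(self, region: int) -> list[str]:
        sub = self.region_cpgs[self.region_cpgs["region"] == region]
        return list(sub.index)

    def snp_effects_long(self) -> pd.DataFrame:
        """Per (snp, cpg) true cis effect (beta scale per effect allele)."""
        rows = []
        for snp, row in self.snps.iterrows():
            for cpg in self.member_cpgs(int(row["region"])):
                rows.append((snp, cpg, row["cis_effect"]))
        return pd.DataFrame(rows, columns=["snp", "cpg", "effect"])


@dataclass
class CohortData:
    """Genotypes, methylation, phenotypes and (for the cohort) survival."""

    dosage: pd.DataFrame
    methylation: MethylationMatrix
    phenotypes: pd.DataFrame
    survival_days: pd.Series | None = None
    event: pd.Series | None = None

    def __post_init__(self):
        dos = self.dosage.to_numpy(dtype=float)
        if dos.size and (dos.min() < 0 or dos.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.survival_days is not None:
            if (self.survival_days <= 0).any():
                raise ValueError("survival_days must be positive")
            ev = np.asarray(self.event)
            if not np.isin(ev, [0, 1]).all():
                raise ValueError("event must be 0/1")

    @property
    def event_fraction(self) -> float:
        if self.event is None:
            raise ValueError("reference panel carries no survival data")
        return float(np.asarray(self.event).mean())


# ---------------------------------------------------------------------------
# exposure derivation rules
# ---------------------------------------------------------------------------

def cigarette_equivalents_per_day(q: QuestionnaireRecord) -> float:
    """Daily cigarette equivalents; a cigar counts as four cigarettes."""
    return (q.cigarettes_per_day + q.handrolled_per_day
            + CIGAR_CIGARETTE_EQUIVALENTS * q.cigars_per_day
            + q.smokeless_per_day)


def derive_smoking_status(q: QuestionnaireRecord) -> bool:
    """Ever/never smoker.

    Ever iff the participant smoked the equivalent of at least one tobacco
    product a day for at least a year, or >= 100 cigarettes in their
    lifetime.  All-zero answers define a never smoker.
    """
    daily = cigarette_equivalents_per_day(q)
    return bool((daily >= 1.0 and q.years_smoked >= 1.0)
                or q.lifetime_cigarettes >= 100.0)


def derive_alcohol_units(q: QuestionnaireRecord) -> float:
    """Average weekly alcohol units; 0 defines a non-drinker."""
    return q.wine_units + q.spirit_units + q.beer_units


def classify_hpv_serostatus(mfi: float) -> bool:
    """HPV16 E6 seropositive iff MFI >= 1000 (inclusive cut-off)."""
    if mfi < 0:
        raise ValueError("MFI must be non-negative")
    return bool(mfi >= HPV16_E6_MFI_CUTOFF)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def build_truth(config: SimulationConfig) -> TruthTable:
    """Draw the genetic/epigenetic architecture shared by panel and cohort."""
    rng = _rng(config, 101)
    region_rows, cpg_rows, snp_rows = [], [], []
    baselines, ann_rows = {}, []
    for r in range(config.n_region):
        chrom = f"chr{r + 1}"
        maf = float(rng.uniform(*config.maf_range))
        start = 1_000_000
        positions = start + 100 * np.arange(config.n_cpg_per_region)
        members = [f"cg_r{r}_{k}" for k in range(config.n_cpg_per_region)]
        base = rng.uniform(*config.region_baseline_range,
                           size=config.n_cpg_per_region)
        for cpg, pos, b in zip(members, positions, base):
            cpg_rows.append((cpg, r))
            baselines[cpg] = float(b)
            ann_rows.append((cpg, chrom, int(pos)))
        # balanced alternating signs (randomly permuted) keep the summed
        # genetic shift small whatever the per-SNP magnitudes
        alternating = ([1.0, -1.0] * ((config.n_snp_per_region + 1) // 2))
        signs = rng.permutation(alternating[: config.n_snp_per_region])
        effects = []
        for j, sign in enumerate(signs):
            mag = float(rng.uniform(*config.cis_effect_range))
            ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            snp = f"snp_r{r}_{j}"
            effects.append(sign * mag)
            snp_rows.append((snp, r, maf, ea, oa, sign * mag))
        # degenerate-config guard: the deterministic beta-scale excursion of
        # the region mean (expected genetic shift + exposure shifts at
        # typical exposure levels) must keep means inside (0, 1), and no
        # single SNP may shift a CpG beyond its local-linear headroom
        shift = abs(2.0 * maf * float(np.sum(effects)))
        for exp, per_region in config.exposure_effects.items():
            scale = 50.0 if exp == "alcohol" else 1.0
            shift += abs(per_region[r]) * scale
        if base.max() + shift >= 0.98 or base.min() - shift <= 0.02:
            raise ValueError(
                f"degenerate config: planted effects push region {r} "
                f"({chrom}) methylation means outside (0, 1)")
        headroom = min(base.min(), 1.0 - base.max())
        if effects and 2.0 * float(np.max(np.abs(effects))) >= headroom:
            raise ValueError(
                f"degenerate config: a single SNP in region {r} ({chrom}) "
                "shifts methylation beyond its (0, 1) headroom")
        region_rows.append({
            "region": r, "chrom": chrom,
            "start": int(positions[0]), "end": int(positions[-1]),
            "mediation_loghr": float(config.mediation_loghr[r]),
            **{f"effect_{e}": float(config.exposure_effects.get(e, (0.0,) * config.n_region)[r])
               for e in EXPOSURES},
        })
    n_bg = config.n_cpg - config.n_region * config.n_cpg_per_region
    for i in range(n_bg):
        cpg = f"cg_bg_{i}"
        chrom = f"chr{(i % config.n_region) + 1}"
        pos = 2_000_000 + 10_000 * (i // config.n_region)
        baselines[cpg] = float(rng.uniform(0.2, 0.8))
        ann_rows.append((cpg, chrom, pos))
    regions = pd.DataFrame(region_rows).set_index("region")
    region_cpgs = pd.DataFrame(cpg_rows, columns=["cpg", "region"]).set_index("cpg")
    snps = pd.DataFrame(
        snp_rows,
        columns=["snp", "region", "maf", "effect_allele", "other_allele", "cis_effect"],
    ).set_index("snp")
    annotation = pd.DataFrame(ann_rows, columns=["cpg", "chrom", "pos"]).set_index("cpg")
    return TruthTable(regions=regions, region_cpgs=region_cpgs, snps=snps,
                      cpg_baseline=pd.Series(baselines, name="baseline"),
                      annotation=annotation)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _simulate_dosage(truth: TruthTable, config: SimulationConfig, n: int,
                     rng: np.random.Generator, prefix: str) -> pd.DataFrame:
    cols = {}
    for r in range(config.n_region):
        snps = truth.snps[truth.snps["region"] == r]
        maf = float(snps["maf"].iloc[0])
        m = len(snps)
        dosage = np.zeros((n, m))
        for hap in range(2):
            h = np.empty((n, m))
            h[:, 0] = rng.random(n) < maf
            for j in range(1, m):
                copy = rng.random(n) < config.ld_decay
                h[:, j] = np.where(copy, h[:, j - 1], rng.random(n) < maf)
            dosage += h
        for j, snp in enumerate(snps.index):
            cols[snp] = dosage[:, j]
    index = pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="sample")
    return pd.DataFrame(cols, index=index)


def _simulate_methylation(truth: TruthTable, config: SimulationConfig,
                          dosage: pd.DataFrame,
                          exposures: pd.DataFrame | None,
                          batch: np.ndarray,
                          rng: np.random.Generator) -> MethylationMatrix:
    cpgs = truth.annotation.index
    n = len(dosage)
    base = truth.cpg_baseline.loc[cpgs].to_numpy()
    scale = 1.0 / (base * (1.0 - base))  # beta-scale -> logit-scale slope
    L = np.tile(logit(base), (n, 1))
    col_of = {c: i for i, c in enumerate(cpgs)}
    for r in range(config.n_region):
        snps = truth.snps[truth.snps["region"] == r]
        shift = dosage[snps.index].to_numpy() @ snps["cis_effect"].to_numpy()
        if exposures is not None:
            for e in EXPOSURES:
                eff = truth.regions.loc[r, f"effect_{e}"]
                if eff != 0.0:
                    shift = shift + eff * exposures[e].to_numpy(dtype=float)
        for cpg in truth.member_cpgs(r):
            i = col_of[cpg]
            L[:, i] += shift * scale[i]
    if config.batch_effect_sd > 0 and config.n_batch > 1:
        affected = rng.random(len(cpgs)) < config.batch_affected_frac
        shifts = rng.normal(0.0, config.batch_effect_sd,
                            size=(config.n_batch, len(cpgs))) * affected
        L += shifts[batch] * scale
    L += rng.normal(0.0, config.noise_sd, size=L.shape) * scale
    beta = pd.DataFrame(expit(L), index=dosage.index, columns=cpgs)
    return MethylationMatrix(beta=beta, annotation=truth.annotation.copy())


def simulate_reference_panel(config: SimulationConfig) -> tuple[CohortData, TruthTable]:
    """Unrelated mQTL reference panel (no survival layer)."""
    truth = build_truth(config)
    rng = _rng(config, 202)
    dosage = _simulate_dosage(truth, config, config.n_panel, rng, "P")
    batch = rng.integers(0, config.n_batch, size=config.n_panel)
    meth = _simulate_methylation(truth, config, dosage, None, batch, rng)
    phen = pd.DataFrame({"batch": batch}, index=dosage.index)
    return CohortData(dosage=dosage, methylation=meth, phenotypes=phen), truth


def _simulate_questionnaires(n: int, rng: np.random.Generator) -> list[QuestionnaireRecord]:
    records = []
    for _ in range(n):
        kw = {}
        if rng.random() < 0.729:  # ever smoker
            cigs = float(rng.uniform(5, 30))
            years = float(rng.uniform(3, 40))
            kw.update(cigarettes_per_day=cigs, years_smoked=years,
                      lifetime_cigarettes=cigs * 365.0 * years)
        if rng.random() < 0.741:  # drinker
            total = float(np.exp(rng.normal(np.log(22.5), 0.7)))
            split = rng.dirichlet([1.0, 1.0, 1.0])
            kw.update(wine_units=total * split[0],
                      spirit_units=total * split[1],
                      beer_units=total * split[2])
        if rng.random() < 0.667:  # HPV16 E6 seropositive
            mfi = float(np.exp(rng.normal(np.log(3500.0), 0.5)))
        else:
            mfi = float(rng.uniform(0.0, 800.0))
        kw.update(hpv16_e6_mfi=mfi)
        records.append(QuestionnaireRecord(**kw))
    return records


def simulate_clinical_cohort(config: SimulationConfig,
                             panel_truth: TruthTable) -> CohortData:
    """Clinical cohort sharing the panel's genetic architecture.

    Exposures shift the planted regions; the per-sample log hazard is the
    sum over regions of ``mediation_loghr * average member-CpG beta`` plus
    any configured direct exposure terms.  Survival times are exponential
    with administrative censoring at ``censor_day``.
    """
    rng = _rng(config, 303)
    dosage = _simulate_dosage(panel_truth, config, config.n_cohort, rng, "C")
    questionnaires = _simulate_questionnaires(config.n_cohort, rng)
    exposures = pd.DataFrame({
        "smoking": [float(derive_smoking_status(q)) for q in questionnaires],
        "alcohol": [derive_alcohol_units(q) for q in questionnaires],
        "hpv16_e6": [float(classify_hpv_serostatus(q.hpv16_e6_mfi))
                     for q in questionnaires],
    }, index=dosage.index)
    batch = rng.integers(0, config.n_batch, size=config.n_cohort)
    meth = _simulate_methylation(panel_truth, config, dosage, exposures, batch, rng)
    age = np.clip(rng.normal(57.5, 9.0, size=config.n_cohort), 30.0, 90.0)
    sex = (rng.random(config.n_cohort) < 0.27).astype(int)  # 1 = female
    phen = pd.DataFrame({
        "smoking_ever": exposures["smoking"].astype(int),
        "alcohol_units": exposures["alcohol"],
        "hpv16_e6_pos": exposures["hpv16_e6"].astype(int),
        "hpv16_e6_mfi": [q.hpv16_e6_mfi for q in questionnaires],
        "age": age,
        "sex": sex,
        "batch": batch,
    }, index=dosage.index)
    lp = np.zeros(config.n_cohort)
    for r in range(config.n_region):
        loghr = panel_truth.regions.loc[r, "mediation_loghr"]
        if loghr != 0.0:
            avg = meth.beta[panel_truth.member_cpgs(r)].mean(axis=1).to_numpy()
            lp += loghr * avg
    for e, loghr in config.direct_exposure_loghr.items():
        lp += loghr * exposures[e].to_numpy(dtype=float)
    lp -= lp.mean()
    hazard = config.baseline_hazard * np.exp(lp)
    t = rng.exponential(1.0 / hazard)
    event = t <= config.censor_day
    if not event.any():
        raise ValueError("degenerate survival layer: no events before the "
                         "censoring day; Cox stages would fail")
    if event.all():
        raise ValueError("degenerate survival layer: every sample dies "
                         "before the censoring day")
    survival_days = pd.Series(np.minimum(t, config.censor_day),
                              index=dosage.index, name="survival_days")
    event_s = pd.Series(event.astype(int), index=dosage.index, name="event")
    return CohortData(dosage=dosage, methylation=meth, phenotypes=phen,
                      survival_days=survival_days, event=event_s)
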