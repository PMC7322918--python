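# Methods

`epimediate` chains five analysis stages — exposure EWAS, survival EWAS,
DMR calling, mQTL instrument construction, and two-sample Mendelian
randomization — and validates them end-to-end on synthetic cohorts with
planted ground truth. This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Exposure definitions

Smoking is dichotomised to ever/never from questionnaire counts of
cigarettes, hand-rolled cigarettes, cigars (one cigar = four cigarettes)
and smokeless tobacco: *ever* means at least one product-equivalent per
day for at least one year, or at least 100 lifetime cigarettes. The
"one product a day per year" phrase is read as a joint condition
(≥ 1/day AND ≥ 1 year), not a pack-year-like product; the predicate is a
single isolated function so the alternative reading can be swapped in.
Alcohol is the sum of weekly wine, spirit and beer units, with zero
defining a non-drinker. HPV16 E6 serostatus is positive at a median
fluorescence intensity ≥ 1000 (inclusive).

## Association engines

The linear EWAS is ordinary least squares of each CpG's beta value
(proportion methylated, in [0,1]) on the exposure, with age, sex, the
other two prognostic factors and surrogate variables as covariates.
Standard errors are homoscedastic OLS SEs with a t reference on
n − p degrees of freedom; effects are also reported ×100 as percentage
points. Working on beta values keeps effects interpretable; an M-value
transform (`beta_to_m_values`) is provided for users who prefer the
variance-stabilised scale.

Survival models use the Cox partial likelihood with the Efron tie
correction, fitted by Newton–Raphson with step-halving (tolerance 1e-9).
The solver is written in numpy and pre-computes the risk-set/tie
structure once per outcome (`CoxPartial`), because the EWAS, the per-SNP
GWAS and the replicate-level calibration studies each require thousands
of small fits; lifelines serves as the independent oracle in the test
suite (coefficients, SEs and log-likelihood agree to 1e-5, and the score
test at β = 0 reproduces the log-rank statistic exactly). Wald P-values
use the normal reference. Non-convergent or monomorphic fits are flagged
in a status column, never silently dropped.

Surrogate variables follow the two-step residual construction: each CpG
is residualised on the model covariates — including the variables of
interest, which keeps the SVs orthogonal to the planned contrasts — and
K is chosen by permutation parallel analysis (observed residual singular
values against the 95th percentile of column-permuted ones, ≥ 20
permutations). The returned scores are the first K left singular
vectors, orthonormal by construction. At reduced CpG panels the dominant
latent factors are the planted mQTL regions themselves rather than
batch; this is a fixture-scale property (a 5-CpG region is negligible
among 850k probes but not among 2,000), which is why the demonstration
pipeline can disable SVA while the SVA unit tests validate batch
recovery on fixtures without genetic structure.

Multiple testing uses alpha/m with the display convention that truncates
the mantissa to one decimal (0.05/862,491 → 5.7e-8); the exact quotient
is available via `truncate=False`. The fixed suggestive threshold is
2.4e-7.

## DMR calling

Candidates are maximal runs of CpGs with nominal P below `p_enter`
(default 0.05), a common effect sign, and inter-CpG gaps of at most
`max_gap` (default 500 bp); singletons are discarded. Every contiguous
sub-window of length ≥ 2 (up to `max_window` = 20 CpGs) is scored by
fixed-effect GLS using the Pearson correlation R of
covariate-residualised methylation: with V = diag(s)·R·diag(s), the
combined estimate is (1ᵀV⁻¹b)/(1ᵀV⁻¹1) with SE (1ᵀV⁻¹1)^(−1/2). A ridge
of 1e-6 on the correlation diagonal repairs near-singular V. The best-P
sub-window per candidate is kept.

The Sidak correction uses T = the number of gap-connected sub-windows of
the **annotation** (all runs, lengths 2..20), not just the windows inside
surviving candidates. The candidate filter conditions on P < 0.05, so a
universe restricted to surviving windows inherits that selection and
fails null calibration badly at desk scale (in an exposure-free
simulation every null candidate was called significant). Counting every
window the scan ranges over restores family-wise control by the union
bound, stays reproducible from the run itself, and leaves planted-region
power essentially untouched. Coordinates are 1-based inclusive
internally; BED export converts to 0-based half-open.

## Instruments

Exposure DMRs intersecting survival DMRs (both at Sidak-adjusted
P < 0.05) define shared regions; the sentinel is the shared CpG with the
lowest exposure-EWAS P (ties by position). mQTL records are filtered at
MAF > 0.05 and P < 5e-8, both strict. Instrument selection iterates CpGs
in ascending exposure-EWAS P starting at the sentinel: each step takes
the CpG's filtered mQTLs whose SNPs are not already genome-wide
significant for an earlier CpG, clumps them greedily at r² < 0.01
(lowest P first, ties broken lexicographically by SNP id — making the
output invariant to input row order), and appends them. Clumping is
within-step; correlation between SNPs selected at different steps is
handled downstream by the LD-adjusted estimators.

Each selected SNP's effects across the CpGs it proxies are combined by a
REML random-effects meta-analysis, y = μ1 + ε, ε ~ N(0, V + τ²I) with
V = diag(se)·R·diag(se), τ² a scalar found by bounded 1-D optimisation
of the restricted log-likelihood (tolerance 1e-10, verified against a
τ²-grid-search oracle). μ̂ is the SNP's effect on average DMR
methylation (β_GP) with SE (1ᵀW1)^(−1/2). τ² is scalar because a single
mQTL contributes few CpG effects; richer heterogeneity structure would
be unidentifiable.

The LD matrix is the signed, effect-allele-aligned Pearson correlation
of panel dosages; the sign is required by the correlated-instrument
estimators, which is why a public r²-only LD service would not suffice.

## Mendelian randomization

Single-instrument estimates are Wald ratios β_GD/β_GP with delta-method
SEs — second-order, sqrt(seGD²/β_GP² + β_GD²·seGP²/β_GP⁴), by default;
the first-order form (used when reducing IVW to a single SNP) is behind
a flag. The correlated-instrument IVW is GLS of β_GD on β_GP through the
origin with Ω_ij = seGD_i·seGD_j·ρ_ij; the "correlation included in the
regression" is implemented as this GLS because it is the estimator whose
null calibration and coverage can be verified, and with ρ = I it reduces
exactly to textbook fixed-effect IVW with first-order weights. MR-Egger
adds a free intercept after orienting all instruments to β_GP ≥ 0
(flipping β_GD and ρ jointly); the intercept with its 95% CI and P is
the directional-pleiotropy test, and pinning it at zero reproduces IVW
exactly. Harmonisation flips survival effects recorded on the other
allele, drops incompatible alleles with a logged reason, and drops
palindromic SNPs with MAF > 0.42 (strand ambiguity unresolvable from
summary data). CIs use z = 1.959964; P-values are two-sided normal.

Power is the closed-form normal approximation
Φ(√(n·r²)·|log OR| − z_{1−α/2}) + Φ(−√(n·r²)·|log OR| − z_{1−α/2}),
with r² the variance in the exposure explained by the instrument. With
summary data, only the strongest single-mQTL r² is identifiable, so the
curves are conservative lower bounds; the formula is cross-checked
against a 2SLS simulation (±0.03) but exact parity with web calculators
is not asserted.

## Synthetic cohorts

The generator emulates the study design: a reference panel of unrelated
individuals for cis-mQTL discovery and a clinical cohort of default 409
patients with administrative censoring at day 1005 (~2.75 years) and a
baseline hazard (3e-4/day) giving ~26% deaths; ~73% ever smokers, ~74%
drinkers with median ~22.5 units/week (log-normal, σ = 0.7), ~67% HPV16
E6 seropositive (raw MFI values classified by the production rule).
Exposures are generated at the questionnaire level and passed through
the same derivation functions the pipeline uses.

Genetics: within a region, haplotypes follow a Markov "copy" chain so
the signed correlation between adjacent SNPs equals `ld_decay` exactly
in expectation (decaying as `ld_decay^|i−j|`); a latent-Gaussian
threshold construction would attenuate the realised r and break the
LD-fidelity contract. The chain requires a common per-region MAF, drawn
once from `maf_range`. Cis effect signs are a randomly permuted balanced
±1 vector, so the summed genetic mean shift stays small for every seed;
each SNP's effect is equal across the region's member CpGs, which makes
the MR estimand (log hazard per unit *average* DMR methylation) coincide
with the planted `mediation_loghr`.

Methylation: effects are specified on the beta scale and applied on the
logit scale through the local slope 1/(b(1−b)) at each CpG's baseline,
noise is Gaussian on the logit scale (beta-scale SD `noise_sd`, default
0.03), and values map back through the logistic — so beta stays strictly
inside (0,1) without clipping. For moderate effects the map is linear to
well under the stated tolerances; at the strong-mQTL architectures used
for MR validation the logistic squashing attenuates β_GP and β_GD by the
same factor, leaving the Wald ratio unbiased (verified empirically).
A degenerate-config guard rejects, naming the region, any configuration
whose deterministic mean excursion leaves (0.02, 0.98) or where a single
SNP exceeds the local-linear headroom.

Survival: the per-sample log hazard is Σ_regions mediation_loghr ×
(average member-CpG beta) plus optional direct exposure terms, centred;
times are exponential with administrative censoring only, so Cox
estimates are analytically checkable. Event fractions of 0 or 1 raise
immediately. Batch structure (the only latent confounder, standing in
for cell composition and technical variation) shifts a configurable
fraction of CpGs per batch and is drawn independently per dataset.

The default `mediation_loghr` of 1.4 per beta unit corresponds to a
published-scale regional hazard ratio of ~1.28 per M-value unit
(dM/dβ ≈ 5.8 at 50% methylation, so one M-unit ≈ 0.17 beta).

What the generator does **not** emulate: array chemistry and probe
types, relatedness, competing risks, cell-type mixtures beyond the
batch factor, trans-mQTLs, and real LD block structure. Passing tests
therefore demonstrate correctness of the estimators and the pipeline
contract under the stated generative model, not robustness to everything
real data can do.

## Validation scenarios and problem sizes

Two planted scenarios (in `epimediate.scenarios`) separate two claims
whose variance requirements conflict within a single region:

* **Mediation recovery** — one region with 24 cis SNPs in moderate LD
  (r = 0.3) and per-allele effects of 0.13–0.20 beta (AHRR-class strong
  mQTLs), panel n = 2000, cohort n = 1000, planted log-HR 0.3. A design
  power analysis shows the IVW SE at ~26% events is ≈ 0.28, so the
  median of 200 replicates resolves the truth to well within 15%; CI
  coverage is checked in [0.90, 0.98].
* **DMR recovery** — a noise-dominated 5-CpG region (cis effects
  0.01–0.03) with a planted 0.05-beta exposure shift among 200 CpGs at
  cohort n = 1000, recovered at Sidak < 0.05 in ≥ 90% of replicates.

Null calibrations run each engine at reduced dimensions (2000 CpGs for
the linear EWAS, 1000 CpGs/SNPs for the Cox engines, 200 replicate
pipelines at panel 1000 / cohort 500 for the end-to-end MR null); these
sizes were chosen so the whole suite stays interactive while keeping
binomial noise far inside the asserted bands.

## Numerical conventions

Interchange files are tab-separated UTF-8 with Unix newlines, `.` for
missing, and floats at 17 significant digits; reads use correctly
rounded parsing so write→read→write is byte-identical. Ridge repairs use
1e-6 on correlation diagonals. P-values are clipped away from exact 0.
All randomness flows from `numpy.random.SeedSequence` children of a
single seed; identical config + seed reproduces identical outputs
bitwise, which the double-run checksum test enforces.

## Known limitations

The Sidak universe choice is conservative for highly correlated windows;
no genomic-control or robust-SE options; the Egger model assumes InSIDE
and is sensitive to near-constant β_GP; weak-instrument behaviour of the
Wald ratio is unguarded beyond the β_GP = 0 error; the generator's
shared-MAF-per-region and equal-effects-per-CpG simplifications are
exactly the conditions under which the DMR-average estimand is
identified — heterogeneous per-CpG effects would make β_GP a
precision-weighted rather than arithmetic average.
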