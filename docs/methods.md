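# Methods

## The two-step design

The package estimates mediation of an exposure→outcome relationship by DNA
methylation using genetic instruments, under the usual instrumental-variable
assumptions: the instrument is associated with its exposure (relevance),
shares no common cause with the outcome (independence — plausible because
alleles are randomized at conception), and affects the outcome only through
the exposure (exclusion; horizontal pleiotropy violates this and is not
diagnosed here — single-instrument Wald ratios admit no pleiotropy test).

**Step 1 (exposure → methylation).** For each CpG j, an MWAS fits

    beta_j = a + b_j · dose + c' covariates + e

by OLS, where `dose` is the maternal instrument dosage (expected effect-
allele count, 0–2) and `beta_j` the methylation proportion. The two-sided
p-value uses the t distribution at the residual degrees of freedom. CpGs at
Benjamini–Hochberg q ≤ 0.05 are carried forward. The causal effect of the
exposure on methylation is the two-sample Wald ratio of the scan
coefficient over an external genotype→exposure summary statistic
(70.21 pg/ml per allele, SE 5.53, n = 3495 in the shipped default), after
effect-allele harmonization.

**Step 2 (methylation → outcome).** cis-SNPs within ±1 Mb of the CpG
(inclusive, positions 1-based) with methylation association p < 1e-7 are
candidate instruments; greedy LD clumping (accept best p, drop everything
with squared dosage correlation above r² = 0.1 with an accepted SNP,
repeat) yields independent instruments, and the best-p survivor is used.
Ties are broken by smaller |SNP − CpG distance|, then lexicographic variant
ID, so clumping is order-invariant. LD is computed in the analysis sample;
no external reference panel. The instrument→outcome regression (IQ on
dosage, adjusted for age at testing only) is fitted in samples disjoint
from those used for mQTL discovery; the Wald ratio against the discovery
mQTL beta gives IQ points per methylation-proportion unit. A conventional
observational regression (IQ on methylation with the full covariate list)
is reported alongside for contrast. A CpG with no surviving cis instrument
is reported as non-instrumentable, not an error.

**Mediation.** `mediated = step2.ratio × step1.ratio × increment`, default
increment 10 pg/ml, in outcome units per increment.

**Standard errors.** Wald ratios use the first-order delta method,
`se² = se_GO²/β_GE² + β_GO²·se_GE²/β_GE⁴`; the cross term is exactly zero
in two-sample designs (independent samples) and is omitted. IV p-values are
standard-normal (large-sample); the per-CpG scan uses t. Instruments with
|β_GE|/se_GE < 3 (F ≈ 9) are flagged weak but not refused — rare-variant
instruments can legitimately reach this state and should be reported, with
the flag, rather than silently dropped.

**Power.** Two-sample MR power is the asymptotic normal approximation
`Φ(|β|·√(n·R²) − z_{1−α/2})` for a standardized causal effect β and
instrument R² on the exposure; at β = 0 it returns α/2 (one tail).
Single-coefficient regression power uses the noncentral F(1, n−2) with
noncentrality f²·(n−2). At methylome-wide α (0.05/485,000), f² = 0.01 at
n ≈ 641 is deeply underpowered by this formula; published claims of 80%
power at such settings are not reproducible with it, and the package
reports what the formula gives.

## Synthetic cohorts

No individual-level data of this kind are openly deposited, so the
generator is the package's study population. The causal chain is

    conf ~ N(0,1)                                (latent socioeconomic confounder)
    dose ~ Binomial(2, MAF)                      (HWE)
    X    = μ_X + β_GX·dose + λ_X·conf + N(0, σ_X)         exposure, pg/ml
    M_j  = expit( logit(b0_j) + [s_j·(X−μ_X) + γ_j·(cis_j − E) + λ_M·conf
                                 + b·batch + N(0, σ_M)] / (b0_j(1−b0_j)) )
    IQ_k = 100 + Σ_j θ_j·(M_j − mean) + λ_Y·conf + shared + N(0, σ'_Y)

Defaults: β_GX = 70.21 pg/ml per allele; instrument MAF 0.40 (a rare
setting down to 0.004 is supported, and the panel MAF can differ from the
cohort MAF to reproduce trans-ancestry two-sample caveats — the shipped
panel default is n = 3495 at the cohort MAF, with 0.459 available); cis
mQTL effects −0.26 (MAF 0.43) and −0.44 (MAF 0.40) proportion per allele,
one responsive CpG deliberately lacking any cis-SNP; outcomes on the
Wechsler scale (marginal mean 100, SD 15, one shared component across the
three subscales). σ_X = 206 and λ_X = 50 are set so the instrument explains
R² ≈ 0.05 of the exposure — the value the published power statements use.
Observed covariates (maternal age, BMI, education, smoking, parity, two
batch axes, two cell-composition proportions) are generated correlated with
the confounder, so covariate adjustment removes part but not all of the
confounding; the latent confounder itself is additionally recorded as a
phenotype column `ses_conf` purely for calibration diagnostics — real
cohorts never observe it, and no default covariate list includes it.

**The logistic squash and recorded truth.** Beta-values must stay in (0,1),
so the linear predictor passes through a logistic centred at each CpG's
baseline b0_j (drawn Uniform(0.15, 0.85)) and scaled by b0_j(1−b0_j), which
makes small planted coefficients locally proportion-scale effects. Large
effects are attenuated by the squash, so `SimTruth` records, besides the
planted slopes, the *realized* average causal effects obtained
counterfactually — the same noise draws are re-evaluated with the exposure
shifted by one allele's worth (β_GX pg/ml), or with one extra cis allele.
These realized values are the estimands genotype-instrumented Wald ratios
target, and all recovery tests compare against them. The default
exposure→methylation slopes are {−4, +3, +2}·10⁻⁴ proportion per pg/ml:
one tenth of the magnitudes a naive reading of published per-pg/ml IV
tables would suggest, because at ~3·10⁻³/pg/ml with a realistic exposure
SD (~218 pg/ml) the linear predictor sweeps the whole logistic range and
the local-linearity premise of the design collapses; the chosen defaults
keep attenuation at the few-percent level while remaining detectable at
realistic sample sizes.

**What the generator does not emulate.** Realistic LD beyond one cis-SNP
plus a few independent null SNPs per CpG; array batch structure beyond a
single linear leakage term; probe cross-reactivity; cell-composition
effects on methylation; relatedness; missing data. Passing tests therefore
demonstrate the statistical machinery under the stated causal model, not
robustness to those real-data complications.

**Genomic inflation in small synthetic scans.** Because one latent
confounder loads on every CpG, a chance correlation between instrument and
confounder shifts the entire scan coherently and λ (median 1-df chi-square
over 0.45494) can drift well away from 1 when only the proxy covariates
are adjusted — the same phenomenon that makes real scans report λ of 0.80
or 0.97 rather than 1. Null-calibration tests therefore adjust for the
recorded `ses_conf`, which is the correctly specified model; under it, λ
stays within [0.9, 1.1] and p-values are uniform at 5,000 CpGs.

## Numerical and procedural choices

- **Outlier handling** (the field's standard practice is some form of
  trimming): per CpG, samples whose beta-value lies beyond 3×IQR from the
  nearest quartile are excluded before the fit; configurable (k, or off).
- **Missing data**: complete cases per CpG; the per-CpG n is recorded.
- **Multiple-testing denominator**: the number of CpGs actually tested, by
  default; `total_tests` overrides it (e.g. 468,622 for a 450K-scale
  claim). BH is the step-up `q_(i) = min_{j≥i} p_(j)·N/j`, capped at 1.
- **Probe QC**: sex-chromosome probes always removed; with a detection-p
  matrix, a probe is dropped when any retained sample exceeds p > 0.05
  (the failing fraction is configurable, since published filters are often
  ambiguous between per-sample and per-proportion rules).
- **Methylation clamping**: beta-values are clamped to (1e-6, 1−1e-6) at
  load so logit transforms stay finite; values outside [0,1] are rejected.
- **Per-CpG OLS implementation**: direct numpy least squares with the
  classical (X'X)⁻¹ covariance, because the scan refits a fresh design per
  CpG (masks differ) and runs methylome-scale; it is verified in the test
  suite against closed-form normal equations and against statsmodels OLS.
- **Partitioning**: when one cohort serves both step-2 roles, a seeded
  random split assigns a methylation-discovery arm (default fraction 0.15,
  echoing the proportion of array-profiled samples in cohorts of this
  kind) and an outcome arm; real-data users supply explicit ID lists.
- **Hit selection**: q ≤ 0.05 on the full scan by default; a `top_k` flag
  exists for stress tests only.
- **Determinism**: one RNG stream per cohort seeded from `SimParams.seed`;
  replicate r conventionally uses seed + r; every pipeline artifact is
  byte-identical under a fixed seed.
- **Problem sizes in the shipped tests**: null calibration uses two
  5,000-CpG scans at n = 700; Wald recovery uses 300 two-sample replicates
  at n = 2,000; the end-to-end mediation check uses 100 replicates of a
  120-CpG methylome at n = 2,000 per arm. These sizes give Monte-Carlo
  error comfortably inside the asserted bands while keeping the suite
  quick on a laptop.

## Known limitations

- Single-instrument estimation only: no IVW/Egger/weighted-median
  multi-instrument estimators, no pleiotropy diagnostics.
- The delta-method SE is first-order; with weak instruments the ratio
  distribution is heavy-tailed and the flag, not the SE, is the signal.
- Cross-cohort replication logic (direction-consistent Bonferroni rules
  and the like) is left to manual comparison of two run directories; the
  exact published decision rules are ambiguous.
- The availability-driven choice among clumped instruments seen in
  practice (a SNP kept because an outcome consortium happens to cover it)
  is modelled only as an optional allow-list filter.
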