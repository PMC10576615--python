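# Methods

## The scientific question

Triglyceride-rich lipoproteins (TRL) and their partially lipolysed remnants
carry cholesterol into the arterial wall just as LDL does, but whether a
remnant particle is *more* atherogenic than an LDL particle has been
contested.  Because every TRL/remnant and LDL particle carries exactly one
apolipoprotein B (apoB) molecule, plasma apoB counts atherogenic particles,
and the question becomes: is the ASCVD risk gradient per unit apoB steeper
when the apoB resides in remnants than when it resides in LDL?

This package implements the full analysis chain used to address that
question with biobank-style data:

1. **Lipid derivations** (`remnantmr.lipids`).  TRL/remnant cholesterol is
   operationalised as non-HDL-C − directly measured LDL-C; an alternative
   estimate ("VLDL-C") comes from the published two-variable Sampson
   equation in TG and non-HDL-C (coefficients transcribed into a constants
   table in mg/dL with explicit mmol/L conversions; the zero-TG limit is 0
   because the companion LDL-C equation's constant belongs to that
   equation).  Odds/hazard ratios are reported per 1.0 unit (mmol/L, or g/L
   for apoB) and per population SD via `OR_sd = OR_unit^sd`.
2. **Variant selection** (`remnantmr.gwas`).  Covariate-adjusted per-variant
   scans (age, sex, five genetic PCs); tier thresholds 1e-21 / 1e-12 / 5e-8
   on the union of the LDL-C and remnant-C scans; MAF > 0.01 and a
   heterozygote-count rule (1000 at reference scale, scaled by cohort size);
   greedy LD pruning at dosage r² < 0.3 keeping the variant with the larger
   combined effect size √(β_LDL² + β_rem²); exclusion of Lp(a)-associated
   variants at Holm-adjusted p < 0.05.
3. **Mendelian randomisation** (`remnantmr.mr`).  Multivariable IVW
   (weighted least squares of outcome log-odds on exposure effects, no
   intercept, multiplicative random-effects SE inflation floored at 1),
   MR-Egger (free intercept after orienting each variant so its effect on
   the first exposure is positive), and the univariable contamination
   mixture (profile likelihood over a theta grid, each variant valid
   N(θ, se_j) or invalid N(0, ψ); ψ defaults to 1.5 × SD of the ratio
   estimates; the 500-point grid spans ±4 pooled SEs around the IVW point,
   widened to the 5–95% quantile range of the ratio estimates so the causal
   value stays inside the grid when outliers drag the IVW point).
4. **SNP clustering** (`remnantmr.clusters`).  Per-variant apoB (g/L) :
   remnant-C (mmol/L) effect-size ratios in minor-vs-major orientation;
   ratios with |β_rem| below one SE are undefined (unassigned).  Fixed
   closed intervals assign cluster 1 (receptor-like) at [0.9, 3.0] and
   cluster 2 (lipolysis-like) at [−0.75, 0.75].  Within each cluster,
   univariable MR of ASCVD on apoB (apoB-raising orientation) gives the
   per-SD-apoB risk gradient; the clusters are compared with a z-test on
   the log-OR difference.
5. **Risk models** (`remnantmr.risk`).  Cluster polygenic scores (weighted
   sums of apoB-raising alleles, weights = apoB betas, so scores are in
   predicted-apoB g/L); decile trait means; Cox proportional-hazards decile
   HRs (incident events, subjects free of prevalent disease, adjusted for
   age and sex); an overall HR per 10 mg/dL apoB from inverse-variance
   weighted regression of decile log-HR on decile mean apoB; an apoB ×
   cluster interaction test on the stacked decile regressions; joint
   observational Cox models (HR per mmol/L); and restricted-cubic-spline
   Cox models of the TG/LDL-C and remnant-C/LDL-C ratios controlling for
   apoB, with and without HDL-C.
6. **Pipeline** (`remnantmr.pipeline`, `remnantmr.cli`).  All stages as a
   configured, seeded, manifest-hashed run; `remnantmr all --config c.yaml
   --out runs/r1 --seed 7`.

## The synthetic cohort generator

No individual-level biobank data can ship with the package, so every stage
is exercised on a generator (`remnantmr.synthetic`) with a known ground
truth.  Two latent particle pools per subject, measured in apoB-equivalents
(g/L of apoB carried): a remnant pool R and an LDL pool L.

**Composition constants.**  `apob_per_particle` = 1.0 by construction;
`chol_per_remnant` = 10/3 and `chol_per_ldl` = 3.0 mmol/L cholesterol per
g/L apoB, so remnants carry more cholesterol per particle than LDL and the
lipolysis-class apoB:remnant-C effect ratio is 0.3 while the receptor class
(which shifts L about 3–5× more than R) lands near 1.5 — the two printed
cluster archetypes.  `tg_per_remnant` = 9.0 mmol TG per g/L remnant apoB
gives r²(TG, remnant-C) ≈ 0.55.

**Variant panel.**  Mechanism classes are assigned block-wise (an LD block
is a locus): *receptor* variants shift R and L concordantly with implied
ratios drawn U(1.2, 1.8); *lipolysis* variants shift mainly R (implied
ratios U(0.24, 0.42), i.e. a weak, sometimes opposite-signed L effect);
*lpa* variants raise Lp(a) mass (10–30 mg/dL per allele) and, through the
Lp(a)-cholesterol included in direct LDL-C assays, the apparent LDL pool —
giving the Holm exclusion filter a live target; *null* variants do nothing.
Per-variant magnitudes follow the usual inverse MAF–effect-size relation
((0.8 + Exp(0.3))/√(2p(1−p)), random signs), which keeps detection power
homogeneous across the panel; with a wide maf-independent dynamic range the
weakest variants' ratio estimates are pure noise and the embedded-ratio
design degrades.  Class totals are scaled so lipolysis variants explain 45%
of remnant-pool variance and receptor variants 45% of LDL-pool variance.

**Genotypes.**  Latent Gaussian AR(1) haplotype chains within blocks,
thresholded at the MAF quantiles; the latent correlation of each adjacent
pair is tetrachorically adjusted (vectorised bisection on an Owen's-T
bivariate-normal orthant) so the realized haplotype allele correlation
equals `ld_rho` (default 0.3).  Blocks are independent; two haplotypes sum
to the dosage.

**Traits.**  Environmental noise components are *solved at run time* from
the realized genetic variances so the marginal SDs of derived remnant-C,
LDL-C, TG and apoB match the configured population targets (0.30, 0.82,
1.00 mmol/L and 0.23 g/L) — the generator raises an error if a target is
structurally unreachable.  Total cholesterol is composed as latent
remnant-C + HDL-C + direct LDL-C + assay noise (SD 0.08 mmol/L), so the
non-HDL-C − LDL-C derivation recovers the latent remnant cholesterol up to
assay noise.  Remnant-pool environment and TG noise are right-skewed
(standardised shifted lognormals, σ = 1.1 and 1.2): with TG SD fixed at
1.0 mmol/L around a mean of 1.75, a Gaussian left tail would truncate ~3%
of TG values at the physical floor (0.01 mmol/L), violating the generator's
own ≤1% truncation rule; the skewed noise also mirrors the real right skew
of TG and remnant-C.  HDL-C is drawn anti-correlated with both remnant-C
(slope 0.5) and TG (slope 0.08), encoding the CE-transfer coupling by which
the lipolysis pathway that enriches remnants simultaneously depletes HDL
cholesterol; this is what makes HDL-C adjustment blunt the remnant/LDL
ratio splines.  Lp(a) is Normal around 30 mg/dL plus genetic effects,
floored at 0.  Covariates: age N(56, 8) truncated to 40–70, sex
Bernoulli(0.5), BMI/SBP/HbA1c around the reference values 26.32 kg/m²,
137 mmHg, 34.8 mmol/mol; PCs standard normal with zero lipid effect by
default (`pc_confounding` adds a PC1→remnant-pool effect for robustness
experiments); the cohort emulates the off-lipid-lowering selection.

**Outcomes.**  Incident events from an exponential time-to-event with
log-hazard = log(baseline) + β_R·(R−R̄) + β_L·(L−L̄) + 0.05·(age−56) +
0.4·male, censored at 12 years; prevalent flags from an independent
logistic draw with the same linear predictor around 5.5% prevalence.
Defaults β_R = 2.19, β_L = 0.645 per g/L of pool apoB are calibrated so the
per-mmol/L gradients exp(β_R/c_R) = 1.93 and exp(β_L/c_L) = 1.24 match the
reported multivariable MR odds ratios; the remnant-vs-LDL per-particle risk
ratio is then ≈3.4.  Baseline 0.0045/yr gives ≈5% incident events over
follow-up (the real combined-outcome event rate is not published; this is a
free parameter).

## What the generator does and does not emulate

It reproduces the marginal trait SDs, the two-cluster effect-ratio
architecture, block LD, an Lp(a) confound, the remnant>LDL per-particle
risk ordering and an HDL–remnant metabolic coupling.  It does *not* model:
population structure or relatedness beyond simulated PCs, imputation error,
real LD decay patterns, non-proportional hazards, competing risks,
left-truncation of prevalent disease (prevalence is an independent draw),
or assay batch effects.  Trait cross-correlations are only approximately
realistic: the SD targets, per-particle composition ratios and cluster
ratio targets overdetermine the covariance, and the chosen compromise keeps
the SDs and ratios exact at the cost of a somewhat weaker LDL-C–apoB
correlation than real panels show.  Passing tests therefore demonstrate
the *methods* recover a truth of this structure — not that real-data
estimates would be unbiased in the presence of the unmodelled features.

## Numerical and inference choices

* Quantitative scans use Frisch–Waugh–Lovell residualisation, matching
  joint OLS exactly; monomorphic variants get β=0, p=1, flagged.
* Binary-outcome scans use the efficient-score (one-step) logistic
  estimator from a single covariates-only fit — the standard biobank GWAS
  approximation, asymptotically equivalent for small per-allele effects;
  exact per-variant ML is available (`exact=True`) and equivalence-tested.
* MR inputs use the combination of prevalent and incident events; score,
  observational and spline analyses use incident events only in subjects
  free of prevalent disease.
* IVW assumes mutually independent instruments, so MR runs on the pruned
  selection; the recovery tests additionally use LD-free panels because
  residual LD below the r² 0.3 ceiling still correlates outcome errors and
  undercovers nominal intervals.
* Cox fits use lifelines (Efron tie handling; simulated event times are
  continuous so ties are absent and Breslow/Efron coincide — a brute-force
  Breslow partial-likelihood maximiser backs the agreement test).
* Restricted cubic splines: 4 knots at the 5/35/65/95% ratio quantiles,
  Harrell natural-spline basis (hand-rolled, ~20 lines); ratio winsorised
  at the 0.5/99.5% quantiles; spline p from a likelihood-ratio test; the
  fitted curve is normalised to HR 1 at the median ratio.
* hr-per-10 mg/dL: inverse-variance weighted regression of decile log-HR on
  decile mean apoB; the reference decile (log-HR fixed at 0) enters with the
  median SE of the others; invariant to the reference choice.
* Cluster intervals are closed; ties at endpoints have measure zero on
  continuous estimates.
* Selection order: tier → MAF/het → LD prune → Lp(a) Holm filter, so the
  Holm family equals the pruned candidate list.  Tier and MAF/het filters
  commute; pruning position is fixed.

## Problem sizes in the test suite

Replicate-based checks run at sizes chosen by power analysis: parameter
recovery at n=4,000 subjects × 150 LD-free variants × 200 replicates;
cluster/score ordering at n=40,000 × 200 variants × 100 replicates with
β_R = 3.0, β_L = 1.5 (the ordering condition fixes the 2:1 per-particle
risk ratio but not the magnitude; the magnitude is set so the decile-HR
contrast has per-replicate z ≈ 2.4, detectable by a ≥95%-of-replicates
check at this scale); null calibration at n=3,000 × 80 variants × 150
replicates; HDL-blunting at n=40,000 × 150 variants × 20 replicates.  The
single large calibration cohort is n=50,000 × 300 variants.

## Known limitations

* One-sample MR throughout (exposure and outcome on the same subjects), as
  in the source design; weak-instrument bias is controlled by selection
  rather than sample splitting.
* The contamination-mixture CI comes from the profile likelihood on a
  finite grid; its resolution is the grid step.
* The decile-regression HR per 10 mg/dL discards within-decile variation;
  the continuous-score Cox alternative (`combined_score_cox`) is more
  efficient but is not the primary presentation.
* `SdTable` defaults to the fixed reference SDs for comparability with the
  published per-SD scale; `estimated_from_cohort` mode recomputes them, and
  both modes are logged in the run config.
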