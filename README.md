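# remnantmr

Remnant cholesterol versus LDL cholesterol as causes of atherosclerotic
cardiovascular disease (ASCVD): a tested, reusable implementation of the
full causal-lipidology analysis chain, exercised end-to-end on a synthetic
biobank-style cohort generator with a known ground truth.

## The problem

Triglyceride-rich lipoprotein (TRL) remnants and LDL both deposit
cholesterol in artery walls, and each particle of either kind carries
exactly one apolipoprotein B (apoB) molecule.  Whether a remnant particle
is more atherogenic than an LDL particle is resolved here the way large
biobank analyses do it:

* derive **TRL/remnant-C** from the standard lipid panel as
  non-HDL-C − direct LDL-C (and, alternatively, **VLDL-C** from the Sampson
  TG/non-HDL-C equation);
* select SNPs associated with LDL-C and/or remnant-C in tiers
  (p < 1e-21 / 1e-12 / 5e-8), prune LD at r² < 0.3 keeping the variant with
  the larger combined effect √(β_LDL² + β_rem²), and drop MAF ≤ 0.01,
  low-heterozygote and Lp(a)-associated (Holm p < 0.05) variants;
* fit **multivariable Mendelian randomisation** (inverse-variance weighted,
  MR-Egger, contamination mixture) of ASCVD on genetically determined
  remnant-C and LDL-C, reporting odds ratios per 1.0 mmol/L (per 1.0 g/L
  for apoB) and per population SD via `OR_sd = OR_unit^sd`
  (SDs: remnant-C 0.30, LDL-C 0.82, TG 1.0 mmol/L, apoB 0.23 g/L,
  VLDL-C 0.43 mmol/L);
* split SNPs into mechanistic clusters by the apoB:remnant-C effect-size
  ratio — **cluster 1** (receptor-pathway-like) at ratio ∈ [0.9, 3.0],
  **cluster 2** (lipolysis-pathway-like) at ratio ∈ [−0.75, 0.75] — and
  compare the per-SD-apoB ASCVD gradients between clusters;
* build per-cluster **polygenic scores** (weighted sums of apoB-raising
  alleles), estimate Cox hazard ratios by score decile and rescale to an HR
  per 10 mg/dL apoB, with an apoB × cluster interaction test;
* fit **observational Cox models** (HR per mmol/L) and restricted-cubic-
  spline models of the TG/LDL-C and remnant-C/LDL-C ratios controlling for
  apoB, with and without HDL-C adjustment.

If remnants carry more risk per particle, the per-mmol/L gradient for
remnant-C exceeds LDL-C's, and the cluster-2 (remnant-dominated) per-apoB
gradient exceeds cluster-1's.  The synthetic generator encodes that truth
with tunable per-particle hazard gradients, so every claim the pipeline
makes is checkable against a known answer.  See `docs/methods.md` for the
model and calibration details.

## Worked example

```bash
remnantmr all --out runs/demo --seed 7      # default desk scale: 20,000 x 1,000
remnantmr report runs/demo
```

or, reproducing exactly the output below, in Python:

```python
from remnantmr.config import RunConfig, CohortParams
from remnantmr.pipeline import run_pipeline

cfg = RunConfig(seed=7)
cfg.cohort = CohortParams(n_subjects=20_000, n_variants=400, seed=7)
results = run_pipeline(cfg, "runs/demo")
```

which simulates a 20,000-subject cohort with 400 variants, runs every stage
and prints (`runs/demo/report.txt`):

```
# remnantmr run report

## Mendelian randomisation (ASCVD odds ratios)
     ivw trl_remnant_c   OR/unit 1.85 [1.48, 2.33]  OR/SD 1.20  p=9.7e-08
     ivw ldl_c           OR/unit 1.18 [0.98, 1.43]  OR/SD 1.15  p=0.086
   egger trl_remnant_c   OR/unit 2.14 [1.29, 3.54]  OR/SD 1.26  p=0.0032
   egger ldl_c           OR/unit 1.22 [0.98, 1.52]  OR/SD 1.18  p=0.072

## SNP clusters (apoB : TRL/remnant-C effect-size ratio)
  cluster 1 [0.9, 3.0]: 29   cluster 2 [-0.75, 0.75]: 82   unassigned: 0
  cluster 1    ivw: OR/SD apoB 1.23 [1.11, 1.36]
  cluster 1 conmix: OR/SD apoB 1.48 [1.29, 1.71]
  cluster 2    ivw: OR/SD apoB 1.47 [1.27, 1.71]
  cluster 2 conmix: OR/SD apoB 1.43 [1.13, 1.75]

## Polygenic-score decile hazards
  cluster 1: HR per 10 mg/dL apoB 1.06 [0.96, 1.17]
  cluster 2: HR per 10 mg/dL apoB 1.13 [0.97, 1.31]
  apoB x cluster interaction p = 0.516

## Observational Cox models (HR per 1.0 mmol/L)
  ldl_c_direct    HR 1.10 [1.03, 1.18]  p=0.0081
  trl_remnant_c   HR 1.91 [1.66, 2.21]  p=3.2e-19
```

Reading the numbers: per 1.0 mmol/L of genetically determined cholesterol,
remnant-C carries a steeper ASCVD odds gradient (1.85) than LDL-C (1.18) —
the generator's truth is 1.93 vs 1.24 — and per SD of apoB the
lipolysis-like cluster 2 outgrades the receptor-like cluster 1 (IVW 1.47
vs 1.23), the signature of higher per-particle remnant atherogenicity.
The observational Cox fit shows the same ordering (1.91 vs 1.10 per
mmol/L).  Confidence intervals are wide at this desk scale; the interaction
test, for example, needs larger cohorts to resolve (the acceptance suite
runs it at n = 40,000 with 100 replicates).

The run directory also contains every intermediate artifact as
tab-separated text (association scans, selected variant lists, cluster
assignments, decile tables, spline curves) plus `manifest.json` with
SHA-256 hashes — identical config + seed reproduces byte-identical files.

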