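"""Run configuration: cohort-generator parameters and pipeline thresholds.

All defaults are the package's reference study conditions; they are chosen to
emulate the marginal structure of a large biobank lipid cohort (trait SDs,
event rates, effect architecture) and are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["CohortParams", "RunConfig", "DEFAULT_MIX"]

#: Default mechanism mix: receptor-pathway loci (concordant remnant+LDL
#: effects), lipolysis-pathway loci (remnant/TG-dominant effects), a small
#: Lp(a) locus fraction to exercise the exclusion filter, and null loci.
DEFAULT_MIX = {"receptor": 0.30, "lipolysis": 0.30, "lpa": 0.04, "null": 0.36}


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Particle pools are measured in apoB-equivalents (g/L of apoB carried), so
    ``apob_per_particle`` is 1.0 by construction and the cholesterol-per-
    particle coefficients are mmol/L cholesterol per g/L apoB.  Remnant
    particles carry more cholesterol per apoB than LDL particles
    (``chol_per_remnant > chol_per_ldl``).
    """

    n_subjects: int = 20_000
    n_variants: int = 1_000
    block_size: int = 5
    ld_rho: float = 0.3          # adjacent-variant haplotype correlation within block
    maf_low: float = 0.05
    maf_high: float = 0.50

    # per-particle composition (pools in apoB-equivalents, g/L)
    apob_per_particle: float = 1.0
    chol_per_remnant: float = 10.0 / 3.0   # mmol/L cholesterol per g/L apoB in remnants
    chol_per_ldl: float = 3.0              # mmol/L cholesterol per g/L apoB in LDL
    tg_per_remnant: float = 9.0            # mmol/L TG per g/L apoB in remnants

    # marginal trait SD targets (population SDs of the measured traits)
    sd_trl_remnant_c: float = 0.30  # mmol/L
    sd_ldl_c: float = 0.82          # mmol/L
    sd_tg: float = 1.00             # mmol/L
    sd_apob: float = 0.23           # g/L
    sd_hdl_c: float = 0.38          # mmol/L

    # trait means
    mean_trl_remnant_c: float = 0.60
    mean_ldl_c: float = 3.56
    mean_tg: float = 1.75
    mean_apob: float = 1.066
    mean_hdl_c: float = 1.435
    mean_lpa: float = 30.0          # mg/dL
    sd_lpa_noise: float = 15.0

    # noise structure
    tc_assay_sd: float = 0.08       # mmol/L; residual of the cholesterol balance
    ldl_pool_sd: float = 0.175      # g/L apoB-equivalents; LDL particle-pool SD
    # HDL-C coupling: the lipolysis/CE-transfer process that enriches remnants
    # with cholesterol simultaneously depletes HDL-C, so HDL-C is drawn
    # anti-correlated with both remnant cholesterol and TG.
    hdl_remnant_slope: float = 0.5  # mmol/L HDL-C decrease per mmol/L remnant-C
    hdl_tg_slope: float = 0.08      # mmol/L HDL-C decrease per mmol/L TG

    # genetic architecture (variance shares solved against, see methods note)
    lipolysis_remnant_var_share: float = 0.45  # of remnant-pool variance
    receptor_ldl_var_share: float = 0.45       # of LDL-pool variance
    receptor_ratio_low: float = 1.2            # implied apoB:remnant-C effect ratio range
    receptor_ratio_high: float = 1.8
    lipolysis_ratio_low: float = 0.24
    lipolysis_ratio_high: float = 0.42
    lpa_effect_low: float = 10.0               # mg/dL Lp(a) per minor allele
    lpa_effect_high: float = 30.0

    # outcome process
    baseline_hazard: float = 0.0045  # incident events/year at mean covariates
    beta_remnant: float = 2.19       # log-hazard per g/L apoB in remnant particles
    beta_ldl: float = 0.645          # log-hazard per g/L apoB in LDL particles
    follow_up_years: float = 12.0
    prevalent_rate: float = 0.055    # prevalence at mean covariates
    age_log_hr: float = 0.05         # per year, centred at mean age
    sex_log_hr: float = 0.40         # male vs female

    # covariates
    mean_age: float = 56.0
    sd_age: float = 8.0
    pc_confounding: float = 0.0      # optional PC1 -> remnant-pool confounding (pool units per PC SD)
    lipid_lowering_frac: float = 0.0 # cohort emulates the off-treatment selection

    truncation_floor: float = 0.01   # mmol/L floor for physically non-negative lipids
    max_truncated_frac: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")
        if self.chol_per_remnant / self.apob_per_particle <= self.chol_per_ldl / self.apob_per_particle:
            raise ValueError(
                "remnant particles must carry more cholesterol per apoB than LDL "
                "(chol_per_remnant/apob_per_particle > chol_per_ldl/apob_per_particle)"
            )
        if self.beta_remnant < 0 or self.beta_ldl < 0:
            raise ValueError("hazard gradients beta_remnant, beta_ldl must be >= 0")
        for name in ("sd_trl_remnant_c", "sd_ldl_c", "sd_tg", "sd_apob", "sd_hdl_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    cohort: CohortParams = field(default_factory=CohortParams)
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    tier: int = 3
    tier_thresholds: dict[int, float] = field(
        default_factory=lambda: {1: 1e-21, 2: 1e-12, 3: 5e-8}
    )
    r2_threshold: float = 0.3
    maf_threshold: float = 0.01
    het_threshold_full_scale: int = 1000
    het_reference_n: int = 354_104   # cohort size at which the het rule is 1000
    scale_het_threshold: bool = True
    holm_alpha: float = 0.05
    cluster1_interval: tuple[float, float] = (0.9, 3.0)
    cluster2_interval: tuple[float, float] = (-0.75, 0.75)
    sd_mode: str = "fixed_reference_values"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tier not in self.tier_thresholds:
            raise ValueError(f"tier must be one of {sorted(self.tier_thresholds)}")
        th = [self.tier_thresholds[k] for k in sorted(self.tier_thresholds)]
        if not all(a < b for a, b in zip(th, th[1:])):
            raise ValueError("tier thresholds must be strictly ordered")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism mix fractions must sum to 1")

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cluster1_interval"] = list(self.cluster1_interval)
        d["cluster2_interval"] = list(self.cluster2_interval)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortParams(**d["cohort"])
        for key in ("cluster1_interval", "cluster2_interval"):
            if key in d:
                d[key] = tuple(d[key])
        if "tier_thresholds" in d:
            d["tier_thresholds"] = {int(k): float(v) for k, v in d["tier_thresholds"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
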