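"""Synthetic biobank-style cohort generator.

Generates the three substrates every downstream stage needs, with a known
ground truth:

* a variant panel with two mechanistic classes — *receptor*-like loci whose
  minor alleles shift remnant and LDL particle pools concordantly (apoB :
  remnant-C effect-size ratios around 1.5), and *lipolysis*-like loci that
  mainly shift the remnant pool and triglyceride (ratios around 0.3) — plus
  Lp(a)-associated loci (to exercise the exclusion filter) and null loci;
* block-LD genotype dosages from latent Gaussian haplotypes;
* a subject table whose lipid panel derives from two latent particle pools
  (remnant and LDL, measured in apoB-equivalents, g/L) and whose incident
  ASCVD events follow an exponential time-to-event process censored at the
  follow-up horizon, with a per-particle hazard gradient that is higher for
  remnant than for LDL particles.

Environmental noise components are solved at run time from the realized
genetic variances so that the marginal SDs of derived remnant-C, LDL-C, TG
and apoB match the configured population targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import DEFAULT_MIX, CohortParams

__all__ = [
    "VariantSpec",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_outcomes",
    "simulate_cohort",
    "implied_effect_ratio",
    "Cohort",
]

MECHANISMS = ("receptor", "lipolysis", "lpa", "null")


@dataclass
class VariantSpec:
    """Ground-truth record for one simulated variant."""

    variant_id: str
    minor_allele: str
    major_allele: str
    maf: float
    ld_block: int
    mechanism: str
    effect_remnant_particles: float  # pool units (g/L apoB-equiv) per minor allele
    effect_ldl_particles: float
    effect_lpa: float                # mg/dL Lp(a) per minor allele

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "receptor":
            if self.effect_remnant_particles * self.effect_ldl_particles < 0:
                raise ValueError("receptor variants must have concordant remnant/LDL effects")
        if self.mechanism == "null":
            if any((self.effect_remnant_particles, self.effect_ldl_particles, self.effect_lpa)):
                raise ValueError("null variants must have zero effects")


def _pool_variance_targets(params: CohortParams) -> tuple[float, float]:
    """Target variances of the remnant and LDL particle pools implied by the
    configured trait-SD targets and noise structure."""
    var_r = (params.sd_trl_remnant_c**2 - params.tc_assay_sd**2) / params.chol_per_remnant**2
    var_l = params.ldl_pool_sd**2
    if var_r <= 0:
        raise ValueError("tc_assay_sd exceeds the remnant-C SD target")
    return var_r, var_l


def implied_effect_ratio(panel: pd.DataFrame, params: CohortParams) -> np.ndarray:
    """Per-variant apoB : TRL/remnant-C effect-size ratio implied by the
    generative model: a*(er+el) / (c_R*er).  NaN where the remnant effect
    is zero."""
    er = panel["effect_remnant_particles"].to_numpy(float)
    el = panel["effect_ldl_particles"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = params.apob_per_particle * (er + el) / (params.chol_per_remnant * er)
    ratio[er == 0] = np.nan
    return ratio


def simulate_panel(
    params: CohortParams,
    mix: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a variant panel with the configured mechanism mix.

    Mechanism classes are assigned block-wise (all variants of an LD block
    share one mechanism), mirroring locus-level biology and keeping null
    blocks free of causal LD tags.  Effect magnitudes are scaled so the
    lipolysis class accounts for ``lipolysis_remnant_var_share`` of the
    remnant-pool variance and the receptor class for
    ``receptor_ldl_var_share`` of the LDL-pool variance (HWE, no-LD
    approximation; random per-variant effect signs cancel LD cross-terms in
    expectation).
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    unknown = set(mix) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanism classes {sorted(unknown)}")
    fracs = np.array([mix.get(m, 0.0) for m in MECHANISMS], float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mix fractions must be non-negative and sum to 1")
    m = int(params.n_variants)
    if m < 1:
        raise ValueError("n_variants must be >= 1")

    n_blocks = int(np.ceil(m / params.block_size))
    block_of = np.repeat(np.arange(n_blocks), params.block_size)[:m]
    block_mech = rng.choice(MECHANISMS, size=n_blocks, p=fracs)
    if mix.get("lpa", 0.0) > 0 and "lpa" not in block_mech:
        block_mech[rng.integers(n_blocks)] = "lpa"  # guarantee the filter substrate
    mech = block_mech[block_of]

    maf = rng.uniform(params.maf_low, params.maf_high, size=m)
    two_pq = 2.0 * maf * (1.0 - maf)
    er = np.zeros(m)
    el = np.zeros(m)
    elpa = np.zeros(m)
    var_r, var_l = _pool_variance_targets(params)
    a = params.apob_per_particle
    c_r = params.chol_per_remnant
    signs = rng.choice([-1.0, 1.0], size=m)
    # heterogeneous magnitudes with the usual inverse MAF-effect-size
    # relation (rarer variants get larger effects), keeping per-variant
    # detection power homogeneous across the panel
    raw = (0.8 + rng.exponential(0.3, size=m)) / np.sqrt(two_pq)

    is_lpa = mech == "lpa"
    # Lp(a) loci: raise Lp(a) mass and, via the Lp(a)-cholesterol included in
    # the direct LDL-C assay, the apparent LDL pool.
    elpa[is_lpa] = rng.uniform(params.lpa_effect_low, params.lpa_effect_high, is_lpa.sum())
    el[is_lpa] = 0.001 * elpa[is_lpa]  # g/L apoB-equivalent per mg/dL Lp(a)

    is_rec = mech == "receptor"
    if is_rec.any():
        # target implied ratio r = a*(1+rho)/c_R  =>  rho = r*c_R/a - 1
        r_target = rng.uniform(params.receptor_ratio_low, params.receptor_ratio_high, is_rec.sum())
        rho = r_target * c_r / a - 1.0
        if np.any(rho <= 0):
            raise ValueError("receptor ratio range implies non-positive LDL/remnant effect ratio")
        el_raw = raw[is_rec] * signs[is_rec]
        budget = params.receptor_ldl_var_share * var_l - float(np.sum(two_pq[is_lpa] * el[is_lpa] ** 2))
        budget = max(budget, 0.0)
        denom = float(np.sum(two_pq[is_rec] * el_raw**2))
        scale = np.sqrt(budget / denom) if denom > 0 else 0.0
        el[is_rec] = el_raw * scale
        er[is_rec] = el[is_rec] / rho

    is_lip = mech == "lipolysis"
    if is_lip.any():
        r_target = rng.uniform(params.lipolysis_ratio_low, params.lipolysis_ratio_high, is_lip.sum())
        delta = r_target * c_r / a - 1.0  # weak, possibly opposite-sign LDL effect
        er_raw = raw[is_lip] * signs[is_lip]
        budget = params.lipolysis_remnant_var_share * var_r
        denom = float(np.sum(two_pq[is_lip] * er_raw**2))
        scale = np.sqrt(budget / denom) if denom > 0 else 0.0
        er[is_lip] = er_raw * scale
        el[is_lip] = delta * er[is_lip]

    alleles = np.array(list("ACGT"))
    minor = rng.integers(0, 4, size=m)
    major = (minor + rng.integers(1, 4, size=m)) % 4
    panel = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(m)],
            "minor_allele": alleles[minor],
            "major_allele": alleles[major],
            "maf": maf,
            "ld_block": block_of,
            "mechanism": mech,
            "effect_remnant_particles": er,
            "effect_ldl_particles": el,
            "effect_lpa": elpa,
        }
    )
    return panel


# --- genotypes ---------------------------------------------------------------

def _bvn_upper(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 > h, Z2 > k) for standard bivariate normal, via Owen's T.

    Valid for h, k >= 0 (MAF <= 0.5 thresholds), vectorised over all inputs.
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = np.asarray(rho, float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    s = np.sqrt(np.maximum(1.0 - rho**2, 1e-12))

    def _t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # Owen's T(x, (y - rho*x)/(x*s)) with the x -> 0 limits:
        # T(0, +-inf) = 1/4 * sign, T(0, a) = arctan(a)/(2*pi)
        safe_x = np.where(x == 0.0, 1.0, x)
        a = (y - rho * x) / (safe_x * s)
        t = special.owens_t(np.abs(x), a)
        lim = np.where(y == 0.0, np.arctan2(-rho, s) / (2 * np.pi), 0.25)
        return np.where(x == 0.0, lim, t)

    # Phi2(h, k) for h*k >= 0: 0.5*(Phi(h)+Phi(k)) - T(h, a_h) - T(k, a_k)
    phi_h = stats.norm.cdf(h)
    phi_k = stats.norm.cdf(k)
    phi2 = 0.5 * (phi_h + phi_k) - _t(h, k) - _t(k, h)
    # upper orthant P(Z1 > h, Z2 > k) = 1 - Phi(h) - Phi(k) + Phi2(h, k)
    out = 1.0 - phi_h - phi_k + phi2
    both_zero = (h == 0.0) & (k == 0.0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), out)
    return out


def _latent_rho_for_target(p1: np.ndarray, p2: np.ndarray, target_r: float) -> np.ndarray:
    """Latent Gaussian correlations giving per-haplotype allele correlation
    ``target_r`` after thresholding at the MAF quantiles (vectorised
    bisection on the monotone tetrachoric relation)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if target_r <= 0:
        return np.zeros(np.broadcast(p1, p2).shape)
    z1 = stats.norm.ppf(1.0 - p1)
    z2 = stats.norm.ppf(1.0 - p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = np.zeros_like(denom)
    hi = np.full_like(denom, 0.9999)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        p11 = _bvn_upper(z1, z2, mid)
        r = (p11 - p1 * p2) / denom
        too_low = r < target_r
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def simulate_genotypes(
    panel: pd.DataFrame,
    n_subjects: int,
    ld_rho: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Dosage matrix (subjects x variants, values 0/1/2 counting minor alleles).

    Haplotypes come from latent Gaussian AR(1) chains within each LD block,
    thresholded at the MAF quantiles; the latent correlation of each adjacent
    pair is tetrachorically adjusted so the realized haplotype allele
    correlation is ``ld_rho``.  Blocks are independent.  Deterministic for a
    fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(panel)
    maf = panel["maf"].to_numpy(float)
    block = panel["ld_block"].to_numpy()
    thresh = stats.norm.ppf(1.0 - maf)

    # latent correlation to the previous variant within the same block
    prev_same_block = np.zeros(m, dtype=bool)
    prev_same_block[1:] = block[1:] == block[:-1]
    lat = np.zeros(m)
    if ld_rho > 0 and prev_same_block.any():
        idx = np.flatnonzero(prev_same_block)
        lat[idx] = _latent_rho_for_target(maf[idx - 1], maf[idx], ld_rho)

    n_hap = 2 * n_subjects
    haplo = np.empty((n_hap, m), dtype=bool)
    z_prev = np.zeros(n_hap)
    for j in range(m):
        eps = rng.standard_normal(n_hap)
        if prev_same_block[j] and lat[j] > 0:
            z = lat[j] * z_prev + np.sqrt(1.0 - lat[j] ** 2) * eps
        else:
            z = eps
        haplo[:, j] = z > thresh[j]
        z_prev = z
    dosage = haplo[:n_subjects].astype(np.int8) + haplo[n_subjects:].astype(np.int8)
    return pd.DataFrame(dosage, columns=panel["variant_id"].to_numpy())


# --- phenotypes --------------------------------------------------------------

_SKEW_R = 1.1
_SKEW_TG = 1.2


def _skew_noise(rng: np.random.Generator, sd: float, sigma: float, size: int) -> np.ndarray:
    """Zero-mean right-skewed noise (standardised shifted lognormal) with a
    hard lower bound of -sd/sqrt(exp(sigma^2)-1); keeps lipid traits physical
    and mirrors the right skew of TG and remnant-C distributions."""
    if sd <= 0:
        return np.zeros(size)
    x = np.exp(sigma * rng.standard_normal(size))
    # standardise on the realized moments: the lognormal's kurtosis makes the
    # sample variance fluctuate enough at moderate n to blow downstream
    # variance budgets if only the theoretical moments were used
    return (x - x.mean()) / x.std() * sd


def _solve_noise_var(target_var: float, explained: float, what: str, floor: float = 0.0) -> float:
    resid = target_var - explained
    if resid < floor**2:
        raise ValueError(
            f"cannot reach the {what} SD target: structural variance "
            f"{explained:.4g} exceeds target {target_var:.4g}"
        )
    return resid


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    panel: pd.DataFrame,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject table (lipids + covariates) and latent pools.

    Generative equations (pools in apoB-equivalents, g/L):

    * remnant pool   R = R0 + G_R + eps_R (right-skewed environment)
    * LDL pool       L = L0 + G_L + eps_L (Gaussian)
    * TG             = mean + tg_per_remnant*(R - mean R) + eps (skewed)
    * apoB           = mean + apob_per_particle*((R+L) - mean) + eps
    * direct LDL-C   = mean + chol_per_ldl*(L - mean L) + eps (composition+assay)
    * latent TRL-C   = mean + chol_per_remnant*(R - mean R)
    * HDL-C          = mean - hdl_remnant_slope*(remnant-C dev)
                              - hdl_tg_slope*(TG dev) + eps
    * TC             = latent TRL-C + HDL-C + direct LDL-C + eps_assay

    so that TC - HDL-C - LDL-C recovers the latent remnant cholesterol up to
    the TC assay noise.  Environmental variances are solved from realized
    genetic variances to match the configured marginal SD targets.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if len(genotypes.columns) != len(panel):
        raise ValueError("genotype and panel dimensions disagree")
    n = len(genotypes)
    g = genotypes.to_numpy(dtype=np.float64)
    er = panel["effect_remnant_particles"].to_numpy(float)
    el = panel["effect_ldl_particles"].to_numpy(float)
    elpa = panel["effect_lpa"].to_numpy(float)
    g_r = g @ er
    g_l = g @ el
    g_lpa = g @ elpa

    var_r_target, var_l_target = _pool_variance_targets(params)
    c_r, c_l = params.chol_per_remnant, params.chol_per_ldl
    a = params.apob_per_particle

    # confounding switch: PCs are standard normals, PC1 optionally shifts R
    pcs = rng.standard_normal((n, 5))
    g_r = g_r + params.pc_confounding * pcs[:, 0]

    env_r_sd = np.sqrt(_solve_noise_var(var_r_target, float(np.var(g_r)), "TRL/remnant-C"))
    eps_r = _skew_noise(rng, env_r_sd, _SKEW_R, n)
    pool_r = params.mean_trl_remnant_c / c_r + (g_r - g_r.mean()) + eps_r

    env_l_sd = np.sqrt(_solve_noise_var(var_l_target, float(np.var(g_l)), "LDL pool"))
    pool_l = params.mean_ldl_c / c_l + (g_l - g_l.mean()) + env_l_sd * rng.standard_normal(n)

    d_r = pool_r - pool_r.mean()
    d_l = pool_l - pool_l.mean()

    trl_latent = params.mean_trl_remnant_c + c_r * d_r

    ldl_assay_sd = np.sqrt(
        _solve_noise_var(params.sd_ldl_c**2, c_l**2 * float(np.var(pool_l)), "LDL-C")
    )
    ldl_direct = params.mean_ldl_c + c_l * d_l + ldl_assay_sd * rng.standard_normal(n)

    tg_noise_sd = np.sqrt(
        _solve_noise_var(params.sd_tg**2, params.tg_per_remnant**2 * float(np.var(pool_r)), "TG")
    )
    tg = params.mean_tg + params.tg_per_remnant * d_r + _skew_noise(rng, tg_noise_sd, _SKEW_TG, n)

    apob_noise_sd = np.sqrt(
        _solve_noise_var(params.sd_apob**2, a**2 * float(np.var(pool_r + pool_l)), "apoB", floor=0.0)
    )
    apob = params.mean_apob + a * (d_r + d_l) + apob_noise_sd * rng.standard_normal(n)

    hdl_structural = params.hdl_remnant_slope * c_r * d_r + params.hdl_tg_slope * (tg - tg.mean())
    hdl_noise_sd = np.sqrt(
        _solve_noise_var(params.sd_hdl_c**2, float(np.var(hdl_structural)), "HDL-C")
    )
    hdl = params.mean_hdl_c - hdl_structural + hdl_noise_sd * rng.standard_normal(n)

    lpa = params.mean_lpa + (g_lpa - g_lpa.mean()) + params.sd_lpa_noise * rng.standard_normal(n)
    lpa = np.maximum(lpa, 0.0)

    # physical floors; the composition identity is built from floored values
    floor = params.truncation_floor
    n_trunc = int(
        (trl_latent < floor).sum() + (ldl_direct < floor).sum()
        + (tg < floor).sum() + (hdl < floor).sum() + (apob < floor / 10).sum()
    )
    if n_trunc > params.max_truncated_frac * 5 * n:
        raise ValueError(
            f"{n_trunc} lipid values truncated at the physical floor "
            f"(> {params.max_truncated_frac:.0%} of records); check noise configuration"
        )
    trl_latent = np.maximum(trl_latent, floor)
    ldl_direct = np.maximum(ldl_direct, floor)
    tg = np.maximum(tg, floor)
    hdl = np.maximum(hdl, floor)
    apob = np.maximum(apob, floor / 10)

    tc = trl_latent + hdl + ldl_direct + params.tc_assay_sd * rng.standard_normal(n)

    age = np.clip(params.mean_age + params.sd_age * rng.standard_normal(n), 40.0, 70.0)
    sex = rng.integers(0, 2, size=n)  # 0 = female, 1 = male
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": _draw_bmi(rng, n),
            "sbp": 137.0 + 18.0 * rng.standard_normal(n),
            "hba1c": 34.8 + 6.0 * rng.standard_normal(n),
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
            "pc5": pcs[:, 4],
            "lipid_lowering": (rng.uniform(size=n) < params.lipid_lowering_frac).astype(int),
            "tc": tc,
            "hdl_c": hdl,
            "ldl_c_direct": ldl_direct,
            "tg": tg,
            "apob": apob,
            "lpa": lpa,
        }
    )
    latents = pd.DataFrame(
        {"remnant_pool": pool_r, "ldl_pool": pool_l, "trl_remnant_c_latent": trl_latent}
    )
    return subjects, latents


def _draw_bmi(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(26.32 + 4.0 * rng.standard_normal(n), 15.0, 50.0)


def simulate_outcomes(
    subjects: pd.DataFrame,
    latents: pd.DataFrame,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Append outcome columns: prevalent flag, incident indicator and
    censored time-to-event.

    Incident events: exponential time-to-event with
    ``log h = log(baseline) + beta_R*(R - mean R) + beta_L*(L - mean L) +
    covariate terms``, censored at ``follow_up_years``.  Prevalent flags come
    from an independent logistic draw with the same linear predictor around
    ``logit(prevalent_rate)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    if not (np.isfinite(params.beta_remnant) and np.isfinite(params.beta_ldl)):
        raise ValueError("hazard gradients must be finite")
    r = latents["remnant_pool"].to_numpy(float)
    l = latents["ldl_pool"].to_numpy(float)
    eta = (
        params.beta_remnant * (r - r.mean())
        + params.beta_ldl * (l - l.mean())
        + params.age_log_hr * (subjects["age"].to_numpy(float) - params.mean_age)
        + params.sex_log_hr * (subjects["sex"].to_numpy(float) - 0.5)
    )
    rate = params.baseline_hazard * np.exp(eta)
    t = rng.exponential(1.0 / rate)
    incident = t <= params.follow_up_years
    time = np.minimum(t, params.follow_up_years)

    p_prev = special.expit(special.logit(params.prevalent_rate) + eta)
    prevalent = rng.uniform(size=len(subjects)) < p_prev

    frac = incident.mean()
    if not (0.0 < frac < 1.0):
        raise ValueError(f"degenerate incident event fraction {frac}; adjust baseline hazard")

    out = subjects.copy()
    out["prevalent_ascvd"] = prevalent.astype(int)
    out["incident_event"] = incident.astype(int)
    out["time_to_event_or_censor"] = time
    return out


@dataclass
class Cohort:
    """Bundle of all simulated artifacts for in-memory pipelines."""

    panel: pd.DataFrame
    genotypes: pd.DataFrame
    subjects: pd.DataFrame
    latents: pd.DataFrame
    params: CohortParams


def simulate_cohort(
    params: CohortParams,
    mix: dict[str, float] | None = None,
    seed: int | None = None,
) -> Cohort:
    """End-to-end simulation: panel -> genotypes -> phenotypes -> outcomes."""
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_panel, r_geno, r_pheno, r_out = [np.random.default_rng(s) for s in ss.spawn(4)]
    panel = simulate_panel(params, mix, rng=r_panel)
    genotypes = simulate_genotypes(panel, params.n_subjects, params.ld_rho, r_geno)
    subjects, latents = simulate_phenotypes(genotypes, panel, params, rng=r_pheno)
    subjects = simulate_outcomes(subjects, latents, params, rng=r_out)
    return Cohort(panel=panel, genotypes=genotypes, subjects=subjects, latents=latents, params=params)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write subjects.tsv, genotypes.tsv, panel.tsv (tab-separated, header)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("subjects.tsv", cohort.subjects),
        ("genotypes.tsv", cohort.genotypes),
        ("panel.tsv", cohort.panel),
    ):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    return paths
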