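"""Per-variant association scans and the tiered SNP selection procedure.

Selection pipeline (in order): tier filter on the LDL-C / TRL-remnant-C
scans (union of the two traits at the tier's p-value threshold), minor-allele
frequency and heterozygote-count filter, greedy LD pruning (dosage r² < 0.3,
keeping the variant with the larger combined effect size), and exclusion of
Lp(a)-associated variants (Holm-adjusted p < 0.05 over the surviving
candidates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "assoc_scan",
    "binary_assoc_scan",
    "covariate_matrix",
    "tier_filter",
    "combined_effect_size",
    "ld_prune",
    "maf_het_filter",
    "lpa_exclusion_filter",
    "select_variants",
    "TIER_THRESHOLDS",
]

#: GWAS significance thresholds of decreasing stringency.
TIER_THRESHOLDS = {1: 1e-21, 2: 1e-12, 3: 5e-8}

DEFAULT_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5")


def covariate_matrix(subjects: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> np.ndarray:
    """Design matrix [1, covariates] for the scan adjustments."""
    cols = [np.ones(len(subjects))]
    cols += [subjects[c].to_numpy(float) for c in covariates]
    return np.column_stack(cols)


def _genotype_summaries(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = g.shape[0]
    eaf = g.mean(axis=0) / 2.0
    n_het = (g == 1).sum(axis=0)
    return eaf, n_het


def assoc_scan(
    genotypes: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    covariates: np.ndarray,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Per-variant OLS of a quantitative trait on minor-allele dosage.

    Covariates are projected out of both trait and dosages
    (Frisch-Waugh-Lovell), so the per-variant slope, SE and two-sided t-test
    match a full joint OLS fit exactly.  Monomorphic variants get beta 0,
    p 1 and a flag.  Missing trait values are dropped record-wise.
    """
    y = np.asarray(trait, dtype=float)
    keep = np.isfinite(y)
    g = genotypes.to_numpy(dtype=np.float64)[keep]
    y = y[keep]
    c = covariates[keep]
    n, m = g.shape
    k = c.shape[1]

    # residualise on covariates
    ct_c = c.T @ c
    y_res = y - c @ np.linalg.solve(ct_c, c.T @ y)
    g_res = g - c @ np.linalg.solve(ct_c, c.T @ g)

    gg = np.einsum("ij,ij->j", g_res, g_res)
    mono = gg <= 1e-12
    gg_safe = np.where(mono, 1.0, gg)
    beta = (g_res.T @ y_res) / gg_safe
    yy = float(y_res @ y_res)
    dof = n - k - 1
    rss = yy - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, 1.0, p)

    eaf, n_het = _genotype_summaries(genotypes.to_numpy())
    return pd.DataFrame(
        {
            "variant_id": genotypes.columns,
            "trait": trait_name,
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "n": n,
            "n_het": n_het,
            "eaf": eaf,
            "maf": np.minimum(eaf, 1.0 - eaf),
            "monomorphic": mono,
        }
    )


def binary_assoc_scan(
    genotypes: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray,
    trait_name: str = "ascvd",
    exact: bool = False,
) -> pd.DataFrame:
    """Per-variant logistic regression of a binary outcome on dosage.

    Default is the efficient-score (one-step) estimator computed from a
    single covariates-only logistic fit: the genotype column is projected out
    of the covariate space under the IRLS weights, giving
    ``beta = U/V, se = 1/sqrt(V)`` with ``U = g̃'(y - p̂)`` and
    ``V = g̃' W g̃``.  This is the standard large-cohort GWAS approximation
    and is asymptotically equivalent to per-variant maximum likelihood for
    the small per-allele effects scanned here; ``exact=True`` runs the full
    per-variant ML fit instead (slow, used for validation).
    """
    y = np.asarray(outcome, dtype=float)
    g = genotypes.to_numpy(dtype=np.float64)
    c = covariates
    n, m = g.shape

    # covariates-only logistic fit by Newton-Raphson
    beta_c = np.zeros(c.shape[1])
    beta_c[0] = special.logit(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    for _ in range(50):
        p_hat = special.expit(c @ beta_c)
        w = p_hat * (1 - p_hat)
        grad = c.T @ (y - p_hat)
        hess = c.T @ (c * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta_c += step
        if np.max(np.abs(step)) < 1e-10:
            break
    p_hat = special.expit(c @ beta_c)
    w = p_hat * (1 - p_hat)
    resid = y - p_hat

    if exact:
        beta = np.empty(m)
        se = np.empty(m)
        import statsmodels.api as sm

        for j in range(m):
            x = np.column_stack([c, g[:, j]])
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            beta[j] = fit.params[-1]
            se[j] = fit.bse[-1]
    else:
        cw = c * w[:, None]
        ctwc = c.T @ cw
        g_proj = g - c @ np.linalg.solve(ctwc, cw.T @ g)
        u = g_proj.T @ resid
        v = np.einsum("ij,ij->j", g_proj * w[:, None], g_proj)
        mono = v <= 1e-12
        v_safe = np.where(mono, 1.0, v)
        beta = np.where(mono, 0.0, u / v_safe)
        se = np.where(mono, np.nan, 1.0 / np.sqrt(v_safe))

    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(p), 1.0, p)

    eaf, n_het = _genotype_summaries(genotypes.to_numpy())
    return pd.DataFrame(
        {
            "variant_id": genotypes.columns,
            "trait": trait_name,
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "n": n,
            "n_het": n_het,
            "eaf": eaf,
            "maf": np.minimum(eaf, 1.0 - eaf),
        }
    )


def tier_filter(
    assoc_ldl: pd.DataFrame,
    assoc_trl: pd.DataFrame,
    tier: int,
    thresholds: dict[int, float] | None = None,
) -> list[str]:
    """Variants associated with LDL-C and/or TRL/remnant-C below the tier
    threshold (the 'and/or' union rule)."""
    thresholds = TIER_THRESHOLDS if thresholds is None else thresholds
    thr = thresholds[tier]
    merged = assoc_ldl.set_index("variant_id")["p"].to_frame("p_ldl").join(
        assoc_trl.set_index("variant_id")["p"].rename("p_trl"), how="inner"
    )
    keep = merged[(merged.p_ldl < thr) | (merged.p_trl < thr)]
    return keep.index.tolist()


def combined_effect_size(beta_ldl, beta_trl):
    """sqrt(beta_LDL² + beta_TRL²): magnitude used as the LD-pruning tie-break."""
    return np.sqrt(np.asarray(beta_ldl, float) ** 2 + np.asarray(beta_trl, float) ** 2)


def ld_prune(
    candidates: list[str],
    genotypes: pd.DataFrame,
    combined_effect: pd.Series,
    r2_threshold: float = 0.3,
) -> list[str]:
    """Greedy LD pruning on dosage r².

    Candidates are visited in order of decreasing combined effect size (ties
    broken by variant id); a variant is retained iff its dosage r² with every
    previously retained variant is below the threshold.  The result contains
    no pair with r² >= threshold, and in any conflicting pair the variant
    with the larger combined effect size wins.
    """
    order = sorted(candidates, key=lambda v: (-float(combined_effect[v]), v))
    g = genotypes[order].to_numpy(dtype=np.float64)
    g = g - g.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", g, g))
    norms[norms == 0] = np.inf
    g = g / norms
    kept_idx: list[int] = []
    for j in range(len(order)):
        if kept_idx:
            r = g[:, kept_idx].T @ g[:, j]
            if np.any(r**2 >= r2_threshold):
                continue
        kept_idx.append(j)
    kept = {order[j] for j in kept_idx}
    return [v for v in candidates if v in kept]


def maf_het_filter(
    assoc: pd.DataFrame,
    maf_threshold: float = 0.01,
    het_threshold: int | None = None,
    reference_n: int = 354_104,
    full_scale_het: int = 1000,
) -> list[str]:
    """Keep variants with MAF > threshold and at least ``het_threshold``
    heterozygous subjects.  By default the full-scale rule of 1000
    heterozygotes is scaled by n/reference_n so the filter stays meaningful
    on desk-scale cohorts."""
    if het_threshold is None:
        n = int(assoc["n"].iloc[0])
        het_threshold = max(1, int(round(full_scale_het * n / reference_n)))
    keep = assoc[(assoc["maf"] > maf_threshold) & (assoc["n_het"] >= het_threshold)]
    return keep["variant_id"].tolist()


def lpa_exclusion_filter(assoc_lpa: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Drop variants whose Holm-adjusted Lp(a) p-value is below alpha.

    The Holm family is the candidate set passed in.  Returns the retained
    variant ids.
    """
    from statsmodels.stats.multitest import multipletests

    p = assoc_lpa["p"].to_numpy(float)
    if len(p) == 0:
        return []
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return assoc_lpa.loc[~reject, "variant_id"].tolist()


def select_variants(
    genotypes: pd.DataFrame,
    scans: dict[str, pd.DataFrame],
    tier: int = 3,
    r2_threshold: float = 0.3,
    maf_threshold: float = 0.01,
    het_threshold: int | None = None,
    holm_alpha: float = 0.05,
    tier_thresholds: dict[int, float] | None = None,
) -> list[str]:
    """Full selection pipeline: tier -> MAF/het -> LD prune -> Lp(a) exclusion.

    ``scans`` must contain 'ldl_c', 'trl_remnant_c' and 'lpa' association
    tables from :func:`assoc_scan`.
    """
    a_ldl = scans["ldl_c"].set_index("variant_id", drop=False)
    a_trl = scans["trl_remnant_c"].set_index("variant_id", drop=False)
    cand = tier_filter(scans["ldl_c"], scans["trl_remnant_c"], tier, tier_thresholds)
    cand = [v for v in cand if v in set(maf_het_filter(a_ldl.loc[cand], maf_threshold, het_threshold))]
    if not cand:
        return []
    combined = pd.Series(
        combined_effect_size(a_ldl.loc[cand, "beta"], a_trl.loc[cand, "beta"]).tolist(),
        index=cand,
    )
    cand = ld_prune(cand, genotypes, combined, r2_threshold)
    a_lpa = scans["lpa"].set_index("variant_id", drop=False).loc[cand]
    return lpa_exclusion_filter(a_lpa, holm_alpha)
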