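"""Individual-level risk analyses.

Cluster polygenic scores (weighted sums of apoB-raising alleles), decile
trait summaries, Cox proportional-hazards modelling of incident ASCVD by
score decile, the per-10 mg/dL apoB hazard-ratio rescaling, the apoB x
cluster interaction test, observational Cox models with lipid exposures,
and restricted-cubic-spline Cox models of TG/LDL-C-type exposure ratios.

All survival fits use lifelines' Cox partial likelihood on incident events
in subjects free of prevalent disease at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "build_gene_score",
    "decile_summary",
    "decile_hazards",
    "hr_per_10mg_dl",
    "interaction_test",
    "observational_cox",
    "ratio_spline",
    "rcs_basis",
    "SplineModel",
]

_Z = stats.norm.ppf(0.975)

DEFAULT_HAZARD_COVARIATES = ("age", "sex")


def build_gene_score(
    genotypes: pd.DataFrame,
    oriented_apob_raising: pd.DataFrame,
    variant_ids: list[str],
) -> pd.Series:
    """Per-subject polygenic score: sum over variants of (apoB-raising allele
    count) x (apoB effect size, g/L per raising allele).

    Dosages count minor alleles; for variants whose apoB-raising allele is
    the major allele the count is reflected (2 - dosage).  Weights are the
    apoB-raising-orientation betas and are therefore non-negative, so the
    score is in predicted-apoB units (g/L).
    """
    missing = [v for v in variant_ids if v not in genotypes.columns]
    if missing:
        raise KeyError(f"variants missing from genotype matrix: {missing[:5]}")
    eff = oriented_apob_raising.set_index("variant_id").loc[variant_ids]
    w = eff["beta_apob"].to_numpy(float)
    if np.any(w < 0):
        raise ValueError("weights must be apoB-raising (non-negative)")
    g = genotypes[variant_ids].to_numpy(dtype=np.float64)
    flipped = eff["orientation_flipped"].to_numpy(bool)
    raising = np.where(flipped[None, :], 2.0 - g, g)
    return pd.Series(raising @ w, index=genotypes.index, name="gene_score")


def _decile_labels(scores: pd.Series, rng: np.random.Generator | None = None) -> pd.Series:
    """Decile labels 1..10 at score quantiles; heavy ties broken by rank with
    a seeded random jitter."""
    s = scores.to_numpy(float)
    try:
        cats = pd.qcut(s, 10, labels=False, duplicates="raise")
    except ValueError:
        rng = np.random.default_rng(0) if rng is None else rng
        jitter = rng.uniform(-0.5, 0.5, len(s))
        order = np.argsort(s, kind="stable")
        rank = np.empty(len(s), float)
        rank[order] = np.arange(len(s))
        cats = pd.qcut(rank + jitter, 10, labels=False)
    return pd.Series(np.asarray(cats) + 1, index=scores.index, name="decile")


def decile_summary(
    scores: pd.Series,
    subjects: pd.DataFrame,
    traits: tuple[str, ...] = ("apob", "tg", "trl_remnant_c", "ldl_c_direct"),
    min_bin: int = 30,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean measured trait levels per decile of gene score."""
    if len(scores) < 10 * min_bin:
        raise ValueError(f"need at least {10 * min_bin} subjects for decile summaries")
    decile = _decile_labels(scores, rng)
    df = subjects[list(traits)].copy()
    df["decile"] = decile.to_numpy()
    df["gene_score"] = scores.to_numpy()
    out = df.groupby("decile").mean().reset_index()
    out["n"] = df.groupby("decile").size().to_numpy()
    return out


def _analysis_cohort(subjects: pd.DataFrame) -> pd.DataFrame:
    """Incident-event analysis set: subjects without prevalent disease."""
    return subjects[subjects["prevalent_ascvd"] == 0]


def decile_hazards(
    scores: pd.Series,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_HAZARD_COVARIATES,
    min_events: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cox HR per score decile (reference decile 1), incident events only,
    subjects free of prevalent disease, adjusted for age and sex.

    Deciles with fewer than ``min_events`` events are flagged; their HRs are
    reported but the CI is unreliable.
    """
    decile = _decile_labels(scores, rng)
    df = _analysis_cohort(subjects.assign(decile=decile.to_numpy()))
    events_per = df.groupby("decile")["incident_event"].sum()
    dummies = pd.get_dummies(df["decile"], prefix="d", dtype=float).drop(columns="d_1")
    fit_df = pd.concat(
        [df[["time_to_event_or_censor", "incident_event", *covariates]].reset_index(drop=True),
         dummies.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="time_to_event_or_censor", event_col="incident_event")
    rows = [{"decile": 1, "log_hr": 0.0, "se": 0.0, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
             "n_events": int(events_per.get(1, 0)), "flagged": bool(events_per.get(1, 0) < min_events)}]
    for d in range(2, 11):
        name = f"d_{d}"
        b = float(cph.params_[name])
        s = float(cph.standard_errors_[name])
        rows.append(
            {
                "decile": d, "log_hr": b, "se": s, "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - _Z * s)), "ci_high": float(np.exp(b + _Z * s)),
                "n_events": int(events_per.get(d, 0)),
                "flagged": bool(events_per.get(d, 0) < min_events),
            }
        )
    return pd.DataFrame(rows)


def hr_per_10mg_dl(hazards: pd.DataFrame, decile_means: pd.DataFrame) -> dict:
    """Overall hazard ratio per 10 mg/dL (0.1 g/L) apoB from the decile fits.

    Inverse-variance-weighted linear regression of decile log-HR on decile
    mean apoB (g/L); the reference decile enters with the pooled variance of
    the others (its log-HR is fixed at 0 by design, not estimated with zero
    error).  Returns slope-based HR with a delta-method CI.  Invariant to
    the choice of reference decile because only log-HR differences matter.
    """
    df = hazards.merge(decile_means[["decile", "apob"]], on="decile")
    df = df[np.isfinite(df["log_hr"]) & np.isfinite(df["se"])]
    nonref = df["se"] > 0
    if nonref.sum() < 3:
        raise ValueError("need at least 3 deciles with finite hazard ratios")
    se = df["se"].to_numpy(float).copy()
    se[~nonref.to_numpy()] = float(np.median(se[nonref.to_numpy()]))
    w = 1.0 / se**2
    x = df["apob"].to_numpy(float)
    y = df["log_hr"].to_numpy(float)
    wx = np.sum(w * x)
    ww = np.sum(w)
    sxx = np.sum(w * (x - wx / ww) ** 2)
    slope = float(np.sum(w * (x - wx / ww) * y) / sxx)
    slope_se = float(1.0 / np.sqrt(sxx))
    hr = float(np.exp(0.1 * slope))
    lo = float(np.exp(0.1 * (slope - _Z * slope_se)))
    hi = float(np.exp(0.1 * (slope + _Z * slope_se)))
    return {"hr_per_10mg_dl": hr, "ci_low": lo, "ci_high": hi,
            "slope_per_g_l": slope, "slope_se": slope_se}


def interaction_test(
    hazards1: pd.DataFrame,
    means1: pd.DataFrame,
    hazards2: pd.DataFrame,
    means2: pd.DataFrame,
) -> dict:
    """apoB x cluster interaction: stacked weighted regression of decile
    log-HR on apoB, cluster indicator and their product; Wald p for the
    interaction coefficient (difference in per-apoB slope between clusters).
    """
    frames = []
    for cl, (hz, mn) in enumerate(((hazards1, means1), (hazards2, means2))):
        df = hz.merge(mn[["decile", "apob"]], on="decile")
        df["cluster"] = float(cl)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    se = df["se"].to_numpy(float).copy()
    pos = se > 0
    se[~pos] = float(np.median(se[pos]))
    w = 1.0 / se**2
    x = np.column_stack(
        [np.ones(len(df)), df["apob"], df["cluster"], df["apob"] * df["cluster"]]
    )
    xw = x * w[:, None]
    cov = np.linalg.inv(x.T @ xw)
    beta = cov @ (xw.T @ df["log_hr"].to_numpy(float))
    se_int = float(np.sqrt(cov[3, 3]))
    z = float(beta[3] / se_int)
    return {
        "interaction_coef": float(beta[3]),
        "se": se_int,
        "z": z,
        "p": float(2 * stats.norm.sf(abs(z))),
    }


def combined_score_cox(
    score1: pd.Series,
    score2: pd.Series,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_HAZARD_COVARIATES,
) -> pd.DataFrame:
    """Whole-cohort Cox model with both cluster polygenic scores included;
    HRs reported per 10 mg/dL (0.1 g/L) of score-predicted apoB."""
    df = _analysis_cohort(
        subjects.assign(score1=score1.to_numpy(), score2=score2.to_numpy())
    )
    cph = CoxPHFitter()
    cph.fit(
        df[["time_to_event_or_censor", "incident_event", "score1", "score2", *covariates]],
        duration_col="time_to_event_or_censor",
        event_col="incident_event",
    )
    rows = []
    for name, cl in (("score1", 1), ("score2", 2)):
        b = float(cph.params_[name])
        s = float(cph.standard_errors_[name])
        rows.append(
            {
                "cluster": cl,
                "hr_per_10mg_dl": float(np.exp(0.1 * b)),
                "ci_low": float(np.exp(0.1 * (b - _Z * s))),
                "ci_high": float(np.exp(0.1 * (b + _Z * s))),
            }
        )
    return pd.DataFrame(rows)


def observational_cox(
    subjects: pd.DataFrame,
    exposures: tuple[str, ...] = ("ldl_c_direct", "trl_remnant_c"),
    covariates: tuple[str, ...] = DEFAULT_HAZARD_COVARIATES,
    collinearity_r: float = 0.95,
) -> pd.DataFrame:
    """Joint Cox fit of incident ASCVD on measured lipid exposures; HR per
    1.0 mmol/L with 95% CI.  Warns on highly collinear exposure pairs."""
    import warnings

    df = _analysis_cohort(subjects)
    if "lipid_flag" in df.columns:
        df = df[~df["lipid_flag"].astype(bool)]
    corr = df[list(exposures)].corr().to_numpy()
    if np.any(np.abs(corr[np.triu_indices_from(corr, 1)]) > collinearity_r):
        warnings.warn("exposures are highly collinear; joint HRs unstable", stacklevel=2)
    cph = CoxPHFitter()
    cph.fit(
        df[["time_to_event_or_censor", "incident_event", *exposures, *covariates]],
        duration_col="time_to_event_or_censor",
        event_col="incident_event",
    )
    rows = []
    for name in exposures:
        b = float(cph.params_[name])
        s = float(cph.standard_errors_[name])
        rows.append(
            {
                "exposure": name,
                "hr_per_unit": float(np.exp(b)),
                "ci_low": float(np.exp(b - _Z * s)),
                "ci_high": float(np.exp(b + _Z * s)),
                "p": float(2 * stats.norm.sf(abs(b / s))),
            }
        )
    return pd.DataFrame(rows)


# --- restricted cubic splines ------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, Harrell parametrisation.

    k knots give k-1 columns: the linear term plus k-2 nonlinear terms that
    are linear beyond the boundary knots.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    cols = [x]
    denom = t[-1] - t[0]

    def cub(u):
        return np.clip(u, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            cub(x - t[j])
            - cub(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cub(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / denom**2)
    return np.column_stack(cols)


@dataclass
class SplineModel:
    """Fitted ratio-spline Cox model."""

    exposure: str
    knots: np.ndarray
    curve: pd.DataFrame          # ratio grid -> HR (1 at the reference ratio)
    p_spline: float              # likelihood-ratio p of the spline term
    reference_ratio: float
    include_hdl: bool
    n: int
    n_events: int
    log_hr_range: float = 0.0
    coefs: dict = field(default_factory=dict)


DEFAULT_SPLINE_COVARIATES = ("apob", "sex", "bmi", "age", "sbp", "hba1c")


def ratio_spline(
    subjects: pd.DataFrame,
    numerator: str,
    denominator: str = "ldl_c_direct",
    covariates: tuple[str, ...] = DEFAULT_SPLINE_COVARIATES,
    include_hdl: bool = False,
    knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95),
    winsor_quantiles: tuple[float, float] = (0.005, 0.995),
    grid_size: int = 60,
) -> SplineModel:
    """Cox model of incident ASCVD on a restricted cubic spline of
    ``numerator/denominator`` (e.g. TG/LDL-C or TRL-remnant-C/LDL-C),
    controlling for apoB and the standard covariates, optionally HDL-C.

    The fitted curve is evaluated on a ratio grid and normalised to HR 1 at
    the reference (median) ratio; the spline term's p-value comes from a
    likelihood-ratio test against the covariates-only model.  Extreme ratios
    are winsorised at the configured quantiles before fitting.
    """
    df = _analysis_cohort(subjects)
    if "lipid_flag" in df.columns:
        df = df[~df["lipid_flag"].astype(bool)]
    denom_vals = df[denominator].to_numpy(float)
    df = df[denom_vals > 0]
    ratio = (df[numerator] / df[denominator]).to_numpy(float)
    lo, hi = np.quantile(ratio, winsor_quantiles)
    ratio = np.clip(ratio, lo, hi)

    covs = list(covariates) + (["hdl_c"] if include_hdl else [])
    knots = np.quantile(ratio, knot_quantiles)
    if len(np.unique(knots)) < len(knots):
        raise ValueError("degenerate knot placement; ratio distribution too concentrated")
    basis = rcs_basis(ratio, knots)
    bcols = [f"rcs_{i}" for i in range(basis.shape[1])]
    fit_df = df[["time_to_event_or_censor", "incident_event", *covs]].reset_index(drop=True)
    fit_df[bcols] = basis

    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="time_to_event_or_censor", event_col="incident_event")
    cph0 = CoxPHFitter()
    cph0.fit(
        fit_df.drop(columns=bcols),
        duration_col="time_to_event_or_censor",
        event_col="incident_event",
    )
    lr = 2.0 * (cph.log_likelihood_ - cph0.log_likelihood_)
    p_spline = float(stats.chi2.sf(max(lr, 0.0), df=len(bcols)))

    ref = float(np.median(ratio))
    grid = np.linspace(np.quantile(ratio, 0.02), np.quantile(ratio, 0.98), grid_size)
    beta = cph.params_[bcols].to_numpy(float)
    log_hr = (rcs_basis(grid, knots) - rcs_basis(np.array([ref]), knots)) @ beta
    curve = pd.DataFrame({"ratio": grid, "hr": np.exp(log_hr), "log_hr": log_hr})
    return SplineModel(
        exposure=f"{numerator}/{denominator}",
        knots=knots,
        curve=curve,
        p_spline=p_spline,
        reference_ratio=ref,
        include_hdl=include_hdl,
        n=len(fit_df),
        n_events=int(fit_df["incident_event"].sum()),
        log_hr_range=float(log_hr.max() - log_hr.min()),
        coefs={c: float(cph.params_[c]) for c in cph.params_.index},
    )
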