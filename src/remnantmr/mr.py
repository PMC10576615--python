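"""Summary-statistics Mendelian randomisation estimators.

Univariable and multivariable inverse-variance-weighted (IVW) regression,
MR-Egger (IVW with a free intercept capturing directional pleiotropy), and
the contamination-mixture estimator (each variant's ratio estimate treated as
either valid — centred on the causal effect — or invalid — dispersed around
zero — with the causal effect maximising the profile likelihood).

Effects are log-odds of the ASCVD outcome per unit of exposure
(mmol/L for lipids, g/L for apoB); per-SD odds ratios come from
``or_per_sd`` applied to the per-unit OR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lipids import SdTable, or_per_sd

__all__ = ["MRInput", "MREstimate", "ivw_fit", "egger_fit", "conmix_fit", "report_estimates"]


@dataclass
class MRInput:
    """Per-variant summary statistics for an MR fit.

    ``exposure_betas`` is variants x exposures (trait units per minor
    allele); ``outcome_beta``/``outcome_se`` are log-odds per allele.
    Variants are assumed mutually independent (post-pruning).
    """

    variant_ids: list[str]
    exposure_names: list[str]
    exposure_betas: np.ndarray          # (m, k)
    exposure_ses: np.ndarray | None     # (m, k), informational
    outcome_beta: np.ndarray            # (m,)
    outcome_se: np.ndarray              # (m,)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        if self.exposure_betas.shape[0] == 1 and len(self.variant_ids) > 1:
            self.exposure_betas = self.exposure_betas.T
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        m = len(self.variant_ids)
        if self.exposure_betas.shape != (m, len(self.exposure_names)):
            raise ValueError("exposure_betas shape does not match variants x exposures")
        if self.outcome_beta.shape != (m,) or self.outcome_se.shape != (m,):
            raise ValueError("outcome effect shapes do not match the variant list")
        if np.any(~np.isfinite(self.exposure_betas)) or np.any(~np.isfinite(self.outcome_beta)):
            raise ValueError("missing or non-finite cells in MR input")
        if np.any(self.outcome_se <= 0):
            raise ValueError("outcome SEs must be > 0")

    @classmethod
    def from_scans(
        cls,
        exposure_scans: dict[str, pd.DataFrame],
        outcome_scan: pd.DataFrame,
        variant_ids: list[str],
    ) -> "MRInput":
        """Assemble an MR input from association tables for a variant set."""
        names = list(exposure_scans)
        out = outcome_scan.set_index("variant_id").loc[variant_ids]
        betas = np.column_stack(
            [exposure_scans[t].set_index("variant_id").loc[variant_ids, "beta"].to_numpy(float) for t in names]
        )
        ses = np.column_stack(
            [exposure_scans[t].set_index("variant_id").loc[variant_ids, "se"].to_numpy(float) for t in names]
        )
        return cls(
            variant_ids=list(variant_ids),
            exposure_names=names,
            exposure_betas=betas,
            exposure_ses=ses,
            outcome_beta=out["beta"].to_numpy(float),
            outcome_se=out["se"].to_numpy(float),
        )


@dataclass
class MREstimate:
    """Causal-effect estimate for one exposure."""

    exposure: str
    method: str                      # ivw | egger | conmix
    theta: float                     # log-odds per exposure unit
    se_theta: float
    ci95: tuple[float, float]        # per-unit OR scale
    p: float
    n_variants: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    valid_variants: list[str] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def or_per_unit(self) -> float:
        return float(np.exp(self.theta))

    def or_per_sd(self, sd: float) -> float:
        return or_per_sd(self.or_per_unit, sd)

    def ci95_per_sd(self, sd: float) -> tuple[float, float]:
        lo, hi = self.ci95
        return (or_per_sd(lo, sd), or_per_sd(hi, sd))


_Z = stats.norm.ppf(0.975)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, exposure_names: list[str]):
    """Weighted least squares with multiplicative random-effects SE inflation
    (dispersion floored at 1)."""
    xw = x * w[:, None]
    xtx = x.T @ xw
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"rank-deficient exposure matrix (collinear exposures among {exposure_names})"
        )
    theta = np.linalg.solve(xtx, xw.T @ y)
    m, k = x.shape
    resid = y - x @ theta
    if m > k:
        dispersion = float(resid @ (w * resid)) / (m - k)
    else:
        dispersion = 1.0
    inflation = max(1.0, dispersion)
    cov = np.linalg.inv(xtx) * inflation
    se = np.sqrt(np.diag(cov))
    return theta, se, dispersion


def ivw_fit(mr_input: MRInput, intercept: bool = False) -> list[MREstimate]:
    """Multivariable IVW: weighted regression of outcome log-odds on the
    exposure effect matrix, weights 1/se_out², no intercept by default.

    SEs use multiplicative random-effects inflation: scaled by
    max(1, sqrt(residual dispersion)).  With ``intercept=True`` this is the
    Egger parametrisation (used internally by :func:`egger_fit`).
    """
    b = mr_input.exposure_betas
    m, k = b.shape
    need = k + (1 if intercept else 0)
    if m < need:
        raise ValueError(f"need at least {need} variants for {k} exposures")
    x = np.column_stack([np.ones(m), b]) if intercept else b
    w = 1.0 / mr_input.outcome_se**2
    theta, se, dispersion = _wls(x, mr_input.outcome_beta, w, mr_input.exposure_names)
    off = 1 if intercept else 0
    method = "egger" if intercept else "ivw"
    out = []
    for i, name in enumerate(mr_input.exposure_names):
        t, s = float(theta[off + i]), float(se[off + i])
        est = MREstimate(
            exposure=name,
            method=method,
            theta=t,
            se_theta=s,
            ci95=(float(np.exp(t - _Z * s)), float(np.exp(t + _Z * s))),
            p=float(2 * stats.norm.sf(abs(t / s))),
            n_variants=m,
            extra={"dispersion": dispersion},
        )
        if intercept:
            i0, s0 = float(theta[0]), float(se[0])
            est.egger_intercept = i0
            est.egger_intercept_se = s0
            est.egger_intercept_p = float(2 * stats.norm.sf(abs(i0 / s0)))
        out.append(est)
    return out


def egger_fit(mr_input: MRInput) -> list[MREstimate]:
    """MR-Egger: IVW with a free intercept, after orienting every variant so
    its effect on the first exposure is positive (Egger estimates are
    orientation-dependent; this convention is fixed and documented)."""
    sign = np.sign(mr_input.exposure_betas[:, 0])
    sign[sign == 0] = 1.0
    oriented = MRInput(
        variant_ids=mr_input.variant_ids,
        exposure_names=mr_input.exposure_names,
        exposure_betas=mr_input.exposure_betas * sign[:, None],
        exposure_ses=mr_input.exposure_ses,
        outcome_beta=mr_input.outcome_beta * sign,
        outcome_se=mr_input.outcome_se,
    )
    return ivw_fit(oriented, intercept=True)


def conmix_fit(
    bx: np.ndarray,
    sx: np.ndarray | None,
    by: np.ndarray,
    sy: np.ndarray,
    psi: float | None = None,
    grid_size: int = 500,
    exposure: str = "exposure",
    variant_ids: list[str] | None = None,
    min_bx: float | None = None,
) -> MREstimate:
    """Contamination-mixture estimator (univariable).

    Per-variant ratio estimates ``theta_j = by_j / bx_j`` with first-order SE
    ``sy_j / |bx_j|``.  Each variant is modelled as valid
    (Normal(theta, se_j)) or invalid (Normal(0, psi)); the causal estimate
    maximises the profile likelihood over a theta grid, with a
    likelihood-ratio 95% CI.  ``psi`` defaults to 1.5 x SD of the ratio
    estimates.  Variants with |bx| below ``min_bx`` (default: its SE, if
    given, else 1e-8) are dropped.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(len(bx))]
    if min_bx is None:
        floor = np.asarray(sx, float) if sx is not None else np.full_like(bx, 1e-8)
    else:
        floor = np.full_like(bx, min_bx)
    keep = np.abs(bx) >= np.maximum(floor, 1e-12)
    dropped = [v for v, k in zip(variant_ids, keep) if not k]
    bx, by, sy = bx[keep], by[keep], sy[keep]
    ids = [v for v, k in zip(variant_ids, keep) if k]
    m = len(bx)
    if m == 0:
        raise ValueError("no variants with usable exposure effects")

    ratio = by / bx
    se = sy / np.abs(bx)
    if m == 1:
        t, s = float(ratio[0]), float(se[0])
        return MREstimate(
            exposure=exposure, method="conmix", theta=t, se_theta=s,
            ci95=(float(np.exp(t - _Z * s)), float(np.exp(t + _Z * s))),
            p=float(2 * stats.norm.sf(abs(t / s))), n_variants=1,
            valid_variants=ids, extra={"dropped": dropped},
        )

    if psi is None:
        psi = 1.5 * float(np.std(ratio, ddof=1))
        if psi <= 0:
            psi = 1.0
    # grid: +-4 pooled SEs around the univariable IVW point, widened to cover
    # the bulk of the ratio estimates (outliers can drag the IVW point far
    # from the causal value, which must stay inside the search grid)
    w = 1.0 / se**2
    ivw_point = float(np.sum(w * ratio) / np.sum(w))
    pooled = float(1.0 / np.sqrt(np.sum(w)))
    span = 4.0 * max(pooled, float(np.median(se)))
    lo = min(ivw_point - span, float(np.quantile(ratio, 0.05) - 2 * np.median(se)))
    hi = max(ivw_point + span, float(np.quantile(ratio, 0.95) + 2 * np.median(se)))
    grid = np.linspace(lo, hi, grid_size)

    ll_valid = stats.norm.logpdf(ratio[None, :], loc=grid[:, None], scale=se[None, :])
    ll_invalid = stats.norm.logpdf(ratio, loc=0.0, scale=psi)[None, :]
    ll = np.sum(np.maximum(ll_valid, ll_invalid), axis=1)
    j_best = int(np.argmax(ll))
    theta = float(grid[j_best])
    valid_mask = ll_valid[j_best] >= ll_invalid[0]
    # likelihood-ratio 95% CI on the profile
    in_ci = 2.0 * (ll[j_best] - ll) <= stats.chi2.ppf(0.95, 1)
    ci_lo, ci_hi = float(grid[in_ci].min()), float(grid[in_ci].max())
    se_theta = (ci_hi - ci_lo) / (2 * _Z) if ci_hi > ci_lo else float(grid[1] - grid[0])
    z = theta / se_theta if se_theta > 0 else np.inf
    return MREstimate(
        exposure=exposure,
        method="conmix",
        theta=theta,
        se_theta=se_theta,
        ci95=(float(np.exp(ci_lo)), float(np.exp(ci_hi))),
        p=float(2 * stats.norm.sf(abs(z))),
        n_variants=m,
        valid_variants=[v for v, ok in zip(ids, valid_mask) if ok],
        extra={"psi": psi, "dropped": dropped, "grid": (float(grid[0]), float(grid[-1]))},
    )


def report_estimates(estimates: list[MREstimate], sd_table: SdTable) -> pd.DataFrame:
    """Result table with per-unit and per-SD ORs, CIs and p-values.

    Values are full precision; rounding to the 2-decimal presentation
    convention belongs to the caller.
    """
    rows = []
    for est in estimates:
        if est.exposure not in sd_table.sds:
            raise KeyError(f"no population SD configured for exposure {est.exposure!r}")
        sd = sd_table[est.exposure]
        lo, hi = est.ci95
        lo_sd, hi_sd = est.ci95_per_sd(sd)
        rows.append(
            {
                "exposure": est.exposure,
                "method": est.method,
                "n_snps": est.n_variants,
                "or_unit": est.or_per_unit,
                "ci_low": lo,
                "ci_high": hi,
                "or_sd": est.or_per_sd(sd),
                "ci_low_sd": lo_sd,
                "ci_high_sd": hi_sd,
                "sd": sd,
                "p": est.p,
            }
        )
    return pd.DataFrame(rows)
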