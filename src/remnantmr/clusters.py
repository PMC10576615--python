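"""Effect-size-ratio SNP clustering and per-cluster MR risk gradients.

Each selected variant gets a ratio of its apoB effect (g/L) to its
TRL/remnant-C effect (mmol/L), computed in minor-vs-major allele
orientation.  The ratio distribution is bimodal: variants acting through
receptor-mediated clearance shift remnant and LDL pools together (large
apoB change per unit remnant-C change, ratios around 1.5), while variants
acting on lipolysis shift mainly the remnant pool (small apoB change,
ratios around 0.3).  The fixed assignment rule is

* cluster 1 (receptor-like):  ratio in [0.9, 3.0]
* cluster 2 (lipolysis-like): ratio in [-0.75, 0.75]
* otherwise unassigned.

Within each cluster, univariable MR of the ASCVD outcome on apoB (apoB-
raising orientation) measures the per-particle risk gradient; a higher
cluster-2 gradient indicates greater atherogenicity of remnant particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lipids import or_per_sd
from .mr import MREstimate, MRInput, conmix_fit, ivw_fit

__all__ = [
    "orient_effects",
    "effect_ratio",
    "ratio_histogram",
    "assign_cluster",
    "assign_clusters",
    "cluster_mr",
    "CLUSTER1_INTERVAL",
    "CLUSTER2_INTERVAL",
]

CLUSTER1_INTERVAL = (0.9, 3.0)
CLUSTER2_INTERVAL = (-0.75, 0.75)


def orient_effects(scans: dict[str, pd.DataFrame], mode: str = "minor_vs_major") -> pd.DataFrame:
    """Wide per-variant effect table in the requested allele orientation.

    ``minor_vs_major`` keeps the estimated minor-allele effects;
    ``apob_raising`` flips all trait betas of variants whose minor-allele
    apoB effect is negative, so every variant's exposure allele raises apoB.
    Variants with apoB beta exactly 0 keep minor-allele orientation and are
    flagged.  Returns columns beta_<trait>, se_<trait> per scanned trait,
    plus ``orientation_flipped`` and ``zero_apob_flag``.
    """
    if "apob" not in scans:
        raise KeyError("orientation requires an apoB scan")
    if mode not in ("minor_vs_major", "apob_raising"):
        raise ValueError(f"unknown orientation mode {mode!r}")
    traits = list(scans)
    base = scans["apob"].set_index("variant_id")
    out = pd.DataFrame(index=base.index)
    for t in traits:
        s = scans[t].set_index("variant_id")
        out[f"beta_{t}"] = s["beta"]
        out[f"se_{t}"] = s["se"]
    flip = np.ones(len(out))
    zero_flag = out["beta_apob"].to_numpy() == 0.0
    if mode == "apob_raising":
        flip = np.where(out["beta_apob"].to_numpy() < 0.0, -1.0, 1.0)
        for t in traits:
            out[f"beta_{t}"] = out[f"beta_{t}"] * flip
    out["orientation_flipped"] = flip < 0
    out["zero_apob_flag"] = zero_flag
    out["orientation"] = mode
    out.index.name = "variant_id"
    return out.reset_index()


def effect_ratio(beta_apob, beta_trl, min_denominator) -> np.ndarray:
    """apoB : TRL/remnant-C effect-size ratio (minor/major orientation).

    NaN (undefined -> unassigned) where |beta_trl| < min_denominator; a
    near-zero denominator makes the quotient noise, and such variants join
    the unallocated set.  ``min_denominator`` may be a scalar or per-variant
    array (default usage: 1 SE of beta_trl).
    """
    beta_apob = np.asarray(beta_apob, float)
    beta_trl = np.asarray(beta_trl, float)
    min_denominator = np.broadcast_to(np.asarray(min_denominator, float), beta_trl.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = beta_apob / beta_trl
    return np.where(np.abs(beta_trl) >= min_denominator, ratio, np.nan)


def assign_cluster(
    ratio,
    cluster1: tuple[float, float] = CLUSTER1_INTERVAL,
    cluster2: tuple[float, float] = CLUSTER2_INTERVAL,
):
    """Fixed-interval cluster rule; intervals are closed.  Returns 1, 2 or 0
    (unassigned, including undefined ratios)."""
    ratio = np.asarray(ratio, float)
    out = np.zeros(ratio.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        out[(ratio >= cluster1[0]) & (ratio <= cluster1[1])] = 1
        out[(ratio >= cluster2[0]) & (ratio <= cluster2[1])] = 2
    return out if out.ndim else int(out)


def assign_clusters(
    oriented: pd.DataFrame,
    cluster1: tuple[float, float] = CLUSTER1_INTERVAL,
    cluster2: tuple[float, float] = CLUSTER2_INTERVAL,
    min_denominator: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Per-variant ratio and cluster label from a minor/major-oriented
    effect table (needs beta_apob, beta_trl_remnant_c, se_trl_remnant_c).

    ``min_denominator`` defaults to 1 SE of the remnant-C beta.
    """
    if min_denominator is None:
        min_denominator = oriented["se_trl_remnant_c"].to_numpy(float)
    ratio = effect_ratio(
        oriented["beta_apob"].to_numpy(float),
        oriented["beta_trl_remnant_c"].to_numpy(float),
        min_denominator,
    )
    return pd.DataFrame(
        {
            "variant_id": oriented["variant_id"],
            "ratio": ratio,
            "cluster": assign_cluster(ratio, cluster1, cluster2),
        }
    )


def ratio_histogram(
    ratios: np.ndarray,
    bin_width: float = 0.1,
    lo: float = -2.0,
    hi: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Binned ratio frequencies plus a descriptive bimodality summary.

    Reports the two highest local modes and the antimode (lowest bin)
    between them.  Purely descriptive — the cluster bounds stay the fixed
    printed intervals.  Zero-count bins are preserved.
    """
    ratios = np.asarray(ratios, float)
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) < 20:
        raise ValueError("need at least 20 defined ratios for a histogram")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(ratios, bins=edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})

    # local modes: bins strictly greater than both neighbours (plateaus: first bin)
    padded = np.concatenate([[-1], counts, [-1]])
    is_mode = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:]) & (counts > 0)
    mode_idx = np.flatnonzero(is_mode)
    mode_idx = mode_idx[np.argsort(counts[mode_idx])[::-1]][:2]
    summary: dict = {"n": len(ratios), "bimodal": False, "modes": [], "antimode": None}
    summary["modes"] = sorted(float(mid[i]) for i in mode_idx)
    if len(mode_idx) == 2:
        i, j = sorted(mode_idx)
        if j > i + 1:
            k = i + 1 + int(np.argmin(counts[i + 1 : j]))
            summary["antimode"] = float(mid[k])
            summary["bimodal"] = counts[k] < min(counts[i], counts[j])
    return table, summary


@dataclass
class ClusterMRResult:
    """Per-cluster apoB risk gradients and their comparison."""

    estimates: dict[int, dict[str, MREstimate]]   # cluster -> method -> estimate
    sd_apob: float
    comparison: dict | None                        # z-test on log-OR difference

    def or_per_sd(self, cluster: int, method: str = "ivw") -> float:
        return self.estimates[cluster][method].or_per_sd(self.sd_apob)


def cluster_mr(
    oriented_apob_raising: pd.DataFrame,
    outcome_scan: pd.DataFrame,
    assignments: pd.DataFrame,
    sd_apob: float = 0.23,
    min_variants: int = 3,
) -> ClusterMRResult:
    """Univariable MR of ASCVD on apoB within each cluster (IVW and
    contamination mixture), reported per population SD of apoB.

    The outcome scan must be in minor/major orientation; it is re-oriented
    here with the same flips as the apoB-raising exposure table.  Emits a
    z-test on the log-OR difference (cluster 2 minus cluster 1) when both
    clusters are estimable, else the comparison is None.
    """
    eff = oriented_apob_raising.set_index("variant_id")
    if not (eff["beta_apob"] >= 0).all():
        raise ValueError("exposure table must be in apoB-raising orientation")
    out = outcome_scan.set_index("variant_id")
    estimates: dict[int, dict[str, MREstimate]] = {}
    for cl in (1, 2):
        ids = assignments.loc[assignments["cluster"] == cl, "variant_id"].tolist()
        if len(ids) < min_variants:
            continue
        flip = np.where(eff.loc[ids, "orientation_flipped"].to_numpy(), -1.0, 1.0)
        bx = eff.loc[ids, "beta_apob"].to_numpy(float)
        sx = eff.loc[ids, "se_apob"].to_numpy(float)
        by = out.loc[ids, "beta"].to_numpy(float) * flip
        sy = out.loc[ids, "se"].to_numpy(float)
        mri = MRInput(
            variant_ids=ids, exposure_names=["apob"],
            exposure_betas=bx[:, None], exposure_ses=sx[:, None],
            outcome_beta=by, outcome_se=sy,
        )
        estimates[cl] = {
            "ivw": ivw_fit(mri)[0],
            "conmix": conmix_fit(bx, sx, by, sy, exposure="apob", variant_ids=ids),
        }
    if not estimates:
        raise ValueError(f"no cluster has at least {min_variants} variants")
    comparison = None
    if 1 in estimates and 2 in estimates:
        e1, e2 = estimates[1]["ivw"], estimates[2]["ivw"]
        diff = e2.theta - e1.theta
        se = float(np.hypot(e1.se_theta, e2.se_theta))
        z = diff / se
        comparison = {
            "log_or_diff_per_unit": diff,
            "log_or_diff_per_sd": diff * sd_apob,
            "se": se,
            "z": z,
            "p": float(2 * stats.norm.sf(abs(z))),
            "cluster2_minus_cluster1": True,
        }
    return ClusterMRResult(estimates=estimates, sd_apob=sd_apob, comparison=comparison)
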