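"""End-to-end pipeline: simulate -> derive -> scan -> select -> MR ->
cluster -> score -> observational models -> report.

Every stage writes tab-separated artifacts into the run directory and
registers them in a manifest with SHA-256 hashes; a rerun with identical
config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import gwas, mr, risk
from .config import RunConfig
from .lipids import SdTable, derive_lipid_columns
from .synthetic import Cohort, simulate_cohort, write_cohort

__all__ = ["run_pipeline", "report", "StageError"]

SCAN_TRAITS = {
    "ldl_c": "ldl_c_direct",
    "trl_remnant_c": "trl_remnant_c",
    "tg": "tg",
    "apob": "apob",
    "vldl_c": "vldl_c",
    "lpa": "lpa",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["files"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig, outdir, cohort: Cohort | None = None) -> dict:
    """Execute all stages; returns a results dict (also serialised to the run
    directory).  A pre-built cohort can be injected for testing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}}
    results: dict = {}
    config.to_yaml(outdir / "config.yaml")
    manifest["files"]["config.yaml"] = _sha256(outdir / "config.yaml")

    stage = "simulate"
    try:
        if cohort is None:
            params = config.cohort.replace(seed=config.seed)
            cohort = simulate_cohort(params, mix=config.mix)
        for name, p in write_cohort(cohort, outdir).items():
            manifest["files"][name] = _sha256(Path(p))

        stage = "derive"
        subjects = derive_lipid_columns(cohort.subjects)
        _write(subjects, outdir / "subjects.tsv", manifest)
        results["n_subjects"] = len(subjects)
        results["n_flagged_lipids"] = int(subjects["lipid_flag"].sum())
        sd_table = (
            SdTable() if config.sd_mode == "fixed_reference_values" else SdTable.from_cohort(subjects)
        )

        stage = "assoc"
        covs = gwas.covariate_matrix(subjects)
        scans: dict[str, pd.DataFrame] = {}
        for trait, col in SCAN_TRAITS.items():
            scans[trait] = gwas.assoc_scan(cohort.genotypes, subjects[col], covs, trait)
            _write(scans[trait], outdir / f"assoc_{trait}.tsv", manifest)
        combined_outcome = (
            (subjects["prevalent_ascvd"] == 1) | (subjects["incident_event"] == 1)
        ).astype(float)
        outcome_scan = gwas.binary_assoc_scan(cohort.genotypes, combined_outcome, covs)
        _write(outcome_scan, outdir / "assoc_ascvd.tsv", manifest)

        stage = "select"
        het = None if config.scale_het_threshold else config.het_threshold_full_scale
        selected = gwas.select_variants(
            cohort.genotypes,
            scans,
            tier=config.tier,
            r2_threshold=config.r2_threshold,
            maf_threshold=config.maf_threshold,
            het_threshold=het,
            holm_alpha=config.holm_alpha,
            tier_thresholds=config.tier_thresholds,
        )
        (outdir / f"selected_tier{config.tier}.txt").write_text("\n".join(selected) + "\n")
        manifest["files"][f"selected_tier{config.tier}.txt"] = _sha256(
            outdir / f"selected_tier{config.tier}.txt"
        )
        results["n_selected"] = len(selected)
        if len(selected) < 3:
            raise RuntimeError(f"only {len(selected)} variants selected; cannot run MR")

        stage = "mr"
        mri = mr.MRInput.from_scans(
            {"trl_remnant_c": scans["trl_remnant_c"], "ldl_c": scans["ldl_c"]},
            outcome_scan,
            selected,
        )
        estimates = mr.ivw_fit(mri) + mr.egger_fit(mri)
        mr_table = mr.report_estimates(estimates, sd_table)
        _write(mr_table, outdir / "mr_results.tsv", manifest)
        results["mr"] = mr_table.to_dict("records")

        stage = "cluster"
        oriented_mm = cl.orient_effects(scans, mode="minor_vs_major")
        oriented_mm = oriented_mm[oriented_mm["variant_id"].isin(selected)].reset_index(drop=True)
        assignments = cl.assign_clusters(
            oriented_mm, config.cluster1_interval, config.cluster2_interval
        )
        _write(assignments, outdir / "clusters.tsv", manifest)
        defined = assignments["ratio"].dropna().to_numpy()
        if len(defined) >= 20:
            hist, bimod = cl.ratio_histogram(defined)
            _write(hist, outdir / "ratio_histogram.tsv", manifest)
            results["bimodality"] = bimod
        oriented_ar = cl.orient_effects(scans, mode="apob_raising")
        oriented_ar = oriented_ar[oriented_ar["variant_id"].isin(selected)].reset_index(drop=True)
        cmr = cl.cluster_mr(oriented_ar, outcome_scan, assignments, sd_apob=sd_table["apob"])
        cmr_rows = []
        for clus, methods in cmr.estimates.items():
            for method, est in methods.items():
                cmr_rows.append(
                    {
                        "cluster": clus,
                        "method": method,
                        "n_snps": est.n_variants,
                        "or_unit": est.or_per_unit,
                        "or_sd": est.or_per_sd(cmr.sd_apob),
                        "ci_low_sd": est.ci95_per_sd(cmr.sd_apob)[0],
                        "ci_high_sd": est.ci95_per_sd(cmr.sd_apob)[1],
                        "p": est.p,
                    }
                )
        cmr_table = pd.DataFrame(cmr_rows)
        _write(cmr_table, outdir / "cluster_mr.tsv", manifest)
        results["cluster_mr"] = cmr_rows
        results["cluster_comparison"] = cmr.comparison
        results["cluster_counts"] = assignments["cluster"].value_counts().to_dict()

        stage = "score"
        score_rows, hz_frames, dec_frames = [], [], []
        per_cluster: dict[int, dict] = {}
        for clus in (1, 2):
            ids = assignments.loc[assignments["cluster"] == clus, "variant_id"].tolist()
            if len(ids) < 3:
                continue
            score = risk.build_gene_score(cohort.genotypes, oriented_ar, ids)
            means = risk.decile_summary(score, subjects)
            hz = risk.decile_hazards(score, subjects)
            overall = risk.hr_per_10mg_dl(hz, means)
            per_cluster[clus] = {"score": score, "means": means, "hz": hz, "overall": overall}
            dec_frames.append(means.assign(cluster=clus))
            hz_frames.append(hz.assign(cluster=clus))
            score_rows.append({"cluster": clus, **overall})
        if dec_frames:
            _write(pd.concat(dec_frames, ignore_index=True), outdir / "score_deciles.tsv", manifest)
            _write(pd.concat(hz_frames, ignore_index=True), outdir / "hazards.tsv", manifest)
        results["hr_per_10mg_dl"] = score_rows
        if len(per_cluster) == 2:
            results["interaction"] = risk.interaction_test(
                per_cluster[1]["hz"], per_cluster[1]["means"],
                per_cluster[2]["hz"], per_cluster[2]["means"],
            )

        stage = "observe"
        obs = risk.observational_cox(subjects)
        _write(obs, outdir / "observational_cox.tsv", manifest)
        results["observational"] = obs.to_dict("records")
        spline_frames = []
        for include_hdl in (False, True):
            sp = risk.ratio_spline(subjects, "trl_remnant_c", include_hdl=include_hdl)
            spline_frames.append(sp.curve.assign(include_hdl=include_hdl, p=sp.p_spline))
            results[f"spline_hdl_{include_hdl}"] = {
                "p": sp.p_spline, "log_hr_range": sp.log_hr_range,
            }
        _write(pd.concat(spline_frames, ignore_index=True), outdir / "spline_curve.tsv", manifest)

        stage = "report"
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True, default=float)
        (outdir / "report.txt").write_text(report(outdir))
        manifest["files"]["report.txt"] = _sha256(outdir / "report.txt")
    except Exception as exc:  # noqa: BLE001 - halt with the stage name
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


def report(rundir) -> str:
    """Human-readable summary of a completed run: per-unit and per-SD ORs,
    cluster counts and HRs per 10 mg/dL apoB; flags gaps when stages are
    missing."""
    rundir = Path(rundir)
    lines = ["# remnantmr run report", ""]

    def _read(name):
        p = rundir / name
        return pd.read_csv(p, sep="\t") if p.exists() else None

    mr_table = _read("mr_results.tsv")
    lines.append("## Mendelian randomisation (ASCVD odds ratios)")
    if mr_table is None:
        lines.append("  [missing stage: mr]")
    else:
        for _, r in mr_table.iterrows():
            lines.append(
                f"  {r['method']:>6} {r['exposure']:<15} OR/unit {r['or_unit']:.2f} "
                f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}]  OR/SD {r['or_sd']:.2f}  p={r['p']:.2g}"
            )
    lines.append("")
    clus = _read("clusters.tsv")
    lines.append("## SNP clusters (apoB : TRL/remnant-C effect-size ratio)")
    if clus is None:
        lines.append("  [missing stage: cluster]")
    else:
        counts = clus["cluster"].value_counts().to_dict()
        lines.append(
            f"  cluster 1 [0.9, 3.0]: {counts.get(1, 0)}   "
            f"cluster 2 [-0.75, 0.75]: {counts.get(2, 0)}   "
            f"unassigned: {counts.get(0, 0)}"
        )
    cmr = _read("cluster_mr.tsv")
    if cmr is not None:
        for _, r in cmr.iterrows():
            lines.append(
                f"  cluster {int(r['cluster'])} {r['method']:>6}: OR/SD apoB {r['or_sd']:.2f} "
                f"[{r['ci_low_sd']:.2f}, {r['ci_high_sd']:.2f}]"
            )
    lines.append("")
    hz = _read("hazards.tsv")
    lines.append("## Polygenic-score decile hazards")
    if hz is None:
        lines.append("  [missing stage: score]")
    else:
        res = json.loads((rundir / "results.json").read_text()) if (rundir / "results.json").exists() else {}
        for row in res.get("hr_per_10mg_dl", []):
            lines.append(
                f"  cluster {row['cluster']}: HR per 10 mg/dL apoB {row['hr_per_10mg_dl']:.2f} "
                f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
            )
        if "interaction" in res:
            lines.append(f"  apoB x cluster interaction p = {res['interaction']['p']:.3g}")
    lines.append("")
    obs = _read("observational_cox.tsv")
    lines.append("## Observational Cox models (HR per 1.0 mmol/L)")
    if obs is None:
        lines.append("  [missing stage: observe]")
    else:
        for _, r in obs.iterrows():
            lines.append(
                f"  {r['exposure']:<15} HR {r['hr_per_unit']:.2f} "
                f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}]  p={r['p']:.2g}"
            )
    lines.append("")
    return "\n".join(lines)
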