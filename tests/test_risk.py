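"""Gene scores, decile hazard modelling, observational Cox and splines."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from remnantmr import risk
from remnantmr.clusters import assign_clusters, orient_effects


def _breslow_partial_loglik(beta, x, t, e):
    """Brute-force Breslow partial log-likelihood (no ties in the data)."""
    eta = x @ beta
    ll = 0.0
    for i in np.flatnonzero(e):
        at_risk = t >= t[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


class TestGeneScore:
    def _oriented(self, ids, betas, flipped=None):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "beta_apob": betas,
                "se_apob": 0.01,
                "orientation_flipped": flipped if flipped is not None else [False] * len(ids),
            }
        )

    def test_single_variant_arithmetic(self):
        g = pd.DataFrame({"v1": [0, 1, 2]})
        score = risk.build_gene_score(g, self._oriented(["v1"], [0.05]), ["v1"])
        assert score.tolist() == pytest.approx([0.0, 0.05, 0.10])

    def test_flipped_variant_counts_major_allele(self):
        g = pd.DataFrame({"v1": [0, 1, 2]})
        score = risk.build_gene_score(g, self._oriented(["v1"], [0.05], [True]), ["v1"])
        assert score.tolist() == pytest.approx([0.10, 0.05, 0.0])

    def test_equal_weights_proportional_to_allele_count(self, rng):
        g = pd.DataFrame(rng.binomial(2, 0.3, size=(50, 3)), columns=["a", "b", "c"])
        score = risk.build_gene_score(g, self._oriented(["a", "b", "c"], [0.02] * 3), ["a", "b", "c"])
        assert np.allclose(score, 0.02 * g.sum(axis=1))

    def test_negative_weight_rejected(self):
        g = pd.DataFrame({"v1": [0, 1]})
        with pytest.raises(ValueError):
            risk.build_gene_score(g, self._oriented(["v1"], [-0.01]), ["v1"])

    def test_missing_variant_rejected(self):
        g = pd.DataFrame({"v1": [0, 1]})
        with pytest.raises(KeyError):
            risk.build_gene_score(g, self._oriented(["v2"], [0.01]), ["v2"])

    def test_score_calibrated_against_measured_apob(self, ld_free_cohort):
        """Beta-weighted score predicts apoB with slope ~1 (g/L per g/L) when
        the variants are independent (LD between score variants double-counts
        tagged signal and attenuates the slope, so the clean calibration
        property is stated for an LD-free panel)."""
        big = ld_free_cohort
        oriented = orient_effects(big.scans, "apob_raising")
        asg = assign_clusters(orient_effects(big.scans, "minor_vs_major"))
        ids = asg.loc[asg["cluster"].isin([1, 2]), "variant_id"].tolist()
        score = risk.build_gene_score(big.cohort.genotypes, oriented, ids)
        x = score.to_numpy() - score.mean()
        y = big.subjects["apob"].to_numpy()
        slope = float(x @ y) / float(x @ x)
        assert slope == pytest.approx(1.0, abs=0.15)


class TestDecileSummaries:
    def test_receptor_score_moves_both_cholesterols(self, big_cohort):
        """Cluster-1-style score: LDL-C and remnant-C rise across deciles
        while TG stays comparatively flat; cluster-2-style score: TG and
        remnant-C rise steeply."""
        oriented = orient_effects(big_cohort.scans, "apob_raising")
        asg = assign_clusters(orient_effects(big_cohort.scans, "minor_vs_major"))
        out = {}
        for cl in (1, 2):
            ids = asg.loc[asg["cluster"] == cl, "variant_id"].tolist()
            score = risk.build_gene_score(big_cohort.cohort.genotypes, oriented, ids)
            means = risk.decile_summary(score, big_cohort.subjects)
            out[cl] = means
        span = lambda m, c: m[c].iloc[-1] - m[c].iloc[0]
        # both scores raise remnant-C and apoB across deciles
        for cl in (1, 2):
            assert span(out[cl], "apob") > 0
            assert span(out[cl], "trl_remnant_c") > 0
        # per unit apoB (the decile plots' x-axis), TG responds far more to
        # the lipolysis-cluster score ...
        tg_per_apob = {cl: span(out[cl], "tg") / span(out[cl], "apob") for cl in (1, 2)}
        assert tg_per_apob[2] > 3 * abs(tg_per_apob[1])
        # ... and LDL-C far more to the receptor-cluster score
        ldl_per_apob = {cl: span(out[cl], "ldl_c_direct") / span(out[cl], "apob") for cl in (1, 2)}
        assert ldl_per_apob[1] > 2 * abs(ldl_per_apob[2])
        # decile mean apoB strictly increasing for both scores
        for cl in (1, 2):
            assert np.all(np.diff(out[cl]["apob"]) > 0)

    def test_null_score_flat_means(self, big_cohort):
        rng = np.random.default_rng(1)
        score = pd.Series(rng.standard_normal(len(big_cohort.subjects)))
        means = risk.decile_summary(score, big_cohort.subjects)
        spread = means["apob"].max() - means["apob"].min()
        assert spread < 0.01  # g/L; pure noise deciles

    def test_tied_scores_partition_evenly(self):
        subjects = pd.DataFrame(
            {"apob": np.random.default_rng(0).normal(1, 0.2, 1000),
             "tg": 1.0, "trl_remnant_c": 0.6, "ldl_c_direct": 3.5}
        )
        score = pd.Series(np.zeros(1000))
        means = risk.decile_summary(score, subjects, min_bin=10)
        assert len(means) == 10
        assert means["n"].min() >= 90


class TestCoxAgainstBruteForce:
    def test_partial_likelihood_oracle(self, rng):
        """lifelines' Cox fit agrees with a brute-force partial-likelihood
        maximiser to 1e-6 in the coefficients (n=200, tie-free)."""
        n = 200
        x = rng.standard_normal((n, 2))
        eta = 0.6 * x[:, 0] - 0.3 * x[:, 1]
        t = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        e = (t <= np.quantile(t, 0.7)).astype(int)
        t = np.minimum(t, np.quantile(t, 0.7))
        # jitter censored times off the event times to keep the data tie-free
        assert len(np.unique(t[e == 1])) == e.sum()
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"T": t, "E": e, "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        res = optimize.minimize(
            lambda b: -_breslow_partial_loglik(b, x, t, e),
            np.zeros(2),
            method="BFGS",
            options={"gtol": 1e-10},
        )
        assert np.allclose(cph.params_.to_numpy(), res.x, atol=1e-6)


class TestDecileHazards:
    def test_log_linear_truth_gives_linear_decile_hrs(self, big_cohort):
        """With a log-linear hazard in the pools, decile log-HRs increase
        roughly linearly in decile mean apoB."""
        oriented = orient_effects(big_cohort.scans, "apob_raising")
        asg = assign_clusters(orient_effects(big_cohort.scans, "minor_vs_major"))
        ids = asg.loc[asg["cluster"] == 1, "variant_id"].tolist()
        score = risk.build_gene_score(big_cohort.cohort.genotypes, oriented, ids)
        hz = risk.decile_hazards(score, big_cohort.subjects)
        means = risk.decile_summary(score, big_cohort.subjects)
        assert hz.loc[hz["decile"] == 1, "hr"].iloc[0] == 1.0
        merged = hz.merge(means[["decile", "apob"]], on="decile")
        r = np.corrcoef(merged["apob"], merged["log_hr"])[0, 1]
        assert r > 0.7

    def test_null_hazard_cis_cover_unity(self):
        from remnantmr.config import CohortParams
        from remnantmr.lipids import derive_lipid_columns
        from remnantmr.synthetic import simulate_cohort

        p = CohortParams(n_subjects=8000, n_variants=60, beta_remnant=0.0, beta_ldl=0.0, seed=77)
        cohort = simulate_cohort(p)
        subjects = derive_lipid_columns(cohort.subjects)
        rng = np.random.default_rng(1)
        score = pd.Series(rng.standard_normal(len(subjects)))
        hz = risk.decile_hazards(score, subjects)
        nonref = hz[hz["decile"] > 1]
        covered = ((nonref["ci_low"] <= 1.0) & (nonref["ci_high"] >= 1.0)).mean()
        assert covered >= 0.8  # ~95% nominal per decile


class TestHrPer10:
    def _hazards(self, apob, log_hr, se=0.05):
        hz = pd.DataFrame(
            {"decile": np.arange(1, 11), "log_hr": log_hr, "se": se,
             "hr": np.exp(log_hr), "ci_low": 1.0, "ci_high": 1.0,
             "n_events": 50, "flagged": False}
        )
        hz.loc[0, "se"] = 0.0
        means = pd.DataFrame({"decile": np.arange(1, 11), "apob": apob})
        return hz, means

    def test_exact_linear_slope(self):
        apob = np.linspace(0.9, 1.2, 10)
        hz, means = self._hazards(apob, 1.0 * (apob - apob[0]))
        out = risk.hr_per_10mg_dl(hz, means)
        assert out["hr_per_10mg_dl"] == pytest.approx(np.exp(0.1), rel=1e-9)

    def test_zero_slope_unity(self):
        apob = np.linspace(0.9, 1.2, 10)
        hz, means = self._hazards(apob, np.zeros(10))
        assert risk.hr_per_10mg_dl(hz, means)["hr_per_10mg_dl"] == pytest.approx(1.0)

    def test_reference_decile_invariance(self):
        """Re-referencing shifts all log-HRs by a constant; the slope-based
        HR per 10 mg/dL is unchanged."""
        apob = np.linspace(0.9, 1.2, 10)
        log_hr = 0.8 * (apob - apob[0])
        hz1, means = self._hazards(apob, log_hr)
        hz2, _ = self._hazards(apob, log_hr - log_hr[4])
        out1 = risk.hr_per_10mg_dl(hz1, means)
        out2 = risk.hr_per_10mg_dl(hz2, means)
        assert out1["hr_per_10mg_dl"] == pytest.approx(out2["hr_per_10mg_dl"], rel=1e-9)

    def test_needs_three_finite_deciles(self):
        hz, means = self._hazards(np.linspace(0.9, 1.2, 10), np.zeros(10))
        hz.loc[1:, "log_hr"] = np.nan
        with pytest.raises(ValueError):
            risk.hr_per_10mg_dl(hz, means)


class TestInteraction:
    def _cluster_inputs(self, slope, seed=0):
        rng = np.random.default_rng(seed)
        apob = np.linspace(0.9, 1.2, 10)
        log_hr = slope * (apob - apob[0]) + rng.normal(0, 0.02, 10)
        hz = pd.DataFrame({"decile": np.arange(1, 11), "log_hr": log_hr, "se": 0.05})
        hz.loc[0, "se"] = 0.0
        means = pd.DataFrame({"decile": np.arange(1, 11), "apob": apob})
        return hz, means

    def test_identical_inputs_no_interaction(self):
        hz, means = self._cluster_inputs(1.0)
        out = risk.interaction_test(hz, means, hz, means)
        assert out["interaction_coef"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_slope_difference_detected(self):
        hz1, m1 = self._cluster_inputs(0.8, seed=1)
        hz2, m2 = self._cluster_inputs(1.6, seed=2)
        out = risk.interaction_test(hz1, m1, hz2, m2)
        assert out["p"] < 0.05 and out["interaction_coef"] > 0

    def test_label_swap_flips_sign(self):
        hz1, m1 = self._cluster_inputs(0.8, seed=1)
        hz2, m2 = self._cluster_inputs(1.6, seed=2)
        a = risk.interaction_test(hz1, m1, hz2, m2)
        b = risk.interaction_test(hz2, m2, hz1, m1)
        assert b["interaction_coef"] == pytest.approx(-a["interaction_coef"], rel=1e-9)
        assert b["p"] == pytest.approx(a["p"], rel=1e-9)


class TestObservationalCox:
    def test_remnant_gradient_exceeds_ldl(self, big_cohort):
        out = risk.observational_cox(big_cohort.subjects).set_index("exposure")
        assert (
            out.loc["trl_remnant_c", "hr_per_unit"] > out.loc["ldl_c_direct", "hr_per_unit"]
        )
        assert out.loc["trl_remnant_c", "p"] < 0.05

    def test_exposure_order_permutes_rows(self, small_cohort):
        a = risk.observational_cox(small_cohort.subjects, ("ldl_c_direct", "trl_remnant_c"))
        b = risk.observational_cox(small_cohort.subjects, ("trl_remnant_c", "ldl_c_direct"))
        a = a.set_index("exposure").sort_index()
        b = b.set_index("exposure").sort_index()
        pd.testing.assert_frame_equal(a, b, rtol=1e-8)

    def test_vldl_exposure_pair_runs(self, small_cohort):
        out = risk.observational_cox(small_cohort.subjects, ("ldl_c_direct", "vldl_c"))
        assert set(out["exposure"]) == {"ldl_c_direct", "vldl_c"}


class TestRcsBasis:
    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.linspace(3.5, 6.0, 50)
        basis = risk.rcs_basis(x, knots)
        # all nonlinear columns are linear in x beyond the last knot
        for j in range(1, basis.shape[1]):
            second_diff = np.diff(basis[:, j], 2)
            assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_column_count(self):
        x = np.linspace(0, 1, 20)
        assert risk.rcs_basis(x, np.array([0.1, 0.5, 0.9])).shape[1] == 2
        assert risk.rcs_basis(x, np.array([0.1, 0.4, 0.6, 0.9])).shape[1] == 3


class TestRatioSpline:
    def test_curve_is_unity_at_reference(self, small_cohort):
        sp = risk.ratio_spline(small_cohort.subjects, "trl_remnant_c")
        at_ref = np.interp(sp.reference_ratio, sp.curve["ratio"], sp.curve["log_hr"])
        assert abs(at_ref) < 0.02 * max(sp.log_hr_range, 0.1) + 1e-6

    def test_significant_signal_detected(self, big_cohort):
        sp = risk.ratio_spline(big_cohort.subjects, "trl_remnant_c")
        assert sp.p_spline < 0.01

    def test_tg_ratio_also_supported(self, small_cohort):
        sp = risk.ratio_spline(small_cohort.subjects, "tg")
        assert sp.exposure == "tg/ldl_c_direct"
        assert sp.n_events > 0
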