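"""GEE, PERMANOVA, NB-GLM/bootstrap, outlier sensitivity, cohort tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from gravidbiome import diversity as dv
from gravidbiome import longitudinal_models as lm
from gravidbiome import synthetic_cohort as sc


def _singleton_frame(rng, n=120):
    """All clusters of size one: GEE must collapse to OLS."""
    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "subject_id": [f"p{i}" for i in range(n)],
            "site": "DRC",
            "arm": rng.choice([1, 2], n),
            "week": 12,
            "batch": rng.choice(["B1", "B2"], n),
        }
    )
    frame["time"] = rng.integers(0, 2, n)
    frame["supplement_status"] = rng.integers(0, 2, n)
    frame["standardized_depth"] = rng.normal(0, 1, n)
    frame["shannon_h"] = (
        4.0 - 0.3 * frame["time"] + 0.1 * frame["supplement_status"]
        + rng.normal(0, 0.4, n)
    )
    return frame


class TestGEE:
    def test_size_one_clusters_equal_ols(self, rng):
        frame = _singleton_frame(rng)
        alpha = frame.set_index("sample_id")[["shannon_h"]]
        spec = lm.DesignSpec(outcome="shannon_h")
        fits = {r.term: r for r in lm.fit_gee_alpha(alpha, frame, spec)}
        ols = smf.ols(
            "shannon_h ~ time + supplement_status + C(batch) + standardized_depth",
            frame,
        ).fit()
        for term, res in fits.items():
            assert res.estimate == pytest.approx(ols.params[term], abs=1e-8)

    def test_noiseless_linear_outcome_recovers_slope_exactly(self):
        rng = np.random.default_rng(5)
        frame = _singleton_frame(rng)
        frame["shannon_h"] = 4.0 - 0.5 * frame["time"]
        alpha = frame.set_index("sample_id")[["shannon_h"]]
        spec = lm.DesignSpec(outcome="shannon_h", include_batch=False,
                             include_depth=False)
        fits = {r.term: r for r in lm.fit_gee_alpha(alpha, frame, spec)}
        assert fits["time"].estimate == pytest.approx(-0.5, abs=1e-8)
        assert fits["time"].se == pytest.approx(0.0, abs=1e-6)

    def test_planted_shannon_time_effect_recovered(self):
        """Repeated-measures recovery of the planted -0.22 contrast."""
        config = sc.default_scenario()
        config.sites = {"DRC": 250}
        config.arm_proportions = {"DRC": config.arm_proportions["DRC"]}
        config.alpha_time_effects = {
            m: {"DRC": v["DRC"]} for m, v in config.alpha_time_effects.items()
        }
        config.alpha_time_effects["shannon_h"]["DRC"] = -0.22
        ests = []
        for seed in sc.spawn_seeds(0, 10):
            frame = sc.generate_alpha_outcomes(config, seed)
            alpha = frame.set_index("sample_id")[["shannon_h"]]
            fits = {r.term: r for r in lm.fit_gee_alpha(
                alpha, frame, lm.DesignSpec(outcome="shannon_h"))}
            assert fits["time"].converged
            ests.append(fits["time"].estimate)
        assert np.mean(ests) == pytest.approx(-0.22, abs=0.02)

    def test_too_few_clusters_rejected(self, rng):
        frame = _singleton_frame(rng).iloc[:2].copy()
        frame["subject_id"] = "p0"
        alpha = frame.set_index("sample_id")[["shannon_h"]]
        with pytest.raises(ValueError, match="clusters"):
            lm.fit_gee_alpha(alpha, frame, lm.DesignSpec(outcome="shannon_h"))


def _paired_frame(n_pairs=25, n_singletons=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pairs):
        arm = 1 + i % 2
        rows.append({"sample_id": f"s{i}a", "subject_id": f"p{i}", "site": "DRC",
                     "arm": arm, "week": 12, "time": 0,
                     "supplement_status": 1 if arm == 1 else 0,
                     "batch": "B1", "standardized_depth": rng.normal()})
        rows.append({"sample_id": f"s{i}b", "subject_id": f"p{i}", "site": "DRC",
                     "arm": arm, "week": 34, "time": 1, "supplement_status": 1,
                     "batch": "B1", "standardized_depth": rng.normal()})
    for i in range(n_singletons):
        rows.append({"sample_id": f"x{i}", "subject_id": f"q{i}", "site": "DRC",
                     "arm": 3, "week": 34, "time": 1, "supplement_status": 0,
                     "batch": "B1", "standardized_depth": rng.normal()})
    return pd.DataFrame(rows)


class TestPermanova:
    def test_label_invariance_under_sample_reordering(self, rng):
        frame = _paired_frame()
        n = len(frame)
        pts = rng.normal(size=(n, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = dv.DistanceMatrix(list(frame["sample_id"]), d)
        spec = lm.DesignSpec(outcome="", include_batch=False)
        r1 = lm.permanova(dm, frame, spec, "time", n_perm=49, seed=1)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r2 = lm.permanova(dm, shuffled, spec, "time", n_perm=49, seed=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)

    def test_maximal_separation_gives_smallest_p(self):
        frame = _paired_frame(n_pairs=20, n_singletons=0)
        profile_a, profile_b = np.eye(2)
        pts = np.array([profile_a if t == 0 else profile_b for t in frame["time"]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = dv.DistanceMatrix(list(frame["sample_id"]), d)
        spec = lm.DesignSpec(outcome="", include_batch=False, include_depth=False)
        r = lm.permanova(dm, frame, spec, "time", n_perm=200, seed=4)
        assert r.p_value == pytest.approx(1 / 201)

    def test_matches_classical_oneway_formula(self, rng):
        """Two-group, no-covariate pseudo-F equals the textbook PERMANOVA
        statistic computed directly from group sums of squared distances."""
        n_a, n_b = 9, 7
        n = n_a + n_b
        pts = rng.normal(size=(n, 3))
        pts[n_a:] += 0.8
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        frame = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "subject_id": [f"p{i}" for i in range(n)],
             "week": 12, "time": [0] * n_a + [1] * n_b,
             "supplement_status": 0, "batch": "B1", "arm": 1}
        )

        class Bare:
            cluster = "subject_id"

            def rhs_terms(self):
                return ["time"]

        r = lm.permanova(
            dv.DistanceMatrix(list(frame["sample_id"]), d), frame, Bare(),
            "time", n_perm=10, seed=0,
        )
        # classical one-way: SST = sum d^2 / n; SSW from within-group sums
        d2 = d**2
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = (
            d2[:n_a, :n_a][np.triu_indices(n_a, 1)].sum() / n_a
            + d2[n_a:, n_a:][np.triu_indices(n_b, 1)].sum() / n_b
        )
        f_classic = (sst - ssw) / (ssw / (n - 2))
        assert r.pseudo_f == pytest.approx(f_classic, rel=1e-10)

    def test_matches_skbio_oneway(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        n = 14
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        grouping = ["a"] * 7 + ["b"] * 7
        frame = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "subject_id": [f"p{i}" for i in range(n)],
             "week": 12, "time": [0] * 7 + [1] * 7,
             "supplement_status": 0, "batch": "B1", "arm": 1}
        )

        class Bare:
            cluster = "subject_id"

            def rhs_terms(self):
                return ["time"]

        ours = lm.permanova(
            dv.DistanceMatrix(list(frame["sample_id"]), d), frame, Bare(),
            "time", n_perm=10, seed=0,
        )
        theirs = skbio_permanova(SkbioDM(d), grouping, permutations=10)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_collinear_term_rejected(self):
        frame = _paired_frame(n_pairs=10, n_singletons=0)
        frame["copy_of_time"] = frame["time"]
        d = np.abs(
            frame["time"].to_numpy()[:, None] - frame["time"].to_numpy()[None, :]
        ).astype(float)
        dm = dv.DistanceMatrix(list(frame["sample_id"]), d)

        class Bare:
            cluster = "subject_id"

            def rhs_terms(self):
                return ["time", "copy_of_time"]

        with pytest.raises(ValueError, match="collinear"):
            lm.permanova(dm, frame, Bare(), "copy_of_time", n_perm=10, seed=0)

    def test_reproducible_with_seed(self, rng):
        frame = _paired_frame()
        pts = rng.normal(size=(len(frame), 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = dv.DistanceMatrix(list(frame["sample_id"]), d)
        spec = lm.DesignSpec(outcome="", include_batch=False)
        r1 = lm.permanova(dm, frame, spec, "time", n_perm=99, seed=12)
        r2 = lm.permanova(dm, frame, spec, "time", n_perm=99, seed=12)
        assert r1.p_value == r2.p_value


class TestNegativeBinomial:
    def test_constant_counts_give_null_slopes(self):
        frame = _paired_frame(n_pairs=30, n_singletons=0)
        counts = np.full(len(frame), 50)
        spec = lm.DesignSpec(outcome="_count", include_batch=False)
        fits = {r.term: r for r in lm.nb_glm_terms(counts, frame, spec)}
        for term, res in fits.items():
            if term != "Intercept":
                assert res.estimate == pytest.approx(0.0, abs=1e-4)

    def test_poisson_limit_matches_poisson_glm(self, rng):
        """With Poisson data the NB fit converges to the Poisson fit."""
        frame = _paired_frame(n_pairs=150, n_singletons=0)
        eta = 3.0 + 0.4 * frame["time"].to_numpy()
        counts = rng.poisson(np.exp(eta))
        spec = lm.DesignSpec(outcome="_count", include_batch=False,
                             include_depth=False)
        fits = {r.term: r for r in lm.nb_glm_terms(counts, frame, spec)}
        pois = sm.GLM(
            counts,
            sm.add_constant(frame[["time", "supplement_status"]].to_numpy(float)),
            family=sm.families.Poisson(),
        ).fit()
        assert fits["time"].estimate == pytest.approx(pois.params[1], abs=0.01)

    def test_planted_log_fold_effect_recovered(self):
        rng = np.random.default_rng(7)
        ests = []
        for seed in range(5):
            frame = _paired_frame(n_pairs=300, n_singletons=0, seed=seed)
            eta = (
                2.5 + 0.326 * frame["time"].to_numpy()
                + rng.normal(0, 0.3, len(frame))
            )
            counts = rng.poisson(np.exp(eta))
            spec = lm.DesignSpec(outcome="_count", include_batch=False)
            fits = {r.term: r for r in lm.nb_glm_terms(counts, frame, spec)}
            ests.append(fits["time"].estimate)
        assert np.mean(ests) == pytest.approx(0.326, abs=0.05)


class TestClusterBootstrap:
    def _counts_frame(self, seed=0, n_pairs=60, effect=0.0):
        rng = np.random.default_rng(seed)
        frame = _paired_frame(n_pairs=n_pairs, n_singletons=10, seed=seed)
        subj_eff = {s: rng.normal(0, 0.3) for s in frame["subject_id"].unique()}
        eta = (
            3.0 + effect * frame["time"].to_numpy()
            + frame["subject_id"].map(subj_eff).to_numpy()
            + rng.normal(0, 0.2, len(frame))
        )
        return rng.poisson(np.exp(eta)), frame

    def test_minimum_replicates_enforced(self):
        counts, frame = self._counts_frame()
        with pytest.raises(ValueError, match="replicates"):
            lm.nb_bootstrap_test(counts, frame,
                                 lm.DesignSpec(outcome="_count"), B=1)

    def test_seed_reproducibility(self):
        counts, frame = self._counts_frame()
        spec = lm.DesignSpec(outcome="_count", include_batch=False)
        b1 = lm.nb_bootstrap_test(counts, frame, spec, B=30, seed=9)
        b2 = lm.nb_bootstrap_test(counts, frame, spec, B=30, seed=9)
        assert b1["time"].p_value == b2["time"].p_value
        np.testing.assert_array_equal(b1["time"].samples, b2["time"].samples)

    def test_invariant_to_order_preserving_relabeling(self):
        counts, frame = self._counts_frame()
        spec = lm.DesignSpec(outcome="_count", include_batch=False)
        b1 = lm.nb_bootstrap_test(counts, frame, spec, B=30, seed=9)
        renamed = frame.copy()
        renamed["subject_id"] = "z_" + renamed["subject_id"]
        b2 = lm.nb_bootstrap_test(counts, renamed, spec, B=30, seed=9)
        assert b1["time"].p_value == pytest.approx(b2["time"].p_value)

    def test_detects_planted_effect(self):
        counts, frame = self._counts_frame(seed=3, effect=-0.44)
        spec = lm.DesignSpec(outcome="_count", include_batch=False)
        b = lm.nb_bootstrap_test(counts, frame, spec, B=100, seed=2)
        assert b["time"].p_value < 0.01
        assert b["time"].estimate == pytest.approx(-0.44, abs=0.15)

    def test_percentile_alternative(self):
        counts, frame = self._counts_frame(seed=3, effect=-0.44)
        spec = lm.DesignSpec(outcome="_count", include_batch=False)
        b = lm.nb_bootstrap_test(counts, frame, spec, B=100, seed=2,
                                 pvalue_method="percentile")
        assert b["time"].p_value <= 2 / 100 * 1.01


class TestOutlierSensitivity:
    def test_hand_quartile_example(self):
        # 5 copies of {-1, 0, 1} plus one gross outlier: Q1=-1, Q3=1,
        # IQR=2, fences at -7/+7 by linear-interpolation quantiles
        residuals = np.r_[np.tile([-1.0, 0.0, 1.0], 5), 1000.0]
        mask = lm.residual_outlier_mask(residuals)
        assert mask.sum() == 1
        assert mask[-1]

    def test_clean_residuals_empty_mask(self, rng):
        assert not lm.residual_outlier_mask(rng.normal(size=200), k=3).any()

    def test_infinite_fence_empty_mask(self, rng):
        r = np.r_[rng.normal(size=50), 1e9]
        assert not lm.residual_outlier_mask(r, k=np.inf).any()

    def test_mask_monotone_in_k(self, rng):
        r = rng.standard_cauchy(300)
        m1 = lm.residual_outlier_mask(r, k=1.0)
        m3 = lm.residual_outlier_mask(r, k=3.0)
        assert (m3 <= m1).all()

    def test_no_outliers_fits_identical(self):
        config = sc.default_scenario()
        config.sites = {"DRC": 80}
        config.arm_proportions = {"DRC": config.arm_proportions["DRC"]}
        frame = sc.generate_alpha_outcomes(config, 3)
        alpha = frame.set_index("sample_id")[["shannon_h"]]
        spec = lm.DesignSpec(outcome="shannon_h")
        res = lm.sensitivity_refit(alpha, frame, spec, k=50.0)
        assert res.removed_sample_ids == []
        full = {f.term: f.estimate for f in res.full}
        red = {f.term: f.estimate for f in res.reduced}
        assert full == pytest.approx(red)

    def test_contaminated_subject_estimate_improves(self):
        config = sc.default_scenario()
        config.sites = {"DRC": 120}
        config.arm_proportions = {"DRC": config.arm_proportions["DRC"]}
        frame = sc.generate_alpha_outcomes(config, 5)
        # one aberrant woman whose 34-week sample is wildly off
        target = frame[(frame["arm"] != 3) & (frame["time"] == 1)].index[0]
        frame.loc[target, "shannon_h"] += 40.0
        alpha = frame.set_index("sample_id")[["shannon_h"]]
        spec = lm.DesignSpec(outcome="shannon_h")
        res = lm.sensitivity_refit(alpha, frame, spec, k=3.0)
        truth = config.alpha_time_effects["shannon_h"]["DRC"]
        full = {f.term: f.estimate for f in res.full}
        red = {f.term: f.estimate for f in res.reduced}
        assert frame.loc[target, "sample_id"] in res.removed_sample_ids
        assert abs(red["time"] - truth) < abs(full["time"] - truth)


class TestPhylumMixedModel:
    def test_planted_site_specific_slopes_detected(self, small_cohort):
        from gravidbiome.feature_tables import aggregate_rank

        phy = aggregate_rank(small_cohort.table, "phylum")
        rel = phy.relative_abundance()
        firm = [i for i in rel.index if "Firmicutes" in i][0]
        y = rel.loc[firm, small_cohort.frame["sample_id"]].to_numpy()
        res = lm.phylum_lmm(pd.Series(y), small_cohort.frame, phylum="Firmicutes")
        # DRC/Guatemala carry Ruminococcaceae declines the other sites lack
        assert res.interaction_p < 0.05
        assert res.model_used == "interaction"
        assert len(res.contrasts) == 8 * 7 // 2

    def test_no_signal_additive_with_no_contrasts(self, rng):
        frame = _paired_frame(n_pairs=40, n_singletons=0)
        frame = pd.concat(
            [frame.assign(site=s) for s in ("A", "B")], ignore_index=True
        )
        frame["subject_id"] = frame["site"] + frame["subject_id"]
        frame["sample_id"] = frame["site"] + frame["sample_id"]
        y = rng.normal(0.5, 0.05, len(frame))
        res = lm.phylum_lmm(pd.Series(y), frame, phylum="null")
        if res.model_used == "additive":
            assert res.contrasts.empty or (res.contrasts["estimate"].abs() < 0.05).all()
        else:
            assert (res.contrasts["estimate"].abs() < 0.05).all()


class TestCohortComparisons:
    def test_trend_flat_table_zero(self):
        z, p = lm.cochran_armitage([[10, 10, 10], [10, 10, 10]])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_trend_matches_brute_force(self):
        table = np.array([[10, 20, 30], [30, 20, 10]], dtype=float)
        scores = np.array([0.0, 1.0, 2.0])
        z, p = lm.cochran_armitage(table, scores)
        # direct computation from the definition
        n_col = table.sum(axis=0)
        n = table.sum()
        rbar = table[0].sum() / n
        num = np.sum(scores * (table[0] - n_col * rbar))
        var = rbar * (1 - rbar) * (
            np.sum(n_col * scores**2) - np.sum(n_col * scores) ** 2 / n
        )
        assert z == pytest.approx(num / np.sqrt(var), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_trend_antisymmetric_under_reversal(self):
        table = [[10, 20, 30], [30, 20, 10]]
        z1, _ = lm.cochran_armitage(table)
        z2, _ = lm.cochran_armitage(np.asarray(table)[:, ::-1])
        assert z1 == pytest.approx(-z2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            lm.cochran_armitage([[0, 0, 0], [1, 2, 3]])

    def test_welch_identical_groups(self):
        t, p = lm.mean_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_separated_groups(self, rng):
        x = rng.normal(0, 0.01, 30)
        y = rng.normal(5, 0.01, 30)
        _, p = lm.mean_difference_test(x, y)
        assert p < 1e-6

    def test_welch_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 2, 25)
        t, p = lm.mean_difference_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestBiomarkers:
    def test_sites_without_biomarkers_skipped(self, small_cohort):
        from gravidbiome.diversity import alpha_table

        alpha = alpha_table(small_cohort.table)
        fits, log = lm.biomarker_models(alpha, small_cohort.frame)
        assert any("DRC" in entry for entry in log)
        assert len(fits) > 0
        assert set(fits["converged"]) == {True}

    def test_planted_agp_decline_detected(self, small_cohort):
        from gravidbiome.diversity import alpha_table

        alpha = alpha_table(small_cohort.table)
        fits, _ = lm.biomarker_models(alpha, small_cohort.frame)
        agp_time = fits[(fits["outcome"] == "log_agp") & (fits["term"] == "time")]
        assert agp_time["estimate"].iloc[0] < -0.2
        assert agp_time["p_value"].iloc[0] < 0.01

    def test_all_missing_biomarker_logged(self, small_cohort):
        from gravidbiome.diversity import alpha_table

        frame = small_cohort.frame.copy()
        frame["agp"] = np.nan
        alpha = alpha_table(small_cohort.table)
        fits, log = lm.biomarker_models(alpha, frame, biomarkers=("agp",))
        assert any("agp" in entry for entry in log)
        assert len(fits) == 0
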