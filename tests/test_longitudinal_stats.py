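"""Mixed-model machinery: change tables, REML contrasts, df, adjustment, agreement."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from junctionzone import (
    TrialConfig,
    arm_contrasts,
    bland_altman,
    build_change_table,
    fit_change_lmm,
    fit_ga_progression,
    simulate_change_table,
    simulate_sqrt_areas,
)
from junctionzone.longitudinal_stats import (
    _max_abs_t_samples,
    _phi_beta,
    single_step_adjust,
)


def feature_rows(values):
    """values: {(pid, month): mean_z} -> minimal ring-feature table."""
    return pd.DataFrame([
        dict(participant_id=p, eye_role="study", arm="sham_pooled", visit_month=m,
             layer="ONL", ring=12, ring_distance_deg=5.16, mean_z=v, n_pixels=100)
        for (p, m), v in values.items()
    ])


class TestChangeTable:
    def test_identical_visits_give_zero_change(self):
        tab = build_change_table(feature_rows({("a", 0): 0.7, ("a", 2): 0.7,
                                               ("a", 12): 0.7}))
        assert np.allclose(tab.change_z, 0.0)
        assert set(tab.visit_month) == {2, 12}

    def test_printed_pair(self):
        tab = build_change_table(feature_rows({("a", 0): 0.5, ("a", 12): 0.2}))
        assert tab.change_z.iloc[0] == pytest.approx(-0.3)
        assert tab.baseline_z.iloc[0] == pytest.approx(0.5)

    def test_matches_join_subtract_oracle(self, small_cohort, norm_model):
        from junctionzone import extract_cohort_features
        feats = extract_cohort_features(small_cohort, norm_model)
        tab = build_change_table(feats)
        merged = feats[feats.visit_month > 0].merge(
            feats[feats.visit_month == 0],
            on=["participant_id", "eye_role", "layer", "ring"],
            suffixes=("", "_b"))
        oracle = dict(zip(
            map(tuple, merged[["participant_id", "eye_role", "layer", "ring",
                               "visit_month"]].to_numpy()),
            merged.mean_z - merged.mean_z_b))
        for r in tab.itertuples():
            key = (r.participant_id, r.eye_role, r.layer, r.ring, r.visit_month)
            assert r.change_z == pytest.approx(oracle[key], abs=1e-12)

    def test_missing_baseline_dropped_with_warning(self, caplog):
        rows = feature_rows({("a", 0): 0.5, ("a", 12): 0.2, ("b", 12): 0.1})
        with caplog.at_level("WARNING"):
            tab = build_change_table(rows)
        assert set(tab.participant_id) == {"a"}
        assert "no baseline" in caplog.text


def balanced_table(rng, n_per_arm=10, effects=None, tau=0.4, sigma=0.2):
    """Additive balanced construction with known coefficients."""
    effects = effects or {}
    rows = []
    pid = 0
    for arm in ("sham_pooled", "monthly", "eom"):
        for _ in range(n_per_arm):
            pid += 1
            b = rng.normal(0, tau)
            for m in (2, 6, 12, 18):
                mu = effects.get((arm, m), 0.0)
                rows.append(dict(participant_id=f"P{pid}", arm=arm, visit_month=m,
                                 change_z=mu + b + rng.normal(0, sigma),
                                 baseline_z=0.0))
    return pd.DataFrame(rows)


class TestFitAndContrasts:
    def test_noise_free_construction_recovered_exactly(self):
        rng = np.random.default_rng(0)
        eff = {("monthly", 12): 0.3, ("monthly", 18): 0.4, ("eom", 12): 0.15}
        tab = balanced_table(rng, n_per_arm=4, effects=eff, tau=0.0, sigma=0.0)
        fit = fit_change_lmm(tab, baseline_col=None)
        res = arm_contrasts(fit, 12)
        con = res.contrasts.set_index("contrast")
        assert con.loc["monthly - sham_pooled", "estimate"] == pytest.approx(0.3, abs=1e-8)
        assert con.loc["eom - sham_pooled", "estimate"] == pytest.approx(0.15, abs=1e-8)

    def test_fixed_effects_match_gls_oracle(self, rng):
        tab = balanced_table(rng)
        fit = fit_change_lmm(tab, baseline_col=None)
        # dense GLS oracle at the fitted variance components
        X, y = fit.X, fit.y
        n = len(y)
        V = fit.sigma2 * np.eye(n)
        for g in range(fit.n_groups):
            sel = np.where(fit.group_codes == g)[0]
            V[np.ix_(sel, sel)] += fit.tau2
        Vi = np.linalg.inv(V)
        beta_oracle = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        beta, phi = fit.beta_cov()
        assert np.allclose(beta, beta_oracle, atol=1e-8)
        assert np.allclose(phi, np.linalg.inv(X.T @ Vi @ X), atol=1e-8)

    def test_contrast_linearity_and_location_invariance(self, rng):
        tab = balanced_table(rng, effects={("monthly", 12): 0.25})
        fit = fit_change_lmm(tab, baseline_col=None)
        res = arm_contrasts(fit, 12)
        con = res.contrasts.set_index("contrast")["estimate"]
        assert con["monthly - sham_pooled"] == pytest.approx(
            con["monthly - eom"] + con["eom - sham_pooled"], abs=1e-10)
        shifted = tab.assign(change_z=tab.change_z + 5.0)
        res2 = arm_contrasts(fit_change_lmm(shifted, baseline_col=None), 12)
        assert np.allclose(res2.contrasts.estimate, res.contrasts.estimate, atol=1e-7)

    def test_satterthwaite_df_balanced_between_subject_stratum(self, rng):
        # dominant between-eye variance: arm contrasts live in the
        # between-subject stratum with G - (number of arms) df
        G = 30
        tab = balanced_table(rng, n_per_arm=G // 3, tau=1.0, sigma=0.05)
        fit = fit_change_lmm(tab, baseline_col=None)
        res = arm_contrasts(fit, 12)
        assert np.allclose(res.contrasts.df, G - 3, rtol=0.05)

    def test_two_arm_family_unadjusted(self, rng):
        tab = balanced_table(rng)
        tab = tab[tab.arm != "eom"]
        fit = fit_change_lmm(tab, baseline_col=None)
        res = arm_contrasts(fit, 12)
        assert len(res.contrasts) == 1
        r = res.contrasts.iloc[0]
        p_un = 2 * stats.t.sf(abs(r.t), r.df)
        assert r.p_adjusted == pytest.approx(p_un, abs=1e-9)

    def test_adjustment_bounds(self):
        # single-step p lies between unadjusted and Bonferroni
        corr = np.array([[1, 0.5, 0.5], [0.5, 1, -0.5], [0.5, -0.5, 1.0]])
        tvals = np.array([2.0, -1.0, 2.9])
        p = single_step_adjust(tvals, corr, df=50)
        p_un = 2 * stats.t.sf(np.abs(tvals), 50)
        assert np.all(p >= p_un - 1e-12)
        assert np.all(p <= np.minimum(3 * p_un, 1.0) + 0.002)

    def test_max_abs_t_matches_studentized_range_case(self):
        # equicorrelated 0.5 family (balanced pairwise comparisons of 3
        # means): single-step equals the Tukey studentized-range law
        corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        df = 40
        samples = _max_abs_t_samples(corr, df, n=400_000)
        for t in (2.0, 2.5, 3.0):
            p_mc = np.mean(samples >= t)
            p_tukey = stats.studentized_range.sf(t * np.sqrt(2), 3, df)
            assert p_mc == pytest.approx(p_tukey, abs=0.004)

    def test_requested_visit_must_exist(self, rng):
        fit = fit_change_lmm(balanced_table(rng), baseline_col=None)
        with pytest.raises(ValueError, match="visit"):
            arm_contrasts(fit, 7)


class TestAgainstRKenwardRoger:
    """Independent oracle: lme4 + emmeans with Kenward-Roger df and Tukey."""

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_contrasts_match_emmeans(self, tmp_path):
        cfg = TrialConfig(n_per_arm=12)
        tab = simulate_change_table(cfg, 5.16, np.random.default_rng(5))
        csv = tmp_path / "chg.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages({{library(lme4); library(emmeans)}})
d <- read.csv('{csv}')
d$arm <- factor(d$arm); d$visit <- factor(d$visit_month)
m <- lmer(change_z ~ arm*visit + baseline_z + (1|participant_id), d, REML=TRUE)
em <- emmeans(m, ~ arm | visit, lmer.df="kenward-roger")
s <- summary(pairs(em), infer=TRUE)
s <- subset(s, visit=="12")
cat(jsonlite::toJSON(s[, c("contrast","estimate","SE","df","lower.CL","upper.CL","p.value")], digits=10))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        oracle = {r["contrast"]: r for r in json.loads(out.stdout)}

        fit = fit_change_lmm(tab)
        res = arm_contrasts(fit, 12)
        name_map = {"monthly - sham_pooled": ("monthly - sham_pooled", 1),
                    "eom - sham_pooled": ("eom - sham_pooled", 1),
                    "monthly - eom": ("eom - monthly", -1)}
        for r in res.contrasts.itertuples():
            rname, sign = name_map[r.contrast]
            o = oracle[rname]
            assert sign * r.estimate == pytest.approx(o["estimate"], abs=1e-5)
            assert r.se == pytest.approx(o["SE"], abs=1e-5)
            # Satterthwaite vs Kenward-Roger: near-identical here
            assert r.df == pytest.approx(o["df"], rel=0.02)
            assert r.p_adjusted == pytest.approx(o["p.value"], abs=0.005)
            lo, hi = sorted((sign * r.ci_low, sign * r.ci_high))
            assert lo == pytest.approx(o["lower.CL"], abs=0.005)
            assert hi == pytest.approx(o["upper.CL"], abs=0.005)


class TestGaProgression:
    def test_uniform_growth_gives_null_contrasts(self):
        cfg = TrialConfig(n_per_arm=8, growth_rate_sd=0.0, sqrt_area_noise_sd=0.0,
                          treatment_growth_reduction={"sham_pooled": 0.0,
                                                      "monthly": 0.0, "eom": 0.0})
        areas = simulate_sqrt_areas(cfg, np.random.default_rng(1))
        res = fit_ga_progression(areas)
        assert np.allclose(res.contrasts_month12.estimate, 0.0, atol=1e-8)
        assert res.reduction_pct_month12["monthly"] == pytest.approx(0.0, abs=1e-6)
        assert res.annualized_slope["sham_pooled"] == pytest.approx(0.30, abs=1e-8)

    def test_configured_reduction_recovered(self):
        cfg = TrialConfig(n_per_arm=60)
        reds = []
        for seed in range(5):
            areas = simulate_sqrt_areas(cfg, np.random.default_rng(100 + seed))
            reds.append(fit_ga_progression(areas).reduction_pct_slope["monthly"])
        # Monte-Carlo SE of the 5-replicate mean is ~2.2 points
        assert np.mean(reds) == pytest.approx(25.0, abs=7.0)


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0
        assert r.limits_of_agreement == (0.0, 0.0)
        assert r.p_bias == 1.0

    def test_constant_offset(self, rng):
        x = rng.normal(2.8, 0.5, 30)
        r = bland_altman(x, x - 0.02)
        assert r.bias == pytest.approx(0.02, abs=1e-12)
        lo, hi = r.limits_of_agreement
        assert lo == pytest.approx(hi)  # zero spread
        assert (lo + hi) / 2 == pytest.approx(r.bias)

    def test_ci_matches_bootstrap_oracle(self, rng):
        x = rng.normal(2.8, 0.5, 60)
        y = x - 0.02 + rng.normal(0, 0.05, 60)
        r = bland_altman(x, y)
        d = x - y
        boots = np.array([
            rng.choice(d, size=60, replace=True).mean() for _ in range(10_000)])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert r.bias_ci[0] == pytest.approx(lo, abs=0.006)
        assert r.bias_ci[1] == pytest.approx(hi, abs=0.006)
        width = r.limits_of_agreement[1] - r.limits_of_agreement[0]
        assert width == pytest.approx(2 * 1.96 * d.std(ddof=1), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            bland_altman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            bland_altman([1, 2], [1, 2])
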