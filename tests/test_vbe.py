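import math

import numpy as np
import pandas as pd
import pytest

from ipdsim.vbe import (
    BE_LIMITS_PCT,
    BeResult,
    PopulationError,
    PopulationSpec,
    UnbalancedDesignError,
    VbeCampaignOutcome,
    be_statistics,
    generate_population,
    run_crossover_trial,
    run_vbe_campaign,
)


def synth_trial_metrics(
    rng, n_subjects=42, gmr=1.0, cv_within_pct=35.0, cv_between_pct=35.0
):
    """Log-normal 2x2 crossover metric table with known true GMR."""
    s_w = math.sqrt(math.log(1.0 + (cv_within_pct / 100.0) ** 2))
    s_b = math.sqrt(math.log(1.0 + (cv_between_pct / 100.0) ** 2))
    half = n_subjects // 2
    sequences = ["TR"] * half + ["RT"] * half
    rows = []
    for i, seq in enumerate(sequences, start=1):
        mu = rng.normal(0.0, s_b)
        for period in (1, 2):
            treatment = seq[period - 1]
            logy = 6.0 + mu + 0.05 * (period - 1) + rng.normal(0.0, s_w)
            if treatment == "T":
                logy += math.log(gmr)
            y = math.exp(logy)
            rows.append(
                {"subject": i, "sequence": seq, "period": period,
                 "treatment": treatment, "cmax": y, "auc0t": y, "auc0inf": y}
            )
    return pd.DataFrame(rows)


def brute_force_crossover(df, metric="cmax", ci_level=0.90):
    """Independent normal-equations solution of the 2x2 crossover model."""
    df = df.sort_values(["subject", "period"]).reset_index(drop=True)
    subjects = sorted(df["subject"].unique())
    n_obs = len(df)
    cols = [np.ones(n_obs)]
    cols.append((df["period"] == 2).to_numpy(float))
    cols.append((df["treatment"] == "T").to_numpy(float))
    for s in subjects[1:]:
        cols.append((df["subject"] == s).to_numpy(float))
    X = np.column_stack(cols)
    y = np.log(df[metric].to_numpy(float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    dof = n_obs - rank
    mse = resid @ resid / dof
    cov = mse * np.linalg.pinv(X.T @ X)
    est, se = beta[2], math.sqrt(cov[2, 2])
    from scipy.stats import t as tdist

    half = tdist.ppf(0.5 + ci_level / 2, dof) * se
    return {
        "gmr_pct": 100.0 * math.exp(est),
        "ci_lower_pct": 100.0 * math.exp(est - half),
        "ci_upper_pct": 100.0 * math.exp(est + half),
        "cv_pct": 100.0 * math.sqrt(math.exp(mse) - 1.0),
    }


class TestGeneratePopulation:
    def test_empirical_cv_matches_specification(self):
        spec = PopulationSpec(n_subjects=100000, peff_between_cv_pct=35.0,
                              peff_within_cv_pct=0.0, seed=7)
        pop = generate_population(spec)
        draws = pop["peff_base"].to_numpy()
        assert draws.std() / draws.mean() == pytest.approx(0.35, rel=0.01)

    def test_zero_cv_collapses_to_population_value(self):
        spec = PopulationSpec(n_subjects=10, peff_between_cv_pct=0.0,
                              peff_within_cv_pct=0.0, seed=1)
        pop = generate_population(spec, peff_population=3.56e-5)
        for col in ("peff_base", "peff_period1", "peff_period2"):
            assert np.all(pop[col] == 3.56e-5)

    def test_seed_determinism(self):
        spec = PopulationSpec(n_subjects=12, seed=42)
        pd.testing.assert_frame_equal(generate_population(spec),
                                      generate_population(spec))

    def test_sequences_allocated_one_to_one(self):
        pop = generate_population(PopulationSpec(n_subjects=20, seed=0))
        assert (pop["sequence"] == "TR").sum() == 10

    def test_invalid_specs_rejected(self):
        with pytest.raises(PopulationError):
            PopulationSpec(n_subjects=7)
        with pytest.raises(PopulationError):
            PopulationSpec(peff_between_cv_pct=-5.0)


class TestCrossoverTrial:
    def test_self_vs_self_without_variability_gives_unit_ratios(
        self, model, ref_release
    ):
        spec = PopulationSpec(n_subjects=4, peff_between_cv_pct=0.0,
                              peff_within_cv_pct=0.0, seed=3)
        pop = generate_population(spec, model.params.peff_cm_per_s)
        metrics = run_crossover_trial(pop, ref_release, ref_release, model)
        for metric in ("cmax", "auc0t", "auc0inf"):
            wide = metrics.pivot(index="subject", columns="treatment",
                                 values=metric)
            assert np.allclose(wide["T"] / wide["R"], 1.0, rtol=1e-12)

    def test_metric_table_layout(self, model, ref_release):
        spec = PopulationSpec(n_subjects=4, seed=5)
        pop = generate_population(spec, model.params.peff_cm_per_s)
        metrics = run_crossover_trial(pop, ref_release, ref_release, model)
        assert len(metrics) == 8
        assert set(metrics["treatment"]) == {"T", "R"}
        assert metrics.groupby("subject")["period"].nunique().eq(2).all()


class TestBeStatistics:
    def test_matches_brute_force_on_toy_dataset(self):
        rows = []
        values = {  # 4 subjects, hand-set positive metrics
            (1, "TR"): (120.0, 100.0), (2, "TR"): (95.0, 80.0),
            (3, "RT"): (110.0, 118.0), (4, "RT"): (70.0, 77.0),
        }
        for (subj, seq), (v1, v2) in values.items():
            for period, v in ((1, v1), (2, v2)):
                rows.append(
                    {"subject": subj, "sequence": seq, "period": period,
                     "treatment": seq[period - 1],
                     "cmax": v, "auc0t": v, "auc0inf": v}
                )
        df = pd.DataFrame(rows)
        res = be_statistics(df)
        oracle = brute_force_crossover(df)
        mb = res.metrics["cmax"]
        assert mb.gmr_pct == pytest.approx(oracle["gmr_pct"], abs=1e-8)
        assert mb.ci_lower_pct == pytest.approx(oracle["ci_lower_pct"], abs=1e-8)
        assert mb.ci_upper_pct == pytest.approx(oracle["ci_upper_pct"], abs=1e-8)
        assert mb.within_subject_cv_pct == pytest.approx(oracle["cv_pct"], abs=1e-8)

    def test_matches_brute_force_on_random_dataset(self):
        df = synth_trial_metrics(np.random.default_rng(11), n_subjects=24,
                                 gmr=1.1)
        res = be_statistics(df)
        oracle = brute_force_crossover(df)
        assert res.metrics["cmax"].gmr_pct == pytest.approx(
            oracle["gmr_pct"], abs=1e-8
        )
        assert res.metrics["cmax"].ci_lower_pct == pytest.approx(
            oracle["ci_lower_pct"], abs=1e-8
        )

    def test_null_treatment_gives_100_and_log_symmetric_ci(self):
        # per-subject values with a period effect but no treatment effect
        rows = []
        rng = np.random.default_rng(2)
        for i, seq in enumerate(["TR"] * 4 + ["RT"] * 4, start=1):
            base = float(rng.uniform(80, 120))
            for period in (1, 2):
                v = base * (1.1 if period == 2 else 1.0)
                rows.append({"subject": i, "sequence": seq, "period": period,
                             "treatment": seq[period - 1],
                             "cmax": v, "auc0t": v, "auc0inf": v})
        res = be_statistics(pd.DataFrame(rows))
        mb = res.metrics["cmax"]
        assert mb.gmr_pct == pytest.approx(100.0, abs=1e-8)
        log_lo = math.log(mb.ci_lower_pct / 100.0)
        log_hi = math.log(mb.ci_upper_pct / 100.0)
        assert log_lo == pytest.approx(-log_hi, abs=1e-10)

    def test_zero_residual_degenerates_to_point(self):
        rows = []
        for i, seq in enumerate(["TR", "TR", "RT", "RT"], start=1):
            base = 100.0 + 10.0 * i
            for period in (1, 2):
                tr = seq[period - 1]
                v = base * (1.25 if tr == "T" else 1.0)
                rows.append({"subject": i, "sequence": seq, "period": period,
                             "treatment": tr, "cmax": v, "auc0t": v,
                             "auc0inf": v})
        res = be_statistics(pd.DataFrame(rows))
        mb = res.metrics["cmax"]
        assert mb.within_subject_cv_pct == pytest.approx(0.0, abs=1e-6)
        assert mb.ci_lower_pct == pytest.approx(mb.gmr_pct, abs=1e-6)
        assert mb.ci_upper_pct == pytest.approx(mb.gmr_pct, abs=1e-6)
        assert mb.gmr_pct == pytest.approx(125.0, rel=1e-10)

    def test_subject_relabeling_invariance(self):
        df = synth_trial_metrics(np.random.default_rng(5), n_subjects=12)
        relabeled = df.copy()
        mapping = {s: 100 - s for s in df["subject"].unique()}
        relabeled["subject"] = relabeled["subject"].map(mapping)
        a = be_statistics(df).metrics["cmax"]
        b = be_statistics(relabeled).metrics["cmax"]
        assert a.gmr_pct == pytest.approx(b.gmr_pct, abs=1e-10)
        assert a.ci_lower_pct == pytest.approx(b.ci_lower_pct, abs=1e-10)

    def test_incomplete_layout_rejected(self):
        df = synth_trial_metrics(np.random.default_rng(1), n_subjects=6)
        with pytest.raises(UnbalancedDesignError):
            be_statistics(df.iloc[:-1])

    def test_deterministic_scaling_gives_exact_gmr(self):
        """A test product whose metrics are exactly 1.3x the reference has a
        point GMR of 130%."""
        df = synth_trial_metrics(np.random.default_rng(9), n_subjects=12,
                                 gmr=1.0, cv_within_pct=0.0)
        df.loc[df["treatment"] == "T", ["cmax", "auc0t", "auc0inf"]] *= 1.3
        res = be_statistics(df)
        assert res.metrics["cmax"].gmr_pct == pytest.approx(130.0, rel=1e-9)


class TestCampaignStatistics:
    def _pass_probability(self, gmr, n_trials=40, seed=0):
        rng = np.random.default_rng(seed)
        passes = 0
        for _ in range(n_trials):
            df = synth_trial_metrics(rng, n_subjects=42, gmr=gmr)
            res = be_statistics(df, metrics=("cmax",), pass_metrics=("cmax",))
            passes += res.passed
        return passes / n_trials

    def test_pass_probability_decreases_away_from_unity(self):
        p_100 = self._pass_probability(1.00)
        p_115 = self._pass_probability(1.15)
        p_130 = self._pass_probability(1.30)
        assert p_100 > p_115 > p_130

    def test_treatment_effect_unbiased_under_null(self):
        rng = np.random.default_rng(17)
        ests = []
        for _ in range(100):
            df = synth_trial_metrics(rng, n_subjects=12, gmr=1.0)
            ests.append(math.log(
                be_statistics(df, metrics=("cmax",),
                              pass_metrics=("cmax",)).metrics["cmax"].gmr_pct
                / 100.0
            ))
        ests = np.asarray(ests)
        assert abs(ests.mean()) < 3.0 * ests.std() / math.sqrt(len(ests))

    def test_ci_widens_with_within_subject_cv(self):
        def mean_log_width(cv):
            rng = np.random.default_rng(23)
            widths = []
            for _ in range(20):
                df = synth_trial_metrics(rng, n_subjects=24,
                                         cv_within_pct=cv)
                mb = be_statistics(df, metrics=("cmax",),
                                   pass_metrics=("cmax",)).metrics["cmax"]
                widths.append(math.log(mb.ci_upper_pct / mb.ci_lower_pct))
            return np.mean(widths)

        assert mean_log_width(15.0) < mean_log_width(30.0) < mean_log_width(60.0)


class TestCampaign:
    def test_threshold_decision_rule(self):
        dummy = BeResult(metrics={}, passed=True, pass_metrics=("cmax",),
                         n_subjects=42)
        out = VbeCampaignOutcome(n_trials=10, pass_count=7, threshold_pct=80.0,
                                 trial_results=(dummy,) * 10, seed=0)
        assert out.decision == "fail" and out.pass_rate_pct == 70.0
        out10 = VbeCampaignOutcome(n_trials=10, pass_count=10,
                                   threshold_pct=80.0,
                                   trial_results=(dummy,) * 10, seed=0)
        assert out10.decision == "pass"

    def test_campaign_replay_is_deterministic(self, model, ref_release):
        spec = PopulationSpec(n_subjects=6)
        kwargs = dict(population_spec=spec, n_trials=2, seed=123)
        a = run_vbe_campaign(model, ref_release, ref_release, **kwargs)
        b = run_vbe_campaign(model, ref_release, ref_release, **kwargs)
        assert a.pass_count == b.pass_count
        for ra, rb in zip(a.trial_results, b.trial_results):
            for metric in ra.metrics:
                assert ra.metrics[metric].gmr_pct == rb.metrics[metric].gmr_pct

    def test_campaign_requires_at_least_one_trial(self, model, ref_release):
        with pytest.raises(PopulationError):
            run_vbe_campaign(model, ref_release, ref_release, n_trials=0)
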