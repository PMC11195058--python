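"""Cox/linear associations, BH correction, Gini, model comparison, KM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from organclock import (
    HazardSpec,
    SimulationConfig,
    adjust_bh,
    compare_mortality_models,
    cox_association,
    generate_cohort,
    generate_events,
    gini_of_log_hazards,
    km_curve,
    linear_association,
)
from organclock.associations import attach_q, event_percentage


def _cohort_with_beta(beta, n=5000, seed=41, organs=("brain", "heart"),
                      lam=0.012):
    cfg = SimulationConfig(n_subjects=n, organs=organs, seed=seed)
    b = generate_cohort(cfg)
    spec = HazardSpec({"heart": beta} if beta else {}, baseline_hazard=lam)
    ev = generate_events(b, "test", spec)
    surv = ev.set_index("subject_id")[["time", "event"]]
    covariates = pd.DataFrame(
        {
            "age": b.subjects.set_index("subject_id")["age_visit0"],
            "sex": b.subjects.set_index("subject_id")["sex"],
        }
    )
    exposure = b.gap_wide(0)["heart"]
    exposure.index = b.subjects["subject_id"]
    return exposure, surv, covariates, ev


class TestCox:
    def test_planted_per_sd_hr_recovered(self):
        beta = float(np.log(1.8))
        exposure, surv, covariates, ev = _cohort_with_beta(beta)
        assert 0.1 < ev["event"].mean() < 0.35  # ~20% events
        res = cox_association(exposure.rename("heart"), surv, covariates)
        assert 1.65 <= res.hazard_ratio <= 1.96

    def test_six_subject_grid_search_oracle(self):
        # no ties, single covariate: maximize the exact partial likelihood
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             "event": [1, 0, 1, 1, 0, 1]},
            index=list("abcdef"),
        )
        x = pd.Series([0.5, -1.0, 1.5, 0.0, 2.0, -0.5], index=surv.index, name="x")

        def neg_log_pl(beta):
            ll = 0.0
            order = surv.sort_values("time")
            for i, row in order.iterrows():
                if row["event"] == 1:
                    risk = order.index[order["time"] >= row["time"]]
                    ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        oracle = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        res = cox_association(x, surv)
        assert res.estimate == pytest.approx(oracle, abs=1e-3)

    def test_null_exposure_ci_coverage(self):
        covered = 0
        n_rep = 200
        rng = np.random.default_rng(43)
        for _ in range(n_rep):
            n = 400
            x = rng.standard_normal(n)
            t = rng.exponential(10.0, n)
            cens = np.minimum(t, 8.0)
            surv = pd.DataFrame(
                {"time": cens, "event": (t <= 8.0).astype(int)},
                index=range(n),
            )
            res = cox_association(pd.Series(x, index=surv.index, name="x"), surv)
            if res.ci_low <= 0.0 <= res.ci_high:
                covered += 1
        assert covered / n_rep >= 0.93

    def test_zero_events_flagged(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]}, index=["a", "b"])
        res = cox_association(pd.Series([1.0, 2.0], index=surv.index, name="x"), surv)
        assert res.flagged and np.isnan(res.estimate)

    def test_categorical_exposure_contrasts_reference(self):
        rng = np.random.default_rng(5)
        n = 600
        group = pd.Series(
            rng.choice(["normal", "aged"], size=n, p=[0.7, 0.3]),
            index=range(n), name="ageotype",
        )
        lp = np.where(group == "aged", 1.0, 0.0)
        t = rng.exponential(1.0 / (0.05 * np.exp(lp)))
        surv = pd.DataFrame(
            {"time": np.minimum(t, 17.0), "event": (t <= 17.0).astype(int)},
            index=group.index,
        )
        results = cox_association(group, surv)
        assert len(results) == 1
        assert results[0].exposure == "ageotype[aged]"
        assert 0.6 <= results[0].estimate <= 1.4


class TestLinear:
    def test_null_ci_covers_zero(self, rng):
        y = pd.Series(rng.normal(size=2000))
        x = pd.Series(rng.normal(size=2000), name="x")
        res = linear_association(y, x)[0]
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_planted_effect_recovered(self, rng):
        n = 10_000
        x = pd.Series(rng.normal(size=n), name="exposure")
        age = pd.Series(rng.uniform(40, 70, n), name="age")
        y = 0.3 * x + 0.01 * age + rng.normal(0, 1, n)
        res = linear_association(y, x, covariates=age.to_frame())[0]
        assert res.estimate == pytest.approx(0.3, abs=0.03)

    def test_two_predictor_normal_equations_oracle(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        y = np.array([3.0, 5.0, 9.0, 8.0, 15.0])
        X = np.column_stack([np.ones(5), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = linear_association(
            pd.Series(y), pd.DataFrame({"x1": x1, "x2": x2})
        )
        assert res[0].estimate == pytest.approx(beta[1], abs=1e-9)
        assert res[1].estimate == pytest.approx(beta[2], abs=1e-9)

    def test_collinear_design_rejected(self, rng):
        x = pd.Series(rng.normal(size=50), name="x")
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            linear_association(pd.Series(rng.normal(size=50)), X)


class TestBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        ps=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20)
    )
    def test_monotone_in_p_and_never_below_p(self, ps):
        q = adjust_bh(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (np.asarray(q) >= np.asarray(ps) - 1e-12).all()

    def test_manual_step_up_oracle(self, rng):
        p = rng.uniform(size=9)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, 0, 1)
        np.testing.assert_allclose(adjust_bh(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestGini:
    def test_equal_vector_zero(self):
        assert gini_of_log_hazards([0.5, 0.5, 0.5, 0.5]).gini == 0.0

    def test_pairwise_difference_oracle(self):
        # (0,0,0,1): sum |xi-xj| = 6, 2 n^2 mean = 2*16*0.25 = 8 -> 0.75
        assert gini_of_log_hazards([0, 0, 0, 1]).gini == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=30)
    @given(
        xs=st.lists(st.floats(min_value=0.01, max_value=10), min_size=2, max_size=8),
        c=st.floats(min_value=0.1, max_value=10),
    )
    def test_scale_invariant_and_bounded(self, xs, c):
        g1 = gini_of_log_hazards(xs).gini
        g2 = gini_of_log_hazards([c * x for x in xs]).gini
        assert g1 == pytest.approx(g2, abs=1e-9)
        assert 0 <= g1 < 1

    def test_concentration_increases_gini(self):
        spread = gini_of_log_hazards([1, 1, 1, 1]).gini
        one_hot = gini_of_log_hazards([0, 0, 0, 4]).gini
        assert one_hot > spread

    def test_negative_values_clipped(self):
        res = gini_of_log_hazards([-0.5, 0.0, 1.0])
        assert (res.values >= 0).all()

    def test_all_zero_flagged(self):
        res = gini_of_log_hazards([-1.0, -2.0])
        assert res.flagged and np.isnan(res.gini)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            gini_of_log_hazards([1.0])


class TestModelComparison:
    @pytest.fixture(scope="class")
    @staticmethod
    def survival_data():
        cfg = SimulationConfig(n_subjects=5000, organs=("brain", "heart"), seed=47)
        b = generate_cohort(cfg)
        spec = HazardSpec(
            {"brain": 0.5, "heart": 0.4}, baseline_hazard=0.01
        )
        ev = generate_events(b, "mortality", spec)
        gaps = b.gap_wide(0)
        gaps.index = b.subjects["subject_id"]
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "time": ev.set_index("subject_id")["time"],
                "event": ev.set_index("subject_id")["event"],
                "age": b.subjects.set_index("subject_id")["age_visit0"],
                "sex": b.subjects.set_index("subject_id")["sex"],
                "brain_gap": gaps["brain"],
                "heart_gap": gaps["heart"],
                "noise1": rng.standard_normal(len(gaps)),
                "noise2": rng.standard_normal(len(gaps)),
            }
        )
        ids = list(data.index)
        return b, spec, data, ids[:3000], ids[3000:]

    def test_true_linear_predictor_matches_oracle_concordance(self, survival_data):
        from lifelines.utils import concordance_index

        b, spec, data, train, test = survival_data
        lp = (0.5 * data["brain_gap"] + 0.4 * data["heart_gap"]
              + spec.age_log_hr * (data["age"] - 55.0) + spec.sex_log_hr * data["sex"])
        oracle = concordance_index(data.loc[test, "time"], -lp.loc[test],
                                   data.loc[test, "event"])
        out = compare_mortality_models(
            {"gaps": ["brain_gap", "heart_gap"]}, data, train, test
        )
        assert out["concordance"]["gaps"]["test"] == pytest.approx(oracle, abs=0.02)

    def test_noise_features_near_chance_without_covariates(self, survival_data):
        b, spec, data, train, test = survival_data
        shuffled = data.copy()
        rng = np.random.default_rng(1)
        # break the age/sex link too: pure-noise model should sit at chance
        out = compare_mortality_models(
            {"noise": ["noise1", "noise2"]}, shuffled, train, test, covariates=()
        )
        assert 0.47 <= out["concordance"]["noise"]["test"] <= 0.53

    def test_gap_features_add_concordance_over_age_sex(self, survival_data):
        b, spec, data, train, test = survival_data
        out = compare_mortality_models(
            {"base": [], "with_gaps": ["brain_gap", "heart_gap"]},
            data, train, test,
        )
        assert (
            out["concordance"]["with_gaps"]["test"]
            > out["concordance"]["base"]["test"] + 0.01
        )

    def test_absent_column_rejected(self, survival_data):
        b, spec, data, train, test = survival_data
        with pytest.raises(ValueError, match="ghost"):
            compare_mortality_models({"bad": ["ghost"]}, data, train, test)


class TestKaplanMeier:
    def test_no_events_flat_survival(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]}, index=list("abc")
        )
        groups = pd.Series(["g"] * 3, index=surv.index)
        km = km_curve(surv, groups)
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # events at t=2 (5 at risk) and t=4 (3 at risk): S=0.8, then 0.8*2/3
        surv = pd.DataFrame(
            {"time": [2.0, 4.0, 3.0, 5.0, 6.0], "event": [1, 1, 0, 0, 0]},
            index=list("abcde"),
        )
        km = km_curve(surv, pd.Series(["g"] * 5, index=surv.index))
        s = km.set_index("time")["survival"]
        assert s.loc[2.0] == pytest.approx(0.8)
        assert s.loc[4.0] == pytest.approx(0.8 * 2 / 3)
        assert km["cumulative_incidence"].iloc[-1] == pytest.approx(1 - 0.8 * 2 / 3)

    def test_late_censoring_time_shift_leaves_event_steps_unchanged(self):
        # subject d is censored after the last event; pushing that censoring
        # time further out cannot change S at any event time
        base = pd.DataFrame(
            {"time": [2.0, 4.0, 3.0, 5.0], "event": [1, 1, 0, 0]},
            index=list("abcd"),
        )
        later = base.copy()
        later.loc["d", "time"] = 50.0
        groups = pd.Series(["g"] * 4, index=base.index)
        sa = km_curve(base, groups).set_index("time")["survival"]
        sb = km_curve(later, groups).set_index("time")["survival"]
        for t in (2.0, 4.0):
            assert sa.loc[t] == pytest.approx(sb.loc[t])


class TestFamilyCorrection:
    def test_attach_q_within_family(self):
        from organclock.associations import AssociationResult

        results = [
            AssociationResult(f"x{i}", "linear", 0.1, 0.01, 0.08, 0.12, p, 100)
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        attach_q(results)
        assert all(r.q == pytest.approx(0.04) for r in results)

    def test_event_percentage_arithmetic(self):
        assert event_percentage(121, 2618) == pytest.approx(4.62, abs=0.005)
        with pytest.raises(ValueError):
            event_percentage(5, 0)


def test_grid_null_type_one_error_rate():
    """Under a global null, ~5% of nominal p-values fall below 0.05."""
    rng = np.random.default_rng(49)
    hits = 0
    n_tests = 400
    for _ in range(n_tests):
        n = 250
        x = pd.Series(rng.standard_normal(n), name="x")
        age = rng.uniform(40, 70, n)
        t = rng.exponential(8.0, n)
        surv = pd.DataFrame(
            {"time": np.minimum(t, 10.0), "event": (t <= 10.0).astype(int)},
            index=x.index,
        )
        covariates = pd.DataFrame(
            {"age": age, "sex": rng.integers(0, 2, n)}, index=x.index
        )
        res = cox_association(x, surv, covariates)
        if res.p < 0.05:
            hits += 1
    assert 0.03 <= hits / n_tests <= 0.07
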