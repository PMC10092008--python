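"""Kaplan–Meier, log-rank and Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest

from camoquant import cox_fit, km_fit, logrank_pairwise
from camoquant.errors import ConvergenceError, DomainError, UsageError
from camoquant.synthetic import (
    PredationSimConfig,
    gen_predation_dataset,
    hazard_for_event_fraction,
)

from conftest import make_event_table


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        df = make_event_table({"a": 0}, n=10)
        km = km_fit(df)
        s, se = km.survival_at("a", 72.0)
        assert s == 1.0 and se == 0.0

    def test_field_counts(self):
        # 100 per treatment, 52/45/35 events, censoring only at 72 h
        df = make_event_table({"bark": 52, "off_lichen": 45, "lichen": 35})
        km = km_fit(df)
        assert km.survival_at("bark", 72.0)[0] == pytest.approx(0.48)
        assert km.survival_at("off_lichen", 72.0)[0] == pytest.approx(0.55)
        assert km.survival_at("lichen", 72.0)[0] == pytest.approx(0.65)
        assert km.survival_at("bark", 72.0)[1] == pytest.approx(0.05, abs=5e-4)

    def test_invariant_to_event_split_across_checks(self):
        # with censoring only at study end, S(end) ignores how the events
        # distribute over the check times
        df1 = make_event_table({"a": 52}, check_split={"a": [(24.0, 52)]})
        df2 = make_event_table({"a": 52}, check_split={"a": [(24.0, 5), (48.0, 40), (72.0, 7)]})
        s1 = km_fit(df1).survival_at("a", 72.0)
        s2 = km_fit(df2).survival_at("a", 72.0)
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)
        assert s1[1] == pytest.approx(s2[1], abs=1e-12)

    def test_hand_product_limit(self):
        # n=4: events at t=1 and t=2, two censored later
        df = pd.DataFrame(
            {"treatment": "x", "time_h": [1.0, 2.0, 3.0, 3.0], "status": [1, 1, 0, 0]}
        )
        km = km_fit(df)
        s, se = km.survival_at("x", 2.5)
        assert s == pytest.approx(0.5)  # (3/4)(2/3)
        assert se == pytest.approx(0.25)  # Greenwood by hand

    def test_no_interim_censoring_closed_form(self):
        # S(end) = 1 − d/n and Greenwood SE = sqrt(p(1−p)/n) exactly
        for d, n in [(52, 100), (35, 100), (7, 40)]:
            df = make_event_table({"a": d}, n=n)
            s, se = km_fit(df).survival_at("a", 72.0)
            p = 1 - d / n
            assert s == pytest.approx(p, abs=1e-12)
            assert se == pytest.approx(np.sqrt(p * (1 - p) / n), abs=1e-12)

    def test_monotone_and_starts_at_one(self):
        df = make_event_table({"a": 52})
        tab = km_fit(df).tables["a"]
        assert (np.diff(tab["survival"]) <= 1e-12).all()
        assert (tab["survival"] <= 1.0).all() and (tab["se"] >= 0).all()

    def test_bad_inputs(self):
        with pytest.raises(UsageError):
            km_fit(pd.DataFrame(columns=["treatment", "time_h", "status"]))
        with pytest.raises(DomainError):
            km_fit(pd.DataFrame({"treatment": ["a"], "time_h": [-1.0], "status": [1]}))


class TestLogrank:
    def test_identical_groups(self):
        df = make_event_table({"a": 30, "b": 30}, n=60)
        res = logrank_pairwise(df)
        assert res.loc[0, "chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc[0, "p"] == pytest.approx(1.0, abs=1e-9)

    def test_extreme_separation(self):
        rows = [("a", 24.0, 1)] * 50 + [("b", 72.0, 0)] * 50
        df = pd.DataFrame(rows, columns=["treatment", "time_h", "status"])
        res = logrank_pairwise(df)
        assert res.loc[0, "p"] < 1e-3

    def test_hand_computed_statistic(self):
        # A: events at 1,2 and censor at 3; B: censor 1, event 2, censor 3
        # observed-minus-expected by hand: O_A=2, E_A=1.5, V=0.25+1/3
        df = pd.DataFrame(
            {
                "treatment": ["a"] * 3 + ["b"] * 3,
                "time_h": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "status": [1, 1, 0, 0, 1, 0],
            }
        )
        res = logrank_pairwise(df)
        assert res.loc[0, "chi2"] == pytest.approx(0.4285714285714286, rel=1e-6)

    def test_adjustment_and_two_group_requirement(self):
        df = make_event_table({"a": 20, "b": 30, "c": 40})
        res = logrank_pairwise(df)
        assert len(res) == 3
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        with pytest.raises(UsageError):
            logrank_pairwise(make_event_table({"a": 20}))


class TestCox:
    def test_single_level_rejected(self):
        with pytest.raises(UsageError):
            cox_fit(make_event_table({"a": 30}))

    def test_no_events_rejected(self):
        df = make_event_table({"a": 0, "b": 0}, n=10)
        with pytest.raises(UsageError):
            cox_fit(df)

    def test_parameter_recovery_two_group_exponential(self):
        lam = hazard_for_event_fraction(0.52)
        df = gen_predation_dataset(
            PredationSimConfig(
                hazards={"bark": lam, "lichen": lam * np.exp(-0.55)},
                n_per_treatment=2000,
                seed=42,
            )
        )
        fit = cox_fit(df)
        assert fit.reference_level == "bark"
        assert fit.coef["treatment[lichen]"] == pytest.approx(-0.55, abs=0.1)
        assert fit.hazard_ratio["treatment[lichen]"] == pytest.approx(
            np.exp(fit.coef["treatment[lichen]"]), rel=1e-12
        )

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = gen_predation_dataset(
            PredationSimConfig(
                hazards={"bark": 0.010, "lichen": 0.006}, n_per_treatment=150, seed=5
            )
        )
        fit = cox_fit(df, ties="efron")
        d = pd.get_dummies(
            df[["time_h", "status", "treatment"]], columns=["treatment"],
            drop_first=True, dtype=float,
        )
        cph = CoxPHFitter().fit(d, "time_h", "status")
        assert fit.coef["treatment[lichen]"] == pytest.approx(
            cph.params_["treatment_lichen"], abs=1e-5
        )
        assert fit.se["treatment[lichen]"] == pytest.approx(
            cph.standard_errors_["treatment_lichen"], abs=1e-5
        )

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 80
        df = pd.DataFrame(
            {
                "treatment": ["a"] * (n // 2) + ["b"] * (n // 2),
                "time_h": rng.exponential(50, n).round(6),
                "status": rng.integers(0, 2, n),
            }
        )
        fe = cox_fit(df, ties="efron")
        fb = cox_fit(df, ties="breslow")
        assert fe.coef.values == pytest.approx(fb.coef.values, abs=1e-9)

    def test_invariances(self):
        df = gen_predation_dataset(
            PredationSimConfig(
                hazards={"bark": 0.010, "lichen": 0.006}, n_per_treatment=100, seed=9
            )
        )
        base = cox_fit(df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["replicate_id"] = [f"z{i}" for i in range(len(shuffled))]
        assert cox_fit(shuffled).coef.values == pytest.approx(base.coef.values, abs=1e-9)
        rescaled = df.assign(time_h=df["time_h"] * 3.5)
        assert cox_fit(rescaled).coef.values == pytest.approx(base.coef.values, abs=1e-9)

    def test_wald_statistic_and_reference(self):
        df = make_event_table({"bark": 52, "off_lichen": 45, "lichen": 35})
        fit = cox_fit(df, reference="bark")
        assert fit.reference_level == "bark"
        assert set(fit.coef.index) == {"treatment[lichen]", "treatment[off_lichen]"}
        assert fit.wald_df == 2
        # both non-bark treatments reduce the hazard
        assert (fit.coef < 0).all()
        assert fit.converged and fit.wald_stat > 0
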