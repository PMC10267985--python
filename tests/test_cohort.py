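"""Kaplan–Meier, log-rank and 2×2 statistics on the printed-table fixtures."""

import numpy as np
import pandas as pd
import pytest

from netscreen import (
    Contingency2x2,
    SimConfig,
    chi2_2x2,
    gen_survival,
    incidence,
    km_curve,
    load_stage_d_fixture,
    load_trae_fixture,
    logrank,
)

from .oracles import km_product_limit, logrank_oe


class TestKaplanMeier:
    def test_stage_d_medians_match_hand_product_limit(self):
        df = load_stage_d_fixture()
        exp = km_curve(df, "exposure")
        non = km_curve(df, "nonexposure")
        assert exp.median == 106.0
        assert non.median == 64.0
        # against the independent product-limit curve
        for arm, km in (("exposure", exp), ("nonexposure", non)):
            sub = df[df["arm"] == arm]
            hand = km_product_limit(list(sub["time_days"]), list(sub["event"]))
            for t, s in hand:
                assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_single_subject_event_drops_to_zero(self):
        df = pd.DataFrame({"id": ["x"], "time_days": [42.0], "event": [1], "arm": ["exposure"]})
        km = km_curve(df, "exposure")
        assert km.survival_at(42.0) == 0.0
        assert km.median == 42.0

    def test_curve_starts_at_one_and_never_increases(self):
        df = gen_survival(SimConfig(seed=5, surv_n_per_arm=30))
        km = km_curve(df, "exposure")
        assert km.survival_at(0) == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_no_censoring_median_is_smallest_t_with_s_below_half(self):
        df = pd.DataFrame(
            {
                "id": list("abcd"),
                "time_days": [10.0, 20.0, 30.0, 40.0],
                "event": [1, 1, 1, 1],
                "arm": ["exposure"] * 4,
            }
        )
        km = km_curve(df, "exposure")
        assert km.median == 20.0  # S(20)=0.5 and 20 is the smallest such time

    def test_empty_arm_rejected(self):
        df = load_stage_d_fixture()
        with pytest.raises(ValueError):
            km_curve(df, "placebo")


class TestLogrank:
    def test_identical_arms_statistic_zero(self):
        half = pd.DataFrame(
            {"id": list("abc"), "time_days": [5.0, 9.0, 14.0], "event": [1, 1, 1]}
        )
        df = pd.concat(
            [half.assign(arm="exposure"), half.assign(arm="nonexposure")],
            ignore_index=True,
        )
        stat, p = logrank(df)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_stage_d_fixture_matches_oe_oracle(self):
        df = load_stage_d_fixture()
        stat, _ = logrank(df)
        assert stat == pytest.approx(logrank_oe(df), abs=1e-10)

    def test_label_swap_invariance(self):
        df = load_stage_d_fixture()
        swapped = df.assign(
            arm=df["arm"].map({"exposure": "nonexposure", "nonexposure": "exposure"})
        )
        assert logrank(df)[0] == pytest.approx(logrank(swapped)[0], abs=1e-12)

    def test_matches_oracle_on_simulated_cohorts(self):
        for seed in range(5):
            df = gen_survival(SimConfig(seed=seed, surv_n_per_arm=30))
            stat, _ = logrank(df)
            assert stat == pytest.approx(logrank_oe(df), abs=1e-10)

    def test_single_arm_rejected(self):
        df = load_stage_d_fixture()
        with pytest.raises(ValueError):
            logrank(df[df["arm"] == "exposure"])


class TestChi2:
    def test_leukopenia_counts_yates_statistic(self):
        stat, p = chi2_2x2(Contingency2x2(10, 40, 19, 28))
        assert stat == pytest.approx(3.90, abs=0.01)
        assert 0.04 < p < 0.06

    def test_proportional_table_statistic_zero(self):
        stat, p = chi2_2x2(Contingency2x2(10, 10, 20, 20))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_uncorrected_at_least_corrected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            tbl = Contingency2x2(int(a), int(b), int(c), int(d))
            assert chi2_2x2(tbl, correction=False)[0] >= chi2_2x2(tbl, correction=True)[0] - 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(Contingency2x2(0, 5, 0, 7))


class TestIncidence:
    def test_leukopenia_and_nausea_printed_percentages(self):
        assert incidence(Contingency2x2(10, 40, 19, 28), "exposure") == 20
        assert incidence(Contingency2x2(20, 30, 29, 18), "nonexposure") == 62

    def test_zero_events(self):
        assert incidence(Contingency2x2(0, 10, 1, 9), "exposure") == 0

    def test_full_trae_table_reproduced(self):
        trae = load_trae_fixture()
        for _, row in trae.iterrows():
            tbl = Contingency2x2(
                int(row["exposure_events"]),
                int(row["exposure_n"] - row["exposure_events"]),
                int(row["nonexposure_events"]),
                int(row["nonexposure_n"] - row["nonexposure_events"]),
            )
            assert incidence(tbl, "exposure") == row["exposure_pct"], row["trae"]
            assert incidence(tbl, "nonexposure") == row["nonexposure_pct"], row["trae"]


class TestCalibration:
    def test_null_hazard_ratio_type_one_error(self):
        """Log-rank rejects at ~alpha when both arms share the hazard."""
        n_reps = 1000
        rej = 0
        for rep in range(n_reps):
            df = gen_survival(SimConfig(seed=rep, surv_hazard_ratio=1.0, surv_n_per_arm=50))
            rej += logrank(df)[1] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rej / n_reps - 0.05) <= 2 * se

    def test_protective_hazard_ratio_detected(self):
        rej = 0
        for rep in range(40):
            df = gen_survival(SimConfig(seed=rep, surv_hazard_ratio=0.5, surv_n_per_arm=200))
            rej += logrank(df)[1] < 0.05
        assert rej / 40 >= 0.8
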