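"""Synthetic-data generator: sampling distributions, dynamics, rendering, missingness."""

import numpy as np
import pandas as pd
import pytest

from burstvar import (
    BurstDesign,
    MarConfig,
    ParameterSet,
    PopulationConfig,
    apply_missingness,
    make_burst_calendar,
    render_observables,
    simulate_dataset,
    simulate_latent_series,
    simulate_population,
)
from burstvar.preprocess import build_daily_table
from burstvar.simulate import default_true_parameters


def _flat_params(**overrides):
    """Covariate-free parameter set (intercept-only means)."""
    base = dict(
        delta_L={"intercept": 0.0}, delta_P={"intercept": 0.0},
        beta=np.zeros((2, 2)), sigma_L=1.0, sigma_P=1.0,
        tau_L=1.0, tau_P=1.0, alpha0=0.0, alpha1=0.0,
    )
    base.update(overrides)
    return ParameterSet(**base)


class TestPopulation:
    def test_single_record_has_all_fields(self):
        out = simulate_population(1, seed=0)
        assert len(out) == 1
        assert out.iloc[0].notna().all()

    def test_runner_share_matches_study_composition(self):
        out = simulate_population(1314, seed=1)
        share = out["runner"].mean()
        se = np.sqrt(0.568 * (1 - 0.568) / 1314)
        assert abs(share - 0.568) < 3 * se

    def test_gender_share_converges(self):
        out = simulate_population(10000, seed=2)
        share = (out["gender"] == "female").mean()
        se = np.sqrt(0.463 * 0.537 / 10000)
        assert abs(share - 0.463) < 3 * se

    def test_age_and_exid_within_bounds(self):
        out = simulate_population(2000, seed=3)
        assert out["age"].between(18, 65).all()
        assert out["exid"].between(9, 63).all()
        assert np.isfinite(out["exid"]).all()

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(10, config=PopulationConfig(ses_probs=(0.5, 0.2, 0.2)))
        with pytest.raises(ValueError):
            simulate_population(10, config=PopulationConfig(p_female=1.4))

    def test_determinism(self):
        a = simulate_population(50, seed=9)
        b = simulate_population(50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCalendar:
    def test_burst_structure(self):
        part = simulate_population(5, seed=0)
        cal = make_burst_calendar(part, seed=0)
        for pid, grp in cal.groupby("person_id"):
            assert sorted(grp["burst_index"].unique()) == [1, 2, 3, 4]
            ends = {}
            for b, days in grp.groupby("burst_index"):
                dates = pd.to_datetime(days["date"]).sort_values()
                assert len(dates) == 14
                assert (dates.diff().dropna() == pd.Timedelta(days=1)).all()
                ends[b] = (dates.iloc[0], dates.iloc[-1])
            for b in (1, 2, 3):
                assert ends[b + 1][0] > ends[b][1], "bursts must not overlap"

    def test_overlapping_design_rejected(self):
        with pytest.raises(ValueError):
            BurstDesign(burst_length=40, burst_offsets_months=(0, 1)).validate()


class TestLatentDynamics:
    def test_white_noise_reduction(self):
        # beta = 0, no covariates, m = 0: L is iid N(delta0, sigma_L^2)
        part = simulate_population(1, seed=0)
        design = BurstDesign(n_bursts=1, burst_length=3000, burst_offsets_months=(0,))
        cal = make_burst_calendar(part, design=design, seed=0)
        params = _flat_params(delta_L={"intercept": 0.7}, sigma_L=1.3)
        params = params.with_random_effects(np.zeros((1, 2)))
        latent, _ = simulate_latent_series(part, cal, params, seed=5)
        L = latent["L"].to_numpy()
        assert abs(L.mean() - 0.7) < 4 * 1.3 / np.sqrt(len(L))
        assert abs(L.var() - 1.3 ** 2) < 0.15
        r1 = np.corrcoef(L[1:], L[:-1])[0, 1]
        assert abs(r1) < 0.06

    def test_ar1_autocorrelation_matches_theory(self):
        part = simulate_population(1, seed=1)
        design = BurstDesign(n_bursts=1, burst_length=2000, burst_offsets_months=(0,))
        cal = make_burst_calendar(part, design=design, seed=0)
        params = _flat_params(beta=np.array([[0.4, 0.0], [0.0, 0.0]]))
        params = params.with_random_effects(np.zeros((1, 2)))
        latent, _ = simulate_latent_series(part, cal, params, seed=11)
        L = latent["L"].to_numpy()
        r1 = np.corrcoef(L[1:], L[:-1])[0, 1]
        assert abs(r1 - 0.4) < 0.03

    def test_zero_link_gives_uncorrelated_disturbances(self):
        part = simulate_population(4, seed=2)
        design = BurstDesign(n_bursts=1, burst_length=1500, burst_offsets_months=(0,))
        cal = make_burst_calendar(part, design=design, seed=0)
        params = _flat_params().with_random_effects(np.zeros((4, 2)))
        latent, _ = simulate_latent_series(part, cal, params, seed=3)
        r = np.corrcoef(latent["L"], latent["P"])[0, 1]
        assert abs(r) < 0.04

    def test_moderated_correlation_increases_with_exid(self):
        part = simulate_population(400, seed=4)
        design = BurstDesign(n_bursts=1, burst_length=60, burst_offsets_months=(0,))
        cal = make_burst_calendar(part, design=design, seed=0)
        params = _flat_params(alpha0=0.3, alpha1=0.3)
        params = params.with_random_effects(np.zeros((400, 2)))
        latent, _ = simulate_latent_series(part, cal, params, seed=6)
        ex = part.set_index("person_id")["exid"]
        med = ex.median()
        by_person = latent.groupby("person_id")[["L", "P"]].corr().unstack().iloc[:, 1]
        hi = by_person[ex[by_person.index] > med].mean()
        lo = by_person[ex[by_person.index] <= med].mean()
        assert hi > lo + 0.05

    def test_nonstationary_beta_refused(self):
        part = simulate_population(2, seed=0)
        cal = make_burst_calendar(part, seed=0)
        bad = _flat_params(beta=np.array([[0.9, 0.9], [0.9, 0.9]]))  # radius 1.8
        with pytest.raises(ValueError, match="stationary"):
            simulate_latent_series(part, cal, bad, seed=0)

    def test_bursts_do_not_share_dynamics(self):
        # with m = 0 and strong autocorrelation, across-gap correlation vanishes
        part = simulate_population(300, seed=5)
        design = BurstDesign(n_bursts=2, burst_length=3, burst_offsets_months=(0, 4))
        cal = make_burst_calendar(part, design=design, seed=0)
        params = _flat_params(beta=np.array([[0.8, 0.0], [0.0, 0.0]]))
        params = params.with_random_effects(np.zeros((300, 2)))
        latent, _ = simulate_latent_series(part, cal, params, seed=7)
        last_b1 = latent[(latent["burst_index"] == 1) & (latent["day_within_burst"] == 3)]
        first_b2 = latent[(latent["burst_index"] == 2) & (latent["day_within_burst"] == 1)]
        r = np.corrcoef(last_b1["L"].to_numpy(), first_b2["L"].to_numpy())[0, 1]
        assert abs(r) < 0.12


class TestRendering:
    @pytest.fixture
    def latent_small(self):
        part = simulate_population(4, seed=8)
        design = BurstDesign(n_bursts=1, burst_length=6, burst_offsets_months=(0,))
        cal = make_burst_calendar(part, design=design, seed=0)
        latent, _ = simulate_latent_series(part, cal, default_true_parameters(), seed=9)
        return latent

    def test_round_trip_through_preprocessing(self, latent_small):
        minutes, surveys = render_observables(latent_small, seed=1)
        daily = build_daily_table(minutes, surveys)
        merged = latent_small.merge(daily, on=["person_id", "date"])
        from burstvar import inverse_transform_ls, inverse_transform_pa
        ls_target = np.clip(inverse_transform_ls(merged["L"].to_numpy()), 0, 100)
        pa_target = np.maximum(inverse_transform_pa(merged["P"].to_numpy()), 0)
        assert np.max(np.abs(merged["ls_mean"] - ls_target)) <= 0.5
        rel = np.abs(merged["pa_rate"] - pa_target) / np.maximum(pa_target, 1e-9)
        assert np.max(rel) <= 0.01

    def test_logit_midpoint_renders_50(self, latent_small):
        latent = latent_small.copy()
        latent["L"] = 0.0
        latent["P"] = 0.0
        minutes, surveys = render_observables(latent, seed=2)
        ls = (surveys["ls_item1"] + surveys["ls_item2"]) / 2
        assert np.max(np.abs(ls - 50.0)) <= 0.5
        daily = build_daily_table(minutes, surveys)
        # latent P = 0 means exp(0) - 1 = 0 steps per wear-hour
        assert np.nanmax(daily["pa_rate"].to_numpy()) == 0.0

    def test_sleep_block_and_wear_structure(self, latent_small):
        minutes, _ = render_observables(latent_small.head(2), seed=3)
        one = minutes[minutes["timestamp"].dt.normalize()
                      == minutes["timestamp"].dt.normalize().iloc[0]]
        assert len(one) == 1440
        assert one["asleep"].sum() == 8 * 60
        awake = one[one["asleep"] == 0]
        # sedentary wear minutes exist (hr only), and so do non-wear minutes
        assert ((awake["steps"] == 0) & (awake["hr_present"] == 1)).any()
        assert ((awake["steps"] == 0) & (awake["hr_present"] == 0)).any()


class TestMissingness:
    @pytest.fixture
    def latent(self):
        part = simulate_population(40, seed=10)
        design = BurstDesign(n_bursts=2, burst_length=10, burst_offsets_months=(0, 4))
        cal = make_burst_calendar(part, design=design, seed=0)
        latent, _ = simulate_latent_series(part, cal, _flat_params(), seed=4)
        return latent

    def test_zero_rate_is_identity(self, latent):
        out = apply_missingness(latent, MarConfig(), seed=0)
        assert out["L"].notna().all() and out["P"].notna().all()
        pd.testing.assert_frame_equal(out[latent.columns], latent)

    def test_realized_rate_within_binomial_error(self, latent):
        out = apply_missingness(latent, MarConfig(ls_rate=0.2, pa_rate=0.2), seed=1)
        n = len(out)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(out["L"].isna().mean() - 0.2) < 3 * se
        assert abs(out["P"].isna().mean() - 0.2) < 3 * se

    def test_weekend_only_mechanism_spares_weekdays(self, latent):
        cfg = MarConfig(ls_rate=0.8, ls_weekday_multipliers={
            d: 0.0 for d in ["monday", "tuesday", "wednesday", "thursday", "friday"]})
        out = apply_missingness(latent, cfg, seed=2)
        wd = pd.to_datetime(out["date"]).dt.weekday
        assert out.loc[wd < 5, "L"].notna().all()
        assert out.loc[wd >= 5, "L"].isna().any()

    def test_value_dependent_mechanism_rejected(self):
        with pytest.raises(ValueError, match="MNAR"):
            MarConfig.from_dict({"ls_rate": 0.1, "ls_value_threshold": 50})

    def test_masked_entries_flagged_not_dropped(self, latent):
        out = apply_missingness(latent, MarConfig(ls_rate=0.3), seed=3)
        assert len(out) == len(latent)
        assert (out["L"].isna() == out["ls_missing"]).all()


def test_end_to_end_determinism():
    a = simulate_dataset(12, seed=21)
    b = simulate_dataset(12, seed=21)
    pd.testing.assert_frame_equal(a.daily, b.daily)
    assert np.array_equal(a.truth.m, b.truth.m)
    c = simulate_dataset(12, seed=22)
    assert not a.daily.equals(c.daily)
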