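"""Synthetic annual dataset: determinism, structure, closed loops."""

import numpy as np
import pandas as pd
import pytest

from standflux import sapflow, synthetic
from standflux.model import ModelParams


class TestWeather:
    def test_same_seed_bit_identical(self):
        a = synthetic.generate_weather(seed=5)
        b = synthetic.generate_weather(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = synthetic.generate_weather(seed=5)
        b = synthetic.generate_weather(seed=6)
        assert not a["et0"].equals(b["et0"])

    def test_et0_bounds(self):
        w = synthetic.generate_weather(seed=0)
        assert w["et0"].min() >= 0.5
        assert w["et0"].max() <= 10.0
        assert len(w) == 365

    def test_noise_free_is_exact_sinusoid(self):
        cfg = synthetic.SyntheticConfig(et0_noise_sd=0.0)
        w = synthetic.generate_weather(cfg, seed=0)
        doy = w.index.dayofyear.to_numpy().astype(float)
        expected = np.clip(
            cfg.et0_mean + cfg.et0_amplitude
            * np.cos(2 * np.pi * (doy - cfg.et0_peak_doy) / 365.0),
            cfg.et0_floor, cfg.et0_ceiling)
        assert np.allclose(w["et0"], expected)

    def test_wet_season_wetter(self):
        w = synthetic.generate_weather(seed=2)
        wet = w[(w.index.month >= 5) & (w.index.month <= 10)]["p"].sum()
        dry = w[(w.index.month < 5) | (w.index.month > 10)]["p"].sum()
        assert wet > dry


class TestPhenology:
    def test_constant_when_min_equals_max(self):
        cfg = synthetic.SyntheticConfig(lai_min=3.9)
        lai = synthetic.generate_phenology(cfg)
        assert (lai == 3.9).all()

    def test_minimum_on_configured_date(self):
        cfg = synthetic.SyntheticConfig()
        lai = synthetic.generate_phenology(cfg)
        assert lai.min() == pytest.approx(cfg.lai_min)
        assert lai.idxmin().dayofyear == cfg.lai_min_doy

    def test_daily_step_bounded_by_segment_slope(self):
        cfg = synthetic.SyntheticConfig()
        lai = synthetic.generate_phenology(cfg)
        shortest = min(cfg.lai_min_doy - cfg.defoliation_start_doy,
                       cfg.refoliation_end_doy - cfg.lai_min_doy)
        bound = (cfg.lai_max - cfg.lai_min) / shortest
        assert lai.diff().abs().max() <= bound + 1e-12

    def test_unordered_nodes_rejected(self):
        cfg = synthetic.SyntheticConfig(lai_min_doy=30, refoliation_end_doy=20)
        with pytest.raises(ValueError, match="ordered"):
            synthetic.generate_phenology(cfg)


class TestSoilBucket:
    def test_no_rain_monotone_drawdown(self):
        cfg = synthetic.SyntheticConfig(rain_p_wet=0.0, rain_p_dry=0.0,
                                        w_init=0.21)
        w = synthetic.generate_weather(cfg, seed=0).assign(p=0.0)
        lai = synthetic.generate_phenology(cfg)
        soil = synthetic.generate_soil_and_truth(w, lai, cfg)
        assert (soil["rew"].diff().dropna() <= 1e-12).all()
        assert soil["rew"].iloc[-1] < 0.05

    def test_heavy_rain_pins_at_field_capacity(self):
        cfg = synthetic.SyntheticConfig(w_init=0.21)
        w = synthetic.generate_weather(cfg, seed=0).assign(p=40.0)
        lai = synthetic.generate_phenology(cfg)
        soil = synthetic.generate_soil_and_truth(w, lai, cfg)
        assert (soil["rew"].iloc[5:] >= 1.0).all()

    def test_default_year_has_critical_drying_episode(self):
        d = synthetic.generate_dataset(seed=0)
        rainy = d["drivers"].loc["2007-06-01":"2007-10-31", "rew"]
        assert (rainy < 0.4).any()      # mid-rains drying below REWc

    def test_layer_outputs_consistent_with_bucket(self):
        d = synthetic.generate_dataset(seed=3)
        assert np.allclose(d["soil"]["rew_weighted"], d["drivers"]["rew"],
                           atol=1e-12)


class TestObservations:
    def test_zero_cv_is_exact(self):
        cfg = synthetic.SyntheticConfig(obs_cv=0.0)
        d = synthetic.generate_dataset(cfg, seed=4)
        assert d["t_obs"].equals(d["t_true"])

    def test_multiplicative_noise_mean_near_one(self):
        cfg = synthetic.SyntheticConfig(obs_cv=0.1)
        d = synthetic.generate_dataset(cfg, seed=4)
        pos = d["t_true"] > 1e-9
        factor = (d["t_obs"][pos] / d["t_true"][pos]).mean()
        assert factor == pytest.approx(1.0, abs=0.03)

    def test_dataset_reproducible(self):
        a = synthetic.generate_dataset(seed=9)
        b = synthetic.generate_dataset(seed=9)
        pd.testing.assert_frame_equal(a["drivers"], b["drivers"])
        pd.testing.assert_series_equal(a["t_obs"], b["t_obs"])


def test_ka_round_trip_recovers_daily_transpiration():
    """Inverting daily T to hourly Ka and running the sap-flow chain forward
    reproduces the series to numerical precision."""
    d = synthetic.generate_dataset(synthetic.SyntheticConfig(obs_cv=0.0),
                                   seed=2)
    t = d["t_obs"].iloc[:30]
    ka = synthetic.ka_from_daily_transpiration(t)
    assert (ka >= 0).all()
    daily = sapflow.daily_transpiration(ka)
    assert np.allclose(daily["t_mea"].to_numpy(), t.to_numpy(), atol=1e-9)


def test_config_serialisable_and_validated():
    cfg = synthetic.SyntheticConfig(params=ModelParams(rm=0.9))
    d = cfg.to_dict()
    assert d["params"]["rm"] == 0.9
    with pytest.raises(ValueError):
        synthetic.generate_observations(
            pd.Series([1.0]), synthetic.SyntheticConfig(obs_cv=-0.1), seed=0)
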