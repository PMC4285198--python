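"""Reduction factors and the daily simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from standflux import model as m


class TestTmax:
    @pytest.mark.parametrize("rm, et0, expected", [
        (1.0, 0.0, 0.0),
        (1.0, 2.0, 2.0),
        (0.9, 2.0, 1.8),
    ])
    def test_proportionality(self, rm, et0, expected):
        assert m.t_max(et0, rm) == pytest.approx(expected)


class TestRLai:
    @pytest.mark.parametrize("lai, expected", [
        (3.9, 1.0),
        (0.0, 0.0),
        (1.95, 0.5),
    ])
    def test_ratio(self, lai, expected):
        assert m.r_lai(lai, 3.9) == pytest.approx(expected)

    def test_above_max_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert m.r_lai(4.2, 3.9) == 1.0


class TestRRewc:
    @pytest.mark.parametrize("rew, expected", [
        (0.8, 1.0),          # above threshold
        (0.2, 0.5),          # (1/0.4) * 0.2
        (0.0, 0.0),
    ])
    def test_piecewise(self, rew, expected):
        assert m.r_rewc(rew, 0.4, 1.0) == pytest.approx(expected)

    def test_continuous_at_threshold(self):
        lo = m.r_rewc(0.4 - 1e-12, 0.4, 0.7)
        hi = m.r_rewc(0.4 + 1e-12, 0.4, 0.7)
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_couples_lai_into_slope(self):
        assert m.r_rewc(0.2, 0.4, 0.5) == pytest.approx(0.25)


class TestREt0c:
    @pytest.mark.parametrize("et0, expected", [
        (2.0, 1.0),                      # below critical demand
        (4.0, 0.4382),                   # -0.585 ln(4) + 1.2492
        (9.0, 0.0),                      # clamped (raw value -0.036)
    ])
    def test_printed_law(self, et0, expected):
        assert m.r_et0c(et0) == pytest.approx(expected, abs=1e-4)

    def test_jump_at_threshold_in_printed_mode(self):
        """As printed the law evaluates to ~0.762 just above ET0c."""
        just_above = m.r_et0c(2.3 + 1e-9)
        assert just_above == pytest.approx(-0.585 * np.log(2.3) + 1.2492, abs=1e-6)
        assert m.r_et0c(2.3) == 1.0

    def test_continuous_min_mode(self):
        p = m.ModelParams(continuity_mode="continuous_min")
        cross = np.exp((1.0 - p.b) / p.a)       # ~1.53 mm/d
        assert m.r_et0c(cross - 0.01, p) == 1.0
        assert m.r_et0c(cross + 0.01, p) < 1.0
        # both modes agree well below the crossing
        assert m.r_et0c(1.2, p) == m.r_et0c(1.2)

    def test_zero_crossing_location(self):
        p = m.DEFAULT_PARAMS
        x = np.exp(p.b / -p.a)                   # ~8.46 mm/d
        assert m.r_et0c(x - 0.01) > 0.0
        assert m.r_et0c(x + 0.01) == 0.0


def _drivers(et0, lai, rew):
    return pd.DataFrame({"et0": [et0], "lai": [lai], "rew": [rew]})


class TestSimulate:
    @pytest.mark.parametrize("et0, rew, expected", [
        (2.0, 1.0, 2.0),                 # no constraint binds
        (4.0, 1.0, 4.0 * 0.43822),       # demand constraint
        (4.0, 0.2, 4.0 * 0.43822),       # min(0.5, 0.438) -> demand wins
    ])
    def test_min_combination(self, et0, rew, expected):
        sim = m.simulate(_drivers(et0, 3.9, rew))
        assert sim["t_mod_et0c"].iloc[0] == pytest.approx(expected, abs=1e-3)

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gaps"):
            m.simulate(_drivers(np.nan, 3.9, 1.0))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            m.simulate(pd.DataFrame({"et0": [1.0], "lai": [3.9]}))

    @given(st.floats(min_value=0, max_value=9),
           st.floats(min_value=0, max_value=3.9),
           st.floats(min_value=0, max_value=1.2))
    def test_ordering_invariant(self, et0, lai, rew):
        """Adding the demand factor never increases transpiration:
        T_mod_ET0c <= T_mod <= T_max, and factors stay in their ranges."""
        sim = m.simulate(_drivers(et0, lai, rew))
        row = sim.iloc[0]
        assert row["t_mod_et0c"] <= row["t_mod"] + 1e-12
        assert row["t_mod"] <= row["t_max"] + 1e-12
        assert 0.0 <= row["r_lai"] <= 1.0
        assert 0.0 <= row["r_et0c"] <= 1.0
        assert 0.0 - 1e-12 <= row["r_rewc"] <= row["r_lai"] + 1e-12

    def test_scalar_composition(self):
        """Constant drivers equal the scalar factor composition."""
        sim = m.simulate(pd.DataFrame({"et0": [4.0] * 3, "lai": [1.95] * 3,
                                       "rew": [0.2] * 3}))
        rl = m.r_lai(1.95, 3.9)
        rr = m.r_rewc(0.2, 0.4, rl)
        re = m.r_et0c(4.0)
        expected = min(rr, re) * 4.0
        assert np.allclose(sim["t_mod_et0c"], expected)


class TestEstimator:
    def test_fixed_params_roundtrip(self):
        est = m.ReductionFactorModel().fit(_drivers(2.0, 3.9, 1.0))
        assert est.params_ == m.DEFAULT_PARAMS
        assert est.predict(_drivers(2.0, 3.9, 1.0))[0] == pytest.approx(2.0)

    def test_sklearn_param_interface(self):
        est = m.ReductionFactorModel(rm=0.9)
        assert est.get_params()["rm"] == 0.9
        est.set_params(rm=1.0)
        assert est.rm == 1.0

    def test_fit_calibrates_from_data(self, noiseless_dataset):
        d = noiseless_dataset
        est = m.ReductionFactorModel().fit(
            d["drivers"][["et0", "lai", "rew"]], d["t_obs"])
        assert est.rm_ == pytest.approx(1.0, abs=1e-6)
        assert est.et0c_ == pytest.approx(2.3, abs=0.1)
        # a fitted model reproduces the noiseless observations
        pred = est.predict(d["drivers"][["et0", "lai", "rew"]])
        assert np.allclose(pred, d["t_obs"].to_numpy(), atol=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            m.ModelParams(rewc=1.5)
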