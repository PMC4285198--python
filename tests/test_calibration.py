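"""Parameter estimation: slopes, log law, breakpoints."""

import numpy as np
import pytest
from scipy import optimize

from standflux import calibration as cal


class TestFitRm:
    def test_exact_slopes(self):
        et0 = np.linspace(0.5, 2.2, 10)
        assert cal.fit_rm(et0, 0.9 * et0)["rm"] == pytest.approx(0.9)
        assert cal.fit_rm(et0, 1.0 * et0)["rm"] == pytest.approx(1.0)

    def test_matches_brute_force_sse_minimum(self):
        """Closed form sum(xy)/sum(x^2) agrees with direct SSE minimisation."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 2.2, 12)
        y = 0.95 * x + rng.normal(0, 0.15, 12)
        closed = cal.fit_rm(x, y)["rm"]
        brute = optimize.minimize_scalar(
            lambda s: np.sum((y - s * x) ** 2), bounds=(0, 3), method="bounded")
        assert closed == pytest.approx(brute.x, abs=1e-5)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 2.2, 30)
        y = 0.95 * x + rng.normal(0, 0.15, 30)
        fit = cal.fit_rm(x, y)
        assert fit["rm"] == pytest.approx(0.95, abs=0.1)
        assert fit["se"] > 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_rm([1.0, 2.0], [1.0, 2.0])


class TestRatioLogLaw:
    def test_noiseless_identity(self):
        et0 = np.linspace(2.4, 7.0, 25)
        ratio = -0.585 * np.log(et0) + 1.2492
        fit = cal.fit_ratio_loglaw(et0, ratio)
        assert fit["a"] == pytest.approx(-0.585, abs=1e-9)
        assert fit["b"] == pytest.approx(1.2492, abs=1e-9)
        assert fit["r2"] == pytest.approx(1.0)

    def test_constant_ratio(self):
        et0 = np.linspace(1.0, 5.0, 10)
        fit = cal.fit_ratio_loglaw(et0, np.ones(10))
        assert fit["a"] == pytest.approx(0.0, abs=1e-12)
        assert fit["b"] == pytest.approx(1.0)

    def test_ratios_above_one_discarded(self):
        et0 = np.concatenate([np.linspace(2.4, 7.0, 20), [1.1, 1.2]])
        ratio = np.concatenate([-0.585 * np.log(et0[:20]) + 1.2492, [1.2, 1.3]])
        fit = cal.fit_ratio_loglaw(et0, ratio)
        assert fit["n_discarded"] == 2
        assert fit["a"] == pytest.approx(-0.585, abs=1e-9)

    def test_insufficient_spread_rejected(self):
        with pytest.raises(ValueError, match="span"):
            cal.fit_ratio_loglaw(np.linspace(3.0, 3.5, 10), np.full(10, 0.5))


def _demand_response(et0, et0c=2.3, rm=1.0, a=-0.585, b=1.2492):
    ratio = np.where(et0 <= et0c, rm, a * np.log(et0) + b)
    return ratio * et0


class TestEstimateEt0c:
    def test_noiseless_breakpoint(self):
        et0 = np.linspace(0.6, 6.0, 80)
        fit = cal.estimate_et0c(et0, _demand_response(et0))
        assert fit["et0c"] == pytest.approx(2.3, abs=0.1)
        assert not fit["flagged"]

    def test_pure_linear_degenerate(self):
        et0 = np.linspace(0.6, 6.0, 40)
        fit = cal.estimate_et0c(et0, 0.9 * et0)
        assert fit["flagged"]
        assert fit["et0c"] == pytest.approx(max(fit["grid"]))

    def test_noisy_recovery(self):
        rng = np.random.default_rng(9)
        et0 = rng.uniform(0.6, 6.5, 120)
        t = _demand_response(et0) * (1 + rng.normal(0, 0.10, 120))
        fit = cal.estimate_et0c(et0, t)
        assert fit["et0c"] == pytest.approx(2.3, abs=0.3)


class TestEstimateRewc:
    def test_noiseless_breakpoint(self):
        rew = np.linspace(0.05, 1.0, 60)
        ratio = np.where(rew > 0.4, 1.0, rew / 0.4)
        fit = cal.estimate_rewc(rew, ratio)
        assert fit["rewc"] == pytest.approx(0.4, abs=0.05)
        assert fit["plateau"] == pytest.approx(1.0, abs=1e-9)

    def test_all_wet_unidentifiable(self):
        rew = np.linspace(0.5, 1.0, 30)
        with pytest.raises(ValueError, match="unidentifiable"):
            cal.estimate_rewc(rew, np.ones(30))

    def test_noisy_recovery(self):
        rng = np.random.default_rng(13)
        rew = rng.uniform(0.05, 1.0, 80)
        ratio = np.where(rew > 0.4, 1.0, rew / 0.4) + rng.normal(0, 0.1, 80)
        fit = cal.estimate_rewc(rew, ratio)
        assert fit["rewc"] == pytest.approx(0.4, abs=0.1)


class TestFullPipeline:
    def test_noiseless_recovery(self, noiseless_dataset):
        """Calibrating on a noiseless synthetic year returns the generating
        parameters: rm, a, b exactly; ET0c, REWc within one grid step."""
        d = noiseless_dataset
        drv = d["drivers"]
        r = cal.calibrate(drv["et0"].to_numpy(), drv["lai"].to_numpy(),
                          drv["rew"].to_numpy(), d["t_obs"].to_numpy())
        assert r["rm"] == pytest.approx(1.0, abs=1e-6)
        assert r["a"] == pytest.approx(-0.585, abs=1e-6)
        assert r["b"] == pytest.approx(1.2492, abs=1e-6)
        assert r["et0c"] == pytest.approx(2.3, abs=0.1)
        assert r["rewc"] == pytest.approx(0.4, abs=0.05)

    def test_noisy_recovery(self, noisy_dataset):
        """10% multiplicative observation noise keeps the estimates inside
        field-realistic tolerances."""
        d = noisy_dataset
        drv = d["drivers"]
        r = cal.calibrate(drv["et0"].to_numpy(), drv["lai"].to_numpy(),
                          drv["rew"].to_numpy(), d["t_obs"].to_numpy())
        assert r["rm"] == pytest.approx(1.0, abs=0.1)
        assert r["et0c"] == pytest.approx(2.3, abs=0.3)
        assert r["rewc"] == pytest.approx(0.4, abs=0.1)
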