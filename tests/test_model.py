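"""Factorial estimation chain: maintenance, growth, efficiency, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netenergy.balance import EnergyBalanceRecord
from netenergy.exceptions import (
    DegreesOfFreedomError,
    RankError,
    ValidationError,
)
from netenergy.model import (
    FactorialNEModel,
    RequirementEquation,
    build_equation,
    fit_efficiency,
    fit_growth,
    fit_maintenance,
    predict_requirement,
)
from netenergy.tables import CarcassRecord


def _records_from_law(mei_values, hp_fn, rep_fn=None, ref_fn=None):
    recs = []
    for i, mei in enumerate(mei_values):
        hp = hp_fn(mei)
        recs.append(
            EnergyBalanceRecord(
                group=f"g{i}", replicate="r1", mbw=1.0,
                mei=mei, re=mei - hp, hp=hp,
                re_p=rep_fn(mei) if rep_fn else 0.3 * (mei - hp),
                re_f=ref_fn(mei) if ref_fn else 0.7 * (mei - hp),
            )
        )
    return recs


class TestMaintenance:
    def test_log_linear_extrapolation(self):
        """HP generated from the published log-linear law is recovered:
        NE_m = 10^2.74 = 549.54, and the published RE line arithmetic
        yields ME_m = 625.59, K_m = 0.88."""
        mei = [1498.0, 1625.33, 1720.48, 1805.63, 1934.25]
        recs = _records_from_law(mei, lambda m: 10 ** (2.74 + 0.00012 * m))
        fit = fit_maintenance(recs)
        assert fit.nem == pytest.approx(549.5408738576248, rel=1e-9)
        assert fit.log_slope == pytest.approx(0.00012, rel=1e-9)

    def test_linear_re_law_recovered(self):
        mei = [1400.0, 1550.0, 1700.0, 1850.0, 2000.0]
        recs = _records_from_law(
            mei, lambda m: m - 0.75 * (m - 625.5866666666667)
        )
        fit = fit_maintenance(recs)
        assert fit.kg == pytest.approx(0.75, rel=1e-12)
        assert fit.mem == pytest.approx(625.5866666666667, rel=1e-9)
        assert fit.km == pytest.approx(fit.nem / fit.mem, rel=1e-12)

    def test_nonpositive_hp_named(self):
        recs = _records_from_law([100.0, 200.0, 300.0], lambda m: 0.5 * m)
        recs[1] = EnergyBalanceRecord(
            "g1", "r1", 1.0, 200.0, 250.0, -50.0, 10.0, 10.0
        )
        with pytest.raises(ValidationError, match="g1/r1"):
            fit_maintenance(recs)

    def test_degenerate_mei_spread(self):
        recs = _records_from_law([500.0] * 4, lambda m: 0.5 * m)
        with pytest.raises(RankError, match="spread"):
            fit_maintenance(recs)

    def test_too_few_records(self):
        recs = _records_from_law([500.0, 600.0], lambda m: 0.5 * m)
        with pytest.raises(DegreesOfFreedomError):
            fit_maintenance(recs)


class TestGrowth:
    def test_serial_slaughter_slope_and_me_scale(self):
        cars = [
            CarcassRecord("initial", "m", 7.0, 171.12, 72.0, 14.0, 13.0,
                          1196.28 / 171.12),
            CarcassRecord("ad_lib", "m", 14.0, 572.70, 68.0, 14.6, 15.6,
                          4815.71 / 572.70),
            CarcassRecord("ad_lib", "m", 21.0, 1143.88, 63.9, 16.5, 13.7,
                          11264.76 / 1143.88),
        ]
        fit = fit_growth(cars, kg=0.75)
        assert fit.neg == pytest.approx(10.413957960736429, rel=1e-9)
        # published rounding: NE_g 10.41 over K_g 0.75 prints ME_g 13.88
        assert 10.41 / 0.75 == pytest.approx(13.88, abs=1e-9)
        assert fit.meg == pytest.approx(fit.neg / 0.75, rel=1e-12)

    def test_proportional_energies(self):
        cars = [
            CarcassRecord("g", f"r{i}", 21.0, bw, 64.0, 16.0, 15.0, 5.0)
            for i, bw in enumerate([200.0, 400.0, 800.0])
        ]
        fit = fit_growth(cars, kg=0.5)
        assert fit.neg == pytest.approx(5.0, rel=1e-12)
        assert fit.fit.r2 == pytest.approx(1.0)

    def test_needs_three_points(self):
        cars = [
            CarcassRecord("g", "r", 21.0, 200.0, 64.0, 16.0, 15.0, 5.0),
            CarcassRecord("g", "r2", 21.0, 300.0, 64.0, 16.0, 15.0, 5.0),
        ]
        with pytest.raises(DegreesOfFreedomError):
            fit_growth(cars, kg=0.75)


class TestEfficiency:
    def test_exact_plane_recovery(self):
        """MEI = 600 + 2 RE_p + 1.25 RE_f gives K_p = 0.5, K_f = 0.8."""
        rng = np.random.default_rng(5)
        rep = rng.uniform(100, 400, size=8)
        ref = rng.uniform(100, 600, size=8)
        mei = 600.0 + 2.0 * rep + 1.25 * ref
        recs = [
            EnergyBalanceRecord("g", f"r{i}", 1.0, m, 0.5 * m, 0.5 * m, p, f)
            for i, (m, p, f) in enumerate(zip(mei, rep, ref))
        ]
        fit = fit_efficiency(recs)
        assert fit.kp == pytest.approx(0.5, rel=1e-9)
        assert fit.kf == pytest.approx(0.8, rel=1e-9)

    def test_published_coefficient_reciprocals(self):
        assert 1.0 / 1.67 == pytest.approx(0.5988023952095809, rel=1e-12)
        assert 1.0 / 1.08 == pytest.approx(0.9259259259259258, rel=1e-12)

    def test_collinear_partition_rejected(self):
        mei = np.linspace(1000, 2000, 6)
        recs = [
            EnergyBalanceRecord("g", f"r{i}", 1.0, m, 0.6 * m, 0.4 * m,
                                0.2 * m, 0.4 * m)
            for i, m in enumerate(mei)
        ]
        with pytest.raises(RankError, match="condition"):
            fit_efficiency(recs)


class TestEquation:
    def test_maintenance_only(self):
        eq = RequirementEquation(nem=549.54, neg=10.41)
        assert predict_requirement(eq, 1.0, 0.0) == pytest.approx(549.54)

    def test_published_scale_example(self):
        # 549.54 + 10.41 * 69.31 computed by direct arithmetic
        eq = RequirementEquation(nem=549.54, neg=10.41, mem=625.59, meg=13.88)
        assert predict_requirement(eq, 1.0, 69.31) == pytest.approx(
            1271.0571, abs=1e-4
        )
        me = predict_requirement(eq, 1.0, 69.31, scale="me")
        assert me == pytest.approx(625.59 + 13.88 * 69.31, rel=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        bw=st.floats(min_value=0.05, max_value=5.0),
        dw=st.floats(min_value=0.0, max_value=150.0),
        dbw=st.floats(min_value=1e-3, max_value=1.0),
        ddw=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_strictly_increasing_in_both_arguments(self, bw, dw, dbw, ddw):
        eq = RequirementEquation(nem=549.54, neg=10.41)
        base = predict_requirement(eq, bw, dw)
        assert predict_requirement(eq, bw + dbw, dw) > base
        assert predict_requirement(eq, bw, dw + ddw) > base

    def test_domain_errors(self):
        eq = RequirementEquation(nem=549.54, neg=10.41)
        with pytest.raises(ValidationError):
            predict_requirement(eq, 0.0, 10.0)
        with pytest.raises(ValidationError):
            predict_requirement(eq, 1.0, -5.0)
        with pytest.raises(ValidationError):
            predict_requirement(eq, 1.0, 5.0, scale="de")


class TestModelResults:
    def test_chain_consistency(self, fit_linear):
        """km*mem = nem and kg*meg = neg hold by construction."""
        p = fit_linear.params
        assert p["km"] * p["mem"] == pytest.approx(p["nem"], rel=1e-9)
        assert p["kg"] * p["meg"] == pytest.approx(p["neg"], rel=1e-9)

    def test_equation_string_and_kv_roundtrip(self, fit_linear):
        text = str(fit_linear.equation)
        assert "BW^0.75" in text and "NE =" in text
        kv = dict(
            line.split("=", 1)
            for line in fit_linear.to_kv().strip().splitlines()
        )
        assert set(kv) == {"nem", "mem", "km", "kg", "neg", "meg", "kp", "kf"}
        for key, value in kv.items():
            assert float(value) == pytest.approx(fit_linear.params[key])

    def test_summary_reports_fits(self, fit_linear):
        s = fit_linear.summary()
        for token in ("NE_m", "ME_m", "K_g", "NE_g", "K_p", "K_f", "R2"):
            assert token in s

    def test_predict_off_results(self, fit_linear):
        val = fit_linear.predict(1.0, 0.0)
        assert val == pytest.approx(fit_linear.params["nem"], rel=1e-12)

    def test_weighting_switch_exposed_and_near_unweighted(self, sim_linear):
        """Group-equalizing weights exist because the reference design has
        10 ad-libitum vs 5 restricted replicates. The simulator's replicate
        offsets are zero-sum under the unweighted convention only, so the
        weighted fit differs — but by well under a percent on noiseless
        data."""
        res_u = FactorialNEModel(sim_linear).fit()
        res_w = FactorialNEModel(sim_linear, weights="replicate-count").fit()
        assert res_u.params["kg"] == pytest.approx(0.75, rel=1e-9)
        assert res_w.params["kg"] == pytest.approx(res_u.params["kg"], rel=5e-3)
        assert res_w.params["kg"] != res_u.params["kg"]
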