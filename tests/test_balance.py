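"""Balance-engine metrics against hand-computed and table-derived oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ibferm import (
    CoefficientError,
    ComputationError,
    EndpointRecord,
    analyze_endpoint,
    analyze_timecourse,
    bi_ratio,
    carbon_recovery,
    classify_mode,
    endpoint_from_timecourse,
    fd_fraction,
    mass_yield,
    nadph_generated,
    nadph_per_cmol,
    nadph_required,
    per_cmol_production,
    productivity,
    scenario,
    simulate_batch,
    to_millimolar,
)
from ibferm.balance import endpoint_at_time

from conftest import random_record


def record(consumed, products, duration=28.0, label="test"):
    return EndpointRecord(label, duration, consumed, products)


class TestMassYieldAndProductivity:
    def test_ph55_butanol_yield(self, fx):
        assert mass_yield(fx.reported["ph55"]) == pytest.approx(0.203, abs=5e-3)

    def test_mixed_feed_yield_uses_total_substrate(self, fx):
        assert mass_yield(fx.table3["14:8"]) == pytest.approx(5.38 / 20.36, rel=1e-12)

    def test_zero_products(self):
        rec = record({"glucose": 10}, {"butanol": 0})
        assert mass_yield(rec) == 0.0

    def test_zero_consumption_is_an_error(self):
        rec = record({"glucose": 0.0}, {"butanol": 1})
        with pytest.raises(ComputationError, match="zero substrate"):
            mass_yield(rec)

    def test_16h_butanol_productivity(self, fx):
        assert productivity(fx.reported["glucose_16h"]) == pytest.approx(
            4.41 / 16, rel=1e-12
        )

    def test_ph55_ib_productivity(self, fx):
        p = productivity(fx.reported["ph55"], ("butanol", "isopropanol"))
        assert p == pytest.approx(13.92 / 32, rel=1e-12)

    def test_zero_titer_productivity(self):
        assert productivity(record({"glucose": 10}, {"butanol": 0})) == 0.0


class TestBiRatio:
    def test_14_8(self, fx):
        assert bi_ratio(fx.table3["14:8"]) == pytest.approx(3.43, abs=0.01)

    def test_equal_titers(self):
        rec = record({"glucose": 10}, {"butanol": 2.0, "isopropanol": 2.0})
        assert bi_ratio(rec) == 1.0

    def test_undefined_when_no_isopropanol(self, fx):
        assert bi_ratio(fx.table2["glycerol"]) is None


class TestNadphGenerated:
    def test_20_2_matches_table(self, fx):
        assert nadph_generated(fx.table3["20:2"]) == pytest.approx(259.97, abs=0.15)

    def test_zero_consumption(self):
        assert nadph_generated(record({"glucose": 0.0}, {})) == 0.0

    def test_xylose_has_no_core_coefficient(self, fx):
        with pytest.raises(CoefficientError, match="xylose"):
            nadph_generated(fx.table2["xylose"])


class TestNadphRequired:
    def test_22_0_matches_table(self, fx):
        assert nadph_required(fx.table3["22:0"]) == pytest.approx(290.02, abs=0.15)

    def test_all_zero_products(self):
        rec = record({"glucose": 10}, {"butanol": 0, "acetone": 0})
        assert nadph_required(rec) == 0.0

    def test_random_compositions_vs_term_by_term_sum(self):
        # brute-force oracle: explicit coefficient times conc/MW*1000 per term
        coef = {"butanol": 4, "butyric_acid": 2, "isopropanol": 1,
                "acetone": 0, "acetic_acid": 0}
        mw = {"butanol": 74.12, "butyric_acid": 88.11, "isopropanol": 60.10,
              "acetone": 58.08, "acetic_acid": 60.05}
        rng = np.random.default_rng(42)
        for _ in range(25):
            products = {sp: float(rng.uniform(0, 8)) for sp in coef}
            rec = record({"glucose": 20}, products)
            expected = sum(coef[sp] * products[sp] / mw[sp] * 1000 for sp in coef)
            assert nadph_required(rec) == pytest.approx(expected, rel=1e-9)

    def test_pdo_requires_opt_in(self, fx):
        with pytest.raises(CoefficientError, match="extrapolated"):
            nadph_required(fx.table2["glycerol"])
        with_pdo = nadph_required(fx.table2["glycerol"], allow_extrapolated=True)
        without = nadph_required(
            record({"glycerol": 18.13},
                   {k: v for k, v in fx.table2["glycerol"].products.items()
                    if k != "pdo_13"})
        )
        assert with_pdo == pytest.approx(without + to_millimolar(3.40, "pdo_13"))

    def test_ethanol_is_excluded(self):
        base = record({"glucose": 10}, {"butanol": 2})
        with_etoh = record({"glucose": 10}, {"butanol": 2, "ethanol": 0.09})
        assert nadph_required(with_etoh) == nadph_required(base)


class TestNadphPerCmol:
    def test_glucose_only_is_exactly_one_third(self, fx):
        assert nadph_per_cmol(fx.table3["22:0"]) == pytest.approx(1 / 3, rel=1e-12)

    def test_glycerol_only_is_exactly_two_thirds(self, fx):
        assert nadph_per_cmol(fx.table2["glycerol"]) == pytest.approx(2 / 3, rel=1e-12)

    def test_14_8_matches_table(self, fx):
        assert nadph_per_cmol(fx.table3["14:8"]) == pytest.approx(0.45, abs=0.005)


class TestFdFraction:
    def test_22_0_from_printed_row(self, fx):
        # arithmetic on the printed table values: (290.02-242.51)/290.02
        assert fd_fraction(fx.table3["22:0"]) == pytest.approx(0.1638, abs=2e-3)

    def test_clipped_to_zero_at_9_13(self, fx):
        assert fd_fraction(fx.table3["9:13"]) == 0.0

    def test_boundary_generated_equals_required(self):
        # choose glucose so that 2*glc_mM == 4*buoh_mM exactly
        buoh = 2.0
        glc = 2 * (buoh / 74.12) * 180.2
        rec = record({"glucose": glc}, {"butanol": buoh})
        assert fd_fraction(rec) == pytest.approx(0.0, abs=1e-12)

    def test_zero_requirement_is_an_error(self):
        rec = record({"glucose": 10}, {"acetone": 1.0})  # coefficient 0
        with pytest.raises(ComputationError, match="requirement"):
            fd_fraction(rec)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_non_increasing_in_glycerol_share(self, s1, s2):
        # fixed 600 mM C split between glucose and glycerol, products held fixed
        lo, hi = sorted((s1, s2))
        products = {"butanol": 4.0, "butyric_acid": 1.0}

        def rec_at(share):
            glc = (1 - share) * 600 / 6 * 180.2 / 1000
            gly = share * 600 / 3 * 92.09 / 1000
            consumed = {k: v for k, v in
                        {"glucose": glc, "glycerol": gly}.items() if v > 0}
            return record(consumed, products)

        assert fd_fraction(rec_at(hi)) <= fd_fraction(rec_at(lo)) + 1e-12


class TestPerCmolAndRecovery:
    def test_zero_products_all_zero(self):
        rec = record({"glucose": 10}, {"butanol": 0})
        assert all(v == 0 for v in per_cmol_production(rec).values())

    def test_22_0_butanol_per_cmol(self, fx):
        # (4.33/74.12*1000)/727.5 from the printed inputs
        assert per_cmol_production(fx.table3["22:0"])["buoh_c"] == pytest.approx(
            0.0803, abs=5e-4
        )

    def test_ib_is_sum_of_components(self, fx):
        pc = per_cmol_production(fx.table3["20:2"])
        assert pc["ib_c"] == pytest.approx(pc["buoh_c"] + pc["ipa_c"], rel=1e-12)

    def test_per_carbon_switch_scales_by_carbon_count(self, fx):
        rec = fx.table3["22:0"]
        mol = per_cmol_production(rec, per_carbon=False)
        cmol = per_cmol_production(rec, per_carbon=True)
        assert cmol["buoh_c"] == pytest.approx(4 * mol["buoh_c"], rel=1e-12)
        assert cmol["aa_c"] == pytest.approx(2 * mol["aa_c"], rel=1e-12)

    def test_ipa_per_cmol_declines_across_glycerol_gradient(self, fx):
        ipa_c = [per_cmol_production(fx.table3[k])["ipa_c"]
                 for k in ("22:0", "20:2", "18:4", "14:8", "9:13")]
        assert all(a > b for a, b in zip(ipa_c, ipa_c[1:]))

    def test_ph55_carbon_recoveries(self, fx):
        rec = fx.reported["ph55"]
        assert carbon_recovery(rec, ("butanol", "isopropanol")) == pytest.approx(
            47.5, abs=0.1
        )
        assert carbon_recovery(rec, ("butanol",)) == pytest.approx(33.0, abs=0.1)

    def test_recovery_is_100_when_product_carbon_equals_substrate_carbon(self):
        glc = 10.0
        carbon_mM = glc / 180.2 * 6000
        buoh = carbon_mM / 4 * 74.12 / 1000
        rec = record({"glucose": glc}, {"butanol": buoh})
        assert carbon_recovery(rec, ("butanol",)) == pytest.approx(100.0, rel=1e-12)


class TestClassifyMode:
    def test_xylose_is_acidogenic(self, fx):
        assert classify_mode(fx.table2["xylose"]) == "acidogenic"

    def test_glucose_is_solventogenic(self, fx):
        assert classify_mode(fx.table2["glucose"]) == "solventogenic"

    def test_tie_rule_warns(self):
        rec = record({"glucose": 10}, {"butanol": 0, "acetic_acid": 0})
        with pytest.warns(UserWarning, match="tie"):
            assert classify_mode(rec) == "solventogenic"


class TestAnalyzeEndpoint:
    def test_22_0_aggregate(self, fx):
        res = analyze_endpoint(fx.table3["22:0"])
        assert res.nadph_req_mM == pytest.approx(290.0, abs=0.15)
        assert res.nadph_c == pytest.approx(1 / 3, rel=1e-12)
        assert res.y_b == pytest.approx(0.198, abs=1e-3)
        assert res.mode == "solventogenic"

    def test_empty_products_flags_fd(self):
        with pytest.warns(UserWarning, match="tie"):
            res = analyze_endpoint(record({"glucose": 10}, {"butanol": 0}))
        assert res.y_b == 0 and res.p_ib == 0
        assert res.fd_fraction is None
        assert any("fd_fraction" in f for f in res.flags)

    def test_aggregate_equals_component_operations(self):
        rng = np.random.default_rng(7)
        for i in range(100):
            rec = random_record(rng, label=f"r{i}")
            res = analyze_endpoint(rec)
            assert res.y_b == mass_yield(rec)
            assert res.y_ib == mass_yield(rec, ("butanol", "isopropanol"))
            assert res.p_b == productivity(rec)
            assert res.bi_ratio == bi_ratio(rec)
            assert res.nadph_gen_mM == nadph_generated(rec)
            assert res.nadph_req_mM == nadph_required(rec)
            assert res.nadph_c == nadph_per_cmol(rec)
            assert res.fd_fraction == fd_fraction(rec)
            assert res.per_cmol == per_cmol_production(rec)
            assert res.carbon_recovery["ib"] == carbon_recovery(rec)

    def test_scale_invariance_of_intensive_metrics(self):
        rec = random_record(np.random.default_rng(3))
        a, b = analyze_endpoint(rec), analyze_endpoint(rec.scaled(2.0))
        for attr in ("y_b", "y_ib", "bi_ratio", "nadph_c", "fd_fraction"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9)
        assert b.per_cmol == pytest.approx(a.per_cmol, rel=1e-9)
        assert b.carbon_recovery == pytest.approx(a.carbon_recovery, rel=1e-9)
        assert b.total_carbon_mM == pytest.approx(2 * a.total_carbon_mM, rel=1e-9)
        assert b.nadph_gen_mM == pytest.approx(2 * a.nadph_gen_mM, rel=1e-9)


@pytest.fixture(scope="module")
def course():
    return simulate_batch(scenario("glucose_20"), latent=True)


class TestAnalyzeTimecourse:
    def test_final_time_matches_endpoint_analysis(self, course):
        res = analyze_timecourse(course, float(course.times[-1]))
        ep = endpoint_from_timecourse(course)
        assert res.y_b == pytest.approx(analyze_endpoint(ep).y_b, rel=1e-12)

    def test_at_time_zero_is_an_error(self, course):
        with pytest.raises(ComputationError):
            analyze_timecourse(course, 0.0)

    def test_sample_point_matches_manual_record(self, course):
        t = float(course.times[200])
        manual = EndpointRecord(
            "manual", t,
            {"glucose": float(course.series["glucose"][0]
                              - course.series["glucose"][200])},
            {sp: float(course.series[sp][200])
             for sp in ("butanol", "isopropanol", "acetone",
                        "acetic_acid", "butyric_acid")},
        )
        auto = endpoint_at_time(course, t)
        assert auto.substrates_consumed == pytest.approx(manual.substrates_consumed)
        assert auto.products == pytest.approx(manual.products)
        assert analyze_timecourse(course, t).y_b == pytest.approx(
            analyze_endpoint(manual).y_b, rel=1e-12
        )
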