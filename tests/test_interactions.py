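"""Inhibition/induction mechanics and perpetrator composition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from hsctpbpk.engine import Regimen, assemble_model, auc_infinity, simulate
from hsctpbpk.interactions import (
    InductionSpec,
    InhibitionSpec,
    combine_perpetrators,
    enzyme_turnover_rhs,
    induction_steady_state_ratio,
    interaction_driver_concentration,
    mbi_steady_state_ratio,
    reversible_rate_factor,
)
from hsctpbpk.synthetic import toy_compound, toy_inhibitor


def spec(type_, ki=1.0, alpha=None, target="CYP3A4"):
    return InhibitionSpec(perpetrator="p", target=target, type=type_, ki=ki, alpha=alpha)


ALL_REVERSIBLE = ["competitive", "uncompetitive", "non-competitive", "mixed"]


class TestReversible:
    @pytest.mark.parametrize("type_", ALL_REVERSIBLE)
    def test_no_inhibitor_no_effect(self, type_):
        s = spec(type_, alpha=2.0 if type_ == "mixed" else None)
        assert reversible_rate_factor(0.5, 0.0, s, Km=1.0) == 1.0

    def test_competitive_linear_range_half(self):
        s = spec("competitive", ki=2.0)
        f = reversible_rate_factor(1e-3, 2.0, s, Km=1.0)
        assert f == pytest.approx(0.5, rel=1e-3)

    def test_noncompetitive_exact_half_any_substrate(self):
        s = spec("non-competitive", ki=3.0)
        for S in (0.001, 0.5, 5.0, 500.0):
            assert reversible_rate_factor(S, 3.0, s, Km=1.0) == pytest.approx(0.5)

    def test_mixed_alpha_one_equals_noncompetitive_on_grid(self):
        mixed = spec("mixed", ki=1.5, alpha=1.0)
        ncomp = spec("non-competitive", ki=1.5)
        for S in np.logspace(-2, 2, 10):
            for I in np.logspace(-2, 2, 10):
                assert reversible_rate_factor(
                    S, I, mixed, Km=0.7
                ) == pytest.approx(reversible_rate_factor(S, I, ncomp, Km=0.7))

    def test_uncompetitive_vanishes_in_linear_range(self):
        s = spec("uncompetitive", ki=1.0)
        assert reversible_rate_factor(1e-4, 10.0, s, Km=1.0) == pytest.approx(
            1.0, rel=1e-3
        )

    def test_irreversible_rejected_here(self):
        mbi = InhibitionSpec(
            perpetrator="p", target="CYP3A4", type="irreversible", kinact=1.0, KI=5.0
        )
        with pytest.raises(TypeError, match="turnover"):
            reversible_rate_factor(1.0, 1.0, mbi)

    @given(
        i1=st.floats(0, 50),
        i2=st.floats(0, 50),
        type_=st.sampled_from(ALL_REVERSIBLE),
    )
    def test_monotone_in_inhibitor(self, i1, i2, type_):
        """More inhibitor never increases the victim rate."""
        s = spec(type_, ki=2.0, alpha=3.0 if type_ == "mixed" else None)
        lo, hi = sorted((i1, i2))
        f_lo = reversible_rate_factor(0.8, lo, s, Km=1.2)
        f_hi = reversible_rate_factor(0.8, hi, s, Km=1.2)
        assert f_hi <= f_lo + 1e-12


class TestTurnover:
    def test_baseline_steady_state(self):
        assert enzyme_turnover_rhs(1.0, 1.0, 0.0158) == pytest.approx(0.0)

    def test_mbi_steady_state_matches_closed_form(self):
        mbi = InhibitionSpec(
            perpetrator="p", target="CYP3A4", type="irreversible", kinact=0.5, KI=5.0
        )
        I, kdeg = 3.0, 0.0158
        sol = solve_ivp(
            lambda t, y: [enzyme_turnover_rhs(y[0], 1.0, kdeg, mbi=[(mbi, I)])],
            (0, 3000),
            [1.0],
            rtol=1e-9,
            atol=1e-12,
        )
        expected = mbi_steady_state_ratio(kdeg, 0.5, 5.0, I)
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-4)

    def test_induction_at_ec50_gives_half_emax(self):
        ind = InductionSpec(perpetrator="p", target="CYP3A4", emax=4.0, ec50=2.0)
        kdeg = 0.02
        sol = solve_ivp(
            lambda t, y: [
                enzyme_turnover_rhs(y[0], 1.0, kdeg, induction=[(ind, 2.0)])
            ],
            (0, 2000),
            [1.0],
            rtol=1e-9,
            atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(1 + 4.0 / 2, rel=1e-4)
        assert induction_steady_state_ratio(4.0, 2.0, 2.0) == pytest.approx(3.0)


class TestCombine:
    def test_single_spec_reduces_to_scalar_operations(self):
        s = spec("competitive", ki=2.0)
        net = combine_perpetrators([s], [2.0], S=1e-3, Km=1.0)
        assert net.reversible_factor == pytest.approx(
            reversible_rate_factor(1e-3, 2.0, s, Km=1.0)
        )
        assert net.inactivation_rate == 0.0
        assert net.induction_term == 0.0

    def test_two_identical_competitive_additive_denominator(self):
        s = spec("competitive", ki=1.0)
        net = combine_perpetrators([s, s], [1.0, 1.0], S=1e-4, Km=1.0)
        assert net.reversible_factor == pytest.approx(1 / 3, rel=1e-3)

    def test_permutation_invariance(self):
        specs = [
            spec("competitive", ki=1.0),
            spec("mixed", ki=2.0, alpha=3.0),
            InductionSpec(perpetrator="q", target="CYP3A4", emax=2.0, ec50=1.0),
            InhibitionSpec(
                perpetrator="r", target="CYP3A4", type="irreversible",
                kinact=0.3, KI=2.0,
            ),
        ]
        conc = [0.5, 1.5, 2.5, 3.5]
        ref = combine_perpetrators(specs, conc, S=0.3, Km=0.9)
        perm = [2, 0, 3, 1]
        out = combine_perpetrators(
            [specs[i] for i in perm], [conc[i] for i in perm], S=0.3, Km=0.9
        )
        assert out == pytest.approx(ref)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            combine_perpetrators(
                [spec("competitive"), spec("competitive", target="CYP2C9")],
                [1.0, 1.0],
            )

    def test_spec_validation_requires_constants(self):
        with pytest.raises(ValueError, match="Ki"):
            InhibitionSpec(perpetrator="p", target="CYP3A4", type="competitive")
        with pytest.raises(ValueError, match="kinact"):
            InhibitionSpec(perpetrator="p", target="CYP3A4", type="irreversible")
        with pytest.raises(ValueError, match="alpha"):
            InhibitionSpec(perpetrator="p", target="CYP3A4", type="mixed", ki=1.0)


class TestDriverConcentration:
    def test_fu_scales_venous_driver(self, individual):
        c = toy_compound(name="perp", fu=0.1)
        system = assemble_model(individual, [c])
        res = simulate(system, {"perp": Regimen.single(100, route="iv_bolus")}, 24.0)
        driver = interaction_driver_concentration(res, "perp", "venous_plasma")
        np.testing.assert_allclose(driver, 0.1 * res.plasma("perp"))

    def test_fu_one_equals_plasma(self, individual):
        c = toy_compound(name="perp", fu=1.0)
        system = assemble_model(individual, [c])
        res = simulate(system, {"perp": Regimen.single(100, route="iv_bolus")}, 24.0)
        np.testing.assert_allclose(
            interaction_driver_concentration(res, "perp", "venous_plasma"),
            res.plasma("perp"),
        )

    def test_liver_first_pass_exceeds_systemic_during_oral_absorption(
        self, individual
    ):
        c = toy_compound(name="perp", fu=0.5, ka=1.0)
        system = assemble_model(individual, [c])
        res = simulate(system, {"perp": Regimen.single(200, route="oral")}, 24.0)
        liver = interaction_driver_concentration(res, "perp", "liver")
        ven = interaction_driver_concentration(res, "perp", "venous_plasma")
        window = (res.t > 0.3) & (res.t < 1.5)  # early absorption phase
        assert np.all(liver[window] > ven[window])

    def test_unknown_site_rejected(self, individual):
        c = toy_compound(name="perp")
        system = assemble_model(individual, [c])
        res = simulate(system, {"perp": Regimen.single(10, route="iv_bolus")}, 12.0)
        with pytest.raises(KeyError):
            interaction_driver_concentration(res, "perp", "pancreas")


class TestCoupledSystem:
    def test_zero_perpetrator_dose_leaves_victim_unchanged(self, individual):
        victim = toy_compound(name="victim")
        perp = toy_inhibitor(name="perp", ki=0.01)
        reg_v = {"victim": Regimen.single(50, route="iv_bolus")}
        both = simulate(
            assemble_model(individual, [victim, perp]), reg_v, 48.0
        )
        alone = simulate(assemble_model(individual, [victim]), reg_v, 48.0)
        np.testing.assert_allclose(
            both.plasma("victim"), alone.plasma("victim"), rtol=1e-6, atol=1e-12
        )

    def test_competitive_perpetrator_raises_victim_auc(self, individual):
        victim = toy_compound(name="victim", clint_specific=20000.0, fu=0.3)
        perp = toy_inhibitor(name="perp", ki=0.5, renal_clearance=5.0)
        regs = {
            "victim": Regimen.single(50, route="iv_bolus", ),
            "perp": Regimen.repeating(200, 12, 8, route="iv_bolus"),
        }
        both = simulate(assemble_model(individual, [victim, perp]), regs, 96.0)
        alone = simulate(
            assemble_model(individual, [victim]), {"victim": regs["victim"]}, 96.0
        )
        assert auc_infinity(both, "victim") > 1.2 * auc_infinity(alone, "victim")
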