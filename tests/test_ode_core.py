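"""ODE core: rate laws, integrator, conservation, limiting behaviour."""

import numpy as np
import pytest

from phthalpbpk.chemistry import KineticConstants, default_chemistry
from phthalpbpk.dosing import DoseEvent, DoseSchedule, continuous_dose, oral_schedule
from phthalpbpk.ode_core import (
    ModelOptions,
    build_model,
    mass_balance,
    michaelis_menten_rate,
    simulate,
)
from phthalpbpk.physiology import build_default_physiology


def make_model(**option_kwargs):
    chem = default_chemistry()
    if "kinetics" in option_kwargs:
        chem.kinetics = option_kwargs.pop("kinetics")
    return build_model(
        build_default_physiology(),
        chem,
        ModelOptions(**option_kwargs),
    )


class TestMichaelisMenten:
    def test_half_saturation(self):
        assert michaelis_menten_rate(100.0, 10.0, 100.0) == pytest.approx(5.0)

    def test_saturation_limit(self):
        assert michaelis_menten_rate(1e12, 10.0, 100.0) == pytest.approx(10.0, rel=1e-9)

    def test_zero_substrate_and_disabled_reaction(self):
        assert michaelis_menten_rate(0.0, 10.0, 100.0) == 0.0
        assert michaelis_menten_rate(50.0, 0.0, 0.0) == 0.0

    def test_first_order_regime(self):
        # C << Km: v ~ (vmax/km) * C
        v = michaelis_menten_rate(1e-3, 10.0, 100.0)
        assert v == pytest.approx(10.0 / 100.0 * 1e-3, rel=1e-4)


class TestAnalyticOracle:
    def test_constant_infusion_with_first_order_loss(self):
        """The gut lumen under constant oral input is the one-compartment
        system dA/dt = R - kA with closed form (R/k)(1 - e^{-kt})."""
        model = make_model()
        R_mg_per_h, t_end = 1.2, 6.0
        schedule = DoseSchedule(
            events=[DoseEvent("oral", 0.0, t_end, R_mg_per_h * t_end)]
        )
        res = simulate(model, schedule, t_end)
        k = model.chemistry.kinetics.kgut
        R_ug = R_mg_per_h * 1000.0
        expected = (R_ug / k) * (1.0 - np.exp(-k * res.time_h))
        mask = res.time_h > 0.1  # skip the tiny-amount start-up grid points
        rel = np.abs(res.gut_lumen_ug[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 1e-6


class TestMassBalance:
    def test_oral_two_day_run_conserves_moles(self, oral_2day):
        report = mass_balance(oral_2day)
        assert report.passed
        assert report.worst_residual < 1e-6

    def test_no_metabolism_conserves_dehp_exactly(self):
        model = make_model(metabolism_enabled=False)
        res = simulate(model, oral_schedule(days=1), 24.0)
        dehp_cols = [i for k, i in model.index.items()
                     if isinstance(k, tuple) and k[0] == "DEHP"]
        total = res.amounts[:, dehp_cols].sum(axis=1) + res.gut_lumen_ug
        dosed = np.asarray(res.schedule.cumulative_input_mg(res.time_h)) * 1000
        np.testing.assert_allclose(total, dosed, rtol=1e-6, atol=1e-6)
        # and no MEHP is ever formed
        assert res.concentration("MEHP", "liver").max() == 0.0

    def test_zero_dose_stays_identically_zero(self):
        model = make_model()
        res = simulate(model, DoseSchedule(events=[]), 12.0)
        assert np.all(res.amounts == 0.0)

    def test_kurine_zero_gives_no_urine(self):
        model = make_model(kinetics=KineticConstants(kgut=7.0, kurine=0.0))
        res = simulate(model, oral_schedule(days=1), 24.0)
        assert np.all(res.cumulative_urine_mg == 0.0)
        assert mass_balance(res).passed


class TestFlowLimitedEquilibrium:
    def test_tissues_equilibrate_to_kp_times_arterial(self):
        """With arterial concentration pinned and metabolism off, every
        perfused tissue must converge to C = Kp * C_art."""
        c_art = 0.01  # ug/mL
        model = make_model(
            metabolism_enabled=False,
            frozen_arterial={"DEHP": c_art, "MEHP": c_art},
            kinetics=KineticConstants(kgut=7.0, kurine=0.0),
        )
        res = simulate(model, DoseSchedule(events=[]), 150.0)
        for species in ("DEHP", "MEHP"):
            sp = model.chemistry.species[species]
            for organ in model.organs[species] + ["lungs"]:
                expected = sp.kp(organ) * c_art
                final = res.concentration(species, organ)[-1]
                assert final == pytest.approx(expected, rel=1e-3), (species, organ)


class TestLowDoseLinearity:
    def test_trajectories_scale_linearly_far_below_km(self):
        model = make_model()
        scale = 1e-6
        # absolute tolerance scaled with the dose so no state sits at the
        # solver's noise floor
        opts = dict(rtol=1e-10, atol=1e-10 * scale)
        res1 = simulate(model, oral_schedule(total_mg_per_day=1.95 * scale), 24.0,
                        **opts)
        res2 = simulate(model, oral_schedule(total_mg_per_day=2 * 1.95 * scale),
                        24.0, **opts)
        a1, a2 = res1.amounts, res2.amounts
        # compare each state where it carries non-negligible mass
        mask = a2 > a2.max(axis=0, keepdims=True) * 1e-3
        dev = np.abs(2 * a1[mask] - a2[mask]) / a2[mask]
        assert dev.max() < 1e-3


class TestResultSurface:
    def test_concentration_is_amount_over_volume(self, oral_2day):
        v = oral_2day.model.physiology.volume("liver")
        np.testing.assert_allclose(
            oral_2day.concentration("DEHP", "liver"),
            oral_2day.amount("DEHP", "liver") / v,
        )

    def test_combined_organ_readout_is_volume_weighted(self, oral_2day):
        phys = oral_2day.model.physiology
        combined = oral_2day.concentration("MEHP", "spleen+pancreas")
        manual = (
            oral_2day.amount("MEHP", "spleen") + oral_2day.amount("MEHP", "pancreas")
        ) / (phys.volume("spleen") + phys.volume("pancreas"))
        np.testing.assert_allclose(combined, manual)

    def test_dehp_has_no_rest_of_body_state(self, oral_2day):
        with pytest.raises(KeyError):
            oral_2day.concentration("DEHP", "rest_of_body")
        # MEHP does distribute there
        assert oral_2day.concentration("MEHP", "rest_of_body").max() > 0

    def test_states_never_negative_beyond_tolerance(self, oral_2day):
        assert oral_2day.amounts.min() > -1e-6

    def test_time_grid_strictly_increasing_and_dense(self, oral_2day):
        dt = np.diff(oral_2day.time_h)
        assert (dt > 0).all()
        assert dt.max() <= 0.05 + 1e-9

    def test_urine_series_non_decreasing(self, oral_2day):
        assert (np.diff(oral_2day.cumulative_urine_mg) >= -1e-12).all()


def test_continuous_dose_reaches_positive_steady_state():
    model = make_model()
    res = simulate(model, continuous_dose("dermal", 0.68, 48.0), 48.0)
    skin = res.concentration("DEHP", "skin")
    assert skin[-1] > 0
    # approach to steady state: growth slows over time
    assert skin[-1] - skin[-241] < skin[241] - skin[0]


def test_bad_t_end_rejected():
    with pytest.raises(ValueError):
        simulate(make_model(), oral_schedule(), 0.0)
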