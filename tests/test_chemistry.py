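"""Parameter tables, capacity scaling, and Monte Carlo sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phthalpbpk.chemistry import (
    ChemistrySet,
    LognormalSpec,
    default_chemistry,
    sample_parameters,
    scale_metabolic_capacity,
)
from phthalpbpk.physiology import build_default_physiology


@pytest.fixture(scope="module")
def chem():
    return default_chemistry()


class TestDefaults:
    def test_partition_coefficients(self, chem):
        dehp = chem.species["DEHP"]
        assert dehp.partition["liver"] == 10.16
        assert dehp.partition["gut"] == 12.86
        assert dehp.partition["rest_of_body"] == 6.24
        mehp = chem.species["MEHP"]
        assert mehp.partition["liver"] == 1.7
        assert mehp.partition["rest_of_body"] == 0.38

    def test_unlisted_organs_fall_back_to_rest_of_body(self, chem):
        assert chem.species["DEHP"].kp("lungs") == 6.24
        assert chem.species["MEHP"].kp("spleen") == 0.38

    def test_kinetic_constants_and_fup(self, chem):
        assert chem.kinetics.kgut == 7.0
        assert chem.kinetics.kurine == 0.35
        assert chem.fup_mehp == 0.007

    def test_liver_m2_km(self, chem):
        assert chem.reaction("liver_M2").km_ug_per_l == 7980.4

    def test_gut_m3_is_disabled(self, chem):
        r = chem.reaction("gut_M3")
        assert r.vmax_ug_per_min_per_mg == 0.0
        assert r.km_ug_per_l == 0.0
        assert not r.enabled

    def test_twelve_reactions_with_expected_substrates(self, chem):
        assert len(chem.reactions) == 12
        dehp_rx = [r for r in chem.reactions if r.substrate == "DEHP"]
        assert {r.product for r in dehp_rx} == {"MEHP"}
        assert len(dehp_rx) == 4  # microsomal + cytosolic, gut + liver

    def test_molecular_weights(self, chem):
        assert chem.species["DEHP"].molecular_weight == 391.0
        assert chem.species["MEHP"].molecular_weight == 278.3
        labelled = default_chemistry(deuterated_mehp=True)
        assert labelled.species["MEHP"].molecular_weight == 281.0

    def test_serialization_round_trip_bit_exact(self, chem):
        clone = ChemistrySet.from_dict(chem.to_dict())
        assert clone.to_dict() == chem.to_dict()


class TestScaling:
    def test_liver_msp_hand_arithmetic(self, chem):
        scaled = scale_metabolic_capacity(
            chem.reactions, build_default_physiology()
        )
        # 0.112 ug/min/mg x 60 min/h x 40 mg/g x 1690 g
        assert scaled["liver_msp_M1"] == pytest.approx(0.112 * 60 * 40 * 1690)

    def test_disabled_reaction_scales_to_zero(self, chem):
        scaled = scale_metabolic_capacity(chem.reactions, build_default_physiology())
        assert scaled["gut_M3"] == 0.0

    def test_capacity_linear_in_tissue_mass(self, chem):
        small = build_default_physiology()
        big = build_default_physiology(overrides={"liver": {"volume_mL": 3380.0}})
        s1 = scale_metabolic_capacity(chem.reactions, small)
        s2 = scale_metabolic_capacity(chem.reactions, big)
        assert s2["liver_M2"] == pytest.approx(2 * s1["liver_M2"])

    def test_missing_protein_content_is_an_error(self, chem):
        with pytest.raises(ValueError, match="protein content"):
            scale_metabolic_capacity(
                chem.reactions, build_default_physiology(),
                protein_mg_per_g={("liver", "msp"): 40.0},
            )


class TestSampling:
    def test_same_seed_reproduces_draws(self, chem):
        a = sample_parameters(chem.lognormal, 100, seed=7)
        b = sample_parameters(chem.lognormal, 100, seed=7)
        for name in a.dtype.names:
            np.testing.assert_array_equal(a[name], b[name])

    def test_draws_truncated_to_pm_1p5_geometric_sd(self, chem):
        draws = sample_parameters(chem.lognormal, 5000, seed=1)
        for name, spec in chem.lognormal.items():
            lo = spec.median * spec.sd_factor ** -1.5
            hi = spec.median * spec.sd_factor ** 1.5
            assert draws[name].min() >= lo - 1e-12
            assert draws[name].max() <= hi + 1e-12

    def test_degenerate_sd_factor_collapses_to_median(self):
        draws = sample_parameters({"k": LognormalSpec(7.0, 1.0)}, 50, seed=0)
        np.testing.assert_array_equal(draws["k"], np.full(50, 7.0))

    def test_all_draws_positive(self, chem):
        draws = sample_parameters(chem.lognormal, 1000, seed=3)
        for name in draws.dtype.names:
            assert (draws[name] > 0).all()

    def test_nonpositive_n_rejected(self, chem):
        with pytest.raises(ValueError):
            sample_parameters(chem.lognormal, 0, seed=0)


@given(median=st.floats(1e-3, 1e3), sd=st.floats(1.01, 2.0),
       seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None)
def test_sampled_values_within_truncation_band(median, sd, seed):
    draws = sample_parameters({"p": LognormalSpec(median, sd)}, 200, seed=seed)
    assert (draws["p"] >= median * sd**-1.5 * (1 - 1e-12)).all()
    assert (draws["p"] <= median * sd**1.5 * (1 + 1e-12)).all()


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        LognormalSpec(-1.0, 1.1)
    with pytest.raises(ValueError):
        LognormalSpec(1.0, 0.9)
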