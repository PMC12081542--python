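"""Born-energy chain, barrier models, and the lipid equilibrium relation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tblmkit import (
    DomainError,
    ImageChargeBarrier,
    LipidEquilibrium,
    MembraneSpec,
    PoreProperties,
    PresetLookupError,
    RangeError,
    ValidationError,
    born_energy,
    full_chain,
    get_barrier_model,
    interfacial_free_energy,
    invert_pore_radius,
    partition_coefficient,
    per_pore_conductance,
    pore_barrier,
    pore_density,
)
from tblmkit.constants import R_GAS, ROOM_TEMPERATURE
from tblmkit.pores import ea_uncertainty_factor

from .conftest import round_1sf
from .oracles import grid_invert_radius

#: Regression value of the default barrier model at r = 3e-11 m, d = 5 nm
#: (a property of this package's documented stand-in formula, not a
#: literature value).
BARRIER_AT_3E11 = 46214.61623603161


class TestBornEnergy:
    @pytest.mark.parametrize("ea, expected", [
        (84e3, 66e3),   # xenon-loaded bilayer
        (73e3, 55e3),   # lipid-only bilayer
        (18e3, 0.0),    # boundary: barrier entirely aqueous
    ])
    def test_aqueous_term_decomposition(self, ea, expected):
        assert born_energy(ea) == expected

    def test_activation_energy_below_aqueous_term_is_domain_error(self):
        with pytest.raises(DomainError):
            born_energy(10e3)


class TestPartitionCoefficient:
    def test_66_kJ_barrier_partitions_to_2e12_at_room_temperature(self):
        gamma = partition_coefficient(66e3, ROOM_TEMPERATURE)
        assert gamma == pytest.approx(
            math.exp(-66e3 / (R_GAS * 295.15)), rel=1e-12)
        assert round_1sf(gamma) == 2e-12

    def test_zero_barrier_partitions_fully(self):
        assert partition_coefficient(0.0, 295.15) == 1.0

    def test_41_kJ_barrier_direct_evaluation(self):
        assert partition_coefficient(41e3, 295.15) == pytest.approx(
            5.5e-8, rel=0.01)

    @given(w1=st.floats(1e3, 1e5), dw=st.floats(1e2, 5e4),
           t=st.floats(250, 350), dt=st.floats(1, 50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_decreasing_in_barrier_increasing_in_temperature(self, w1, dw,
                                                             t, dt):
        assert partition_coefficient(w1 + dw, t) < \
            partition_coefficient(w1, t)
        assert partition_coefficient(w1, t + dt) > \
            partition_coefficient(w1, t)


class TestPoreConductance:
    def test_reconstructs_reference_specific_pore_conductivity(
            self, membrane_spec):
        """gamma ~2e-12 through a 0.03 nm pore in a 5 nm bilayer, normalized
        by the electrode area, lands on the reference ~9e-19 S/m^2."""
        gamma = partition_coefficient(66e3, ROOM_TEMPERATURE)
        g = per_pore_conductance(gamma, membrane_spec, 3e-11)
        assert round_1sf(g / membrane_spec.area) == 9e-19

    def test_zero_partition_means_zero_conductance(self, membrane_spec):
        assert per_pore_conductance(0.0, membrane_spec, 3e-11) == 0.0

    def test_doubling_radius_quadruples_conductance(self, membrane_spec):
        g1 = per_pore_conductance(1e-12, membrane_spec, 3e-11)
        g2 = per_pore_conductance(1e-12, membrane_spec, 6e-11)
        assert g2 == pytest.approx(4 * g1, rel=1e-12)

    def test_pore_density_reconstructs_reference_count(self, membrane_spec):
        gamma = partition_coefficient(66e3, ROOM_TEMPERATURE)
        g = per_pore_conductance(gamma, membrane_spec, 3e-11)
        n = pore_density(9e-7 / 2.1e-6, g)
        assert round_1sf(n) == 2e23

    def test_pore_density_inverse_identity(self):
        n = pore_density(0.4286, 1.86e-24)
        assert n * 1.86e-24 == pytest.approx(0.4286, rel=1e-15)

    def test_zero_membrane_conductance_means_zero_pores(self):
        assert pore_density(0.0, 1e-24) == 0.0

    def test_zero_per_pore_conductance_is_a_domain_error(self):
        with pytest.raises(DomainError, match="per_pore"):
            pore_density(0.4, 0.0)


class TestBarrierModel:
    def test_barrier_decreases_with_radius(self, membrane_spec):
        for r in np.geomspace(1e-12, 5e-9, 20):
            assert pore_barrier(2 * r, membrane_spec) < \
                pore_barrier(r, membrane_spec)

    def test_default_model_regression_value(self, membrane_spec):
        assert pore_barrier(3e-11, membrane_spec) == pytest.approx(
            BARRIER_AT_3E11, rel=1e-9)

    def test_model_documents_itself(self):
        m = get_barrier_model("image-charge")
        assert "W(r)" in m.formula
        assert m.citation

    def test_unknown_model_lookup_error(self, membrane_spec):
        with pytest.raises(PresetLookupError, match="image-charge"):
            pore_barrier(1e-10, membrane_spec, model="no_such_model")

    @pytest.mark.parametrize("radius", np.geomspace(1e-11, 1e-9, 7))
    def test_invert_round_trip_identity(self, membrane_spec, radius):
        w = pore_barrier(radius, membrane_spec)
        back = invert_pore_radius(w, membrane_spec)
        assert back == pytest.approx(radius, rel=1e-9)

    def test_larger_barrier_inverts_to_smaller_radius(self, membrane_spec):
        r1 = invert_pore_radius(40e3, membrane_spec)
        r2 = invert_pore_radius(66e3, membrane_spec)
        assert r2 < r1

    def test_inversion_agrees_with_dense_grid_oracle(self, membrane_spec):
        target = 66e3
        root = invert_pore_radius(target, membrane_spec)
        grid_r, step = grid_invert_radius(target, membrane_spec,
                                          ImageChargeBarrier)
        assert abs(root - grid_r) <= step

    def test_target_outside_attainable_range_reports_bounds(
            self, membrane_spec):
        with pytest.raises(RangeError, match="W\\(r_min\\)"):
            invert_pore_radius(1e9, membrane_spec)


class TestInterfacialFreeEnergy:
    def test_equal_chemical_potentials_and_unit_fraction_give_zero(self):
        eq = LipidEquilibrium(mu_monomer_std=1e-20, mu_bilayer_std=1e-20,
                              mole_fraction_monomer=1.0,
                              area_per_molecule=6e-19)
        assert interfacial_free_energy(eq) == 0.0

    def test_one_kT_difference_over_typical_lipid_area(self):
        eq = LipidEquilibrium(mu_monomer_std=4.07e-21, mu_bilayer_std=0.0,
                              mole_fraction_monomer=1.0,
                              area_per_molecule=6e-19, temperature=295.0)
        gamma_m = interfacial_free_energy(eq)
        assert gamma_m == pytest.approx(4.07e-21 / 6e-19, rel=1e-12)
        assert f"{gamma_m:.2g}" == "0.0068"

    def test_shrinking_area_per_molecule_raises_surface_energy(self):
        """The xenon argument: tighter lipid packing (smaller a) increases
        gamma_m at a fixed chemical-potential difference."""
        def gamma(a):
            return interfacial_free_energy(LipidEquilibrium(
                mu_monomer_std=4e-21, mu_bilayer_std=0.0,
                mole_fraction_monomer=1.0, area_per_molecule=a))
        assert gamma(4e-19) > gamma(6e-19)

    def test_negative_energy_warns_but_returns(self):
        eq = LipidEquilibrium(mu_monomer_std=0.0, mu_bilayer_std=4e-21,
                              mole_fraction_monomer=1.0,
                              area_per_molecule=6e-19)
        with pytest.warns(UserWarning, match="negative"):
            assert interfacial_free_energy(eq) < 0

    @pytest.mark.parametrize("kwargs, field", [
        (dict(mu_monomer_std=0, mu_bilayer_std=0, mole_fraction_monomer=1.0,
              area_per_molecule=0.0), "area_per_molecule"),
        (dict(mu_monomer_std=0, mu_bilayer_std=0, mole_fraction_monomer=1.5,
              area_per_molecule=6e-19), "mole_fraction_monomer"),
    ])
    def test_validation_names_offending_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            LipidEquilibrium(**kwargs)


class TestFullChain:
    def test_xenon_row_reproduced_from_84_kJ_and_measured_conductance(
            self, membrane_spec):
        """84 kJ/mol and G_m = 0.4286 S/m^2 with the reported 0.03 nm radius
        give the reference Born energy, partition coefficient, pore
        conductivity and pore count (to their 1 s.f. printing)."""
        props = full_chain(84e3, 9e-7 / 2.1e-6, spec=membrane_spec,
                           radius=3e-11)
        assert props.born_energy == 66e3
        assert round_1sf(props.partition_coefficient) == 2e-12
        assert round_1sf(props.specific_pore_conductivity) == 9e-19
        assert round_1sf(props.pore_density) == 2e23

    def test_barrier_free_limit(self, membrane_spec):
        gm = 0.4286
        r = 3e-11
        props = full_chain(18e3, gm, spec=membrane_spec, radius=r)
        assert props.partition_coefficient == 1.0
        expected_n = gm / (membrane_spec.electrolyte_conductivity
                           * math.pi * r ** 2 / membrane_spec.thickness)
        assert props.pore_density == pytest.approx(expected_n, rel=1e-12)

    def test_closed_loop_identity_holds_everywhere(self, membrane_spec):
        for ea, gm in [(84e3, 0.4286), (73e3, 0.1), (30e3, 5.0)]:
            props = full_chain(ea, gm, spec=membrane_spec, radius=3e-11)
            assert props.pore_density * props.per_pore_conductance == \
                pytest.approx(gm, rel=1e-12)

    def test_radius_inverted_when_not_supplied(self, membrane_spec):
        props = full_chain(84e3, 0.4286, spec=membrane_spec)
        assert props.pore_radius == pytest.approx(
            invert_pore_radius(66e3, membrane_spec), rel=1e-12)

    def test_ea_uncertainty_swings_partition_fivefold(self):
        """The +/- 4 kJ/mol on Ea maps to a factor exp(4000/RT) ~ 5 on the
        partition coefficient and everything downstream of it."""
        f = ea_uncertainty_factor(4e3, ROOM_TEMPERATURE)
        assert f == pytest.approx(math.exp(4e3 / (R_GAS * 295.15)),
                                  rel=1e-12)
        assert f == pytest.approx(5.1, abs=0.1)
        lo = full_chain(80e3, 0.4286, radius=3e-11)
        hi = full_chain(88e3, 0.4286, radius=3e-11)
        ratio = lo.partition_coefficient / hi.partition_coefficient
        assert ratio == pytest.approx(f * f, rel=1e-9)

    def test_self_consistency_invariant_enforced(self):
        with pytest.raises(ValidationError, match="pore_density"):
            PoreProperties(
                born_energy=66e3, partition_coefficient=2e-12,
                pore_radius=3e-11, per_pore_conductance=1.9e-24,
                specific_pore_conductivity=9e-19,
                pore_density=1e23,  # inconsistent with G_m below
                membrane_conductance_specific=0.4286,
            )

    def test_membrane_spec_validation(self):
        with pytest.raises(ValidationError, match="eps_water"):
            MembraneSpec(eps_water=1.5, eps_membrane=2.2)
        with pytest.raises(ValidationError, match="thickness"):
            MembraneSpec(thickness=0.0)
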