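"""Boltzmann weighting, Gaussian band convolution and configuration calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirokit import (
    BandShapeParams,
    ConformerRecord,
    Transition,
    assign_configuration,
    boltzmann_weights,
    mirror_conformers,
    simulate_ecd,
)
from chirokit.ecdsim import (
    CGS_PREFACTOR,
    EV_NM,
    KB_KCAL_MOL_K,
    read_spectrum,
    read_transition_tables,
    write_spectrum,
    write_transition_tables,
)
from chirokit.exceptions import (
    IndeterminateAssignmentError,
    RangeError,
    ValidationError,
)


def single_transition(energy=EV_NM / 250.0, strength=10.0):
    return [ConformerRecord("c0", 0.0, (Transition(energy, strength),))]


class TestBoltzmannWeights:
    def test_equal_energies_share_population(self):
        np.testing.assert_allclose(boltzmann_weights([1.0] * 4), [0.25] * 4)

    def test_rt_ln2_gap_gives_two_to_one(self):
        gap = KB_KCAL_MOL_K * 298.15 * math.log(2.0)
        w = boltzmann_weights([0.0, gap])
        np.testing.assert_allclose(w, [2.0 / 3.0, 1.0 / 3.0], rtol=1e-12)

    def test_zero_temperature_limit(self):
        w = boltzmann_weights([0.0, 1.0], temperature=1.0)
        assert w[0] == pytest.approx(1.0, abs=1e-9)
        assert w[1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_energy_list_rejected(self):
        with pytest.raises(ValidationError):
            boltzmann_weights([])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        energies=st.lists(st.floats(0.0, 50.0, allow_nan=False), min_size=1, max_size=20),
        temperature=st.floats(1.0, 1000.0, allow_nan=False),
    )
    def test_weights_normalized_and_monotone(self, energies, temperature):
        w = boltzmann_weights(energies, temperature)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(energies)
        sorted_w = w[order]
        assert np.all(np.diff(sorted_w) <= 1e-15)  # lower energy never less populated


class TestSimulateECD:
    def params(self, **kw):
        defaults = dict(sigma=0.35, grid_min=180.0, grid_max=400.0, grid_step=0.5)
        defaults.update(kw)
        return BandShapeParams(**defaults)

    def test_zero_strengths_give_zero_spectrum(self):
        conformers = [ConformerRecord("c0", 0.0, (Transition(4.0, 0.0), Transition(5.0, 0.0)))]
        spec = simulate_ecd(conformers, self.params())
        assert np.all(spec.delta_epsilon == 0.0)

    def test_single_transition_peak_value_matches_formula(self):
        # Delta-eps at band centre = E*R / (2.297e-39 * sqrt(pi) * sigma) with R in cgs
        energy = EV_NM / 250.0
        spec = simulate_ecd(single_transition(energy, 10.0), self.params())
        expected = energy * 10.0e-40 / (CGS_PREFACTOR * math.sqrt(math.pi) * 0.35)
        assert expected == pytest.approx(3.48, abs=0.01)  # hand value at 250 nm
        assert spec.value_at(250.0) == pytest.approx(expected, rel=1e-9)
        apex = spec.wavelength[np.argmax(spec.delta_epsilon)]
        assert apex == pytest.approx(250.0, abs=0.5)

    def test_enantiomer_spectrum_is_pointwise_negation(self):
        from chirokit import gen_transition_table

        conformers = gen_transition_table(n_conformers=3, n_transitions=10, seed=11)
        spec = simulate_ecd(conformers, self.params())
        mirror_spec = simulate_ecd(mirror_conformers(conformers), self.params())
        np.testing.assert_allclose(mirror_spec.delta_epsilon, -spec.delta_epsilon, atol=1e-12)

    def test_band_area_over_energy_recovers_rotational_strength(self):
        # integral of Delta-eps dE = E_i * R_i / 2.297e-39 (Gaussian normalization)
        energy, strength = EV_NM / 250.0, 10.0
        spec = simulate_ecd(
            single_transition(energy, strength), self.params(grid_step=0.1)
        )
        e_grid = EV_NM / spec.wavelength
        order = np.argsort(e_grid)
        area = np.trapezoid(spec.delta_epsilon[order], e_grid[order])
        expected = energy * strength * 1e-40 / CGS_PREFACTOR
        assert area == pytest.approx(expected, rel=0.005)

    def test_grid_refinement_does_not_change_shared_points(self):
        conformers = single_transition()
        coarse = simulate_ecd(conformers, self.params(grid_step=1.0))
        fine = simulate_ecd(conformers, self.params(grid_step=0.5))
        shared = np.isin(fine.wavelength, coarse.wavelength)
        np.testing.assert_allclose(
            fine.delta_epsilon[shared], coarse.delta_epsilon, rtol=0, atol=1e-15
        )

    def test_conformer_average_matches_hand_weighting(self):
        gap = 1.0
        conformers = [
            ConformerRecord("a", 0.0, (Transition(4.0, 5.0),)),
            ConformerRecord("b", gap, (Transition(5.5, -20.0),)),
        ]
        params = self.params()
        combined = simulate_ecd(conformers, params)
        w = boltzmann_weights([0.0, gap], params.temperature)
        spec_a = simulate_ecd([conformers[0]], params)
        spec_b = simulate_ecd([ConformerRecord("b", 0.0, conformers[1].transitions)], params)
        np.testing.assert_allclose(
            combined.delta_epsilon,
            w[0] * spec_a.delta_epsilon + w[1] * spec_b.delta_epsilon,
            rtol=1e-12,
            atol=1e-15,
        )


class TestAssignConfiguration:
    def test_matching_positive_sign_calls_r(self):
        spec = simulate_ecd(single_transition(strength=10.0), BandShapeParams())
        call = assign_configuration("positive", 250.0, spec)
        assert call.configuration == "R"
        assert call.delta_epsilon_sim > 0

    def test_opposite_sign_calls_s(self):
        spec = simulate_ecd(single_transition(strength=10.0), BandShapeParams())
        assert assign_configuration("negative", 250.0, spec).configuration == "S"

    def test_zero_amplitude_is_indeterminate(self):
        spec = simulate_ecd(
            [ConformerRecord("c0", 0.0, (Transition(4.9594, 0.0),))], BandShapeParams()
        )
        with pytest.raises(IndeterminateAssignmentError):
            assign_configuration("positive", 250.0, spec)

    def test_weak_tail_below_floor_is_indeterminate(self):
        spec = simulate_ecd(single_transition(strength=10.0), BandShapeParams())
        with pytest.raises(IndeterminateAssignmentError):
            assign_configuration("positive", 399.0, spec)  # far from the band

    def test_wavelength_outside_grid_raises(self):
        spec = simulate_ecd(single_transition(), BandShapeParams())
        with pytest.raises(RangeError):
            assign_configuration("positive", 500.0, spec)


class TestIO:
    def test_transition_table_roundtrip(self, tmp_path):
        from chirokit import gen_transition_table

        records = gen_transition_table(n_conformers=2, n_transitions=5, seed=3)
        path = tmp_path / "tt.csv"
        write_transition_tables(records, path)
        back = read_transition_tables(path)
        assert [c.conformer_id for c in back] == [c.conformer_id for c in records]
        for a, b in zip(records, back):
            assert a.relative_energy == pytest.approx(b.relative_energy)
            for ta, tb in zip(a.transitions, b.transitions):
                assert ta.energy == pytest.approx(tb.energy)
                assert ta.rotational_strength == pytest.approx(tb.rotational_strength)

    def test_spectrum_roundtrip(self, tmp_path):
        spec = simulate_ecd(single_transition(), BandShapeParams())
        path = tmp_path / "spec.csv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.delta_epsilon, spec.delta_epsilon, rtol=1e-8)
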