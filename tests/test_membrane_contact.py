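import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmem import (ContactParams, HydrophobicityScale, MembraneSlab,
                   alpha_membrane, burial_switch, contact_energy_z,
                   local_density, make_helix_fixture, membrane_burial_energy,
                   pair_contact_energy)
from cgmem.membrane_contact import (interaction_well, load_gamma_matrix,
                                    save_gamma_matrix)

from conftest import pair_system


class TestAlphaMembrane:
    def test_deep_inside_is_one(self):
        assert alpha_membrane(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_at_boundary_is_half(self):
        # one tanh term vanishes exactly at z = b
        assert alpha_membrane(15.0) == pytest.approx(0.5, abs=1e-12)

    def test_far_outside_vanishes(self):
        assert alpha_membrane(50.0) < 1e-12

    @given(st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_even_bounded_decreasing(self, z):
        a = alpha_membrane(z)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(alpha_membrane(-z), abs=1e-12)
        assert alpha_membrane(abs(z) + 1.0) <= a + 1e-12


class TestBurialSwitch:
    def test_limits(self):
        assert burial_switch(0.0) == pytest.approx(1.0, abs=1e-10)
        assert burial_switch(15.0) == pytest.approx(0.5, abs=1e-12)
        assert burial_switch(60.0) < 1e-12

    @given(st.floats(-80, 80))
    @settings(max_examples=50, deadline=None)
    def test_even_and_bounded(self, z):
        v = burial_switch(z)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(burial_switch(-z), abs=1e-12)


class TestLocalDensity:
    def test_isolated_residue_zero(self):
        cg = pair_system(100.0)
        assert local_density(cg, 0) < 1e-12

    def test_neighbor_at_well_center(self):
        cg = pair_system(5.5)
        # direct evaluation of the window at the center of [4.5, 6.5]
        expect = interaction_well(5.5, 4.5, 6.5, 5.0)
        assert local_density(cg, 0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.0, abs=1e-4)

    def test_far_neighbor_negligible(self):
        cg = pair_system(20.0)
        assert local_density(cg, 0) < 1e-6

    def test_adjacent_residues_excluded(self):
        cg = pair_system(5.5, sep=1)
        assert local_density(cg, 0) == 0.0


class TestPairContactEnergy:
    def test_far_pair_zero(self, random_params):
        cg = pair_system(30.0)
        for env in ("water", "membrane"):
            assert abs(pair_contact_energy(cg, 0, 1, env, random_params)) < 1e-6

    def test_zero_matrices_give_zero(self):
        cg = pair_system(5.5)
        params = ContactParams.uniform(0.0)
        assert pair_contact_energy(cg, 0, 1, "water", params) == 0.0

    def test_direct_well_low_density(self):
        cg = pair_system(5.5)
        params = ContactParams.direct_only(1.0)
        v = pair_contact_energy(cg, 0, 1, "water", params)
        assert v == pytest.approx(-1.0, abs=2e-4)

    def test_close_sequence_pair_rejected(self, random_params):
        cg = pair_system(5.5, sep=5)
        with pytest.raises(ValueError):
            pair_contact_energy(cg, 0, 1, "water", random_params)


def brute_force_contact(cg, params, slab):
    """Independent re-derivation: explicit loops straight from the formulas."""
    cb = cg.cb_positions()
    z = cg.ca_positions()[:, 2]
    L = cg.L
    rho = np.zeros(L)
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            sep = cg.sequence_separation(i, j)
            if sep is not None and sep < 2:
                continue
            r = np.linalg.norm(cb[i] - cb[j])
            rho[i] += 0.25 * (1 + np.tanh(params.eta_c * (r - params.r_min_I))) \
                * (1 + np.tanh(params.eta_c * (params.r_max_I - r)))
    sig = 0.5 * (1 + np.tanh(params.eta_sigma * (params.rho_0 - rho)))
    aa = [params.index(t) for t in cg.res_types]
    total = 0.0
    for i in range(L):
        for j in range(i + 1, L):
            sep = cg.sequence_separation(i, j)
            if sep is not None and sep <= 9:
                continue
            r = np.linalg.norm(cb[i] - cb[j])
            tI = 0.25 * (1 + np.tanh(params.eta_c * (r - params.r_min_I))) \
                * (1 + np.tanh(params.eta_c * (params.r_max_I - r)))
            tII = 0.25 * (1 + np.tanh(params.eta_c * (r - params.r_min_II))) \
                * (1 + np.tanh(params.eta_c * (params.r_max_II - r)))
            s_ij = sig[i] * sig[j]

            def env(direct, protein, water):
                med = s_ij * water[aa[i], aa[j]] + (1 - s_ij) * protein[aa[i], aa[j]]
                return -direct[aa[i], aa[j]] * tI - tII * med

            vw = env(params.gamma_direct_wat, params.gamma_protein_wat,
                     params.gamma_water_wat)
            vm = env(params.gamma_direct_mem, params.gamma_protein_mem,
                     params.gamma_water_mem)
            ai = 0.5 * (np.tanh(slab.eta * (z[i] + slab.b))
                        + np.tanh(slab.eta * (slab.b - z[i])))
            aj = 0.5 * (np.tanh(slab.eta * (z[j] + slab.b))
                        + np.tanh(slab.eta * (slab.b - z[j])))
            total += (1 - ai * aj) * vw + params.k_relative * ai * aj * vm
    return total


class TestContactEnergyZ:
    def test_matches_brute_force_oracle(self, varied_helix, random_params, slab):
        total, _ = contact_energy_z(varied_helix, random_params, slab)
        assert total == pytest.approx(
            brute_force_contact(varied_helix, random_params, slab), rel=1e-10)

    def test_buried_system_uses_membrane_matrices(self, random_params, slab):
        # helix along x at z=0: every alpha ~ 1
        cg = make_helix_fixture(25, axis=(1, 0, 0), sequence="W" * 25)
        total, br = contact_energy_z(cg, random_params, slab)
        assert np.all(br.alpha_weight > 1 - 1e-10)
        assert total == pytest.approx(np.sum(br.v_membrane), rel=1e-6)

    def test_aqueous_system_uses_water_matrices(self, random_params, slab):
        cg = make_helix_fixture(25, axis=(1, 0, 0), z_offset=100.0,
                                sequence="W" * 25)
        total, br = contact_energy_z(cg, random_params, slab)
        assert np.all(br.alpha_weight < 1e-10)
        assert total == pytest.approx(np.sum(br.v_water), rel=1e-6)

    def test_split_pair_interacts_as_in_water(self, random_params, slab):
        # one partner deep inside, the other far outside: membrane weight ~ 0
        cg = pair_system(5.5)
        coords = cg.coords.copy()
        coords[2:, 2] += 100.0  # second residue far above the slab
        cg = cg.with_coords(coords)
        _, br = contact_energy_z(cg, random_params, slab)
        assert br.alpha_weight[0] < 1e-10

    def test_collapses_when_environments_identical(self, varied_helix, slab):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 20))
        g = (a + a.T) / 2
        params = ContactParams(g, g * 0.5, g * 0.2, g, g * 0.5, g * 0.2,
                               k_relative=1.0)
        total, br = contact_energy_z(varied_helix, params, slab)
        env_free = float(np.sum(br.v_water))  # plain contact sum
        assert total == pytest.approx(env_free, rel=1e-10)

    def test_invariance_under_xy_translation_and_z_rotation(
            self, varied_helix, random_params, slab):
        total, _ = contact_energy_z(varied_helix, random_params, slab)
        moved = varied_helix.translated((13.0, -7.0, 0.0))
        t = np.radians(73.0)
        Rz = np.array([[np.cos(t), -np.sin(t), 0],
                       [np.sin(t), np.cos(t), 0], [0, 0, 1]])
        moved = moved.rotated(Rz)
        total2, _ = contact_energy_z(moved, random_params, slab)
        assert total2 == pytest.approx(total, rel=1e-9)


class TestMembraneBurial:
    def test_far_outside_negligible(self, surface_helix):
        scale = HydrophobicityScale.wimley_white_octanol()
        assert abs(membrane_burial_energy(surface_helix, scale)) < 1e-10

    def test_single_buried_residue(self):
        cg = pair_system(100.0)  # both residues at z ~ 0
        scale = HydrophobicityScale.uniform(-2.0)
        e = membrane_burial_energy(cg, scale)
        assert e == pytest.approx(-4.0, abs=1e-9)  # two residues, theta ~ 1

    def test_zero_scale_gives_zero(self, membrane_helix):
        assert membrane_burial_energy(
            membrane_helix, HydrophobicityScale.uniform(0.0)) == 0.0

    def test_missing_residue_type_raises(self, membrane_helix):
        bad = HydrophobicityScale.wimley_white_octanol()
        del bad.values["A"]
        with pytest.raises(ValueError):
            membrane_burial_energy(membrane_helix, bad)


class TestParameterFiles:
    def test_gamma_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 20))
        g = (a + a.T) / 2
        p = tmp_path / "gamma.txt"
        save_gamma_matrix(g, p)
        assert np.allclose(load_gamma_matrix(p), g, atol=1e-6)

    def test_asymmetric_matrix_rejected(self, tmp_path):
        m = np.zeros((20, 20))
        m[0, 1] = 1.0
        with pytest.raises(ValueError):
            ContactParams(m, m, m, m, m, m)

    def test_octanol_scale_complete(self):
        scale = HydrophobicityScale.wimley_white_octanol()
        assert len(scale.values) == 20
        assert scale["W"] < 0 < scale["K"]  # Trp likes the membrane; Lys does not
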