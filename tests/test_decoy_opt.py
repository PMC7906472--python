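import numpy as np
import pytest

from cgmem import (ContactParams, HydrophobicityScale, MembraneSlab,
                   contact_energy_z, generate_decoys, make_helix_fixture,
                   optimize_coefficients, phi_features, select_training,
                   weighted_decoy_average, z_score)
from cgmem.decoy_opt import PAPER_ANGLES, PAPER_SHIFTS


def planted_entry(rng, k_target, n=200, scales=(2.0, 1.0, 1.5), noise=0.0):
    """Decoy features whose empirical optimum direction is exactly k_target.

    Native = decoy mean - C @ k_target with C the empirical covariance, so
    maximizing (mean - native) . k / sqrt(k' C k) recovers k_target.
    """
    X = rng.normal(0, 1, (n, 3)) @ np.diag(scales)
    if noise:
        X += rng.normal(0, noise, X.shape)
    m = X.mean(axis=0)
    C = np.cov(X.T, bias=True)
    native = m - C @ np.asarray(k_target, dtype=float)
    return native, (X, np.zeros(n))


def grid_search_oracle(entries, step=0.1, top=10.0):
    best_k, best_val = None, -np.inf
    ks = np.arange(0.0, top + 1e-9, step)
    for k2 in ks:
        for k3 in ks:
            val = np.mean([-z_score([1.0, k2, k3], nat, f, t)
                           for nat, (f, t) in entries])
            if val > best_val:
                best_val, best_k = val, (k2, k3)
    return best_k, best_val


class TestGenerateDecoys:
    def test_canonical_grid_yields_240(self, membrane_helix):
        ds = generate_decoys(membrane_helix, PAPER_ANGLES, PAPER_SHIFTS)
        assert len(ds) == len(PAPER_ANGLES) * len(PAPER_SHIFTS) == 240

    def test_identity_decoy_has_unit_theta(self, membrane_helix):
        ds = generate_decoys(membrane_helix, angles=[0.0], shifts=[0.0])
        assert ds.theta_d[0] == 1.0 and ds.weights[0] == 0.0
        assert np.allclose(ds.coords[0], membrane_helix.coords)

    def test_large_shift_flips_every_burial_assignment(self):
        cg = make_helix_fixture(12, axis=(1, 0, 0))  # fully inside the slab
        ds = generate_decoys(cg, angles=[0.0], shifts=[40.0])
        assert ds.theta_d[0] == 0.0 and ds.weights[0] == 1.0

    def test_empty_grid_rejected(self, membrane_helix):
        with pytest.raises(ValueError):
            generate_decoys(membrane_helix, angles=[], shifts=[0.0])

    def test_deterministic(self, membrane_helix):
        a = generate_decoys(membrane_helix, angles=[30.0], shifts=[8.0])
        b = generate_decoys(membrane_helix, angles=[30.0], shifts=[8.0])
        assert np.array_equal(a.coords[0], b.coords[0])


class TestPhiFeatures:
    def test_aqueous_structure_has_no_membrane_terms(self, surface_helix,
                                                     random_params, slab):
        scale = HydrophobicityScale.wimley_white_octanol()
        _, phi_mem, phi_burial = phi_features(surface_helix, random_params,
                                              slab, scale)
        assert abs(phi_mem) < 1e-8 and abs(phi_burial) < 1e-8

    def test_buried_structure_has_no_water_term(self, random_params, slab):
        cg = make_helix_fixture(25, axis=(1, 0, 0), sequence="F" * 25)
        scale = HydrophobicityScale.wimley_white_octanol()
        phi_wat, _, _ = phi_features(cg, random_params, slab, scale)
        assert abs(phi_wat) < 1e-6

    def test_decomposition_matches_contact_energy(self, varied_helix,
                                                  random_params, slab):
        scale = HydrophobicityScale.uniform(0.0)
        phi_wat, phi_mem, _ = phi_features(varied_helix, random_params, slab,
                                           scale)
        total, _ = contact_energy_z(varied_helix, random_params, slab)
        assert phi_wat + random_params.k_relative * phi_mem == pytest.approx(
            total, rel=1e-12)


class TestWeightedAverage:
    def test_zero_theta_is_plain_mean(self):
        assert weighted_decoy_average([1.0, 2.0, 6.0], [0, 0, 0]) == pytest.approx(3.0)

    def test_unit_theta_decoy_contributes_nothing(self):
        assert weighted_decoy_average([5.0, 1000.0], [0.0, 1.0]) == 5.0

    def test_equal_weights(self):
        assert weighted_decoy_average([2.0, 4.0], [0.5, 0.5]) == pytest.approx(3.0)

    def test_all_unit_theta_rejected(self):
        with pytest.raises(ValueError):
            weighted_decoy_average([1.0, 2.0], [1.0, 1.0])


class TestZScore:
    def test_native_at_decoy_mean_is_zero(self):
        feats = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert z_score([1, 0, 0], [2.0, 0, 0], feats, [0, 0]) == pytest.approx(0.0)

    def test_population_sigma_arithmetic(self):
        feats = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        z = z_score([1, 0, 0], [0.0, 0, 0], feats, [0, 0, 0])
        assert z == pytest.approx(-2.0 / np.std([1, 2, 3]), rel=1e-12)
        assert z == pytest.approx(-2.449489742783178, rel=1e-12)

    def test_scale_invariance_of_coefficients(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(0, 1, (20, 3))
        native = rng.normal(0, 1, 3)
        theta = rng.uniform(0, 0.9, 20)
        z1 = z_score([1.0, 2.0, 0.5], native, feats, theta)
        z2 = z_score([3.0, 6.0, 1.5], native, feats, theta)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_zero_variance_rejected(self):
        feats = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            z_score([1, 0, 0], [0, 0, 0], feats, [0, 0])

    def test_too_few_weighted_decoys_rejected(self):
        feats = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            z_score([1, 0, 0], [0, 0, 0], feats, [1.0, 0.3])


class TestOptimizeCoefficients:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        entries = [planted_entry(rng, [1.0, 3.3, 3.3]),
                   planted_entry(rng, [1.0, 3.0, 3.5])]
        (gk2, gk3), gval = grid_search_oracle(entries)
        res = optimize_coefficients(entries)
        assert abs(res.coefficients[1] - gk2) <= 0.1 + 1e-9
        assert abs(res.coefficients[2] - gk3) <= 0.1 + 1e-9
        assert -res.z >= gval - 1e-6  # polish can only improve on the grid

    def test_recovers_planted_direction_within_five_percent(self):
        rng = np.random.default_rng(11)
        res = optimize_coefficients([planted_entry(rng, [1.0, 2.0, 0.5])])
        assert res.coefficients[1] == pytest.approx(2.0, rel=0.05)
        assert res.coefficients[2] == pytest.approx(0.5, rel=0.05)

    def test_boundary_optimum_recovered(self):
        rng = np.random.default_rng(13)
        res = optimize_coefficients([planted_entry(rng, [1.0, 2.0, 0.0])])
        assert res.coefficients[1] == pytest.approx(2.0, rel=0.05)
        assert res.coefficients[2] == pytest.approx(0.0, abs=0.05)

    def test_noisy_direction_cosine_similarity(self):
        rng = np.random.default_rng(21)
        target = np.array([1.0, 3.3, 3.3])
        entries = [planted_entry(rng, target, n=400, noise=0.3)
                   for _ in range(3)]
        res = optimize_coefficients(entries)
        k = np.asarray(res.coefficients)
        cos = k @ target / (np.linalg.norm(k) * np.linalg.norm(target))
        assert cos > 0.95

    def test_uninformative_features_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 3))
        native = X.mean(axis=0)
        res = optimize_coefficients([(native, (X, np.zeros(60)))])
        assert res.degenerate
        assert abs(res.z) < 1e-6

    def test_signed_z_is_funneled(self):
        rng = np.random.default_rng(5)
        res = optimize_coefficients([planted_entry(rng, [1.0, 1.0, 1.0])])
        assert res.z < 0  # native below the decoy mean


class TestSelectTraining:
    def test_chi_and_length_filters(self):
        kept = make_helix_fixture(100, axis=(1, 0, 0), z_offset=14.0)
        # helix along x near the slab edge: some residues in, some out
        assert 0.2 <= np.mean(
            np.abs(kept.ca_positions()[:, 2]) < 15) <= 0.8
        dropped_chi = make_helix_fixture(20, z_offset=100.0)  # chi = 0
        out = select_training([kept, dropped_chi])
        assert out == [kept]

    def test_long_protein_dropped(self):
        long = make_helix_fixture(2500, axis=(1, 0, 0))
        assert select_training([long]) == []
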