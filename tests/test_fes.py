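"""Frame reweighting, distance features, PCA, the surface and its minima."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import zwitterphase as zp
from zwitterphase import fes as F
from zwitterphase.datatypes import FrameSet
from zwitterphase.errors import MappingError

from ._oracles import brute_force_two_state_delta_f

KBT = zp.kbt_kj_per_mol()


def frameset(n, coords=None, window=0, v_z=None, v_r=None, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = rng.normal(0.5, 0.2, size=(n, 6, 3))
    z = np.linalg.norm(coords[:, 3:].mean(axis=1) - coords[:, :3].mean(axis=1), axis=1)
    return FrameSet(
        coords=coords, window_index=np.full(n, window),
        z=z, v_z=np.zeros(n) if v_z is None else np.asarray(v_z, float),
        v_r=np.zeros(n) if v_r is None else np.asarray(v_r, float),
        labels=None if labels is None else np.asarray(labels),
    )


class TestFrameWeights:
    def test_no_bias_single_window_is_uniform(self):
        fs = frameset(50)
        w = zp.frame_weights(fs, {0: 0.0})
        assert np.allclose(w.weights, 1 / 50)
        assert w.retained.all()

    def test_exclusion_rule_is_exact_at_the_threshold(self):
        """Retained set == {j : V_z + V_r <= 4 kBT}, straddling fixtures."""
        v_tot_kbt = np.array([0.0, 3.999999, 4.0, 4.0 + 1e-12, 4.000001, 5.0, 9.0])
        n = v_tot_kbt.size
        fs = frameset(n, v_z=v_tot_kbt * KBT * 0.25, v_r=v_tot_kbt * KBT * 0.75)
        w = zp.frame_weights(fs, {0: 0.0})
        expected = (fs.v_z + fs.v_r) / KBT <= 4.0
        np.testing.assert_array_equal(w.retained, expected)
        assert w.weights[~w.retained].sum() == 0.0

    def test_one_kbt_bias_gives_e_fold_weight_ratio(self):
        fs = frameset(2, v_z=np.array([0.0, KBT]))
        w = zp.frame_weights(fs, {0: 0.0})
        assert w.weights[1] / w.weights[0] == pytest.approx(np.e, rel=1e-9)

    def test_alignment_constant_cancels_within_a_window(self):
        fs = frameset(4, v_z=np.array([0.0, 1.0, 2.0, 3.0]))
        a = zp.frame_weights(fs, {0: 0.0}).weights
        b = zp.frame_weights(fs, {0: 5.0}).weights
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_unknown_window_raises_mapping_error(self):
        fs = frameset(3, window=7)
        with pytest.raises(MappingError):
            zp.frame_weights(fs, {0: 0.0})

    def test_weights_sum_to_one_over_retained(self):
        fs = frameset(100, v_z=np.linspace(0, 20, 100), seed=4)
        w = zp.frame_weights(fs, {0: 0.3})
        assert w.weights.sum() == pytest.approx(1.0)


class TestDistanceFeatures:
    def test_fifteen_unique_pair_features(self):
        feats = zp.distance_features(frameset(10))
        assert feats.values.shape == (10, 15)
        assert len(set(feats.labels)) == 15
        assert np.all(feats.values > 0)

    def test_direct_euclidean_distance(self):
        coords = np.zeros((1, 6, 3))
        coords[0, 1] = [0.0, 0.0, 0.3]
        coords[0, 2:] = [[1 + k, 2, 3] for k in range(4)]
        fs = frameset(1, coords=coords)
        feats = zp.distance_features(fs)
        i = feats.labels.index("mol1:Cc-mol1:N")
        assert feats.values[0, i] == pytest.approx(0.3)

    def test_rigid_motions_leave_features_unchanged(self):
        fs = frameset(20, seed=8)
        base = zp.distance_features(fs).values
        rng = np.random.default_rng(12)
        rot = Rotation.random(random_state=34).as_matrix()
        shift = rng.normal(0, 2.0, size=3)
        moved = frameset(20, coords=fs.coords @ rot.T + shift)
        np.testing.assert_allclose(zp.distance_features(moved).values, base,
                                   atol=1e-10)


class TestPCA:
    def test_collinear_data_loads_on_pc1(self):
        t = np.linspace(0, 1, 200)
        direction = np.arange(1, 16, dtype=float)
        values = np.outer(t, direction) + 5.0
        values += np.random.default_rng(0).normal(0, 1e-9, values.shape)
        proj = zp.pca_project(F.FeatureMatrix(values=values, labels=tuple(map(str, range(15)))))
        assert proj.explained_variance_ratio[0] > 0.999999

    def test_components_are_orthonormal_with_positive_leading_loading(self):
        fs = frameset(300, seed=5)
        proj = zp.pca_project(zp.distance_features(fs))
        c = proj.components
        assert c[0] @ c[1] == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.norm(c[0]) == pytest.approx(1.0)
        for k in range(2):
            assert c[k, np.argmax(np.abs(c[k]))] > 0

    def test_two_conformer_clusters_are_separable(self, conformer_setup):
        frames, _, _ = conformer_setup
        proj = zp.pca_project(zp.distance_features(frames))
        closed = frames.labels == "closed"
        mu_c = proj.scores[closed].mean(axis=0)
        mu_o = proj.scores[~closed].mean(axis=0)
        axis = (mu_o - mu_c) / np.linalg.norm(mu_o - mu_c)
        # separation along the inter-centroid axis beats the in-cluster spread
        spread = max(np.std(proj.scores[closed] @ axis),
                     np.std(proj.scores[~closed] @ axis))
        assert np.linalg.norm(mu_c - mu_o) > 3 * spread

    def test_degenerate_rank_rejected(self):
        values = np.tile(np.arange(15.0), (30, 1)) + np.linspace(0, 1, 30)[:, None]
        with pytest.raises(ValueError):
            zp.pca_project(F.FeatureMatrix(values=values, labels=tuple(map(str, range(15)))))


def gaussian_cluster_projection(n1, n2, offset=(1.0, 0.0), sd=0.08, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        rng.normal(0.0, sd, size=(n1, 2)),
        rng.normal(0.0, sd, size=(n2, 2)) + np.asarray(offset),
    ])
    proj = F.Projection(scores=pts, components=np.eye(2, 15),
                        explained_variance_ratio=np.array([0.6, 0.3]),
                        mean=np.zeros(15))
    w = F.FrameWeights(weights=np.full(n1 + n2, 1.0 / (n1 + n2)),
                       retained=np.ones(n1 + n2, bool), threshold=4.0)
    return proj, w


class TestSurfaceAndMinima:
    def test_unimodal_cluster_yields_single_minimum_at_centroid(self):
        proj, w = gaussian_cluster_projection(4000, 0, seed=3)
        surf = zp.build_fes(proj, w, grid_size=120)
        minima = zp.locate_minima(surf, 0.1, proj, w)
        assert len(minima) == 1
        assert abs(minima[0].pc1) < 0.05 and abs(minima[0].pc2) < 0.05

    def test_grid_minimum_is_zero_by_construction(self):
        proj, w = gaussian_cluster_projection(2000, 2000, seed=9)
        surf = zp.build_fes(proj, w, grid_size=100)
        assert np.nanmin(surf.g) == pytest.approx(0.0, abs=1e-12)

    def test_designed_population_ratio_sets_the_free_energy_gap(self):
        """Two clusters with weight ratio e^-1 differ by ~1 kBT."""
        n1 = 6000
        n2 = int(round(n1 * np.exp(-1.0)))
        proj, w = gaussian_cluster_projection(n1, n2, seed=14)
        surf = zp.build_fes(proj, w, grid_size=150)
        minima = zp.locate_minima(surf, 0.1, proj, w)
        assert len(minima) == 2
        assert minima[1].g - minima[0].g == pytest.approx(1.0, abs=0.2)

    def test_nearby_candidates_merge_within_cutoff(self):
        proj, w = gaussian_cluster_projection(4000, 4000, offset=(0.06, 0.0),
                                              sd=0.05, seed=2)
        surf = zp.build_fes(proj, w, grid_size=100)
        minima = zp.locate_minima(surf, averaging_cutoff=0.2)
        assert len(minima) == 1

    def test_zero_retained_frames_rejected(self):
        proj, w = gaussian_cluster_projection(300, 0)
        w.retained[:] = False
        with pytest.raises(ValueError):
            zp.build_fes(proj, w)


class TestRepresentativeFrames:
    def test_representatives_carry_the_cluster_ground_truth(self, conformer_setup):
        frames, f_i, _ = conformer_setup
        w = zp.frame_weights(frames, f_i)
        proj = zp.pca_project(zp.distance_features(frames))
        surf = zp.build_fes(proj, w, grid_size=120)
        minima = zp.locate_minima(surf, 0.1, proj, w)
        assert len(minima) == 2
        for minimum, expected in zip(minima, ("closed", "open")):
            reps = zp.representative_frames(minimum, proj, w, k=15)
            labels = frames.labels[reps]
            assert np.mean(labels == expected) >= 0.95

    def test_tiny_cutoff_returns_empty_not_error(self, conformer_setup):
        frames, f_i, _ = conformer_setup
        w = zp.frame_weights(frames, f_i)
        proj = zp.pca_project(zp.distance_features(frames))
        far = F.Minimum(pc1=50.0, pc2=50.0, g=0.0, member_frames=np.empty(0, int))
        assert zp.representative_frames(far, proj, w, cutoff=1e-9, k=5).size == 0

    def test_k_larger_than_qualifying_returns_all(self):
        proj, w = gaussian_cluster_projection(50, 0, seed=6)
        m = F.Minimum(pc1=0.0, pc2=0.0, g=0.0, member_frames=np.empty(0, int))
        reps = zp.representative_frames(m, proj, w, cutoff=10.0, k=10_000)
        assert reps.size == 50


class TestIntramolecularDistribution:
    def test_area_is_one(self, conformer_setup):
        frames, f_i, _ = conformer_setup
        w = zp.frame_weights(frames, f_i)
        edges, dens = zp.intramolecular_distance_distribution(frames, w)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_equal_offsets_give_balanced_bimodal_distribution(self):
        """Closed/open at 0.5/0.9 nm with equal stability: ~equal masses."""
        model = zp.two_state_dimer_model(delta_f=0.0)
        ladder = zp.make_window_ladder(4, 0.6, 0.9, 600.0, 25_000.0)
        frames = zp.generate_conformer_frames(model, ladder, 2000, seed=5)
        w = zp.frame_weights(frames, {k.index: 0.0 for k in ladder})
        edges, dens = zp.intramolecular_distance_distribution(frames, w, bins=50)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mass_closed = np.sum((dens * np.diff(edges))[centers < 0.7])
        assert mass_closed == pytest.approx(0.5, abs=0.05)

    def test_zero_noise_single_conformer_is_a_point_mass(self):
        conf = zp.two_state_dimer_model().conformers[0]
        model = zp.ConformerModel(conformers=(conf,), noise=0.0)
        ladder = [zp.UmbrellaWindow(index=0, center=0.7, k_z=600.0)]
        frames = zp.generate_conformer_frames(model, ladder, 300, seed=3)
        w = zp.frame_weights(frames, {0: 0.0})
        edges, dens = zp.intramolecular_distance_distribution(frames, w, bins=20)
        assert np.sum(dens > 0) == 1

    def test_cross_molecule_pair_rejected(self, conformer_setup):
        frames, f_i, _ = conformer_setup
        w = zp.frame_weights(frames, f_i)
        with pytest.raises(ValueError):
            zp.intramolecular_distance_distribution(frames, w,
                                                    role_pair=("mol1:S", "mol2:N"))


class TestTwoStateRecovery:
    @pytest.mark.parametrize("delta_f", [0.5, 1.0, 2.0])
    def test_reweighted_populations_recover_the_designed_gap(self, delta_f,
                                                             well_model):
        ladder = zp.make_window_ladder(6, 0.5, 1.0, 600.0, 25_000.0)
        model = zp.two_state_dimer_model(delta_f=delta_f)
        frames = zp.generate_conformer_frames(model, ladder, 5000,
                                              seed=int(10 * delta_f),
                                              z_pmf=well_model)
        from zwitterphase.synthetic import analytic_alignment_constants
        f_i = analytic_alignment_constants(well_model, ladder)
        w = zp.frame_weights(frames, f_i)
        got = brute_force_two_state_delta_f(frames.labels, w.weights,
                                            "closed", "open")
        assert got == pytest.approx(delta_f, abs=0.2)
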