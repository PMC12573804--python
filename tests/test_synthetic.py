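"""Ground-truth generators: analytic PMFs, biased samplers, conformer frames."""
import numpy as np
import pytest

import zwitterphase as zp
from zwitterphase.errors import DomainError
from zwitterphase.synthetic import analytic_alignment_constants

KBT = zp.kbt_kj_per_mol()  # 2.494 kJ/mol at 300 K


class TestEvaluatePMF:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (0.55, -3.0),                       # well minimum by construction
            (0.67, -3.0 * np.exp(-0.5)),        # one width from the centre
            (3.4, -3.0 * np.exp(-(2.85**2) / (2 * 0.12**2))),  # far tail ~ 0
        ],
    )
    def test_gaussian_well_closed_form(self, well_model, z, expected):
        assert zp.evaluate_pmf(well_model, z) == pytest.approx(expected, abs=1e-12)

    def test_flat_is_zero_everywhere(self, flat_model):
        z = np.linspace(0.0, 3.5, 37)
        assert np.all(zp.evaluate_pmf(flat_model, z) == 0.0)

    def test_double_well_superposes_two_gaussians(self):
        m = zp.AnalyticPMF("double_well", well_depth=2.0, well_center=0.5,
                           well_width=0.1, well2_depth=1.0, well2_center=1.2,
                           well2_width=0.15)
        expected = (-2.0 * np.exp(-(0.2**2) / (2 * 0.01))
                    - 1.0 * np.exp(-(0.5**2) / (2 * 0.0225)))
        assert zp.evaluate_pmf(m, 0.7) == pytest.approx(expected, rel=1e-12)

    def test_outside_domain_raises(self, well_model):
        with pytest.raises(DomainError):
            zp.evaluate_pmf(well_model, 4.0)
        with pytest.raises(DomainError):
            zp.evaluate_pmf(well_model, np.array([0.5, -0.1]))


class TestSampleWindow:
    def test_harmonic_moments_on_flat_pmf(self, flat_model):
        w = zp.UmbrellaWindow(index=0, center=1.5, k_z=600.0)
        out = zp.sample_window(flat_model, w, 50_000, burn_in=2000, seed=7)
        var_expected = KBT / 600.0
        # autocorrelated chain: allow ~3 effective standard errors on the mean
        se_mean = np.sqrt(var_expected / 50_000) * 5
        assert out.series.mean() == pytest.approx(1.5, abs=3 * se_mean)
        assert out.series.var() == pytest.approx(var_expected, rel=0.1)

    def test_seeded_determinism_is_bitwise(self, flat_model):
        w = zp.UmbrellaWindow(index=0, center=1.0, k_z=400.0, k_r=25_000.0)
        a = zp.sample_window(flat_model, w, 500, burn_in=50, seed=42)
        b = zp.sample_window(flat_model, w, 500, burn_in=50, seed=42)
        np.testing.assert_array_equal(a.series, b.series)
        np.testing.assert_array_equal(a.r_series, b.r_series)

    def test_stationary_histogram_matches_biased_density(self, well_model):
        """Long-run z histogram converges to exp(-[PMF+V]/kBT) normalised."""
        w = zp.UmbrellaWindow(index=0, center=0.7, k_z=300.0)
        out = zp.sample_window(well_model, w, 80_000, burn_in=4000, seed=3)
        counts, edges = np.histogram(out.series, bins=40)
        centers = 0.5 * (edges[:-1] + edges[1:])
        logp = -(zp.evaluate_pmf(well_model, centers)
                 + 0.5 * 300.0 * (centers - 0.7) ** 2 / KBT)
        expected = np.exp(logp - logp.max())
        expected *= counts.sum() / expected.sum()
        keep = expected > 50
        chi = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        # inflated acceptance band: the Metropolis chain is autocorrelated
        assert chi / keep.sum() < 12.0

    def test_invalid_sample_count_rejected(self, flat_model):
        w = zp.UmbrellaWindow(index=0, center=1.0, k_z=100.0)
        with pytest.raises(ValueError):
            zp.sample_window(flat_model, w, 0, seed=1)


class TestConformerFrames:
    def test_label_fractions_follow_boltzmann(self):
        model = zp.two_state_dimer_model(delta_f=1.0)
        ladder = zp.make_window_ladder(6, 0.5, 1.0, 600.0, 25_000.0)
        frames = zp.generate_conformer_frames(model, ladder, 5000, seed=9)
        p_closed = np.mean(frames.labels == "closed")
        expected = 1.0 / (1.0 + np.exp(-1.0))          # 0.731
        binom_se = np.sqrt(expected * (1 - expected) / len(frames))
        assert p_closed == pytest.approx(expected, abs=4 * binom_se)

    def test_single_conformer_is_degenerate(self):
        conf = zp.two_state_dimer_model().conformers[0]
        model = zp.ConformerModel(conformers=(conf,), noise=0.01)
        ladder = [zp.UmbrellaWindow(index=0, center=0.7, k_z=600.0)]
        frames = zp.generate_conformer_frames(model, ladder, 200, seed=2)
        assert set(frames.labels) == {"closed"}

    def test_zero_noise_gives_identical_internal_geometry(self):
        conf = zp.two_state_dimer_model().conformers[0]
        model = zp.ConformerModel(conformers=(conf,), noise=0.0)
        ladder = [zp.UmbrellaWindow(index=0, center=0.7, k_z=600.0)]
        frames = zp.generate_conformer_frames(model, ladder, 50, seed=2)
        feats = zp.distance_features(frames)
        intra = [i for i, lab in enumerate(feats.labels)
                 if lab.split("-")[0][:4] == lab.split("-")[1][:4]]
        # intramolecular distances untouched by the COM placement
        assert np.allclose(np.ptp(feats.values[:, intra], axis=0), 0.0, atol=1e-12)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            zp.generate_conformer_frames(zp.two_state_dimer_model(), [], 100, seed=1)

    def test_boltzmann_populations_sum_to_one(self):
        model = zp.two_state_dimer_model(delta_f=2.0)
        assert model.populations().sum() == pytest.approx(1.0)


class TestReferenceInteractionEnergy:
    def test_flat_pmf_has_zero_interaction(self, flat_model):
        assert zp.reference_interaction_energy(flat_model) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_well_depth_recovered(self, well_model):
        # tail contribution in the 1.75-2.25 nm reference window is ~e^-50
        assert zp.reference_interaction_energy(well_model) == pytest.approx(3.0, abs=1e-6)

    def test_constrained_minimum_when_well_below_search_floor(self):
        m = zp.AnalyticPMF("gaussian_well", well_depth=3.0, well_center=0.2,
                           well_width=0.12)
        # minimum restricted to z >= 0.4: the well edge, not the full depth
        expected = 3.0 * np.exp(-(0.2**2) / (2 * 0.12**2))
        got = zp.reference_interaction_energy(m, search_min=0.4)
        assert got == pytest.approx(expected, abs=1e-6)


class TestAlignmentConstantOracle:
    def test_relative_f_i_match_wham_on_toy_experiment(self, toy_well_windows,
                                                       toy_well_pmf, well_model):
        """Dense-quadrature F_i agree with sampled WHAM F_i up to a gauge."""
        ladder = [zp.UmbrellaWindow(index=w.index, center=w.center, k_z=w.k_z)
                  for w in toy_well_windows]
        oracle = analytic_alignment_constants(well_model, ladder)
        got = toy_well_pmf.f_i
        rel_oracle = np.array([oracle[w.index] for w in ladder])
        rel_oracle -= rel_oracle[0]
        rel_got = got - got[0]
        # inter-window alignment noise at 2,000 samples/window is ~0.2 kBT
        assert np.allclose(rel_got, rel_oracle, atol=0.35)
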