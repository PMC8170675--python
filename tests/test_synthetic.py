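"""Generator contracts: determinism, invariants and noise-free inversion."""

import numpy as np
import pytest

import dnallostery as dl


@pytest.fixture(scope="module")
def stream():
    return dl.simulate_photon_stream(
        dl.FretPopulations(), dl.SimulationConfig(seed=5, duration=20.0))


class TestPhotonStream:
    def test_deterministic_given_seed(self):
        cfg = dl.SimulationConfig(seed=9, duration=5.0)
        a = dl.simulate_photon_stream(dl.FretPopulations(), cfg)
        b = dl.simulate_photon_stream(dl.FretPopulations(), cfg)
        np.testing.assert_array_equal(a.macrotimes, b.macrotimes)
        np.testing.assert_array_equal(a.channels, b.channels)
        c = dl.simulate_photon_stream(
            dl.FretPopulations(), dl.SimulationConfig(seed=10, duration=5.0))
        assert c.n_photons != a.n_photons or not np.array_equal(
            c.macrotimes, a.macrotimes)

    def test_photon_record_invariants(self, stream):
        assert np.all(np.diff(stream.macrotimes) >= 0)
        assert set(np.unique(stream.channels)) <= {1, 2}
        assert np.all((stream.microtimes >= 0)
                      & (stream.microtimes < 50.0))
        # microtimes sit on the 32 ps grid
        frac = stream.microtimes / 0.032
        np.testing.assert_allclose(frac, np.round(frac), atol=1e-6)

    def test_single_component_peak_position(self):
        truth = dl.FretPopulations(components=[(0.5, 0.0, 1.0)],
                                   donor_only_fraction=0.0,
                                   bleach_fraction=0.0,
                                   background_rates=(0.0, 0.0))
        stream = dl.simulate_photon_stream(
            truth, dl.SimulationConfig(seed=2, duration=40.0))
        bursts, _ = dl.find_bursts(stream)
        for b in bursts:
            dl.burst_metrics(b)
        kept = dl.filter_bursts(bursts)
        e = np.array([b.E for b in kept])
        assert len(kept) > 300
        assert e.mean() == pytest.approx(0.5, abs=0.01)

    def test_two_component_weight_recovery(self, calibration_peaks):
        """A 0.40/0.28 free/bound mixture (plus donor-only molecules) is
        recovered by the fixed-peak histogram fit within 0.03."""
        w_free, w_bound = 0.40, 0.28
        truth = dl.FretPopulations(
            components=[(0.45, 0.03, w_free / (w_free + w_bound)),
                        (0.63, 0.03, w_bound / (w_free + w_bound))],
            donor_only_fraction=1.0 - w_free - w_bound,
        )
        stream = dl.simulate_photon_stream(
            truth, dl.SimulationConfig(seed=13, duration=250.0))
        bursts, _ = dl.find_bursts(stream)
        for b in bursts:
            dl.burst_metrics(b)
        kept = dl.filter_bursts(bursts)
        assert len(kept) > 2000
        pf, pb = calibration_peaks
        spec = dl.PeakFit(components=[
            dl.PeakComponent(pf.mean, pf.width),
            dl.PeakComponent(pb.mean, pb.width)], bound_index=1)
        fit = dl.fit_fret_histogram([b.E for b in kept], spec)
        assert fit.bound_fraction == pytest.approx(
            w_bound / (w_free + w_bound), abs=0.03)

    def test_donor_only_molecules_lack_acceptor_excitation_photons(self):
        truth = dl.FretPopulations(components=[(0.5, 0.0, 1.0)],
                                   donor_only_fraction=1.0,
                                   bleach_fraction=0.0,
                                   background_rates=(0.0, 0.0))
        stream = dl.simulate_photon_stream(
            truth, dl.SimulationConfig(seed=4, duration=10.0))
        assert np.all(stream.microtimes < 25.0)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            dl.FretPopulations(components=[(0.5, 0.03, 0.6),
                                           (0.7, 0.03, 0.6)])
        with pytest.raises(ValueError):
            dl.SimulationConfig(duration=-1.0)


class TestTitration:
    def test_noise_free_matches_model_exactly(self):
        model = dl.KNFModel(dg_K=1.0, dg_sigma=-2.0, dg_J=-3.0)
        x = np.geomspace(0.1, 100, 9)
        iso = dl.simulate_titration(model, x)
        np.testing.assert_array_equal(iso.f, dl.knf_fraction(x, model))

    def test_neutral_knf_mean_fraction(self):
        model = dl.KNFModel(dg_K=0.0, dg_sigma=0.0, dg_J=0.0)
        iso = dl.simulate_titration(model, [1.0])
        assert iso.f[0] == pytest.approx(1.0 / 12.0)

    def test_hill_midpoint(self):
        iso = dl.simulate_titration(dl.HillFit(n=2.0, K_Hill=25.0), [25.0])
        assert iso.f[0] == pytest.approx(0.5)

    def test_noise_clipped_to_unit_interval(self):
        iso = dl.simulate_titration(dl.HillFit(n=2.0, K_Hill=1.0),
                                    np.geomspace(0.01, 100, 30),
                                    noise_sd=0.3, n_rep=4, seed=0)
        assert np.all((iso.f >= 0) & (iso.f <= 1))

    def test_replicates_independent_but_seeded(self):
        a = dl.simulate_titration(dl.HillFit(n=2.0, K_Hill=1.0), [1.0],
                                  noise_sd=0.1, n_rep=2, seed=3)
        b = dl.simulate_titration(dl.HillFit(n=2.0, K_Hill=1.0), [1.0],
                                  noise_sd=0.1, n_rep=2, seed=3)
        np.testing.assert_array_equal(a.f, b.f)
        assert a.f[0] != a.f[1]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dl.simulate_titration(dl.HillFit(n=1.0, K_Hill=1.0), [])


class TestOccupancySampling:
    def test_all_or_none_limit(self):
        model = dl.KNFModel(dg_K=0.0, dg_sigma=0.0, dg_J=-30.0)
        dist = dl.sample_occupancy_counts(model, 0.01, 20000, seed=1)
        assert dist.p[0] + dist.p[4] > 0.999

    def test_multinomial_matches_enumeration(self):
        model = dl.KNFModel(dg_K=0.0, dg_sigma=0.0, dg_J=0.0)
        dist = dl.sample_occupancy_counts(model, 1.0, 200000, seed=2)
        ref = dl.occupancy_distribution(1.0, model).p
        np.testing.assert_allclose(dist.p, ref, atol=0.01)

    def test_invalid_inputs_rejected(self):
        model = dl.KNFModel(dg_K=0.0)
        with pytest.raises(ValueError):
            dl.sample_occupancy_counts(model, 1.0, 0, seed=0)
        with pytest.raises(ValueError):
            dl.sample_occupancy_counts(model, -1.0, 10, seed=0)


class TestSpacerSeries:
    def test_noise_free_energy_values(self):
        model = dl.ElasticModel(alpha_bend=24.0, xi=14.0)
        series = dl.simulate_spacer_series(model, [8, 18, 31])
        np.testing.assert_array_equal(
            series.y, dl.coupling_energy(np.array([8.0, 18.0, 31.0]), model))

    def test_zero_bend_angle_gives_zero_coupling(self):
        model = dl.ElasticModel(alpha_bend=0.0, xi=14.0)
        series = dl.simulate_spacer_series(model, np.arange(6, 30))
        np.testing.assert_allclose(series.y, 0.0, atol=1e-15)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dl.simulate_spacer_series(dl.ElasticModel(), [])


class TestCenterlineFactory:
    def test_point_spacing(self):
        for kind in ("straight", "arc"):
            line = dl.make_centerline(kind, 50, radius=12.0)
            d = np.linalg.norm(np.diff(line.points, axis=0), axis=1)
            if kind == "straight":
                np.testing.assert_allclose(d, 0.34, rtol=1e-12)
            else:
                # chord length of a 0.34 nm arc segment
                np.testing.assert_allclose(d, d[0], rtol=1e-9)
                assert d[0] == pytest.approx(0.34, rel=1e-3)

    def test_custom_needs_matching_angle_count(self):
        with pytest.raises(ValueError):
            dl.make_centerline("custom", 10, angles_deg=np.ones(5))


class TestDenaturation:
    MODEL = dl.UnfoldingModel(dG0=-8.8, m=7.0, v_f=33.5, m_u=25.0,
                              n_u=170.0)

    def test_noise_free_matches_forward_model(self):
        x = np.linspace(0, 6, 13)
        curve = dl.simulate_denaturation_curve(self.MODEL, x)
        np.testing.assert_array_equal(
            curve.radius, dl.predicted_radius(x, self.MODEL))

    def test_midpoint_radius_is_halfway_volume(self):
        x_mid = self.MODEL.midpoint
        r = float(dl.predicted_radius(x_mid, self.MODEL))
        v_u = self.MODEL.m_u * x_mid + self.MODEL.n_u
        v_half = 0.5 * (self.MODEL.v_f + v_u)
        assert 4 / 3 * np.pi * r**3 == pytest.approx(v_half, rel=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dl.simulate_denaturation_curve(self.MODEL, [])
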