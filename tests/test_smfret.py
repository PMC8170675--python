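"""Photon-count corrections, burst search, filters and histogram fits."""

import numpy as np
import pytest

import dnallostery as dl


def make_stream(macrotimes, channels, microtimes=None, duration=10.0):
    macrotimes = np.asarray(macrotimes, dtype=float)
    if microtimes is None:
        microtimes = np.full(macrotimes.size, 5.0)  # donor window
    return dl.PhotonStream(macrotimes, np.asarray(channels),
                           np.asarray(microtimes), duration)


def cluster(t0, n, spacing=1e-6, channel_pattern=(1, 2)):
    times = t0 + np.arange(n) * spacing
    channels = np.tile(channel_pattern, n // len(channel_pattern) + 1)[:n]
    return times, channels


class TestCorrectCounts:
    def test_identity_corrections_are_identity(self):
        nA, nD = dl.correct_counts(100, 100, 0, 0, 1.0,
                                   dl.CorrectionSet.identity())
        assert (nA, nD) == (100.0, 100.0)

    def test_default_corrections_reference_value(self):
        nA, nD = dl.correct_counts(100, 100, 0, 0, 1.0, dl.CorrectionSet())
        assert nA == pytest.approx(84.87, abs=0.01)
        assert nD == pytest.approx(111.79, abs=0.01)

    def test_uniform_background_cancels_exactly(self):
        b1, b2, T = 300.0, 200.0, 0.5
        nA, nD = dl.correct_counts(b1 * T, b2 * T, b1, b2, T,
                                   dl.CorrectionSet())
        assert nA == pytest.approx(0.0, abs=1e-9)
        assert nD == pytest.approx(0.0, abs=1e-9)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            dl.correct_counts(10, 10, 0, 0, -1.0, dl.CorrectionSet())


class TestFindBursts:
    def test_empty_stream(self):
        stream = make_stream([], [], [])
        bursts, bg = dl.find_bursts(stream)
        assert bursts == [] and bg == (0.0, 0.0)

    def test_single_cluster_is_one_burst(self):
        t, ch = cluster(5.0, 200)
        bursts, _ = dl.find_bursts(make_stream(t, ch))
        assert len(bursts) == 1
        assert bursts[0].n1 + bursts[0].n2 == 200

    def test_dim_cluster_below_threshold_rejected(self):
        # 60 raw photons cannot reach 80 corrected
        t, ch = cluster(5.0, 60)
        bursts, _ = dl.find_bursts(make_stream(t, ch))
        assert bursts == []

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError):
            dl.find_bursts(make_stream([2.0, 1.0, 3.0], [1, 2, 1]))

    def test_invariant_to_empty_time_padding(self):
        t, ch = cluster(5.0, 200)
        stream = make_stream(t, ch, duration=10.0)
        padded = make_stream(t + 100.0, ch, duration=400.0)
        b1, _ = dl.find_bursts(stream)
        b2, _ = dl.find_bursts(padded)
        assert len(b1) == len(b2) == 1
        assert b1[0].n1 == b2[0].n1 and b1[0].T == pytest.approx(b2[0].T)

    def test_search_monotone_in_threshold_and_dt_max(self, two_pop_stream):
        base = dl.BurstSearchConfig()
        found = dl.find_bursts(two_pop_stream, cfg=base)[0]
        n_base = len(found)
        stricter = dl.BurstSearchConfig(min_corrected_photons=160)
        assert len(dl.find_bursts(two_pop_stream, cfg=stricter)[0]) <= n_base
        # a wider inter-photon window can merge neighbouring bursts, so the
        # monotone quantity is the number of photons inside bursts
        wider = dl.BurstSearchConfig(dt_max=200e-6)
        found_wide = dl.find_bursts(two_pop_stream, cfg=wider)[0]

        def photons(bursts):
            return sum(b.stop - b.start for b in bursts)

        assert photons(found_wide) >= photons(found)

    def test_background_estimate_converges_to_truth(self, two_pop_stream):
        _, (b1, b2) = dl.find_bursts(two_pop_stream)
        # generator default: 500/s per channel in the donor window
        assert b1 == pytest.approx(500.0, rel=0.1)
        assert b2 == pytest.approx(500.0, rel=0.1)


class TestBurstMetrics:
    def make_burst(self, nA, nD, n_AA=10, T=1e-3):
        return dl.Burst(start=0, stop=nA + nD, T=T, n1=nA, n2=nD,
                        n_DD=nD, n_DA=nA, n_AA=n_AA,
                        nA_corr=float(nA), nD_corr=float(nD),
                        t_D=np.linspace(0, T, max(nD, 1)),
                        t_A=np.linspace(0, T, max(nA, 1)))

    def test_symmetric_counts_give_half_efficiency(self):
        b = dl.burst_metrics(self.make_burst(50, 50))
        assert b.E == pytest.approx(0.5)

    def test_shot_noise_asymmetry_width(self):
        b = dl.burst_metrics(self.make_burst(25, 25, T=1000e-6))
        assert b.sigma_DA == pytest.approx(81.65e-6, rel=1e-3)

    def test_no_acceptor_excitation_signal_means_donor_only(self):
        b = dl.burst_metrics(self.make_burst(5, 95, n_AA=0))
        assert b.S == 1.0

    def test_zero_corrected_sum_flagged(self):
        b = self.make_burst(0, 0)
        b.nA_corr = b.nD_corr = 0.0
        assert np.isnan(dl.burst_metrics(b).E)


class TestFilters:
    def test_symmetric_burst_retained(self):
        b = dl.Burst(start=0, stop=10, T=1e-3, n1=50, n2=50, n_DD=50,
                     n_DA=50, n_AA=30, nA_corr=50.0, nD_corr=50.0,
                     t_D=np.array([1e-4, 5e-4]), t_A=np.array([1e-4, 5e-4]))
        dl.burst_metrics(b)
        assert dl.filter_bursts([b]) == [b]
        assert b.pass_asymmetry

    def test_high_stoichiometry_dropped(self):
        b = dl.Burst(start=0, stop=10, T=1e-3, n1=10, n2=90, n_DD=90,
                     n_DA=10, n_AA=2, nA_corr=10.0, nD_corr=90.0,
                     t_D=np.array([1e-4]), t_A=np.array([1e-4]))
        dl.burst_metrics(b)
        assert b.S > 0.9
        assert dl.filter_bursts([b]) == []
        assert not b.pass_stoichiometry

    def test_symmetric_population_retention_near_gaussian_expectation(self):
        """Without bleaching the asymmetry of a burst is pure shot noise, so
        the |alpha| <= sigma filter retains about P(|Z| <= 1) = 68%."""
        truth = dl.FretPopulations(components=[(0.5, 0.0, 1.0)],
                                   donor_only_fraction=0.0,
                                   bleach_fraction=0.0)
        stream = dl.simulate_photon_stream(
            truth, dl.SimulationConfig(seed=21, duration=60.0))
        bursts, _ = dl.find_bursts(stream)
        for b in bursts:
            dl.burst_metrics(b)
        frac = np.mean([abs(b.alpha_DA) <= b.sigma_DA for b in bursts])
        assert frac == pytest.approx(0.683, abs=0.06)

    def test_bleached_bursts_rejected_by_combined_filter(self):
        """Acceptor bleaching either skews arrival times (asymmetry filter)
        or, for early bleaches, removes the acceptor-excitation signal
        (stoichiometry filter); together they reject nearly all marked
        bursts."""
        truth = dl.FretPopulations(components=[(0.5, 0.0, 1.0)],
                                   donor_only_fraction=0.0,
                                   bleach_fraction=0.3, brightness=300)
        stream = dl.simulate_photon_stream(
            truth, dl.SimulationConfig(seed=3, duration=120.0))
        bursts, _ = dl.find_bursts(stream)
        for b in bursts:
            dl.burst_metrics(b)
        dl.filter_bursts(bursts)

        t0s = stream.truth["t0"].to_numpy()
        marked = stream.truth["bleached"].to_numpy()
        fail_asym, fail_any = [], []
        for b in bursts:
            ts = stream.macrotimes[b.start]
            te = stream.macrotimes[b.stop - 1]
            idx = np.flatnonzero((t0s >= ts - 2e-3) & (t0s <= te))
            if idx.size != 1 or not marked[idx[0]]:
                continue
            fail_asym.append(not b.pass_asymmetry)
            fail_any.append(not b.retained)
        assert len(fail_any) > 300
        assert np.mean(fail_asym) > 0.75
        assert np.mean(fail_any) > 0.90


class TestHistogramFit:
    def test_single_population_has_no_bound_area(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0.45, 0.05, 4000)
        spec = dl.PeakFit(components=[
            dl.PeakComponent(0.45, 0.05), dl.PeakComponent(0.75, 0.05)],
            bound_index=1)
        fit = dl.fit_fret_histogram(e, spec)
        assert fit.bound_fraction < 0.02

    def test_fifty_fifty_mixture(self):
        rng = np.random.default_rng(1)
        e = np.r_[rng.normal(0.45, 0.05, 2500), rng.normal(0.75, 0.05, 2500)]
        spec = dl.PeakFit(components=[
            dl.PeakComponent(0.45, 0.05), dl.PeakComponent(0.75, 0.05)],
            bound_index=1)
        fit = dl.fit_fret_histogram(e, spec)
        assert fit.bound_fraction == pytest.approx(0.5, abs=0.03)

    def test_fully_bound_population(self):
        rng = np.random.default_rng(2)
        e = rng.normal(0.75, 0.05, 3000)
        spec = dl.PeakFit(components=[
            dl.PeakComponent(0.45, 0.05), dl.PeakComponent(0.75, 0.05)],
            bound_index=1)
        fit = dl.fit_fret_histogram(e, spec)
        assert fit.bound_fraction > 0.98

    def test_empty_histogram_rejected(self):
        spec = dl.PeakFit(components=[dl.PeakComponent(0.5, 0.05)])
        with pytest.raises(ValueError):
            dl.fit_fret_histogram(np.array([5.0, 6.0]), spec)  # outside bins


class TestStreamIO:
    def test_table_round_trip(self, tmp_path):
        t, ch = cluster(1.0, 50)
        stream = make_stream(t, ch, duration=5.0)
        path = tmp_path / "stream.txt"
        stream.to_table(path)
        back = dl.PhotonStream.from_table(path)
        np.testing.assert_allclose(back.macrotimes, stream.macrotimes)
        assert back.duration == stream.duration

    def test_hdf5_round_trip(self, tmp_path):
        t, ch = cluster(1.0, 50)
        stream = make_stream(t, ch, duration=5.0)
        path = tmp_path / "stream.h5"
        stream.to_hdf5(path)
        back = dl.PhotonStream.from_hdf5(path)
        np.testing.assert_allclose(back.macrotimes, stream.macrotimes)
        np.testing.assert_array_equal(back.channels, stream.channels)
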