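"""Shared fixtures: simulated photon streams are expensive, so the
two-population measurement and its single-population calibration runs are
built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import dnallostery as dl

BASE_SEED = 42

FREE_PEAK = (0.45, 0.03)
BOUND_PEAK = (0.63, 0.03)


@pytest.fixture(scope="session")
def two_pop_stream() -> dl.PhotonStream:
    """~5000 bursts of a 50/50 free/bound mixture with donor-only molecules
    and occasional acceptor bleaching."""
    truth = dl.FretPopulations(
        components=[FREE_PEAK + (0.5,), BOUND_PEAK + (0.5,)],
    )
    cfg = dl.SimulationConfig(seed=BASE_SEED, duration=250.0)
    return dl.simulate_photon_stream(truth, cfg)


def _analyse(stream: dl.PhotonStream) -> list[dl.Burst]:
    bursts, _ = dl.find_bursts(stream)
    for b in bursts:
        dl.burst_metrics(b)
    return dl.filter_bursts(bursts)


@pytest.fixture(scope="session")
def two_pop_bursts(two_pop_stream) -> list[dl.Burst]:
    return _analyse(two_pop_stream)


@pytest.fixture(scope="session")
def calibration_peaks() -> tuple[dl.PeakComponent, dl.PeakComponent]:
    """Fixed peak position/width of the free and bound populations, each
    fitted on a single-population reference simulation — the same protocol
    as calibrating on ligand-free and ligand-saturated measurements."""
    peaks = []
    for i, comp in enumerate((FREE_PEAK, BOUND_PEAK)):
        truth = dl.FretPopulations(
            components=[comp + (1.0,)],
            donor_only_fraction=0.0,
            bleach_fraction=0.0,
        )
        cfg = dl.SimulationConfig(seed=BASE_SEED + 100 + i, duration=60.0)
        kept = _analyse(dl.simulate_photon_stream(truth, cfg))
        peaks.append(dl.fit_single_peak([b.E for b in kept]))
    return tuple(peaks)
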