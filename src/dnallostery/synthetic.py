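"""Synthetic-data generators for every stage of the pipeline.

Each generator inverts the corresponding analysis model, so that running the
analysis on noise-free synthetic input recovers the generating parameters.
The photon-stream generator emulates a confocal PIE measurement of freely
diffusing promoter molecules: a superposition of FRET subpopulations (free
and ligand-bound promoter), donor-only molecules, uniform background in both
channels, and mid-burst acceptor photobleaching.  The channel split of each
burst applies the forward of the count-correction model, so analysing the
stream with the same correction set recovers the population efficiencies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingIsotherm, HillFit, KNFModel, knf_fraction, \
    occupancy_distribution, OccupancyDistribution
from .curvature import Centerline
from .elastic import ElasticModel, SpacerSeries, coupling_energy, \
    hill_vs_spacer
from .smfret import CorrectionSet, PhotonStream
from .unfolding import DenaturationCurve, UnfoldingModel, predicted_radius

__all__ = [
    "FretPopulations",
    "SimulationConfig",
    "simulate_photon_stream",
    "simulate_titration",
    "transition_grid",
    "sample_occupancy_counts",
    "simulate_spacer_series",
    "make_centerline",
    "simulate_denaturation_curve",
]


# --------------------------------------------------------------------------
# photon streams
# --------------------------------------------------------------------------

@dataclass
class FretPopulations:
    """Ground-truth composition of a simulated smFRET measurement.

    components : list of (mean efficiency, peak width, weight); the
        molecule-to-molecule spread adds to shot noise in the histogram
    donor_only_fraction : fraction of molecules without active acceptor
    bleach_fraction : fraction of double-labelled bursts with a mid-burst
        acceptor bleach
    donor_lifetime : donor-only fluorescence lifetime, ns
    acceptor_lifetime : acceptor fluorescence lifetime, ns
    background_rates : donor-excitation-window background (b1, b2), photons/s
    burst_rate : molecule transits per second
    brightness : mean photons per burst (all PIE windows)
    burst_duration : transit duration, s
    aex_fraction : fraction of a burst's photons from acceptor excitation
    """

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.45, 0.03, 0.5), (0.63, 0.03, 0.5)]
    )
    donor_only_fraction: float = 0.1
    bleach_fraction: float = 0.05
    donor_lifetime: float = 3.8
    acceptor_lifetime: float = 3.7
    background_rates: tuple[float, float] = (500.0, 500.0)
    burst_rate: float = 20.0
    brightness: float = 200.0
    burst_duration: float = 1e-3
    aex_fraction: float = 1.0 / 3.5

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if not math.isclose(w, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("component weights must sum to 1")
        for frac in (self.donor_only_fraction, self.bleach_fraction,
                     self.aex_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if min(self.background_rates) < 0 or self.burst_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimulationConfig:
    """Timing layout of the simulated PIE experiment."""

    seed: int = 0
    duration: float = 10.0
    pie_period: float = 50.0          # ns
    donor_window: tuple[float, float] = (0.0, 25.0)
    acceptor_window: tuple[float, float] = (25.0, 50.0)
    time_resolution: float = 0.032    # ns (32 ps)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.time_resolution <= 0:
            raise ValueError("time resolution must be positive")
        if not (self.donor_window[0] == 0.0
                and self.donor_window[1] == self.acceptor_window[0]
                and self.acceptor_window[1] == self.pie_period):
            raise ValueError("PIE windows must partition the period")


def _forward_channel_prob(e_target: float, corr: CorrectionSet) -> float:
    """Probability that a donor-excitation photon lands in channel 1 so
    that the corrected efficiency equals ``e_target``.

    Inverts the correction chain: target corrected counts (E, 1-E) are
    mapped back through the direct-excitation step and the inverse of the
    leakage/efficiency matrix to expected raw channel intensities.
    """
    nA_corr, nD_corr = e_target, 1.0 - e_target
    nA_pre = (nA_corr + corr.alpha_direct * nD_corr) / (1.0 - corr.alpha_direct)
    det = corr.gamma1 * corr.gamma2 - corr.beta_DA * corr.beta_AD
    r1 = (corr.gamma2 * nA_pre + corr.beta_DA * nD_corr) / det
    r2 = (corr.beta_AD * nA_pre + corr.gamma1 * nD_corr) / det
    return r1 / (r1 + r2)


def _donor_only_channel_prob(corr: CorrectionSet) -> float:
    """Raw channel-1 probability of a molecule without acceptor: pure
    donor leakage."""
    return corr.beta_DA / (corr.beta_DA + corr.gamma1)


def simulate_photon_stream(
    truth: FretPopulations,
    cfg: SimulationConfig,
    corr: CorrectionSet | None = None,
) -> PhotonStream:
    """Simulate a time-tagged two-channel PIE photon record.

    Burst start times are Poisson with rate ``truth.burst_rate``; photon
    counts per burst are Poisson with mean ``truth.brightness`` and arrival
    times uniform over the transit.  A bleached burst switches its acceptor
    off at a uniformly distributed time, converting later donor-excitation
    acceptor photons to donor photons and dropping later acceptor-excitation
    photons — which produces a positive burst asymmetry.  Donor microtimes
    decay with ``tau_D (1 - E)``.

    The returned stream carries a ``truth`` table with one row per burst
    (start, duration, component index or -1 for donor-only, bleach flag).
    """
    corr = corr or CorrectionSet()
    rng = np.random.default_rng(cfg.seed)

    n_bursts = rng.poisson(truth.burst_rate * cfg.duration)
    burst_t0 = np.sort(rng.uniform(0.0, cfg.duration, n_bursts))

    means = np.array([c[0] for c in truth.components])
    widths = np.array([c[1] for c in truth.components])
    weights = np.array([c[2] for c in truth.components])

    q_donor_only = _donor_only_channel_prob(corr)
    dwin = cfg.donor_window[1]

    macro, chan, micro = [], [], []
    records = []
    for t0 in burst_t0:
        n = rng.poisson(truth.brightness)
        donor_only = rng.random() < truth.donor_only_fraction
        comp = -1
        bleached = False
        if donor_only:
            e_true = 0.0
            n_aex = 0
        else:
            comp = int(rng.choice(means.size, p=weights))
            e_true = float(np.clip(rng.normal(means[comp], widths[comp]),
                                   0.0, 1.0))
            n_aex = rng.binomial(n, truth.aex_fraction)
            bleached = rng.random() < truth.bleach_fraction
        n_dex = n - n_aex

        T = truth.burst_duration
        t_dex = rng.uniform(0.0, T, n_dex)
        t_aex = rng.uniform(0.0, T, n_aex)
        t_switch = rng.uniform(0.0, T) if bleached else np.inf

        q = _forward_channel_prob(e_true, corr) if not donor_only \
            else q_donor_only
        is_a = rng.random(n_dex) < q
        late = t_dex > t_switch
        if bleached:
            # acceptor dark after the switch: re-draw late photons with the
            # donor-only split and drop late acceptor-excitation photons
            is_a[late] = rng.random(int(late.sum())) < q_donor_only
            keep_aex = t_aex <= t_switch
            t_aex = t_aex[keep_aex]

        # microtimes: donor photons decay with tau_D (1 - E)
        tau_dd = truth.donor_lifetime * max(1.0 - e_true, 1e-3)
        m_dex = np.empty(n_dex)
        m_dex[~is_a] = rng.exponential(
            np.where(late[~is_a], truth.donor_lifetime, tau_dd)
        ) % dwin
        m_dex[is_a] = rng.exponential(truth.acceptor_lifetime,
                                      int(is_a.sum())) % dwin
        m_aex = dwin + rng.exponential(truth.acceptor_lifetime,
                                       t_aex.size) % dwin

        macro.append(t0 + t_dex)
        chan.append(np.where(is_a, 1, 2))
        micro.append(m_dex)
        macro.append(t0 + t_aex)
        chan.append(np.ones(t_aex.size, dtype=int))
        micro.append(m_aex)
        records.append((t0, T, comp, donor_only, bleached, e_true,
                        n_dex + t_aex.size))

    # uniform background, both channels, uniform microtimes; the configured
    # rates refer to the donor-excitation window, hence the factor 2 over
    # the full period
    for ch, rate in zip((1, 2), truth.background_rates):
        n_bg = rng.poisson(2.0 * rate * cfg.duration)
        macro.append(rng.uniform(0.0, cfg.duration, n_bg))
        chan.append(np.full(n_bg, ch, dtype=int))
        micro.append(rng.uniform(0.0, cfg.pie_period, n_bg))

    macro = np.concatenate(macro) if macro else np.empty(0)
    chan = np.concatenate(chan) if chan else np.empty(0, dtype=int)
    micro = np.concatenate(micro) if micro else np.empty(0)

    res = cfg.time_resolution
    micro = np.round(micro / res) * res
    macro = np.round(macro / (res * 1e-9)) * (res * 1e-9)
    order = np.argsort(macro, kind="stable")

    truth_table = pd.DataFrame(
        records,
        columns=["t0", "T", "component", "donor_only", "bleached",
                 "E_true", "n_photons"],
    )
    return PhotonStream(
        macrotimes=macro[order], channels=chan[order],
        microtimes=micro[order], duration=cfg.duration,
        donor_window=cfg.donor_window, acceptor_window=cfg.acceptor_window,
        truth=truth_table,
    )


# --------------------------------------------------------------------------
# isotherms, occupancy counts, spacer series
# --------------------------------------------------------------------------

def transition_grid(model, n: int = 20, width: float = 23.0) -> np.ndarray:
    """Log-spaced concentration grid centred on the model's half-saturation
    point, spanning ``width``-fold below and above it — the way a titration
    is designed around the transition of the construct at hand."""
    from scipy.optimize import brentq

    xm = brentq(lambda x: float(_model_fraction(model, np.array([x]))[0])
                - 0.5, 1e-8, 1e8)
    return np.geomspace(xm / width, xm * width, n)


def _model_fraction(model, x: np.ndarray) -> np.ndarray:
    if isinstance(model, KNFModel):
        return knf_fraction(x, model)
    if isinstance(model, HillFit):
        return model.fraction(x)
    raise TypeError("model must be a KNFModel or HillFit")


def simulate_titration(
    model,
    concentrations,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
    label: str = "",
) -> BindingIsotherm:
    """Bound fraction versus concentration with additive truncated Gaussian
    noise (clipped to [0, 1]); replicates are independent given the seed."""
    x = np.asarray(concentrations, dtype=float)
    if x.size == 0:
        raise ValueError("empty concentration grid")
    if np.any(x < 0) or noise_sd < 0:
        raise ValueError("concentrations and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x_all = np.tile(x, n_rep)
    f = _model_fraction(model, x_all)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, f.size), 0.0, 1.0)
    n_boxes = model.n_boxes if isinstance(model, KNFModel) else 2
    return BindingIsotherm(
        x=x_all, f=f,
        f_err=np.full(f.size, noise_sd) if noise_sd > 0 else None,
        label=label, n_boxes=n_boxes,
    )


def sample_occupancy_counts(
    model: KNFModel,
    concentration: float,
    n_particles: int,
    seed: int = 0,
) -> OccupancyDistribution:
    """Multinomial sample of the per-particle ligand count distribution at
    one concentration, as counted from single-particle class averages."""
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    p = occupancy_distribution(concentration, model).p
    counts = rng.multinomial(n_particles, p)
    return OccupancyDistribution(p=counts / n_particles, N=4)


def simulate_spacer_series(
    elastic: ElasticModel,
    spacers,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "energy",
    gel_coeffs: tuple[float, float, float, float] = (0.5, 0.3, 0.2, 15.0),
) -> SpacerSeries:
    """Coupling free energies, Hill exponents or gel band fractions versus
    spacer length, with additive Gaussian noise.

    For ``kind='gel_fraction'`` the empirical cosine-plus-exponential model
    ``c0 + c1 cos[2 pi (ds + ds0)/lambda] + c2 exp(-ds/c3)`` is used with
    the phase/periodicity of ``elastic`` and coefficients ``gel_coeffs``.
    """
    ds = np.asarray(spacers, dtype=float)
    if ds.size == 0:
        raise ValueError("empty spacer grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if kind == "energy":
        y = coupling_energy(ds, elastic)
    elif kind == "hill":
        y = hill_vs_spacer(ds, elastic)
    elif kind == "gel_fraction":
        c0, c1, c2, c3 = gel_coeffs
        phase = 2.0 * math.pi * (ds + elastic.ds0) / elastic.lambda_helix
        y = c0 + c1 * np.cos(phase) + c2 * np.exp(-ds / c3)
    else:
        raise ValueError("kind must be energy|hill|gel_fraction")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.size)
    return SpacerSeries(
        ds=ds, y=y,
        y_err=np.full(y.size, noise_sd) if noise_sd > 0 else None,
        kind=kind,
    )


# --------------------------------------------------------------------------
# centerlines and denaturation curves
# --------------------------------------------------------------------------

def make_centerline(
    kind: str,
    length_bp: int,
    b: float = 0.34,
    radius: float = 10.0,
    angles_deg=None,
    class_label: str = "",
) -> Centerline:
    """Construct a reference DNA centerline with ``length_bp`` points
    spaced ``b`` nm apart.

    kind='straight' : points along the x axis
    kind='arc'      : planar circular arc of the given ``radius`` (nm);
                      every segment pair turns by b/radius
    kind='custom'   : planar polyline whose successive turning angles are
                      ``angles_deg`` (length_bp - 2 values)
    """
    if length_bp < 3:
        raise ValueError("need at least 3 points")
    if kind == "straight":
        pts = np.zeros((length_bp, 3))
        pts[:, 0] = np.arange(length_bp) * b
    elif kind == "arc":
        if radius <= 0:
            raise ValueError("radius must be positive")
        dphi = b / radius
        phi = np.arange(length_bp) * dphi
        pts = np.column_stack([radius * np.sin(phi),
                               radius * (1.0 - np.cos(phi)),
                               np.zeros(length_bp)])
    elif kind == "custom":
        turns = np.radians(np.asarray(angles_deg, dtype=float))
        if turns.size != length_bp - 2:
            raise ValueError("need length_bp - 2 turning angles")
        heading = np.r_[0.0, np.cumsum(turns)]
        steps = b * np.column_stack([np.cos(heading), np.sin(heading),
                                     np.zeros(length_bp - 1)])
        pts = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ValueError("kind must be straight|arc|custom")
    return Centerline(points=pts, b=b, class_label=class_label)


def simulate_denaturation_curve(
    params: UnfoldingModel,
    x_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DenaturationCurve:
    """Stokes radius versus denaturant with additive Gaussian noise (nm)."""
    x = np.asarray(x_grid, dtype=float)
    if x.size == 0:
        raise ValueError("empty denaturant grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    r = predicted_radius(x, params)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, r.size)
    return DenaturationCurve(
        x=x, radius=r,
        radius_err=np.full(r.size, noise_sd) if noise_sd > 0 else None,
    )
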