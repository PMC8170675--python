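"""Photon-level single-molecule FRET burst analysis.

A confocal two-channel photon record (channel 1 = acceptor, channel 2 =
donor) with pulsed interleaved excitation (PIE) microtimes is searched for
fluorescence bursts of single diffusing molecules.  Detected raw counts are
corrected for detection efficiency, spectral leakage and acceptor direct
excitation,

    (n_A, n'_D) = (gamma1, -beta_DA; -beta_AD, gamma2) (n1 - b1 T, n2 - b2 T)
    n'_A = n_A - alpha (n'_D + n_A),

and per-burst transfer efficiency E = n'_A / (n'_A + n'_D), PIE
stoichiometry S, and the bleaching diagnostic "burst asymmetry" (difference
of mean donor and acceptor arrival times, with its shot-noise standard
deviation) are computed.  Bursts with a mid-transit acceptor photobleach
(|asymmetry| above one standard deviation) or without an active acceptor
(S >= 0.8) are excluded, and the efficiency histogram of the survivors is
fitted with fixed-peak mixtures to extract the bound fraction.

Burst search follows an inter-photon-time criterion: a photon extends the
current burst when its gap to the previous photon is at most
``gamma_channel * dt_max``; a candidate is kept when its corrected photon
sum exceeds a threshold (default 80).  Background rates are re-estimated
from the non-burst photons and the search repeated until the burst count is
stable (typically within three iterations).

Corrections, the burst threshold and background rates all refer to photons
in the donor-excitation PIE window; acceptor-excitation photons enter only
the stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls

__all__ = [
    "CorrectionSet",
    "BurstSearchConfig",
    "PhotonStream",
    "Burst",
    "PeakComponent",
    "PeakFit",
    "correct_counts",
    "find_bursts",
    "burst_metrics",
    "filter_bursts",
    "fit_fret_histogram",
    "fit_single_peak",
    "bursts_to_dataframe",
    "default_bins",
]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass
class CorrectionSet:
    """Photon-count correction factors of the two-channel PIE setup.

    gamma1/gamma2 : relative detection efficiencies of channels 1 and 2
    beta_DA : leakage of donor photons into the acceptor channel
    beta_AD : leakage of acceptor photons into the donor channel
    alpha_direct : probability of directly exciting the acceptor at the
        donor wavelength
    gamma_PIE : excitation-intensity factor entering the stoichiometry
    """

    gamma1: float = 1.0
    gamma2: float = 1.12
    beta_DA: float = 0.050
    beta_AD: float = 0.0021
    alpha_direct: float = 0.049
    gamma_PIE: float = 2.5

    def __post_init__(self) -> None:
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("gamma factors must be positive")
        for v in (self.beta_DA, self.beta_AD, self.alpha_direct):
            if not 0.0 <= v < 1.0:
                raise ValueError("beta and alpha must be in [0, 1)")

    @classmethod
    def identity(cls) -> "CorrectionSet":
        return cls(gamma1=1.0, gamma2=1.0, beta_DA=0.0, beta_AD=0.0,
                   alpha_direct=0.0, gamma_PIE=1.0)


@dataclass
class BurstSearchConfig:
    """Burst-search parameters."""

    dt_max: float = 100e-6            # maximal inter-photon time, s
    min_corrected_photons: float = 80  # burst threshold on n'_A + n'_D
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.dt_max <= 0 or self.min_corrected_photons <= 0:
            raise ValueError("dt_max and threshold must be positive")


@dataclass
class PhotonStream:
    """Time-tagged two-channel photon record.

    macrotimes : photon arrival times, s (non-decreasing)
    channels   : 1 = acceptor channel, 2 = donor channel
    microtimes : arrival time within the PIE period, ns
    duration   : total measurement time, s
    donor_window / acceptor_window : PIE microtime windows, ns
    truth      : optional per-burst ground-truth table attached by the
        synthetic generator
    """

    macrotimes: np.ndarray
    channels: np.ndarray
    microtimes: np.ndarray
    duration: float
    donor_window: tuple[float, float] = (0.0, 25.0)
    acceptor_window: tuple[float, float] = (25.0, 50.0)
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        self.microtimes = np.asarray(self.microtimes, dtype=float)
        if not (self.macrotimes.size == self.channels.size
                == self.microtimes.size):
            raise ValueError("photon arrays must have equal length")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_photons(self) -> int:
        return self.macrotimes.size

    def donor_excited(self) -> np.ndarray:
        lo, hi = self.donor_window
        return (self.microtimes >= lo) & (self.microtimes < hi)

    # ---- I/O ------------------------------------------------------------
    def to_table(self, path) -> None:
        """Write as whitespace-separated columnar text."""
        df = pd.DataFrame({
            "macrotime_s": self.macrotimes,
            "channel": self.channels,
            "microtime_ns": self.microtimes,
        })
        with open(path, "w") as fh:
            fh.write(f"# duration_s {self.duration}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "PhotonStream":
        with open(path) as fh:
            header = fh.readline()
            duration = float(header.split()[-1])
            df = pd.read_csv(fh, sep="\t")
        return cls(df["macrotime_s"].to_numpy(), df["channel"].to_numpy(),
                   df["microtime_ns"].to_numpy(), duration)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("macrotime_s", data=self.macrotimes)
            f.create_dataset("channel", data=self.channels)
            f.create_dataset("microtime_ns", data=self.microtimes)
            f.attrs["duration_s"] = self.duration
            f.attrs["donor_window_ns"] = self.donor_window
            f.attrs["acceptor_window_ns"] = self.acceptor_window

    @classmethod
    def from_hdf5(cls, path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            return cls(
                f["macrotime_s"][:], f["channel"][:], f["microtime_ns"][:],
                float(f.attrs["duration_s"]),
                tuple(f.attrs.get("donor_window_ns", (0.0, 25.0))),
                tuple(f.attrs.get("acceptor_window_ns", (25.0, 50.0))),
            )


@dataclass
class Burst:
    """One detected fluorescence burst with raw, PIE-resolved and corrected
    counts and the derived per-burst observables."""

    start: int
    stop: int                 # exclusive photon index
    T: float                  # duration, s
    n1: int                   # donor-window acceptor-channel raw counts
    n2: int                   # donor-window donor-channel raw counts
    n_DD: int
    n_DA: int
    n_AA: int
    nA_corr: float
    nD_corr: float
    t_D: np.ndarray = field(repr=False)   # donor arrival times rel. start, s
    t_A: np.ndarray = field(repr=False)   # acceptor arrival times, s
    E: float = float("nan")
    S: float = float("nan")
    alpha_DA: float = float("nan")
    sigma_DA: float = float("nan")
    mean_donor_microtime: float = float("nan")
    pass_asymmetry: bool = True
    pass_stoichiometry: bool = True
    retained: bool = True


# --------------------------------------------------------------------------
# corrections
# --------------------------------------------------------------------------

def correct_counts(n1, n2, b1, b2, T, corr: CorrectionSet):
    """Background-subtract and correct raw channel counts.

    Applies the 2x2 leakage/efficiency matrix to the background-subtracted
    counts, then removes the direct-excitation contribution from the
    acceptor.  Results may be slightly negative under noise and are not
    clipped.  Returns ``(n'_A, n'_D)``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("burst duration must be non-negative")
    d1 = n1 - b1 * T
    d2 = n2 - b2 * T
    nA = corr.gamma1 * d1 - corr.beta_DA * d2
    nD = -corr.beta_AD * d1 + corr.gamma2 * d2
    nA = nA - corr.alpha_direct * (nD + nA)
    return nA, nD


# --------------------------------------------------------------------------
# burst search
# --------------------------------------------------------------------------

def _segments(stream: PhotonStream, corr: CorrectionSet,
              dt_max: float) -> np.ndarray:
    """Start indices of photon clusters under the inter-photon-time rule."""
    t = stream.macrotimes
    dt = np.diff(t, prepend=-np.inf)
    gamma = np.where(stream.channels == 1, corr.gamma1, corr.gamma2)
    extends = dt <= gamma * dt_max
    return np.flatnonzero(~extends)


def find_bursts(
    stream: PhotonStream,
    corr: CorrectionSet | None = None,
    cfg: BurstSearchConfig | None = None,
) -> tuple[list[Burst], tuple[float, float]]:
    """Iterative burst search with background re-estimation.

    Returns the retained bursts and the converged donor-window background
    rates ``(b1, b2)`` in photons/s.  An empty stream yields no bursts.
    Raises on an unsorted photon record.
    """
    corr = corr or CorrectionSet()
    cfg = cfg or BurstSearchConfig()
    t = stream.macrotimes
    if t.size == 0:
        return [], (0.0, 0.0)
    if np.any(np.diff(t) < 0):
        raise ValueError("photon macrotimes must be non-decreasing")

    dex = stream.donor_excited()
    ch1 = stream.channels == 1
    is_n1 = dex & ch1
    is_n2 = dex & ~ch1

    starts = _segments(stream, corr, cfg.dt_max)
    ends = np.r_[starts[1:], t.size]
    T_seg = t[ends - 1] - t[starts]
    n1_seg = np.add.reduceat(is_n1.astype(np.int64), starts)
    n2_seg = np.add.reduceat(is_n2.astype(np.int64), starts)

    b1 = float(is_n1.sum()) / stream.duration
    b2 = float(is_n2.sum()) / stream.duration

    retained = np.zeros(starts.size, dtype=bool)
    prev_count = -1
    for _ in range(cfg.max_iterations):
        nA, nD = correct_counts(n1_seg, n2_seg, b1, b2, T_seg, corr)
        retained = (nA + nD) > cfg.min_corrected_photons
        count = int(retained.sum())
        if count == prev_count:
            break
        prev_count = count
        # background from photons outside retained bursts
        burst_time = float(T_seg[retained].sum())
        free_time = max(stream.duration - burst_time, 1e-12)
        in_burst = np.zeros(t.size, dtype=bool)
        for s, e in zip(starts[retained], ends[retained]):
            in_burst[s:e] = True
        b1 = float(is_n1[~in_burst].sum()) / free_time
        b2 = float(is_n2[~in_burst].sum()) / free_time

    nA, nD = correct_counts(n1_seg, n2_seg, b1, b2, T_seg, corr)
    aex_a = (~dex) & ch1
    bursts: list[Burst] = []
    for i in np.flatnonzero(retained):
        s, e = starts[i], ends[i]
        sl = slice(s, e)
        t0 = t[s]
        bursts.append(Burst(
            start=int(s), stop=int(e), T=float(T_seg[i]),
            n1=int(n1_seg[i]), n2=int(n2_seg[i]),
            n_DD=int(n2_seg[i]), n_DA=int(n1_seg[i]),
            n_AA=int(aex_a[sl].sum()),
            nA_corr=float(nA[i]), nD_corr=float(nD[i]),
            t_D=t[sl][is_n2[sl]] - t0,
            t_A=t[sl][is_n1[sl]] - t0,
            mean_donor_microtime=float(
                stream.microtimes[sl][is_n2[sl]].mean()
            ) if n2_seg[i] else float("nan"),
        ))
    return bursts, (b1, b2)


# --------------------------------------------------------------------------
# per-burst observables and filters
# --------------------------------------------------------------------------

def burst_metrics(burst: Burst, corr: CorrectionSet | None = None) -> Burst:
    """Fill transfer efficiency, stoichiometry and asymmetry of a burst.

    E uses the corrected counts; S combines the corrected donor-excitation
    counts with the raw acceptor-excitation counts scaled by gamma_PIE.  The
    asymmetry compares mean raw donor and acceptor arrival times relative to
    the burst start; its shot-noise standard deviation is
    ``T / (2 sqrt 3) * (1/n'_D + 1/n'_A)^(1/2)``.
    """
    corr = corr or CorrectionSet()
    total = burst.nA_corr + burst.nD_corr
    burst.E = burst.nA_corr / total if total != 0 else float("nan")

    dex = burst.nD_corr + burst.nA_corr
    denom = dex + corr.gamma_PIE * burst.n_AA
    burst.S = dex / denom if denom != 0 else float("nan")

    if burst.t_D.size and burst.t_A.size:
        burst.alpha_DA = float(burst.t_D.mean() - burst.t_A.mean())
    else:
        burst.alpha_DA = 0.0
    if burst.nA_corr > 0 and burst.nD_corr > 0:
        burst.sigma_DA = (burst.T / (2.0 * math.sqrt(3.0))) * math.sqrt(
            1.0 / burst.nD_corr + 1.0 / burst.nA_corr
        )
    else:
        burst.sigma_DA = float("inf")
    return burst


def filter_bursts(bursts: list[Burst],
                  s_max: float = 0.8) -> list[Burst]:
    """Apply the acceptor-bleach and stoichiometry filters.

    A burst is retained when |alpha_DA| <= sigma_DA (no bleaching signature)
    and S < ``s_max`` (active acceptor present).  Per-burst flags are
    recorded; the retained subset is returned.
    """
    kept = []
    for b in bursts:
        b.pass_asymmetry = abs(b.alpha_DA) <= b.sigma_DA
        b.pass_stoichiometry = bool(np.isfinite(b.S) and b.S < s_max)
        b.retained = b.pass_asymmetry and b.pass_stoichiometry
        if b.retained:
            kept.append(b)
    return kept


def bursts_to_dataframe(bursts: list[Burst]) -> pd.DataFrame:
    cols = ["start", "stop", "T", "n1", "n2", "n_DD", "n_DA", "n_AA",
            "nA_corr", "nD_corr", "E", "S", "alpha_DA", "sigma_DA",
            "mean_donor_microtime", "pass_asymmetry", "pass_stoichiometry",
            "retained"]
    return pd.DataFrame({c: [getattr(b, c) for b in bursts] for c in cols})


# --------------------------------------------------------------------------
# efficiency-histogram fitting
# --------------------------------------------------------------------------

@dataclass
class PeakComponent:
    """One mixture component of an efficiency histogram."""

    mean: float
    width: float
    amplitude: float = 1.0
    shape: str = "gaussian"     # or "lognormal"
    fix_mean: bool = True
    fix_width: bool = True

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(
                -0.5 * ((x - self.mean) / self.width) ** 2
            )
        if self.shape == "lognormal":
            out = np.zeros_like(x)
            pos = x > 0
            out[pos] = self.amplitude / x[pos] * np.exp(
                -0.5 * ((np.log(x[pos]) - self.mean) / self.width) ** 2
            )
            return out
        raise ValueError(f"unknown peak shape {self.shape!r}")


@dataclass
class PeakFit:
    """Mixture fit of an efficiency histogram; the component at
    ``bound_index`` is the ligand-bound subpopulation."""

    components: list[PeakComponent]
    bound_index: int = -1
    bound_fraction: float = float("nan")
    converged: bool = True


def default_bins(width: float = 0.02,
                 lo: float = -0.1, hi: float = 1.1) -> np.ndarray:
    """Histogram bin edges; corrected efficiencies can leave [0, 1]."""
    return np.arange(lo, hi + width / 2, width)


def fit_fret_histogram(
    e_values,
    spec: PeakFit,
    bins: np.ndarray | None = None,
) -> PeakFit:
    """Fit a peak mixture to a transfer-efficiency histogram.

    When every component has fixed mean and width (the two-state protocol:
    peak positions/widths determined from ligand-free and ligand-saturated
    reference histograms), only the amplitudes are fitted, by non-negative
    linear least squares.  Otherwise all unfixed parameters are fitted
    nonlinearly.  The bound fraction is the numerically integrated area of
    the bound component over the total area.
    """
    e_values = np.asarray(e_values, dtype=float)
    if e_values.size < 1:
        raise ValueError("need at least one burst")
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    counts, edges = np.histogram(e_values, bins=bins)
    if counts.sum() == 0:
        raise ValueError("all-zero histogram: no efficiencies inside bins")
    centers = 0.5 * (edges[:-1] + edges[1:])

    comps = [PeakComponent(**vars(c)) for c in spec.components]
    all_fixed = all(c.fix_mean and c.fix_width for c in comps)

    if all_fixed:
        basis = np.column_stack([
            PeakComponent(c.mean, c.width, 1.0, c.shape).density(centers)
            for c in comps
        ])
        amps, _ = nnls(basis, counts.astype(float))
        for c, a in zip(comps, amps):
            c.amplitude = a
        converged = True
    else:
        comps, converged = _fit_free(centers, counts, comps)

    grid = np.linspace(edges[0], edges[-1], 2001)
    areas = np.array([np.trapezoid(c.density(grid), grid) for c in comps])
    total = areas.sum()
    bound = areas[spec.bound_index] / total if total > 0 else float("nan")
    return PeakFit(components=comps, bound_index=spec.bound_index,
                   bound_fraction=float(bound), converged=converged)


def _fit_free(centers, counts, comps):
    """Nonlinear mixture fit for components with free means/widths."""
    p0, lo, hi = [], [], []
    for c in comps:
        p0 += [c.amplitude or counts.max(), c.mean, c.width]
        lo += [0.0,
               c.mean - 1e-12 if c.fix_mean else -2.0,
               c.width * (1 - 1e-12) if c.fix_width else 1e-4]
        hi += [np.inf,
               c.mean + 1e-12 if c.fix_mean else 2.0,
               c.width * (1 + 1e-12) if c.fix_width else 2.0]

    def model(x, *p):
        y = np.zeros_like(x)
        for k, c in enumerate(comps):
            y += PeakComponent(p[3 * k + 1], p[3 * k + 2], p[3 * k],
                               c.shape).density(x)
        return y

    try:
        popt, _ = curve_fit(model, centers, counts.astype(float), p0=p0,
                            bounds=(lo, hi), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    for k, c in enumerate(comps):
        c.amplitude, c.mean, c.width = popt[3 * k: 3 * k + 3]
    return comps, converged


def fit_single_peak(e_values, shape: str = "gaussian",
                    bins: np.ndarray | None = None) -> PeakComponent:
    """Free single-component fit; used to calibrate the fixed peak position
    and width from a one-population reference measurement."""
    e_values = np.asarray(e_values, dtype=float)
    comp = PeakComponent(mean=float(np.median(e_values)),
                         width=float(e_values.std() or 0.05),
                         shape=shape, fix_mean=False, fix_width=False)
    fit = fit_fret_histogram(e_values, PeakFit(components=[comp]), bins)
    return fit.components[0]
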