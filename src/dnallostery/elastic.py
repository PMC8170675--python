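"""Elastic-coupling model of allosteric transmission through DNA.

A protein that changes the local bend of DNA at its binding site sets up a
tension field that decays along the helix with a characteristic decay length
``xi = sqrt(kBT * lp / f)`` (``lp`` persistence length, ``f`` tension).  Two
binding sites separated by a spacer of ``ds`` base pairs then couple
elastically.  Within a small-angle worm-like-chain treatment the enthalpic
cost of two kinks of local angle ``alpha`` is

    dE = 2 alpha^2 (lp / xi) (1 +/- exp(-ds / xi))      [kBT]

with + for the symmetric and - for the antisymmetric kink arrangement.  The
helical periodicity ``lambda`` (10.5 bp) interpolates between the two
parities, giving the coupling free energy as a cosine-modulated decay and an
analogous empirical expression for the Hill exponent versus spacer length.

Sign/branch convention: the cosine term can enter with either sign depending
on whether the protein introduces or relieves bending.  For a bend-relieving
protein, spacers near an integer number of helical turns sit on the
high-coupling branch (coupling decreasing with spacer length); this is the
default (``branch='native_high'``).  ``branch='printed'`` selects the
opposite sign.  Entropic contributions are small and omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "ElasticModel",
    "SpacerSeries",
    "NM_PER_BP",
    "kink_energy",
    "coupling_energy",
    "hill_vs_spacer",
    "fit_elastic",
    "tension_and_bend",
    "fit_periodicity",
]

NM_PER_BP = 0.34  # contour length per base pair


@dataclass
class ElasticModel:
    """Parameters of the elastic-coupling model.

    alpha_bend : local bending-angle change per box, degrees
    xi         : tension decay length, bp
    lp         : persistence length, nm (40 nm for B-DNA)
    lambda_helix : helical periodicity, bp
    ds0        : phase shift of the helical modulation, bp
    kBT        : thermal energy, pN nm (4.11 at 23 C)
    a, b       : scale and offset of the Hill-exponent expression
    branch     : 'native_high' (default) or 'printed' cosine sign
    """

    alpha_bend: float = 24.0
    xi: float = 14.0
    lp: float = 40.0
    lambda_helix: float = 10.5
    ds0: float = 8.0
    kBT: float = 4.11
    a: float = 1.0
    b: float = 1.0
    branch: str = "native_high"

    alpha_err: float = field(default=float("nan"), repr=False)
    xi_err: float = field(default=float("nan"), repr=False)

    def __post_init__(self) -> None:
        if self.xi <= 0 or self.lp <= 0 or self.lambda_helix <= 0:
            raise ValueError("xi, lp and lambda_helix must be positive")
        if not 0.0 <= self.alpha_bend < 90.0:
            raise ValueError("alpha_bend must be in [0, 90) degrees")
        if self.branch not in ("native_high", "printed"):
            raise ValueError("branch must be 'native_high' or 'printed'")

    @property
    def lp_bp(self) -> float:
        return self.lp / NM_PER_BP

    @property
    def cos_sign(self) -> float:
        return -1.0 if self.branch == "native_high" else 1.0


@dataclass
class SpacerSeries:
    """Observable versus spacer length (bp).

    ``kind`` identifies the observable: 'energy' for coupling free energies
    (kBT), 'hill' for Hill exponents, 'gel_fraction' for band fractions from
    an electrophoretic mobility shift assay.
    """

    ds: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    kind: str = "energy"

    def __post_init__(self) -> None:
        self.ds = np.asarray(self.ds, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.ds.shape != self.y.shape:
            raise ValueError("ds and y must have matching shapes")
        if np.any(self.ds <= 0):
            raise ValueError("spacer lengths must be positive")
        if self.kind not in ("energy", "hill", "gel_fraction"):
            raise ValueError("kind must be energy|hill|gel_fraction")


# --------------------------------------------------------------------------
# forward expressions
# --------------------------------------------------------------------------

def kink_energy(ds, alpha: float, xi: float, lp_bp: float,
                parity: str = "symmetric") -> np.ndarray:
    """Enthalpic cost (kBT) of two DNA kinks of ``alpha`` degrees separated
    by ``ds`` bp, for a symmetric (+) or antisymmetric (-) arrangement.

    ``lp_bp`` is the persistence length in bp (nm value / 0.34).
    """
    ds = np.asarray(ds, dtype=float)
    a_rad = math.radians(alpha)
    sign = {"symmetric": 1.0, "antisymmetric": -1.0}[parity]
    return 2.0 * a_rad ** 2 * (lp_bp / xi) * (1.0 + sign * np.exp(-ds / xi))


def _modulation(ds, model: ElasticModel) -> np.ndarray:
    ds = np.asarray(ds, dtype=float)
    phase = 2.0 * math.pi * (ds + model.ds0) / model.lambda_helix
    return model.cos_sign * np.cos(phase) * np.exp(-ds / model.xi)


def coupling_energy(ds, model: ElasticModel) -> np.ndarray:
    """Inter-box coupling free energy magnitude (kBT) versus spacer length.

    ``2 alpha^2 (lp/xi) (1 + sign * cos[2 pi (ds + ds0) / lambda]
    exp(-ds/xi))`` with the sign set by the branch convention.
    """
    a_rad = math.radians(model.alpha_bend)
    amp = 2.0 * a_rad ** 2 * (model.lp_bp / model.xi)
    return amp * (1.0 + _modulation(ds, model))


def hill_vs_spacer(ds, model: ElasticModel) -> np.ndarray:
    """Hill exponent versus spacer length: ``n = a (b + sign * cos * exp)``."""
    return model.a * (model.b + _modulation(ds, model))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_elastic(
    series: SpacerSeries,
    model: ElasticModel | None = None,
    fix_xi: bool | None = None,
) -> ElasticModel:
    """Fit the elastic-coupling model to a spacer series.

    The sequential protocol mirrors how the two observables constrain the
    model: a Hill-exponent series (``kind='hill'``) determines the decay
    length ``xi`` together with the empirical scale/offset ``(a, b)``; an
    energy series (``kind='energy'``) then determines the bending angle
    ``alpha`` with ``xi`` fixed (default) or free.  ``lambda_helix`` and
    ``ds0`` are always taken from ``model``.

    Returns a new :class:`ElasticModel` with fitted values and asymptotic
    standard errors.
    """
    model = model or ElasticModel()
    if series.kind == "gel_fraction":
        raise ValueError("use fit_periodicity for gel-fraction series")

    w = None
    if series.y_err is not None:
        w = 1.0 / np.where(series.y_err > 0, series.y_err, np.inf)

    params = lmfit.Parameters()
    if series.kind == "hill":
        if fix_xi is None:
            fix_xi = False
        nfree = 2 + (0 if fix_xi else 1)
        if series.ds.size < nfree:
            raise ValueError("fewer points than free parameters")
        params.add("a", value=max(series.y.mean(), 0.1), min=1e-6)
        params.add("b", value=1.0, min=1e-6)
        params.add("xi", value=model.xi, min=0.5, max=500.0, vary=not fix_xi)

        def resid(p):
            m = _clone(model, xi=p["xi"].value, a=p["a"].value, b=p["b"].value)
            r = hill_vs_spacer(series.ds, m) - series.y
            return r if w is None else r * w

        out = lmfit.minimize(resid, params)
        return _clone(
            model,
            a=out.params["a"].value,
            b=out.params["b"].value,
            xi=out.params["xi"].value,
            xi_err=out.params["xi"].stderr or float("nan"),
        )

    # energy series -> alpha (and optionally xi)
    if fix_xi is None:
        fix_xi = True
    nfree = 1 + (0 if fix_xi else 1)
    if series.ds.size < nfree:
        raise ValueError("fewer points than free parameters")
    params.add("alpha", value=max(model.alpha_bend, 5.0), min=0.0, max=89.9)
    params.add("xi", value=model.xi, min=0.5, max=500.0, vary=not fix_xi)

    def resid(p):
        m = _clone(model, alpha_bend=p["alpha"].value, xi=p["xi"].value)
        r = coupling_energy(series.ds, m) - series.y
        return r if w is None else r * w

    out = lmfit.minimize(resid, params)
    return _clone(
        model,
        alpha_bend=out.params["alpha"].value,
        xi=out.params["xi"].value,
        alpha_err=out.params["alpha"].stderr or float("nan"),
        xi_err=out.params["xi"].stderr or float("nan"),
    )


def _clone(model: ElasticModel, **overrides) -> ElasticModel:
    kwargs = dict(
        alpha_bend=model.alpha_bend,
        xi=model.xi,
        lp=model.lp,
        lambda_helix=model.lambda_helix,
        ds0=model.ds0,
        kBT=model.kBT,
        a=model.a,
        b=model.b,
        branch=model.branch,
        alpha_err=model.alpha_err,
        xi_err=model.xi_err,
    )
    kwargs.update(overrides)
    return ElasticModel(**kwargs)


def tension_and_bend(model: ElasticModel, span_bp: float = 44.0) -> tuple[float, float]:
    """Derived quantities: tension and mean bend change.

    Tension ``f = kBT lp / xi^2`` (pN, with xi converted to nm) and the mean
    bending change per bp, ``2 alpha / span`` (degrees/bp), for two boxes a
    ``span_bp`` apart.
    """
    if model.xi <= 0:
        raise ValueError("xi must be positive")
    if span_bp <= 0:
        raise ValueError("span must be positive")
    xi_nm = model.xi * NM_PER_BP
    force = model.kBT * model.lp / xi_nm ** 2
    mean_bend = 2.0 * model.alpha_bend / span_bp
    return force, mean_bend


def fit_periodicity(
    gel: SpacerSeries,
    lambda_helix: float | None = 10.5,
) -> dict:
    """Empirical cosine-plus-exponential fit of a gel-shift spacer screen.

    Model: ``y = c0 + c1 cos[2 pi (ds + ds0) / lambda] + c2 exp(-ds / c3)``.
    ``lambda_helix`` is fixed when given (default 10.5 bp) or fitted when
    None.  The phase ``ds0`` is reported modulo the periodicity.  Requires at
    least 6 spacer points.
    """
    if gel.kind != "gel_fraction":
        raise ValueError("fit_periodicity expects a gel_fraction series")
    if gel.ds.size < 6:
        raise ValueError("need at least 6 spacer points")

    lam0 = lambda_helix if lambda_helix is not None else 10.5
    # coarse phase scan for a robust starting point
    best = None
    for ds0_try in np.linspace(0.0, lam0, 22, endpoint=False):
        c = np.cos(2 * math.pi * (gel.ds + ds0_try) / lam0)
        amp = np.dot(c - c.mean(), gel.y - gel.y.mean()) / max(
            np.dot(c - c.mean(), c - c.mean()), 1e-12
        )
        sse = np.sum((gel.y - gel.y.mean() - amp * (c - c.mean())) ** 2)
        if best is None or sse < best[0]:
            best = (sse, ds0_try, amp)
    _, ds0_init, amp_init = best

    params = lmfit.Parameters()
    params.add("c0", value=float(gel.y.mean()))
    params.add("c1", value=float(abs(amp_init) + 1e-3), min=0.0)
    params.add("c2", value=float(np.ptp(gel.y)) or 0.1)
    params.add("c3", value=15.0, min=1.0, max=500.0)
    params.add("ds0", value=float(ds0_init if amp_init >= 0 else ds0_init + lam0 / 2))
    params.add("lam", value=lam0, min=6.0, max=16.0, vary=lambda_helix is None)

    def resid(p):
        phase = 2 * math.pi * (gel.ds + p["ds0"].value) / p["lam"].value
        y = (
            p["c0"].value
            + p["c1"].value * np.cos(phase)
            + p["c2"].value * np.exp(-gel.ds / p["c3"].value)
        )
        r = y - gel.y
        if gel.y_err is not None:
            r = r / np.where(gel.y_err > 0, gel.y_err, np.inf)
        return r

    out = lmfit.minimize(resid, params)
    lam = out.params["lam"].value
    ds0 = out.params["ds0"].value % lam
    return {
        "ds0": ds0,
        "ds0_err": out.params["ds0"].stderr,
        "lambda_helix": lam,
        "lambda_err": out.params["lam"].stderr if lambda_helix is None else None,
        "coeffs": {k: out.params[k].value for k in ("c0", "c1", "c2", "c3")},
        "redchi": out.redchi,
    }
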