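"""Two-state protein unfolding from Stokes-radius denaturation curves.

The measured hydrodynamic radius of a protein population that interconverts
between a compact folded state and an expanded unfolded state is modelled as
the volume-weighted average of two spheres:

    <R> = [3/(4 pi) (f v_f + (1 - f) v_u)]^(1/3)

The folded fraction follows two-state thermodynamics with a linear free
energy dependence on denaturant concentration x,

    f = exp(-dG/RT) / (1 + exp(-dG/RT)),    dG = m x + dG0,

and the unfolded-state volume expands linearly with denaturant,
``v_u = m_u x + n_u``.  dG is folded-minus-unfolded, so a stable protein has
dG0 < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "UnfoldingModel",
    "DenaturationCurve",
    "folded_fraction",
    "predicted_radius",
    "fit_unfolding",
]


@dataclass
class UnfoldingModel:
    """Two-state unfolding parameters.

    dG0 : folding free energy at zero denaturant, kJ/mol (negative = stable)
    m   : denaturant dependence of dG, kJ/mol/M
    v_f : folded-state volume, nm^3
    m_u, n_u : slope (nm^3/M) and intercept (nm^3) of the unfolded volume
    RT  : gas constant times temperature, kJ/mol (2.48 at 298 K)
    """

    dG0: float
    m: float
    v_f: float
    m_u: float
    n_u: float
    RT: float = 2.48

    dG0_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.v_f <= 0 or self.n_u <= 0:
            raise ValueError("volumes must be positive")
        if self.RT <= 0:
            raise ValueError("RT must be positive")

    @property
    def midpoint(self) -> float:
        """Denaturant concentration at which half the population is folded."""
        return -self.dG0 / self.m


def folded_fraction(x, model: UnfoldingModel) -> np.ndarray:
    """Fraction of folded molecules at denaturant concentration x (M)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("denaturant concentration must be non-negative")
    dg = (model.m * x + model.dG0) / model.RT
    # numerically stable logistic
    return np.where(dg < 0, 1.0 / (1.0 + np.exp(dg)),
                    np.exp(-np.clip(dg, None, 500)) /
                    (1.0 + np.exp(-np.clip(dg, None, 500))))


def predicted_radius(x, model: UnfoldingModel) -> np.ndarray:
    """Population-averaged Stokes radius (nm) at denaturant x (M)."""
    x = np.asarray(x, dtype=float)
    f = folded_fraction(x, model)
    v_u = model.m_u * x + model.n_u
    if np.any(v_u <= 0):
        raise ValueError("unfolded volume non-positive at given x")
    v = f * model.v_f + (1.0 - f) * v_u
    return np.cbrt(3.0 * v / (4.0 * math.pi))


@dataclass
class DenaturationCurve:
    """Stokes radius versus denaturant concentration."""

    x: np.ndarray
    radius: np.ndarray
    radius_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.x.shape != self.radius.shape:
            raise ValueError("x and radius must have matching shapes")


def fit_unfolding(curve: DenaturationCurve, RT: float = 2.48) -> UnfoldingModel:
    """Nonlinear least-squares fit of the two-state radius model.

    Fits (dG0, m, v_f, m_u, n_u) simultaneously.  Initial guesses come from
    the low- and high-denaturant plateaus; requires at least 6 points and a
    visible transition (radius span above 5% of the baseline).
    """
    x, r = curve.x, curve.radius
    if x.size < 6:
        raise ValueError("need at least 6 points spanning the transition")
    if np.ptp(r) < 0.05 * r.min():
        raise ValueError("no unfolding transition in the sampled range")

    order = np.argsort(x)
    x, r = x[order], r[order]
    vol = 4.0 * math.pi / 3.0 * r ** 3
    n_edge = max(2, x.size // 5)
    v_f0 = float(vol[:n_edge].mean())
    # unfolded line from the top quarter of the curve
    hi = slice(-max(2, x.size // 4), None)
    mu0, nu0 = np.polyfit(x[hi], vol[hi], 1)
    if nu0 <= v_f0:
        nu0 = 1.5 * v_f0
        mu0 = max(mu0, 1e-3)
    # midpoint guess: x where radius crosses half its span
    rmid = r.min() + 0.5 * np.ptp(r)
    xmid = float(np.interp(rmid, r, x))
    m0 = 4.0 * RT / max(np.ptp(x), 1e-6)
    dg0 = -m0 * xmid

    def resid(p):
        dG0, m, v_f, m_u, n_u = p
        model = UnfoldingModel(dG0=dG0, m=m, v_f=v_f, m_u=m_u, n_u=n_u, RT=RT)
        pred = predicted_radius(x, model)
        w = curve.radius_err
        if w is not None:
            return (pred - r) / np.where(w[order] > 0, w[order], np.inf)
        return pred - r

    lo = [-200.0, 0.0, 1e-3, 0.0, 1e-3]
    hiB = [50.0, 200.0, 1e4, 1e3, 1e4]
    sol = least_squares(resid, x0=[dg0, m0, v_f0, max(mu0, 1e-3), nu0],
                        bounds=(lo, hiB))
    if not sol.success:
        raise RuntimeError("unfolding fit did not converge")

    dG0, m, v_f, m_u, n_u = sol.x
    # asymptotic standard error on dG0
    dof = max(x.size - 5, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        dG0_err = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        dG0_err = float("nan")
    return UnfoldingModel(dG0=dG0, m=m, v_f=v_f, m_u=m_u, n_u=n_u, RT=RT,
                          dG0_err=dG0_err)
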