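"""Thermodynamic models of cooperative transcription-factor binding to a
two-box promoter.

The promoter carries two binding boxes with two protein-binding sites each
(four sites total).  Binding follows a sequential (Koshland-Nemethy-Filmer
style) scheme: the first ligand binds any of the four sites with microscopic
association constant ``K``; the second ligand binds only into the box that
already holds one ligand, with affinity raised by the intra-box cooperativity
factor ``sigma``; the third ligand opens the second box with the inter-box
factor ``J``; the fourth completes it with ``sigma * J``.  With the reduced
concentration ``s = K x`` the binding polynomial is

    Q = 1 + 4 s + 2 sigma s^2 + 4 J sigma s^3 + J^2 sigma^2 s^4

and the fraction of fully bound promoter is the last term over ``Q``.
An isolated box follows ``f = sigma s^2 / (1 + 2 s + sigma s^2)``.

Free energies are expressed in units of kBT with ``K = exp(-dg_K)`` per nM
(the standard state of the concentration axis), ``sigma = exp(-dg_sigma)``
and ``J = exp(-dg_J)``; the DNA-mediated coupling free energy reported in the
results is ``-dg_J``.

These closed forms hold in the dilute-promoter limit (promoter concentration
much below 1/K), where the free ligand concentration equals the total one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "KNFModel",
    "BindingIsotherm",
    "HillFit",
    "OccupancyDistribution",
    "KNF_STATE_OCCUPANCY",
    "knf_fraction",
    "enumerate_states",
    "occupancy_distribution",
    "fit_hill",
    "fit_knf_global",
    "hill_from_occupancy",
    "hill_transform",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class KNFModel:
    """Sequential binding model with intra- (sigma) and inter-box (J)
    cooperativity.

    Parameters are free energies in kBT; ``dg_K`` is referenced to a 1 nM
    standard state so that ``K = exp(-dg_K)`` carries units of 1/nM.
    ``dg_J`` is ignored for a single isolated box (``n_boxes=1``).
    """

    dg_K: float
    dg_sigma: float = 0.0
    dg_J: float = 0.0
    n_boxes: int = 2

    def __post_init__(self) -> None:
        if self.n_boxes not in (1, 2):
            raise ValueError("n_boxes must be 1 or 2")

    @property
    def K(self) -> float:
        return math.exp(-self.dg_K)

    @property
    def sigma(self) -> float:
        return math.exp(-self.dg_sigma)

    @property
    def J(self) -> float:
        return math.exp(-self.dg_J)

    @property
    def coupling_energy(self) -> float:
        """DNA-mediated coupling free energy ``-dg_J`` in kBT."""
        return -self.dg_J


@dataclass
class BindingIsotherm:
    """Bound fraction versus free ligand concentration (nM)."""

    x: np.ndarray
    f: np.ndarray
    f_err: np.ndarray | None = None
    label: str = ""
    n_boxes: int = 2

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.x.shape != self.f.shape:
            raise ValueError("x and f must have matching shapes")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if self.f_err is not None:
            self.f_err = np.asarray(self.f_err, dtype=float)


@dataclass
class HillFit:
    """Empirical Hill isotherm ``f = x^n / (K_Hill^n + x^n)``."""

    n: float
    K_Hill: float
    n_err: float = float("nan")
    K_err: float = float("nan")

    def fraction(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (x / self.K_Hill) ** self.n
            f = s / (1.0 + s)
        return np.where(x == 0, 0.0, f)


@dataclass
class OccupancyDistribution:
    """Probability ``p[i]`` that a promoter particle carries ``i`` bound
    ligands, ``i = 0..N``."""

    p: np.ndarray
    N: int = 4

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != self.N + 1:
            raise ValueError("p must have N+1 entries")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.p.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("probabilities must sum to 1")


# --------------------------------------------------------------------------
# state enumeration and occupancy
# --------------------------------------------------------------------------

# ligand count of the 12 allowed microstates of the two-box scheme:
# empty, 4 singly bound, 2 within-box doubles, 4 triples, 1 fully bound.
# Cross-box doubles are forbidden (the second ligand always completes a box).
KNF_STATE_OCCUPANCY = np.array([0, 1, 1, 1, 1, 2, 2, 3, 3, 3, 3, 4])


def _state_weights(s: float, sigma: float, J: float) -> np.ndarray:
    """Unnormalised statistical weights of the 12 allowed microstates."""
    single = s
    double = sigma * s * s
    triple = J * sigma * s ** 3
    quad = (J * sigma * s * s) ** 2
    return np.array(
        [1.0] + [single] * 4 + [double] * 2 + [triple] * 4 + [quad]
    )


def enumerate_states(x: float, model: KNFModel) -> tuple[np.ndarray, np.ndarray]:
    """Normalised microstate probabilities of the two-box model.

    Returns ``(occupancy, probability)`` over the 12 allowed states.  The
    weights before normalisation are ``{1, 4s, 2 sigma s^2, 4 J sigma s^3,
    J^2 sigma^2 s^4}`` grouped by occupancy, i.e. exactly the terms of the
    binding polynomial Q.
    """
    if x < 0:
        raise ValueError("concentration must be non-negative")
    if model.n_boxes != 2:
        raise ValueError("state enumeration is defined for the two-box model")
    w = _state_weights(model.K * x, model.sigma, model.J)
    return KNF_STATE_OCCUPANCY.copy(), w / w.sum()


def occupancy_distribution(x: float, model: KNFModel) -> OccupancyDistribution:
    """Aggregate microstate probabilities into p(i), i = 0..4."""
    occ, prob = enumerate_states(x, model)
    p = np.bincount(occ, weights=prob, minlength=5)
    return OccupancyDistribution(p=p, N=4)


def knf_fraction(x, model: KNFModel) -> np.ndarray:
    """Fraction of fully bound promoter (two-box) or fully bound box
    (single-box) at free ligand concentration ``x`` (nM)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    s = model.K * x
    sigma = model.sigma
    if model.n_boxes == 1:
        return sigma * s ** 2 / (1.0 + 2.0 * s + sigma * s ** 2)
    J = model.J
    quad = (J * sigma * s * s) ** 2
    Q = 1.0 + 4.0 * s + 2.0 * sigma * s ** 2 + 4.0 * J * sigma * s ** 3 + quad
    return quad / Q


# --------------------------------------------------------------------------
# isotherm fitting
# --------------------------------------------------------------------------

def _weights(iso: BindingIsotherm) -> np.ndarray | None:
    if iso.f_err is None:
        return None
    err = np.where(iso.f_err > 0, iso.f_err, np.nan)
    w = 1.0 / err
    return np.where(np.isfinite(w), w, np.nanmax(w[np.isfinite(w)]))


def fit_hill(iso: BindingIsotherm) -> HillFit:
    """Weighted nonlinear least-squares fit of the Hill equation.

    Fitting is performed on f versus x with the midpoint parameterised in
    log-concentration for stability.  Raises if the isotherm shows no
    transition (f span below 0.1) or has fewer than four points.
    """
    if iso.x.size < 4:
        raise ValueError("need at least 4 concentrations to fit a Hill curve")
    if np.ptp(iso.f) < 0.1:
        raise ValueError("no binding transition in the sampled range")

    pos = iso.x > 0
    # midpoint initial guess: concentration where f crosses half its span
    fmid = iso.f.min() + 0.5 * np.ptp(iso.f)
    k0 = float(np.interp(fmid, iso.f[pos], iso.x[pos], period=None)) or float(
        np.median(iso.x[pos])
    )

    params = lmfit.Parameters()
    params.add("n", value=1.5, min=0.05, max=20.0)
    params.add("logK", value=math.log(max(k0, 1e-12)))

    w = _weights(iso)

    def residual(p):
        fit = HillFit(n=p["n"].value, K_Hill=math.exp(p["logK"].value))
        r = fit.fraction(iso.x) - iso.f
        return r if w is None else r * w

    out = lmfit.minimize(residual, params)
    n = out.params["n"]
    logK = out.params["logK"]
    K = math.exp(logK.value)
    K_err = K * logK.stderr if logK.stderr else float("nan")
    return HillFit(
        n=n.value,
        K_Hill=K,
        n_err=n.stderr if n.stderr else float("nan"),
        K_err=K_err,
    )


def fit_knf_global(
    isotherms: list[BindingIsotherm],
    dg_sigma: float | None = None,
) -> dict:
    """Two-stage global fit of the sequential binding model.

    Stage 1 fits all single-box isotherms (``n_boxes == 1``) with a global
    intra-box cooperativity ``dg_sigma`` and a local ``dg_K`` per isotherm
    label.  Stage 2 fixes ``dg_sigma`` and fits the two-box isotherms with a
    local ``dg_K`` and one ``dg_J`` shared by all isotherms carrying the same
    label (the per-promoter coupling).

    Parameters
    ----------
    isotherms
        Mixed list of single-box and two-box isotherms.  Labels group the
        datasets that share parameters.
    dg_sigma
        If given, skips stage 1 and uses this intra-box free energy.

    Returns
    -------
    dict with keys ``dg_sigma``, ``dg_sigma_err``, ``dg_K`` (label -> value),
    ``dg_J`` / ``dg_J_err`` (label -> value) and ``coupling_energy``
    (label -> -dg_J).
    """
    singles = [iso for iso in isotherms if iso.n_boxes == 1]
    doubles = [iso for iso in isotherms if iso.n_boxes == 2]

    result: dict = {"dg_K": {}, "dg_J": {}, "dg_J_err": {}, "coupling_energy": {}}

    if dg_sigma is None:
        if not singles:
            raise ValueError(
                "single-box isotherms required to calibrate dg_sigma "
                "(or pass dg_sigma explicitly)"
            )
        single_labels = sorted({iso.label for iso in singles})

        def resid1(p):
            chunks = []
            for iso in singles:
                m = KNFModel(
                    dg_K=p[f"dg_K_{_safe(iso.label)}"].value,
                    dg_sigma=p["dg_sigma"].value,
                    n_boxes=1,
                )
                r = knf_fraction(iso.x, m) - iso.f
                w = _weights(iso)
                chunks.append(r if w is None else r * w)
            return np.concatenate(chunks)

        # multi-start over the intra-box cooperativity to avoid the shallow
        # sigma/K trade-off minimum
        out1 = None
        for sigma0 in (-1.0, -3.0, -6.0):
            params = lmfit.Parameters()
            params.add("dg_sigma", value=sigma0, min=-30.0, max=10.0)
            for lab in single_labels:
                guess = np.mean([_dg_k_guess(iso) for iso in singles
                                 if iso.label == lab])
                params.add(f"dg_K_{_safe(lab)}", value=guess,
                           min=-30.0, max=30.0)
            trial = lmfit.minimize(resid1, params)
            if out1 is None or trial.chisqr < out1.chisqr:
                out1 = trial
        dg_sigma = out1.params["dg_sigma"].value
        result["dg_sigma_err"] = out1.params["dg_sigma"].stderr
        for lab in single_labels:
            result["dg_K"][lab] = out1.params[f"dg_K_{_safe(lab)}"].value
    else:
        result["dg_sigma_err"] = None
    result["dg_sigma"] = dg_sigma

    if doubles:
        labels = sorted({iso.label for iso in doubles})

        def resid2(p):
            chunks = []
            for iso in doubles:
                m = KNFModel(
                    dg_K=p[f"dg_K2_{_safe(iso.label)}"].value,
                    dg_sigma=dg_sigma,
                    dg_J=p[f"dg_J_{_safe(iso.label)}"].value,
                    n_boxes=2,
                )
                r = knf_fraction(iso.x, m) - iso.f
                w = _weights(iso)
                chunks.append(r if w is None else r * w)
            return np.concatenate(chunks)

        out2 = None
        for j0 in (-0.5, -2.0, -4.0, -6.0):
            params = lmfit.Parameters()
            for lab in labels:
                params.add(f"dg_J_{_safe(lab)}", value=j0, min=-30.0, max=10.0)
                guess = np.mean([_dg_k_guess(iso) for iso in doubles
                                 if iso.label == lab])
                params.add(f"dg_K2_{_safe(lab)}", value=guess,
                           min=-30.0, max=30.0)
            trial = lmfit.minimize(resid2, params)
            if out2 is None or trial.chisqr < out2.chisqr:
                out2 = trial
        for lab in labels:
            par = out2.params[f"dg_J_{_safe(lab)}"]
            result["dg_J"][lab] = par.value
            result["dg_J_err"][lab] = par.stderr
            result["coupling_energy"][lab] = -par.value
    return result


def _dg_k_guess(iso: BindingIsotherm) -> float:
    """Initial dg_K from the half-saturation concentration."""
    pos = iso.x > 0
    if not np.any(pos):
        return 0.0
    fmid = iso.f.min() + 0.5 * np.ptp(iso.f)
    k0 = float(np.interp(fmid, iso.f[pos], iso.x[pos]))
    return math.log(max(k0, 1e-9))


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label) or "x"


# --------------------------------------------------------------------------
# Hill statistic of an occupancy distribution
# --------------------------------------------------------------------------

def hill_from_occupancy(dist: OccupancyDistribution) -> float:
    """Hill coefficient from the distribution of bound ligands.

    ``n = Var(i) / (<i> (1 - <i>/N))``: the observed variance over the
    variance of the binomial (non-cooperative) distribution with the same
    mean.  Undefined (raises) when the mean occupancy is 0 or N.
    """
    i = np.arange(dist.N + 1)
    mean = float(np.dot(i, dist.p))
    second = float(np.dot(i * i, dist.p))
    if mean <= 0 or mean >= dist.N:
        raise ValueError("Hill statistic undefined at empty or full occupancy")
    var = second - mean * mean
    return var / (mean * (1.0 - mean / dist.N))


def hill_transform(iso: BindingIsotherm) -> tuple[np.ndarray, np.ndarray]:
    """Hill-plot coordinates ``(log10 x, log10 (f/(1-f)))`` for display.

    Points with f outside (0, 1) or x == 0 are dropped.
    """
    ok = (iso.f > 0) & (iso.f < 1) & (iso.x > 0)
    return np.log10(iso.x[ok]), np.log10(iso.f[ok] / (1.0 - iso.f[ok]))
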