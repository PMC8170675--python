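"""Dye-linker conformer clouds and cloud-averaged FRET prediction.

Fluorophores are tethered to a DNA base through a flexible alkyl chain.  The
accessible positions of the dye are modelled with the rotational isomeric
state (RIS) picture: the linker nitrogen is planted in the base plane (132 pm
from the C8 atom at an N-C8-N9 angle of 123 degrees) and a polyethylene
chain of seven carbons follows, each backbone dihedral sampling the anti
(180), gauche+ (+60) and gauche- (-60) rotamers with a Boltzmann penalty per
gauche state.  Full enumeration yields 3^7 = 2187 chains; conformers whose
linker atoms or terminal fluorophore sphere clash with supplied excluded-
volume atoms are discarded and the weights renormalised.

The FRET efficiency between two such clouds is the weight-averaged Forster
expression over all donor/acceptor position pairs:

    E = sum_i sum_j p_i q_j R0^6 / (R0^6 + r_ij^6)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DyeAttachment",
    "DyeCloud",
    "anchor_frame_from_base",
    "enumerate_conformers",
    "predicted_fret",
    "read_clash_atoms",
]

# standard polyethylene geometry
BOND_LENGTH_NM = 0.153
TETRAHEDRAL_ANGLE_DEG = 109.5
CARBON_RADIUS_NM = 0.17
RT_KJ_MOL = 2.48

ROTAMER_DIHEDRALS_DEG = (180.0, 60.0, -60.0)  # anti, gauche+, gauche-
_N_GAUCHE = np.array([0, 1, 1])


@dataclass
class DyeAttachment:
    """Anchoring geometry and chain parameters of one dye.

    ``anchor`` is the linker nitrogen position; ``ref1``/``ref2`` are the
    two preceding reference atoms (C8 and N9 of the base) that define the
    first two backbone dihedrals.  All coordinates in nm.
    """

    anchor: np.ndarray
    ref1: np.ndarray
    ref2: np.ndarray
    n_bonds: int = 7
    bond_length: float = BOND_LENGTH_NM
    bond_angle: float = TETRAHEDRAL_ANGLE_DEG
    gauche_penalty: float = 2.1   # kJ/mol per gauche rotamer
    fluorophore_radius: float = 0.35

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.ref1 = np.asarray(self.ref1, dtype=float)
        self.ref2 = np.asarray(self.ref2, dtype=float)
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be at least 1")
        if self.gauche_penalty < 0:
            raise ValueError("gauche penalty must be non-negative")


@dataclass
class DyeCloud:
    """Weighted dye positions (nm); weights sum to 1 over retained
    conformers."""

    positions: np.ndarray
    weights: np.ndarray
    n_enumerated: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.positions.shape[0] != self.weights.size:
            raise ValueError("positions and weights must match")
        if self.positions.shape[0] == 0:
            raise ValueError("empty dye cloud")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        self.weights = self.weights / total


def anchor_frame_from_base(c8, n9, plane_ref) -> DyeAttachment:
    """Place the linker nitrogen relative to an adenine base.

    The nitrogen sits 0.132 nm from C8, in the base plane spanned by C8, N9
    and ``plane_ref`` (any third in-plane atom), at an N-C8-N9 angle of 123
    degrees, on the side away from ``plane_ref``.
    """
    c8 = np.asarray(c8, dtype=float)
    n9 = np.asarray(n9, dtype=float)
    plane_ref = np.asarray(plane_ref, dtype=float)
    e1 = n9 - c8
    e1 /= np.linalg.norm(e1)
    normal = np.cross(e1, plane_ref - c8)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("base reference atoms are collinear")
    normal /= nn
    e2 = np.cross(normal, e1)
    ang = math.radians(123.0)
    anchor = c8 + 0.132 * (math.cos(ang) * e1 - math.sin(ang) * e2)
    return DyeAttachment(anchor=anchor, ref1=c8, ref2=n9)


def _extend(prev3: np.ndarray, prev2: np.ndarray, prev1: np.ndarray,
            bond: float, angle_deg: float,
            dihedral_deg: np.ndarray) -> np.ndarray:
    """Vectorised natural-extension placement of the next chain atom.

    ``prev*`` have shape (n, 3); ``dihedral_deg`` shape (n,).  Returns the
    new atom positions, bond length ``bond`` from prev1, with the given bond
    angle and dihedral.
    """
    b1 = prev2 - prev3
    b2 = prev1 - prev2
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, b2n)
    theta = math.radians(180.0 - angle_deg)
    phi = np.radians(dihedral_deg)[:, None]
    d = (
        math.cos(theta) * b2n
        + math.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n)
    )
    return prev1 + bond * d


def enumerate_conformers(
    att: DyeAttachment,
    clash_positions: np.ndarray | None = None,
    clash_radii: np.ndarray | float | None = None,
    allowed_clash_prefix: int = 0,
) -> DyeCloud:
    """Enumerate all RIS chains of the dye linker and return the retained,
    Boltzmann-weighted fluorophore positions.

    Each of the ``n_bonds`` backbone dihedrals samples anti/gauche+/gauche-,
    giving ``3 ** n_bonds`` conformers.  Weights are proportional to
    ``exp(-n_gauche * gauche_penalty / RT)``.  When ``clash_positions`` is
    given, chain carbons beyond the first ``allowed_clash_prefix`` atoms
    (and always the terminal fluorophore, modelled as a sphere of
    ``att.fluorophore_radius``) are tested for overlap against the excluded-
    volume atoms and clashing conformers are discarded.

    Raises when every conformer clashes.
    """
    n_conf = 3 ** att.n_bonds
    choices = np.array(
        list(itertools.product(range(3), repeat=att.n_bonds)), dtype=np.int8
    )
    dihedrals = np.asarray(ROTAMER_DIHEDRALS_DEG)[choices]  # (n_conf, n_bonds)
    n_gauche = _N_GAUCHE[choices].sum(axis=1)

    # grow the chain: reference atoms N9 -> C8 -> N(anchor), then n_bonds C
    prev3 = np.broadcast_to(att.ref2, (n_conf, 3)).copy()
    prev2 = np.broadcast_to(att.ref1, (n_conf, 3)).copy()
    prev1 = np.broadcast_to(att.anchor, (n_conf, 3)).copy()
    chain = np.empty((n_conf, att.n_bonds, 3))
    for k in range(att.n_bonds):
        new = _extend(prev3, prev2, prev1, att.bond_length, att.bond_angle,
                      dihedrals[:, k])
        chain[:, k, :] = new
        prev3, prev2, prev1 = prev2, prev1, new

    keep = np.ones(n_conf, dtype=bool)
    if clash_positions is not None and len(clash_positions):
        clash_positions = np.atleast_2d(np.asarray(clash_positions, float))
        if clash_radii is None:
            clash_radii = CARBON_RADIUS_NM
        radii = np.broadcast_to(
            np.asarray(clash_radii, dtype=float), (clash_positions.shape[0],)
        )
        for k in range(att.n_bonds):
            last = k == att.n_bonds - 1
            if k < allowed_clash_prefix and not last:
                continue
            own = att.fluorophore_radius if last else CARBON_RADIUS_NM
            d = cdist(chain[:, k, :], clash_positions)
            keep &= np.all(d >= radii[None, :] + own, axis=1)
    if not np.any(keep):
        raise ValueError("all conformers clash with the excluded volume")

    weights = np.exp(-n_gauche[keep] * att.gauche_penalty / RT_KJ_MOL)
    return DyeCloud(
        positions=chain[keep, -1, :],
        weights=weights,
        n_enumerated=n_conf,
    )


def predicted_fret(donor: DyeCloud, acceptor: DyeCloud,
                   R0: float = 5.4) -> float:
    """Cloud-averaged FRET efficiency between donor and acceptor dye
    clouds."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    r = cdist(donor.positions, acceptor.positions)
    with np.errstate(divide="ignore"):
        e = R0 ** 6 / (R0 ** 6 + r ** 6)
    e[r == 0] = 1.0
    return float(donor.weights @ e @ acceptor.weights)


def read_clash_atoms(path) -> tuple[np.ndarray, np.ndarray]:
    """Read excluded-volume atoms from a PDB file.

    Returns (positions in nm, van der Waals radii in nm).  Radii use a small
    per-element table; unknown elements default to carbon.
    """
    from Bio.PDB import PDBParser

    vdw = {"H": 0.12, "C": 0.17, "N": 0.155, "O": 0.152, "P": 0.18,
           "S": 0.18}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("clash", str(path))
    pos, rad = [], []
    for atom in structure.get_atoms():
        pos.append(atom.coord / 10.0)  # angstrom -> nm
        rad.append(vdw.get((atom.element or "C").upper(), 0.17))
    return np.asarray(pos, dtype=float), np.asarray(rad, dtype=float)
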