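"""Karplus-based analysis of vicinal J-couplings, sugar pseudorotation and
backbone torsion restraints for B-form DNA.

The deoxyribose ring conformation is described by the pseudorotation phase
``P`` (degrees, 0-360) and puckering amplitude ``phi_m`` (degrees).  The five
endocyclic torsions are

    nu_j = phi_m * cos(P + 144 * (j - 2)),   j = 0..4

so that ``nu2 = phi_m * cos(P)``.  S-type (C2'-endo, P ~ 90-270 deg) sugars
characterise B-DNA; N-type (C3'-endo, P near 18 deg) characterise A-form.

Vicinal couplings follow the Karplus relationship

    3J(theta) = A cos^2(theta) + B cos(theta) + C

with the proton-proton dihedrals tied to the ring torsions by empirical
linear phase relations (see :data:`HH_PHASE`).  Coefficients are
configurable; the defaults below are standard deoxyribose H-H and H-P sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "KarplusParams",
    "SugarPucker",
    "CouplingSet",
    "BackboneTorsions",
    "TorsionRestraint",
    "KARPLUS_HH",
    "KARPLUS_HP",
    "karplus_j",
    "pucker_to_endocyclic",
    "endocyclic_to_pucker",
    "predict_sugar_couplings",
    "estimate_pucker",
    "epsilon_from_j",
    "zeta_from_epsilon",
    "beta_classify",
]


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients of 3J(theta) = A cos^2 theta + B cos theta + C (Hz)."""

    A: float
    B: float
    C: float
    label: str = "HH"

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("Karplus A coefficient must be positive")

    @property
    def jmax(self) -> float:
        """Maximum of the curve over theta (attained at cos theta = +-1
        or at the interior stationary point when it lies in [-1, 1])."""
        candidates = [self.A + self.B + self.C, self.A - self.B + self.C]
        return max(candidates)


#: Default proton-proton coefficients (Hz).
KARPLUS_HH = KarplusParams(10.2, -0.8, 0.0, "HH")
#: Default phosphorus-proton coefficients (Hz).
KARPLUS_HP = KarplusParams(15.3, -6.2, 1.5, "HP")

#: Linear phase relations theta(nu) tying each sugar H-H dihedral to the
#: endocyclic torsion it rides on: theta = offset + slope * nu.
HH_PHASE = {
    "J_H1p_H2p": ("nu1", 121.4, 1.03),
    "J_H1p_H2pp": ("nu1", 0.9, 1.02),
    "J_H2p_H3p": ("nu2", 2.4, 1.06),
    "J_H2pp_H3p": ("nu2", 122.9, 1.06),
}


@dataclass(frozen=True)
class SugarPucker:
    """Pseudorotation phase P and amplitude phi_m, both in degrees."""

    P: float
    phi_m: float
    degenerate: bool = False

    def __post_init__(self):
        object.__setattr__(self, "P", float(self.P) % 360.0)

    @property
    def conformer(self) -> str:
        """'S' (C2'-endo family, B-DNA) or 'N' (C3'-endo family, A-DNA)."""
        return "S" if 90.0 <= self.P < 270.0 else "N"


@dataclass
class CouplingSet:
    """Measured or predicted sugar/backbone couplings in Hz (None = absent)."""

    J_H1p_H2p: Optional[float] = None
    J_H1p_H2pp: Optional[float] = None
    J_H2p_H3p: Optional[float] = None
    J_H2pp_H3p: Optional[float] = None
    J_H3p_P: Optional[float] = None
    J_P_H5p: Optional[float] = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not (0.0 <= v <= 25.0):
                raise ValueError(f"{f.name}={v} Hz outside plausible range")

    def hh_items(self):
        return [(n, getattr(self, n)) for n in HH_PHASE if getattr(self, n) is not None]


@dataclass
class BackboneTorsions:
    """One residue's backbone torsions alpha..zeta and ring torsions nu0..nu4
    (degrees, (-180, 180])."""

    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    epsilon: Optional[float] = None
    zeta: Optional[float] = None
    nu: Optional[np.ndarray] = None


@dataclass(frozen=True)
class TorsionRestraint:
    """Torsion restraint: center +- width, degrees in (-180, 180]."""

    name: str
    center: float
    width: float

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("restraint width must be positive")
        c = (self.center + 180.0) % 360.0 - 180.0
        object.__setattr__(self, "center", 180.0 if c == -180.0 else c)

    @property
    def bounds(self):
        return (self.center - self.width, self.center + self.width)


def karplus_j(theta, params: KarplusParams = KARPLUS_HH):
    """Evaluate the Karplus curve at dihedral *theta* (degrees)."""
    c = np.cos(np.radians(theta))
    return params.A * c * c + params.B * c + params.C


def pucker_to_endocyclic(pucker: SugarPucker) -> np.ndarray:
    """Endocyclic torsions nu0..nu4 (degrees) of a given pucker."""
    j = np.arange(5)
    return pucker.phi_m * np.cos(np.radians(pucker.P + 144.0 * (j - 2)))


def endocyclic_to_pucker(nu) -> SugarPucker:
    """Invert nu0..nu4 to (P, phi_m).

    Uses the exact least-squares inversion: the nu vector of a pure pucker is
    phi_m * cos(P + 144 (j-2)), so projecting onto the cos/sin harmonics of
    the 144-degree lattice recovers phase and amplitude.  A planar ring
    (all nu ~ 0) is returned flagged degenerate.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,) or not np.all(np.isfinite(nu)):
        raise ValueError("need five finite endocyclic torsions")
    ang = np.radians(144.0 * (np.arange(5) - 2))
    # nu_j = phi cosP cos(ang_j) - phi sinP sin(ang_j); orthogonal projection
    a = 2.0 / 5.0 * (nu @ np.cos(ang))   # = phi_m cos P
    b = -2.0 / 5.0 * (nu @ np.sin(ang))  # = phi_m sin P
    amp = float(np.hypot(a, b))
    if amp < 1e-9:
        return SugarPucker(0.0, 0.0, degenerate=True)
    P = float(np.degrees(np.arctan2(b, a))) % 360.0
    return SugarPucker(P, amp)


def predict_sugar_couplings(
    pucker: SugarPucker, params: KarplusParams = KARPLUS_HH
) -> CouplingSet:
    """Predict the four sugar H-H couplings of a pucker via the configured
    phase relations and Karplus curve."""
    nu = pucker_to_endocyclic(pucker)
    lookup = {"nu1": nu[1], "nu2": nu[2]}
    vals = {}
    for jname, (nuname, offset, slope) in HH_PHASE.items():
        theta = offset + slope * lookup[nuname]
        # the quadratic form can dip fractionally below zero near its root
        vals[jname] = max(0.0, float(karplus_j(theta, params)))
    return CouplingSet(**vals)


def _predict_grid(P, phi, params):
    """Vectorised coupling prediction over broadcastable P/phi arrays."""
    out = {}
    for jname, (nuname, offset, slope) in HH_PHASE.items():
        k = 1 if nuname == "nu1" else 2
        nu = phi * np.cos(np.radians(P + 144.0 * (k - 2)))
        out[jname] = np.maximum(0.0, karplus_j(offset + slope * nu, params))
    return out


def estimate_pucker(
    couplings: CouplingSet,
    params: KarplusParams = KARPLUS_HH,
    p_step: float = 1.0,
    phi_range=(20.0, 50.0),
    phi_step: float = 0.5,
):
    """Grid-search (P, phi_m) minimising the sum of squared deviations
    between predicted and observed H-H couplings.

    Returns ``(SugarPucker, residual)`` where residual is the sum of squared
    coupling errors (Hz^2) at the optimum.  Requires at least two observed
    H-H couplings; the search is deterministic.
    """
    obs = couplings.hh_items()
    if len(obs) < 2:
        raise ValueError("need at least two H-H couplings to fit a pucker")
    P = np.arange(0.0, 360.0, p_step)
    phi = np.arange(phi_range[0], phi_range[1] + 1e-9, phi_step)
    PP, FF = np.meshgrid(P, phi, indexing="ij")
    pred = _predict_grid(PP, FF, params)
    sse = np.zeros_like(PP)
    for jname, jval in obs:
        sse += (pred[jname] - jval) ** 2
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return SugarPucker(float(PP[i, j]), float(FF[i, j])), float(sse[i, j])


#: B-DNA epsilon range (degrees, trans/-gauche region) used for branch choice.
BDNA_EPSILON_RANGE = (-210.0, -120.0)


def _in_epsilon_range(eps: float) -> bool:
    lo, hi = BDNA_EPSILON_RANGE
    e = eps % 360.0
    return lo % 360.0 <= e <= hi % 360.0


def epsilon_from_j(
    j_h3p: float,
    params: KarplusParams = KARPLUS_HP,
    shift: float = -120.0,
    width: float = 30.0,
) -> TorsionRestraint:
    """Backbone epsilon (C4'-C3'-O3'-P) restraint from the H3'-P coupling.

    Inverts the H-P Karplus curve for the candidate H3'-C3'-O3'-P dihedrals,
    applies the configured shift (default -120 deg) relating that dihedral to
    epsilon, and keeps the branch falling in the B-DNA epsilon region; if no
    candidate falls inside, the nearest one is used.
    """
    if j_h3p < 0:
        raise ValueError("coupling must be non-negative")
    if j_h3p > params.jmax + 1e-9:
        raise ValueError(
            f"J = {j_h3p} Hz exceeds the Karplus curve maximum ({params.jmax:.2f} Hz)"
        )
    # A c^2 + B c + (C - J) = 0
    disc = params.B**2 - 4.0 * params.A * (params.C - j_h3p)
    roots = []
    if disc >= 0:
        for s in (+1.0, -1.0):
            c = (-params.B + s * np.sqrt(disc)) / (2.0 * params.A)
            if -1.0 <= c <= 1.0:
                roots.append(float(np.degrees(np.arccos(c))))
    if not roots:  # only possible through rounding at the extremum
        roots = [180.0]
    candidates = []
    for th in roots:
        for sign in (+1.0, -1.0):
            candidates.append(sign * th + shift)
    inside = [e for e in candidates if _in_epsilon_range(e)]
    pool = inside if inside else candidates
    lo, hi = BDNA_EPSILON_RANGE
    mid = (lo + hi) / 2.0
    best = min(pool, key=lambda e: abs((e - mid + 180.0) % 360.0 - 180.0))
    return TorsionRestraint("epsilon", best, width)


def zeta_from_epsilon(
    epsilon: float, delta_b1: float = 90.0, width: float = 30.0
) -> TorsionRestraint:
    """Zeta (C3'-O3'-P-O5') restraint from epsilon via the B-DNA BI
    correlation epsilon - zeta ~ -90 deg (zeta = epsilon + delta_b1)."""
    if not _in_epsilon_range(epsilon):
        raise ValueError(f"epsilon = {epsilon} deg outside the B-DNA range")
    return TorsionRestraint("zeta", epsilon + delta_b1, width)


def beta_classify(j_ph5: float, width: float = 30.0):
    """Classify beta from the P-H5' coupling: values of 2-5 Hz indicate a
    trans backbone (beta = 180 deg); anything else is left unclassified."""
    if j_ph5 < 0:
        raise ValueError("coupling must be non-negative")
    if 2.0 <= j_ph5 <= 5.0:
        return TorsionRestraint("beta", 180.0, width)
    return None
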