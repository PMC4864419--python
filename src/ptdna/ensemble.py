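"""Quantitative geometry on structure ensembles.

Superposition is ordinary least-squares (Kabsch); pairwise and
cross-ensemble RMSDs, ensemble-averaged atom distances, groove
localization of backbone atoms and coordinate-based sugar puckers are the
quantities the NMR-ensemble comparison of PT-free versus PT-modified
duplexes rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .coupling import SugarPucker, endocyclic_to_pucker
from .duplex import Ensemble, StructureModel
from .geom import dihedral, fit_line, kabsch

__all__ = [
    "BACKBONE_ATOMS",
    "RmsdReport",
    "DistanceStat",
    "GrooveAssignment",
    "resolve_selection",
    "superpose",
    "average_pairwise_rmsd",
    "cross_ensemble_rmsd",
    "ensemble_distance",
    "groove_assign",
    "pucker_from_coords",
]

#: backbone atom names (sulfur substitutes included)
BACKBONE_ATOMS = frozenset(
    {"P", "O1P", "O2P", "S1P", "S2P", "O5'", "C5'", "C4'", "C3'", "O3'"}
)

#: sulfur <-> oxygen positional mapping used when comparing PT and PT-free
SULFUR_MAP = {"S1P": "O1P", "S2P": "O2P"}


@dataclass
class RmsdReport:
    selection: str
    mean: float
    sd: float
    matrix: np.ndarray  # symmetric, zero diagonal


@dataclass
class DistanceStat:
    pairs: List[Tuple[int, str, int, str]]
    per_model: np.ndarray  # (n_models, n_pairs)
    mean: float
    sd: float

    @property
    def per_site_mean(self) -> np.ndarray:
        return self.per_model.mean(axis=0)


@dataclass
class GrooveAssignment:
    res_num: int
    atom: str
    label: str  # major | minor | exterior
    margin: float

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def _normalized_key(atom, map_sulfur: bool):
    name = SULFUR_MAP.get(atom.name, atom.name) if map_sulfur else atom.name
    return (atom.chain, atom.res_num, name)


def resolve_selection(
    model: StructureModel,
    selection: str = "backbone",
    map_sulfur: bool = False,
    exclude_terminal: bool = False,
):
    """Return ordered (key, index) pairs for a named selection.

    ``selection`` is one of ``backbone`` (sugar-phosphate heavy atoms),
    ``heavy`` (all non-hydrogen) or ``all``.  With ``map_sulfur`` the
    phosphorothioate sulfurs are keyed as the oxygen they replace so that
    PT and PT-free structures share a selection.  With ``exclude_terminal``
    the first and last residue of each chain are dropped (end fraying).
    """
    chains = {}
    for a in model.atoms:
        chains.setdefault(a.chain, set()).add(a.res_num)
    terminal = set()
    for nums in chains.values():
        terminal.add(min(nums))
        terminal.add(max(nums))
    out = []
    for i, a in enumerate(model.atoms):
        if exclude_terminal and a.res_num in terminal:
            continue
        if selection == "backbone" and a.name not in BACKBONE_ATOMS:
            continue
        if selection == "heavy" and a.element == "H":
            continue
        elif selection not in ("backbone", "heavy", "all"):
            raise ValueError(f"unknown selection {selection!r}")
        out.append((_normalized_key(a, map_sulfur), i))
    return out


def _matched_coords(mobile, reference, selection, map_sulfur=False, exclude_terminal=False):
    sel_m = dict(resolve_selection(mobile, selection, map_sulfur, exclude_terminal))
    sel_r = dict(resolve_selection(reference, selection, map_sulfur, exclude_terminal))
    keys = [k for k in sel_m if k in sel_r]
    if len(keys) < 3:
        raise ValueError("selections share fewer than 3 atoms")
    cm = mobile.coords()[[sel_m[k] for k in keys]]
    cr = reference.coords()[[sel_r[k] for k in keys]]
    return cm, cr, keys


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str = "backbone",
    map_sulfur: bool = False,
    exclude_terminal: bool = False,
):
    """Least-squares superposition of *mobile* onto *reference*.

    The transform is fitted on the selection but applied to every atom.
    Returns ``(moved_model, rmsd)`` where rmsd is over the selection.
    """
    cm, cr, _ = _matched_coords(mobile, reference, selection, map_sulfur, exclude_terminal)
    R, t, rmsd = kabsch(cm, cr)
    moved = mobile.with_coords(mobile.coords() @ R.T + t)
    return moved, rmsd


def average_pairwise_rmsd(
    ensemble: Ensemble, selection: str = "backbone"
) -> RmsdReport:
    """Mean +- sd of the RMSD over all unordered model pairs, each pair
    superposed independently on the selection."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 models")
    sel = [i for _, i in resolve_selection(ensemble[0], selection)]
    coords = ensemble.coords()[:, sel, :]
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    vals = np.array(vals)
    return RmsdReport(selection, float(vals.mean()), float(vals.std(ddof=1)), mat)


def _mean_structure(ensemble: Ensemble, sel_idx) -> np.ndarray:
    """Coordinates of the ensemble mean after superposing every model onto
    the first, iterated once against the running mean."""
    coords = ensemble.coords()[:, sel_idx, :]
    ref = coords[0]
    for _ in range(2):
        aligned = []
        for c in coords:
            R, t, _ = kabsch(c, ref)
            aligned.append(c @ R.T + t)
        ref = np.mean(aligned, axis=0)
    return ref


def cross_ensemble_rmsd(
    ensemble_a: Ensemble,
    ensemble_b: Ensemble,
    selection: str = "heavy",
    mode: str = "mean-structure",
    exclude_terminal: bool = True,
) -> float:
    """RMSD between two ensembles on a shared selection.

    Sulfurs are mapped onto the oxygens they replace (S1P->O1P, S2P->O2P)
    so PT-modified and PT-free duplexes are comparable.  ``mode`` is
    ``mean-structure`` (RMSD between iteratively superposed ensemble means)
    or ``model1`` (RMSD between the two first models).
    """
    ma, mb = ensemble_a[0], ensemble_b[0]
    sel_a = dict(resolve_selection(ma, selection, True, exclude_terminal))
    sel_b = dict(resolve_selection(mb, selection, True, exclude_terminal))
    keys = [k for k in sel_a if k in sel_b]
    if len(keys) < 3:
        raise ValueError("ensembles share fewer than 3 atoms in the selection")
    ia = [sel_a[k] for k in keys]
    ib = [sel_b[k] for k in keys]
    if mode == "model1":
        ca, cb = ma.coords()[ia], mb.coords()[ib]
    elif mode == "mean-structure":
        ca = _mean_structure(ensemble_a, ia)
        cb = _mean_structure(ensemble_b, ib)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _, _, rmsd = kabsch(ca, cb)
    return rmsd


def ensemble_distance(
    ensemble: Ensemble, pairs: Sequence[Tuple[int, str, int, str]]
) -> DistanceStat:
    """Per-model Euclidean distances for one or more atom pairs.

    When several symmetry-related pairs are given (e.g. G2:H2''-G3:O2P and
    G16:H2''-G17:O2P) the reported mean +- sd pools all of them; per-site
    means remain available on the result.
    """
    if not pairs:
        raise ValueError("no atom pairs given")
    per_model = np.zeros((len(ensemble), len(pairs)))
    for im, model in enumerate(ensemble):
        for ip, (ra, aa, rb, ab) in enumerate(pairs):
            ca = model.atom(ra, aa).coord
            cb = model.atom(rb, ab).coord
            per_model[im, ip] = np.linalg.norm(ca - cb)
    flat = per_model.ravel()
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    return DistanceStat(list(pairs), per_model, float(flat.mean()), sd)


#: base-edge atoms facing each groove
MAJOR_EDGE = {
    "DG": ("O6", "N7"),
    "DA": ("N6", "N7"),
    "DC": ("N4", "C5"),
    "DT": ("O4", "C5"),
}
MINOR_EDGE = {
    "DG": ("N3", "N2"),
    "DA": ("N3", "C2"),
    "DC": ("O2",),
    "DT": ("O2",),
}
# PT-modified guanines keep guanine edges
for _alias in ("RSG", "SSG"):
    MAJOR_EDGE[_alias] = MAJOR_EDGE["DG"]
    MINOR_EDGE[_alias] = MINOR_EDGE["DG"]


def helical_axis(model: StructureModel):
    """Best-fit line through the C1'-C1' midpoints of the paired levels."""
    by_chain = {}
    for a in model.atoms:
        if a.name == "C1'":
            by_chain.setdefault(a.chain, []).append(a)
    if len(by_chain) != 2:
        raise ValueError("duplex with two chains required")
    (ca, cb) = (sorted(v, key=lambda x: x.res_num) for v in by_chain.values())
    if len(ca) != len(cb):
        raise ValueError("strands differ in length")
    mids = [
        0.5 * (a.coord + b.coord) for a, b in zip(ca, reversed(cb))
    ]
    return fit_line(np.array(mids))


def _axial_radius(point, center, direction):
    v = point - center
    return float(np.linalg.norm(v - (v @ direction) * direction))


def groove_assign(
    model: StructureModel,
    res_num: int,
    atom_name: str,
    margin: float = 0.5,
) -> GrooveAssignment:
    """Locate an atom relative to the helix grooves.

    ``exterior`` if the atom lies farther from the helical axis than the
    mean phosphorus radius plus the margin; otherwise ``major`` / ``minor``
    by which base-edge atom set is closer (by more than the margin; exact
    ties fall to the closer set with the achieved margin reported).
    """
    target = model.atom(res_num, atom_name).coord
    center, direction = helical_axis(model)
    p_radii = [
        _axial_radius(a.coord, center, direction)
        for a in model.atoms
        if a.name == "P"
    ]
    if p_radii:
        r = _axial_radius(target, center, direction)
        if r > np.mean(p_radii) + margin:
            return GrooveAssignment(
                res_num, atom_name, "exterior", float(r - np.mean(p_radii))
            )
    dmaj = dmin = np.inf
    for a in model.atoms:
        if a.res_num == res_num and a.name == atom_name:
            continue
        if a.name in MAJOR_EDGE.get(a.res_name, ()):
            dmaj = min(dmaj, float(np.linalg.norm(a.coord - target)))
        if a.name in MINOR_EDGE.get(a.res_name, ()):
            dmin = min(dmin, float(np.linalg.norm(a.coord - target)))
    if not np.isfinite(dmaj) or not np.isfinite(dmin):
        raise ValueError("model has no classified base-edge atoms")
    label = "major" if dmaj <= dmin else "minor"
    return GrooveAssignment(res_num, atom_name, label, abs(dmin - dmaj))


RING_DIHEDRALS = [
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
]


def pucker_from_coords(model: StructureModel, res_num: int):
    """Sugar pucker of one residue from its ring coordinates.

    Returns ``(SugarPucker, label)`` with label 'S' for P in [90, 270) and
    'N' otherwise; a planar ring raises.
    """
    coords = {}
    for name in ("C1'", "C2'", "C3'", "C4'", "O4'"):
        coords[name] = model.atom(res_num, name).coord
    nu = [dihedral(*(coords[n] for n in quad)) for quad in RING_DIHEDRALS]
    pucker = endocyclic_to_pucker(np.array(nu))
    if pucker.degenerate:
        raise ValueError(f"residue {res_num}: planar (degenerate) sugar ring")
    return pucker, pucker.conformer
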