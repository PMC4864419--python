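"""NOE-derived distance restraints and Watson-Crick restraints.

NOE cross-peak volumes are converted to distances under the isolated spin
pair approximation (ISPA), d = d_ref * (V_ref / V)^(1/6), calibrated on the
cytosine H5-H6 distance of 2.45 A.  Calibrated distances are binned into
loose bounds: non-exchangeable protons into 1.8-2.9 / 1.8-3.5 / 1.8-6.0 A
(strong / medium / weak), exchangeable protons into 1.8-4.0 / 1.8-5.0 /
1.8-8.0 A, where the exchangeable classes follow the NOESY mixing-time
behaviour (strong at 50 ms, weak at 50 ms, observed only at 200 ms).
Degenerate proton groups (methyls) receive a pseudoatom correction on the
upper bound.  Watson-Crick pairs additionally contribute hydrogen-bond and
base-pair planarity restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from .duplex import DuplexSpec, WC_COMPLEMENT

__all__ = [
    "NoePeak",
    "DistanceRestraint",
    "HBondRestraint",
    "PlanarityRestraint",
    "REFERENCE_DISTANCE",
    "calibrate_distance",
    "classify_noe",
    "classify_exchangeable_series",
    "pseudoatom_correction",
    "generate_wc_restraints",
    "restraint_counts",
    "write_restraint_table",
    "read_restraint_table",
]

REFERENCE_DISTANCE = 2.45  # cytosine H5-H6, Angstrom

#: distance bounds per intensity class
BOUNDS_NONEXCHANGEABLE = {
    "strong": (1.8, 2.9),
    "medium": (1.8, 3.5),
    "weak": (1.8, 6.0),
}
BOUNDS_EXCHANGEABLE = {
    "strong": (1.8, 4.0),
    "medium": (1.8, 5.0),
    "weak": (1.8, 8.0),
}

#: calibrated-distance thresholds for class assignment (non-exchangeable)
CLASS_THRESHOLDS = (2.9, 3.5)


@dataclass(frozen=True)
class NoePeak:
    """One NOESY cross peak between two protons."""

    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    volume: Optional[float] = None
    mixing_time_ms: float = 150.0
    exchangeable: bool = False
    intensity: Optional[str] = None  # strong | medium | weak | None

    def __post_init__(self):
        if self.volume is not None and not self.volume > 0:
            raise ValueError("peak volume must be positive")
        if not self.mixing_time_ms > 0:
            raise ValueError("mixing time must be positive")
        if self.intensity is not None and self.intensity not in (
            "strong",
            "medium",
            "weak",
        ):
            raise ValueError(f"unknown intensity class {self.intensity!r}")


@dataclass(frozen=True)
class DistanceRestraint:
    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    lower: float
    upper: float
    label: str = ""
    pseudoatom_corrected: bool = False

    def __post_init__(self):
        if not (1.8 <= self.lower < self.upper):
            raise ValueError(
                f"invalid bounds ({self.lower}, {self.upper}): need 1.8 <= lower < upper"
            )


@dataclass(frozen=True)
class HBondRestraint:
    """One Watson-Crick hydrogen bond: donor-H...acceptor."""

    donor_res: int
    donor_atom: str
    hydrogen: str
    acceptor_res: int
    acceptor_atom: str
    heavy_bounds: Tuple[float, float] = (2.8, 3.0)
    hydrogen_bounds: Tuple[float, float] = (1.8, 2.0)


@dataclass(frozen=True)
class PlanarityRestraint:
    """Keep the two bases of a pair coplanar (one group per pair)."""

    res_a: int
    res_b: int


def calibrate_distance(
    volume: float,
    reference_volume: float,
    reference_distance: float = REFERENCE_DISTANCE,
) -> float:
    """ISPA distance calibration: d = d_ref * (V_ref / V)^(1/6)."""
    if not (volume > 0 and reference_volume > 0):
        raise ValueError("volumes must be positive")
    return reference_distance * (reference_volume / volume) ** (1.0 / 6.0)


def classify_noe(
    peak: NoePeak, calibrated_distance: Optional[float] = None
) -> DistanceRestraint:
    """Turn one peak into a distance restraint.

    An explicit intensity class on the peak wins; otherwise the calibrated
    distance is thresholded (<= 2.9 strong, <= 3.5 medium, else weak).
    Exchangeable peaks use the wider exchangeable bounds and require an
    explicit class when no calibrated distance is given (use
    :func:`classify_exchangeable_series` to derive classes from the
    mixing-time series).
    """
    cls = peak.intensity
    if cls is None:
        if calibrated_distance is None:
            raise ValueError("peak has neither an intensity class nor a distance")
        if calibrated_distance <= CLASS_THRESHOLDS[0]:
            cls = "strong"
        elif calibrated_distance <= CLASS_THRESHOLDS[1]:
            cls = "medium"
        else:
            cls = "weak"
    table = BOUNDS_EXCHANGEABLE if peak.exchangeable else BOUNDS_NONEXCHANGEABLE
    lo, hi = table[cls]
    return DistanceRestraint(
        peak.res_a, peak.atom_a, peak.res_b, peak.atom_b, lo, hi, label=cls
    )


def classify_exchangeable_series(
    peaks: Sequence[NoePeak], strong_threshold: float
) -> List[NoePeak]:
    """Assign intensity classes to exchangeable peaks from the two-mixing-time
    NOESY convention: strong = intense at 50 ms (volume >= threshold),
    medium = present but weak at 50 ms, weak = observed only at 200 ms.

    Peaks describing the same proton pair at different mixing times are
    grouped; one classified peak per pair is returned.
    """
    groups = {}
    for p in peaks:
        if not p.exchangeable:
            raise ValueError("series classification applies to exchangeable peaks")
        key = tuple(sorted([(p.res_a, p.atom_a), (p.res_b, p.atom_b)]))
        groups.setdefault(key, []).append(p)
    out = []
    for plist in groups.values():
        at50 = [p for p in plist if abs(p.mixing_time_ms - 50.0) < 1e-6]
        if at50 and at50[0].volume is not None and at50[0].volume >= strong_threshold:
            cls, rep = "strong", at50[0]
        elif at50:
            cls, rep = "medium", at50[0]
        else:
            cls, rep = "weak", plist[0]
        out.append(replace(rep, intensity=cls))
    return out


def pseudoatom_correction(
    restraint: DistanceRestraint, group: str = "methyl", correction: float = 1.0
) -> DistanceRestraint:
    """Widen the upper bound of a restraint targeting a degenerate proton
    group (default +1.0 A for methyls) and flag it as corrected."""
    if group not in ("methyl", "degenerate"):
        raise ValueError(f"not a degenerate proton group: {group!r}")
    if correction == 0.0:
        return restraint
    return replace(
        restraint, upper=restraint.upper + correction, pseudoatom_corrected=True
    )


#: Watson-Crick hydrogen bond topology, purine heavy atom listed first.
_WC_FULL = {
    "GC": [
        # (purine heavy, hydrogen, pyrimidine heavy, donor side)
        ("O6", "H41", "N4", "py"),
        ("N1", "H1", "N3", "pu"),
        ("N2", "H21", "O2", "pu"),
    ],
    "AT": [
        ("N6", "H61", "O4", "pu"),
        ("N1", "H3", "N3", "py"),
    ],
}


def generate_wc_restraints(spec: DuplexSpec):
    """Hydrogen-bond and planarity restraints for every pair of *spec*.

    G·C pairs contribute three hydrogen bonds, A·T pairs two; each pair
    contributes one planarity group.  Returns ``(hbonds, planarity)``.
    """
    hbonds: List[HBondRestraint] = []
    planes: List[PlanarityRestraint] = []
    lookup = {r.number: r.base for r in spec.strand1 + spec.strand2}
    for a, b in spec.pairing:
        ba, bb = lookup[a], lookup[b]
        if ba in "GA":
            pu_res, py_res, ptype = a, b, "GC" if ba == "G" else "AT"
        else:
            pu_res, py_res, ptype = b, a, "GC" if bb == "G" else "AT"
        for pu_atom, hyd, py_atom, donor in _WC_FULL[ptype]:
            if donor == "pu":
                hbonds.append(
                    HBondRestraint(pu_res, pu_atom, hyd, py_res, py_atom)
                )
            else:
                hbonds.append(
                    HBondRestraint(py_res, py_atom, hyd, pu_res, pu_atom)
                )
        planes.append(PlanarityRestraint(a, b))
    return hbonds, planes


def restraint_counts(restraints: Iterable[DistanceRestraint], spec: DuplexSpec) -> dict:
    """Bookkeeping in the style of NMR structure statistics tables: total,
    intra-residue, inter-residue, sequential (|i-j| = 1 within a strand) and
    non-sequential counts.  Inter-strand contacts count as non-sequential."""
    total = intra = sequential = nonseq = 0
    for r in restraints:
        total += 1
        if r.res_a == r.res_b:
            intra += 1
        elif (
            abs(r.res_a - r.res_b) == 1
            and spec.strand_of(r.res_a) == spec.strand_of(r.res_b)
        ):
            sequential += 1
        else:
            nonseq += 1
    return {
        "total": total,
        "intra_residue": intra,
        "inter_residue": sequential + nonseq,
        "sequential": sequential,
        "non_sequential": nonseq,
    }


def write_restraint_table(restraints: Sequence[DistanceRestraint], path) -> None:
    """Write XPLOR/CNS-dialect ``assign`` statements.

    Encoding: ``assign (resid i and name A) (resid j and name B) d dminus
    dplus`` with d = upper bound, dminus = upper - lower, dplus = 0, so the
    allowed range is [d - dminus, d + dplus].  The class label and
    pseudoatom flag ride in a trailing comment and round-trip through
    :func:`read_restraint_table`.
    """
    restraints = list(restraints)
    if not restraints:
        raise ValueError("no restraints to write")
    lines = []
    for r in restraints:
        d = r.upper
        dminus = r.upper - r.lower
        flags = r.label or "unset"
        if r.pseudoatom_corrected:
            flags += ",pseudo"
        lines.append(
            f"assign (resid {r.res_a:3d} and name {r.atom_a:<4s}) "
            f"(resid {r.res_b:3d} and name {r.atom_b:<4s}) "
            f"{d:7.3f} {dminus:7.3f} {0.0:7.3f} ! {flags}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_restraint_table(path) -> List[DistanceRestraint]:
    """Read the dialect written by :func:`write_restraint_table`."""
    import re

    pat = re.compile(
        r"assign \(resid\s+(\d+) and name (\S+)\s*\) "
        r"\(resid\s+(\d+) and name (\S+)\s*\) "
        r"\s*([\d.]+)\s+([\d.]+)\s+([\d.]+)\s*(?:! (\S+))?"
    )
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            m = pat.match(line)
            if not m:
                raise ValueError(f"unparsable restraint line: {line!r}")
            ra, aa, rb, ab, d, dminus, _dplus, flags = m.groups()
            flags = flags or "unset"
            label, _, pseudo = flags.partition(",")
            out.append(
                DistanceRestraint(
                    int(ra),
                    aa,
                    int(rb),
                    ab,
                    lower=round(float(d) - float(dminus), 6),
                    upper=float(d),
                    label="" if label == "unset" else label,
                    pseudoatom_corrected=pseudo == "pseudo",
                )
            )
    if not out:
        raise ValueError(f"no restraints found in {path}")
    return out
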