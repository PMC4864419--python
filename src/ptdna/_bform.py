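"""Runtime assembly of idealized B-form duplexes from frozen pair units.

The frozen data (:mod:`._bform_data`) holds one Watson-Crick pair per pair
type (G·C and A·T) in the level-0 helix frame: helix axis = z, pair dyad =
x (pointing toward the major groove edge).  A duplex is assembled by

* choosing the pair unit for each base pair (pairs with a pyrimidine on
  strand 1 are generated by the pair pseudo-dyad, a rotation of pi about
  the x axis, which swaps the strand roles), and
* stacking level i with a rotation of ``twist * i`` about z plus a
  translation of ``rise * i`` along z.

Strand 1 runs 5'->3' in +z; strand 2 is antiparallel.
"""

from __future__ import annotations

import numpy as np

from ._bform_data import PAIR_UNITS
from .geom import rotation_about_axis

RISE = 3.38  # Angstrom per base pair
TWIST = 36.0  # degrees per base pair

PHOSPHATE_ATOMS = frozenset({"P", "O1P", "O2P"})

#: pair pseudo-dyad: pi about the helix-frame x axis (proper rotation)
DYAD = np.diag([1.0, -1.0, -1.0])

_PAIR_OF = {"G": "GC", "C": "GC", "A": "AT", "T": "AT"}
_IS_PURINE = {"G": True, "A": True, "C": False, "T": False}


def nucleotide(
    base1: str,
    strand: int,
    level: int,
    rise: float = RISE,
    twist: float = TWIST,
    with_phosphate: bool = True,
):
    """Atoms (name, element, xyz) of one nucleotide of the pair at *level*.

    ``base1`` is the strand-1 base of the pair; ``strand`` selects which
    member is returned (1 or 2).
    """
    if base1 not in _PAIR_OF:
        raise ValueError(f"unknown base {base1!r}")
    if strand not in (1, 2):
        raise ValueError("strand must be 1 or 2")
    flip = not _IS_PURINE[base1]
    want = strand if not flip else (2 if strand == 1 else 1)
    R = rotation_about_axis([0.0, 0.0, 1.0], twist * level)
    t = np.array([0.0, 0.0, rise * level])
    out = []
    for name, element, s, xyz in PAIR_UNITS[_PAIR_OF[base1]]:
        if s != want:
            continue
        if not with_phosphate and name in PHOSPHATE_ATOMS:
            continue
        v = np.asarray(xyz, dtype=float)
        if flip:
            v = DYAD @ v
        out.append((name, element, R @ v + t))
    return out
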