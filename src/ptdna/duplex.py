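"""Phosphorothioate-modified DNA duplexes and idealized B-form templates.

A duplex is specified by its two strands (5'->3'), the Watson-Crick pairing
between them, and the phosphorothioate (PT) sites.  A PT modification
replaces one of the two non-bridging phosphate oxygens by sulfur and is
chiral at phosphorus: the Rp configuration substitutes O2P (the oxygen
facing the major groove in B-form DNA), the Sp configuration substitutes
O1P (the solvent-exposed oxygen).  Modified guanines are renamed RSG / SSG
so that downstream tools can carry stereochemistry in the residue name.

Residue numbering is continuous across the duplex: strand 1 is 1..n
(chain A), strand 2 is n+1..2n (chain B), each strand numbered 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from . import _bform

__all__ = [
    "WC_COMPLEMENT",
    "Residue",
    "DuplexSpec",
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "build_duplex_spec",
    "build_bform_template",
    "apply_pt_modification",
]

WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

RESIDUE_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

#: residue names carrying PT stereochemistry
PT_RESIDUE_NAME = {"Rp": "RSG", "Sp": "SSG"}
#: non-bridging oxygen replaced by sulfur, and the sulfur atom name
PT_SUBSTITUTION = {"Rp": ("O2P", "S2P"), "Sp": ("O1P", "S1P")}

DEFAULT_P_S_BOND = 1.98  # Angstrom, standard phosphorothioate P-S length


@dataclass(frozen=True)
class Residue:
    base: str
    number: int

    def __post_init__(self):
        if self.base not in WC_COMPLEMENT:
            raise ValueError(f"unknown base {self.base!r}")


@dataclass(frozen=True)
class DuplexSpec:
    """Sequences, PT sites and Watson-Crick pairing of one duplex."""

    strand1: Tuple[Residue, ...]
    strand2: Tuple[Residue, ...]
    pt_sites: Tuple[Tuple[int, str], ...] = ()
    name: str = "duplex"

    def __post_init__(self):
        n = len(self.strand1)
        if n == 0:
            raise ValueError("empty duplex")
        if len(self.strand2) != n:
            raise ValueError("strands differ in length")
        for a, b in self.pairing:
            ra, rb = self.residue(a), self.residue(b)
            if WC_COMPLEMENT[ra.base] != rb.base:
                raise ValueError(f"{ra.base}{a}·{rb.base}{b} is not Watson-Crick")
        five_prime_terminal = {self.strand1[0].number, self.strand2[0].number}
        for num, chirality in self.pt_sites:
            if chirality not in ("Rp", "Sp", "none"):
                raise ValueError(f"chirality {chirality!r} not in {{Rp, Sp, none}}")
            self.residue(num)  # existence check
            if num in five_prime_terminal:
                raise ValueError(
                    f"residue {num} is 5'-terminal and has no phosphate to modify"
                )

    @property
    def n_bp(self) -> int:
        return len(self.strand1)

    @property
    def pairing(self) -> Tuple[Tuple[int, int], ...]:
        n = self.n_bp
        return tuple(
            (self.strand1[i].number, self.strand2[n - 1 - i].number) for i in range(n)
        )

    def residue(self, number: int) -> Residue:
        for r in self.strand1 + self.strand2:
            if r.number == number:
                return r
        raise KeyError(f"no residue numbered {number}")

    def strand_of(self, number: int) -> int:
        if any(r.number == number for r in self.strand1):
            return 1
        if any(r.number == number for r in self.strand2):
            return 2
        raise KeyError(f"no residue numbered {number}")


@dataclass
class AtomRecord:
    """One atom in PDB v3 naming (internal dialect: O1P/O2P, H2', H2'')."""

    name: str
    element: str
    res_num: int
    res_name: str
    chain: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"bad coordinates for {self.name}")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain, self.res_num, self.name)


class StructureModel:
    """An ordered list of atoms forming one conformer of a structure."""

    def __init__(self, atoms: Sequence[AtomRecord], model_index: int = 1):
        atoms = list(atoms)
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate atom keys: {sorted(dupes)[:3]}")
        self.atoms = atoms
        self.model_index = model_index
        self._index = {a.key: i for i, a in enumerate(atoms)}

    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def atom(self, res_num: int, name: str) -> AtomRecord:
        """Look up an atom by residue number and atom name (chain-agnostic,
        valid because residue numbering is continuous across the duplex)."""
        for a in self.atoms:
            if a.res_num == res_num and a.name == name:
                return a
        raise KeyError(f"atom {name} of residue {res_num} not present")

    def has_atom(self, res_num: int, name: str) -> bool:
        try:
            self.atom(res_num, name)
            return True
        except KeyError:
            return False

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def with_coords(self, coords: np.ndarray, model_index: Optional[int] = None):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace_coord(a, c) for a, c in zip(self.atoms, coords)]
        return StructureModel(
            atoms, self.model_index if model_index is None else model_index
        )

    def residue_numbers(self):
        seen = []
        for a in self.atoms:
            if a.res_num not in seen:
                seen.append(a.res_num)
        return seen

    def residue_atoms(self, res_num: int):
        return [a for a in self.atoms if a.res_num == res_num]


def replace_coord(atom: AtomRecord, coord) -> AtomRecord:
    return AtomRecord(
        atom.name, atom.element, atom.res_num, atom.res_name, atom.chain, coord
    )


class Ensemble:
    """A set of conformers sharing an identical atom inventory."""

    def __init__(self, models: Sequence[StructureModel], label: str = ""):
        models = list(models)
        if not models:
            raise ValueError("empty ensemble")
        inventory = [a.key for a in models[0].atoms]
        for m in models[1:]:
            if [a.key for a in m.atoms] != inventory:
                raise ValueError("models differ in atom inventory")
        self.models = models
        self.label = label

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack."""
        return np.array([m.coords() for m in self.models])


def build_duplex_spec(
    seq1: str,
    seq2: str,
    mods: Iterable[Tuple[int, str]] = (),
    name: str = "duplex",
) -> DuplexSpec:
    """Build a duplex specification from two 5'->3' sequences.

    ``seq2`` read 3'->5' must be the Watson-Crick complement of ``seq1``.
    ``mods`` are (residue number, chirality) pairs in the continuous
    1..2n numbering.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2) or not seq1:
        raise ValueError("strands must be non-empty and of equal length")
    n = len(seq1)
    for i, b in enumerate(seq1):
        partner = seq2[n - 1 - i]
        if WC_COMPLEMENT.get(b) != partner:
            raise ValueError(
                f"strands are not complementary at pair {b}{i + 1}·{partner}{2 * n - i}"
            )
    strand1 = tuple(Residue(b, i + 1) for i, b in enumerate(seq1))
    strand2 = tuple(Residue(b, n + i + 1) for i, b in enumerate(seq2))
    return DuplexSpec(strand1, strand2, tuple(mods), name=name)


def build_bform_template(
    spec: DuplexSpec,
    rise: float = _bform.RISE,
    twist: float = _bform.TWIST,
    p_s_bond: float = DEFAULT_P_S_BOND,
) -> StructureModel:
    """All-atom idealized B-form duplex for *spec*.

    Fiber-type geometry: every base pair is a rigid, internally optimized
    Watson-Crick unit stacked with the given helical rise (Angstrom) and
    twist (degrees); sugars are C2'-endo (S-type) and glycosidic angles are
    anti.  5'-terminal residues carry no phosphate.  PT sites from the spec
    are applied via :func:`apply_pt_modification`.
    """
    atoms = []
    n = spec.n_bp
    # chain A: strand 1 residues 5'->3' (level i), then chain B: strand 2
    # residues 5'->3' (level n-1-j); grouping by chain matches PDB layout
    plan = [(1, i, spec.strand1[i], spec.strand1[i]) for i in range(n)]
    plan += [
        (2, n - 1 - j, spec.strand2[j], spec.strand1[n - 1 - j]) for j in range(n)
    ]
    for strand, level, res, strand1_partner in plan:
        with_p = not (
            (strand == 1 and res.number == spec.strand1[0].number)
            or (strand == 2 and res.number == spec.strand2[0].number)
        )
        for name, element, xyz in _bform.nucleotide(
            strand1_partner.base,
            strand,
            level=level,
            rise=rise,
            twist=twist,
            with_phosphate=with_p,
        ):
            atoms.append(
                AtomRecord(
                    name,
                    element,
                    res.number,
                    RESIDUE_NAMES[res.base],
                    "A" if strand == 1 else "B",
                    xyz,
                )
            )
    model = StructureModel(atoms)
    for num, chirality in spec.pt_sites:
        if chirality == "none":
            continue
        model = apply_pt_modification(model, num, chirality, p_s_bond=p_s_bond)
    return model


def apply_pt_modification(
    model: StructureModel,
    res_num: int,
    chirality: str,
    p_s_bond: float = DEFAULT_P_S_BOND,
) -> StructureModel:
    """Replace one non-bridging phosphate oxygen of *res_num* by sulfur.

    Rp substitutes O2P (sulfur named S2P), Sp substitutes O1P (S1P); the
    sulfur is placed along the original P-O direction at the configured P-S
    bond length and the residue is renamed RSG / SSG.  Exactly one atom
    changes; applying the same modification twice raises (the oxygen is
    already gone).
    """
    if chirality not in PT_SUBSTITUTION:
        raise ValueError(f"chirality must be Rp or Sp, got {chirality!r}")
    o_name, s_name = PT_SUBSTITUTION[chirality]
    try:
        p = model.atom(res_num, "P")
        o = model.atom(res_num, o_name)
    except KeyError as exc:
        raise ValueError(
            f"residue {res_num} lacks a phosphate atom needed for {chirality} "
            f"modification: {exc}"
        ) from exc
    new_res_name = PT_RESIDUE_NAME[chirality]
    sulfur_coord = p.coord + (p_s_bond / np.linalg.norm(o.coord - p.coord)) * (
        o.coord - p.coord
    )
    atoms = []
    for a in model.atoms:
        if a.res_num == res_num:
            if a.name == o_name:
                atoms.append(
                    AtomRecord(s_name, "S", a.res_num, new_res_name, a.chain, sulfur_coord)
                )
            else:
                atoms.append(
                    AtomRecord(a.name, a.element, a.res_num, new_res_name, a.chain, a.coord)
                )
        else:
            atoms.append(a)
    return StructureModel(atoms, model.model_index)
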