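"""File formats: multi-MODEL PDB, CSV tables, NMR-STAR shift subset.

Atom-name dialects are normalized on reading to the internal convention
(O1P/O2P, H2'/H2'', H5'/H5''); writers emit that convention, so every
writer round-trips through its paired reader.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np
import pandas as pd

from .coupling import CouplingSet
from .duplex import AtomRecord, Ensemble, StructureModel
from .melting import DEFAULT_CT, DscCurve
from .restraints import NoePeak

__all__ = [
    "normalize_atom_name",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_peak_table",
    "write_peak_table",
    "read_coupling_table",
    "write_coupling_table",
    "ShiftTable",
    "read_shift_table",
    "shift_delta",
    "read_dsc_curve",
    "write_dsc_curve",
    "write_pt_topology_stub",
    "file_checksum",
]

#: atom-name dialect map -> internal convention
_NAME_MAP = {
    "OP1": "O1P",
    "OP2": "O2P",
    "SP1": "S1P",
    "SP2": "S2P",
    "H2'1": "H2'",
    "H2'2": "H2''",
    "1H2'": "H2'",
    "2H2'": "H2''",
    "H5'1": "H5'",
    "H5'2": "H5''",
    "1H5'": "H5'",
    "2H5'": "H5''",
    "H2′": "H2'",
    "H2″": "H2''",
}


def normalize_atom_name(name: str) -> str:
    name = name.strip().replace('"', "''")
    return _NAME_MAP.get(name, name)


def read_pdb_ensemble(path) -> Ensemble:
    """Read a (multi-MODEL) PDB file into an :class:`Ensemble`.

    Atom names are dialect-normalized; models must share one atom
    inventory.
    """
    st = gemmi.read_structure(str(path))
    models = []
    for im, model in enumerate(st, start=1):
        atoms = []
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(
                        AtomRecord(
                            normalize_atom_name(atom.name),
                            atom.element.name,
                            res.seqid.num,
                            res.name.strip(),
                            chain.name,
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
        models.append(StructureModel(atoms, model_index=im))
    if not models:
        raise ValueError(f"no models in {path}")
    return Ensemble(models, label=Path(str(path)).stem)


def write_pdb_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB file."""
    st = gemmi.Structure()
    st.name = ensemble.label or "ptdna"
    for m in ensemble:
        gm = gemmi.Model(m.model_index)
        chains: Dict[str, gemmi.Chain] = {}
        for a in m.atoms:
            ch = chains.get(a.chain)
            if ch is None:
                ch = gemmi.Chain(a.chain)
                chains[a.chain] = ch
            if len(ch) == 0 or ch[-1].seqid.num != a.res_num:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_num, " ")
                ch.add_residue(res)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coord)
            atom.occ = 1.0
            atom.b_iso = 0.0
            ch[-1].add_atom(atom)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(str(path)).write_text(doc)


_PEAK_COLUMNS = [
    "res_a", "atom_a", "res_b", "atom_b",
    "volume", "mixing_time_ms", "exchangeable", "intensity",
]


def write_peak_table(peaks: List[NoePeak], path) -> None:
    rows = [
        {
            "res_a": p.res_a, "atom_a": p.atom_a,
            "res_b": p.res_b, "atom_b": p.atom_b,
            "volume": p.volume, "mixing_time_ms": p.mixing_time_ms,
            "exchangeable": p.exchangeable,
            "intensity": p.intensity or "",
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, index=False)


def read_peak_table(path) -> List[NoePeak]:
    df = pd.read_csv(path)
    missing = set(_PEAK_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        intensity = getattr(row, "intensity", None)
        if pd.isna(intensity) or intensity == "":
            intensity = None
        peaks.append(
            NoePeak(
                int(row.res_a), normalize_atom_name(str(row.atom_a)),
                int(row.res_b), normalize_atom_name(str(row.atom_b)),
                volume=None if pd.isna(row.volume) else float(row.volume),
                mixing_time_ms=float(getattr(row, "mixing_time_ms", 150.0)),
                exchangeable=bool(getattr(row, "exchangeable", False)),
                intensity=intensity,
            )
        )
    return peaks


def write_coupling_table(couplings: Dict[int, CouplingSet], path) -> None:
    rows = []
    for res, cs in sorted(couplings.items()):
        for name in (
            "J_H1p_H2p", "J_H1p_H2pp", "J_H2p_H3p", "J_H2pp_H3p", "J_H3p_P", "J_P_H5p",
        ):
            v = getattr(cs, name)
            if v is not None:
                rows.append({"residue": res, "j_name": name, "value_hz": v})
    pd.DataFrame(rows, columns=["residue", "j_name", "value_hz"]).to_csv(path, index=False)


def read_coupling_table(path) -> Dict[int, CouplingSet]:
    df = pd.read_csv(path)
    for col in ("residue", "j_name", "value_hz"):
        if col not in df.columns:
            raise ValueError(f"coupling table missing column {col!r}")
    out: Dict[int, Dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.residue), {})[str(row.j_name)] = float(row.value_hz)
    return {res: CouplingSet(**vals) for res, vals in sorted(out.items())}


@dataclass
class ShiftTable:
    """Chemical shifts indexed by (residue number, atom name, nucleus)."""

    shifts: Dict[Tuple[int, str, str], float]
    label: str = ""

    def __len__(self):
        return len(self.shifts)

    def get(self, res_num: int, atom: str, nucleus: Optional[str] = None):
        for (r, a, n), v in self.shifts.items():
            if r == res_num and a == atom and (nucleus is None or n == nucleus):
                return v
        raise KeyError(f"no shift for residue {res_num} atom {atom}")


def read_shift_table(path, dialect: str = "auto") -> ShiftTable:
    """Read chemical shifts from CSV (columns residue, atom, nucleus,
    shift_ppm) or from the Atom_chem_shift loop of an NMR-STAR file."""
    path = Path(str(path))
    if dialect == "auto":
        dialect = "nmrstar" if path.suffix.lower() in (".str", ".star") else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = {"residue", "atom", "nucleus", "shift_ppm"} - set(df.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        shifts = {
            (int(r.residue), normalize_atom_name(str(r.atom)), str(r.nucleus)): float(
                r.shift_ppm
            )
            for r in df.itertuples(index=False)
        }
        return ShiftTable(shifts, label=path.stem)
    if dialect == "nmrstar":
        return _read_star_shifts(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_star_shifts(path: Path) -> ShiftTable:
    """Minimal NMR-STAR v3 reader covering only Atom_chem_shift loops."""
    tags: List[str] = []
    shifts: Dict[Tuple[int, str, str], float] = {}
    in_loop = header_done = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line == "loop_":
            in_loop, header_done, tags = True, False, []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            if header_done:  # a new non-shift loop header
                in_loop = False
                continue
            tags.append(line.split(".")[-1] if "." in line else line)
            continue
        if line in ("stop_", ""):
            if line == "stop_":
                in_loop = False
            continue
        # data row
        if not header_done:
            header_done = True
            if not any(t in ("Val", "Chem_shift_val") for t in tags):
                in_loop = False
                continue
        fields = line.split()
        if len(fields) != len(tags):
            continue
        row = dict(zip(tags, fields))
        try:
            seq = int(row.get("Seq_ID") or row.get("Comp_index_ID"))
            atom = normalize_atom_name(row.get("Atom_ID", ""))
            nucleus = row.get("Atom_type", "?")
            iso = row.get("Atom_isotope_number", "")
            val = float(row.get("Val") or row.get("Chem_shift_val"))
        except (TypeError, ValueError):
            continue
        nucleus = f"{iso}{nucleus}" if iso and iso != "." else nucleus
        shifts[(seq, atom, nucleus)] = val
    if not shifts:
        raise ValueError(f"no Atom_chem_shift loop found in {path}")
    return ShiftTable(shifts, label=path.stem)


def shift_delta(
    modified: ShiftTable, reference: ShiftTable, threshold: float = 0.2
) -> pd.DataFrame:
    """Per-atom shift differences (modified - reference) on the key
    intersection, with a |delta| >= threshold flag (default 0.2 ppm)."""
    keys = sorted(set(modified.shifts) & set(reference.shifts))
    if not keys:
        raise ValueError("shift tables share no (residue, atom, nucleus) keys")
    rows = []
    for r, a, n in keys:
        d = modified.shifts[(r, a, n)] - reference.shifts[(r, a, n)]
        rows.append(
            {
                "residue": r, "atom": a, "nucleus": n,
                "delta_ppm": d, "flagged": abs(d) >= threshold,
            }
        )
    return pd.DataFrame(rows)


def write_dsc_curve(curve: DscCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ct_mol_per_l = {curve.ct!r}\n")
        pd.DataFrame({"T_C": curve.temperature_c, "dCp": curve.dcp}).to_csv(
            fh, index=False
        )


def read_dsc_curve(path, ct: Optional[float] = None) -> DscCurve:
    path = Path(str(path))
    header_ct = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "ct_mol_per_l" in first:
            header_ct = float(first.split("=")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if not {"T_C", "dCp"} <= set(df.columns):
        raise ValueError("DSC CSV needs columns T_C, dCp")
    return DscCurve(
        df["T_C"].to_numpy(), df["dCp"].to_numpy(), ct or header_ct or DEFAULT_CT
    )


def write_pt_topology_stub(path, chirality: str = "Rp") -> None:
    """XPLOR-style topology/parameter stub for a PT-modified guanine.

    Masses and the O->S bond substitution are real; force-field constants
    are placeholder artifact defaults for downstream refinement engines.
    """
    res = "RSG" if chirality == "Rp" else "SSG"
    s_atom = "S2P" if chirality == "Rp" else "S1P"
    o_gone = "O2P" if chirality == "Rp" else "O1P"
    o_kept = "O1P" if chirality == "Rp" else "O2P"
    text = f"""! topology/parameter stub for {res} ({chirality}-phosphorothioate dG)
! derived from guanine by replacing {o_gone} with sulfur ({s_atom})
residue {res}
  atom P    type=P   charge= 1.20 mass=30.974
  atom {s_atom}  type=SP  charge=-0.90 mass=32.060
  atom {o_kept}  type=OP  charge=-0.70 mass=15.999
  bond P {s_atom}   ! P-S 1.98 A, kb=230.0 (artifact default)
  bond P {o_kept}   ! P-O 1.48 A, kb=580.0
  angle {s_atom} P {o_kept}  ! 112.0 deg, ka=80.0 (artifact default)
end
"""
    Path(str(path)).write_text(text)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(str(path)).read_bytes()).hexdigest()[:16]
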