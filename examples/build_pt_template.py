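"""Build idealized B-form templates of the PT decamer in all three states.

The duplex is d(C1..A10)·d(T11..G20) with phosphorothioate sites at G3 and
G17.  Rp modification replaces the major-groove-facing O2P by sulfur (atom
S2P, residue RSG); Sp replaces the solvent-facing O1P (S1P, SSG).
"""

import numpy as np

from ptdna import build_bform_template, build_duplex_spec, groove_assign
from ptdna.duplex import Ensemble
from ptdna.io import write_pdb_ensemble

SEQ1, SEQ2 = "CGGCCGCCGA", "TCGGCGGCCG"

for name, mods in [
    ("PT-free", []),
    ("[Rp,Rp]-PT", [(3, "Rp"), (17, "Rp")]),
    ("[Sp,Sp]-PT", [(3, "Sp"), (17, "Sp")]),
]:
    spec = build_duplex_spec(SEQ1, SEQ2, mods, name=name)
    model = build_bform_template(spec)
    print(f"{name}: {len(model)} atoms, {spec.n_bp} bp")
    if mods:
        chirality = mods[0][1]
        s_name = "S2P" if chirality == "Rp" else "S1P"
        p = model.atom(3, "P").coord
        s = model.atom(3, s_name).coord
        groove = groove_assign(model, 3, s_name)
        print(
            f"  G3 {s_name}: P-S bond {np.linalg.norm(s - p):.2f} A, "
            f"located {groove.label} (margin {groove.margin:.2f} A)"
        )
        # sulfur in the major groove (Rp) faces the duplex interior where
        # proteins read the sequence; the Sp sulfur points at solvent
        write_pdb_ensemble(Ensemble([model], label=name), f"template_{chirality}.pdb")
        print(f"  wrote template_{chirality}.pdb")
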