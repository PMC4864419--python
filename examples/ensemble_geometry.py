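"""Ensemble geometry: RMSD statistics, sulfur contacts and groove location.

Builds 20-model synthetic conformer bundles of the three duplex states and
measures the quantities that distinguish the stereoisomers: the short
H2''...O2P/S2P contact next to the modification sites and the groove
localization of the sulfur.
"""

from ptdna import build_bform_template, build_duplex_spec
from ptdna.ensemble import (
    average_pairwise_rmsd,
    cross_ensemble_rmsd,
    ensemble_distance,
    groove_assign,
)
from ptdna.synth import SynthConfig, synth_ensemble

SEQ1, SEQ2 = "CGGCCGCCGA", "TCGGCGGCCG"
states = {
    "PT-free": ([], "O2P"),
    "[Sp,Sp]": ([(3, "Sp"), (17, "Sp")], "O2P"),
    "[Rp,Rp]": ([(3, "Rp"), (17, "Rp")], "S2P"),
}

ensembles = {}
for i, (name, (mods, contact_atom)) in enumerate(states.items()):
    template = build_bform_template(build_duplex_spec(SEQ1, SEQ2, mods))
    e = synth_ensemble(template, SynthConfig(seed=10 + i))
    ensembles[name] = e
    rep = average_pairwise_rmsd(e, "backbone")
    st = ensemble_distance(
        e, [(2, "H2''", 3, contact_atom), (16, "H2''", 17, contact_atom)]
    )
    print(f"{name}: pairwise backbone RMSD {rep.mean:.3f} +- {rep.sd:.3f} A; "
          f"H2''...{contact_atom} {st.mean:.2f} +- {st.sd:.2f} A")
# the H2''...S2P contact of the Rp duplex is slightly longer than the
# H2''...O2P contact it replaces: a repulsive C-H...S clash where the
# PT-free helix has an attractive C-H...O contact

for name in ("[Sp,Sp]", "[Rp,Rp]"):
    r = cross_ensemble_rmsd(ensembles[name], ensembles["PT-free"])
    print(f"{name} vs PT-free: cross-ensemble heavy-atom RMSD {r:.3f} A "
          f"(sulfur mapped onto the oxygen it replaces)")

rp = build_bform_template(build_duplex_spec(SEQ1, SEQ2, [(3, "Rp"), (17, "Rp")]))
sp = build_bform_template(build_duplex_spec(SEQ1, SEQ2, [(3, "Sp"), (17, "Sp")]))
print("groove location: Rp S2P ->", groove_assign(rp, 3, "S2P").label,
      "| Sp S1P ->", groove_assign(sp, 3, "S1P").label)
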