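"""Sugar pucker and backbone torsions from J-couplings.

Predicts the four sugar H-H couplings of S-type (B-DNA) and N-type
(A-DNA) deoxyribose, fits pseudorotation parameters back from synthetic
couplings of the template, and derives epsilon/zeta/beta torsion
restraints from H-P couplings.
"""

from ptdna import build_bform_template, build_duplex_spec
from ptdna.coupling import (
    SugarPucker,
    beta_classify,
    epsilon_from_j,
    estimate_pucker,
    predict_sugar_couplings,
    zeta_from_epsilon,
)
from ptdna.synth import SynthConfig, synth_couplings

s_type = predict_sugar_couplings(SugarPucker(162.0, 35.0))
n_type = predict_sugar_couplings(SugarPucker(18.0, 38.0))
print(f"J(H1'-H2'): S-type {s_type.J_H1p_H2p:.1f} Hz vs N-type "
      f"{n_type.J_H1p_H2p:.1f} Hz")
print("  (large H1'-H2' couplings, ~9-10 Hz, are the B-form signature)")

template = build_bform_template(build_duplex_spec("CGGCCGCCGA", "TCGGCGGCCG"))
couplings = synth_couplings(template, SynthConfig(seed=1))
for res in (2, 3, 16, 17):
    pucker, residual = estimate_pucker(couplings[res])
    print(f"residue {res:2d}: P = {pucker.P:5.1f} deg, phi_m = "
          f"{pucker.phi_m:4.1f} deg -> {pucker.conformer}-type "
          f"(fit residual {residual:.2f} Hz^2)")

# backbone: a 6 Hz H3'-P coupling inverted through the H-P Karplus curve,
# shifted by -120 deg onto epsilon, then the BI correlation gives zeta
eps = epsilon_from_j(6.0)
zeta = zeta_from_epsilon(eps.center if eps.center < 0 else eps.center - 360.0)
beta = beta_classify(3.5)
print(f"J(H3'-P) = 6.0 Hz -> epsilon {eps.center:.0f} +- {eps.width:.0f} deg")
print(f"BI correlation -> zeta {zeta.center:.0f} +- {zeta.width:.0f} deg")
print(f"J(P-H5') = 3.5 Hz -> beta {beta.center:.0f} deg (trans)")
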