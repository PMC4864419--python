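# ptdna

Structural analysis of physiological DNA phosphorothioate (PT)
modification: stereospecific PT duplex modelling, NMR restraint
generation, J-coupling / pseudorotation analysis, structure-ensemble
geometry, and two-state DSC melting thermodynamics.

## The problem

Bacterial *dnd* systems replace a non-bridging phosphate oxygen of the DNA
backbone by sulfur, stereospecifically at phosphorus (Rp or Sp).  For the
*Streptomyces lividans* decamer
d(C₁G₂ᴾˣG₃C₄C₅G₆C₇C₈G₉A₁₀)·d(T₁₁C₁₂G₁₃G₁₄C₁₅G₁₆ᴾˣG₁₇C₁₈C₁₉G₂₀)
(X = O or S), the questions are structural and thermodynamic: does PT
modification change the B-form helix, where does the sulfur sit, and how
much does each stereoisomer (de)stabilize the duplex?  This package
implements the computational side of that analysis for structural
biologists working with NOESY volumes, J-couplings, NMR conformer bundles
and DSC traces.

## What is in the box

| module | core content |
| --- | --- |
| `ptdna.duplex` | `DuplexSpec` with Watson–Crick validation; idealized all-atom B-form templates (rise 3.38 Å, twist 36°, C2′-endo sugars); stereospecific sulfur substitution (Rp → O2P→S2P, residue RSG; Sp → O1P→S1P, SSG) |
| `ptdna.restraints` | ISPA calibration *d* = d_ref (V_ref/V)^(1/6) on the cytosine H5–H6 reference (2.45 Å); strong/medium/weak bounds (1.8–2.9 / 3.5 / 6.0 Å; exchangeable 4.0 / 5.0 / 8.0 Å); methyl pseudoatom correction; Watson–Crick H-bond + planarity restraints; XPLOR-dialect tables |
| `ptdna.coupling` | Karplus ³J(θ) = A cos²θ + B cosθ + C; pseudorotation ν_j = φ_m cos(P + 144°(j−2)) with exact inverse; (P, φ_m) grid fitting from couplings; ε from the H3′–P coupling (−120° shift), ζ from the BI correlation (ζ = ε + 90°), β trans classification (2–5 Hz) |
| `ptdna.ensemble` | Kabsch superposition, average pairwise and cross-ensemble RMSD (S↔O mapped), ensemble-averaged distances, major/minor-groove/exterior assignment, coordinate-based sugar puckers |
| `ptdna.melting` | anchored bimolecular two-state model A+B⇌AB with α(Tm)=½, ΔCp(T) = −ΔH dα/dT; ΔH_cal and ΔS area integrals; nonlinear fitting |
| `ptdna.synth` | synthetic NOE tables, couplings, conformer bundles and DSC traces with the statistical structure each stage assumes — the whole pipeline runs offline |
| `ptdna.io` / `ptdna.cli` | multi-MODEL PDB (dialect-normalized names), NMR-STAR shift loops, CSV tables, `ptdna` command line (`template`, `restraints`, `pucker`, `analyze`, `melt`, `simulate`, `fetch`) |

## A worked example

```bash
python examples/ensemble_geometry.py
```

prints (seeded, reproducible):

```
PT-free: pairwise backbone RMSD 0.096 +- 0.009 A; H2''...O2P 2.53 +- 0.05 A
[Sp,Sp]: pairwise backbone RMSD 0.094 +- 0.009 A; H2''...O2P 2.53 +- 0.06 A
[Rp,Rp]: pairwise backbone RMSD 0.096 +- 0.009 A; H2''...S2P 2.57 +- 0.05 A
[Sp,Sp] vs PT-free: cross-ensemble heavy-atom RMSD 0.044 A (sulfur mapped onto the oxygen it replaces)
[Rp,Rp] vs PT-free: cross-ensemble heavy-atom RMSD 0.043 A (sulfur mapped onto the oxygen it replaces)
groove location: Rp S2P -> major | Sp S1P -> exterior
```

The pairwise RMSD is the precision of a 20-model synthetic conformer
bundle; the H2″(G2/G16)···O2P/S2P(G3/G17) distance is the short
sugar–phosphate contact flanking the modification sites — replacing the
attractive C–H···O by the bulkier C–H···S is what destabilizes the Rp
duplex — and the groove labels show the stereochemical asymmetry: the Rp
sulfur sits in the major groove (where restriction enzymes read it), the
Sp sulfur points at solvent.  `examples/dsc_melting.py` closes the loop
thermodynamically: two-state fits of simulated DSC traces at the measured
melting temperatures recover a 4.5 °C melting depression for the Rp
duplex.  The other examples cover template building, NOE restraint
generation and pucker fitting.

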