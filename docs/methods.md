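# Methods

This note records the models, conventions and numerical choices behind
`ptdna`, in the order the pipeline uses them.

## Duplex specification and numbering

A duplex is two 5′→3′ strands plus Watson–Crick pairing; residue
numbering is continuous (strand 1 = 1..n on chain A, strand 2 = n+1..2n
on chain B), so the study decamer spans residues 1–20 with PT sites at
G3 and G17.  Validation enforces complementarity, a pairing bijection,
and that every PT site owns a 5′-phosphate (5′-terminal residues carry
none).  Stereochemistry is carried by the atom and residue names: the Rp
configuration replaces O2P (the non-bridging oxygen facing the major
groove) by S2P and renames the guanine RSG; Sp replaces the
solvent-facing O1P by S1P (SSG).  The sulfur is placed along the original
P–O direction at 1.98 Å (standard phosphorothioate P–S length;
configurable).

## The B-form template generator

The template is a fiber-type model: one internally optimized, rigid
Watson–Crick pair per pair type (G·C and A·T), stacked with rise 3.38 Å
and twist 36° about the helix axis; pairs with a pyrimidine on strand 1
are generated by the pair pseudo-dyad (a π rotation about the groove
axis).  The per-nucleotide coordinates were derived once, offline, by
least squares and frozen into `_bform_data.py`:

* base fragments from ideal chemical-component geometry, flattened and
  paired by fitting the heavy-atom hydrogen-bond distances into the
  2.8–3.0 Å band while constraining the two glycosidic attachments to be
  dyad images of each other (without this symmetry the two backbones
  cannot both close);
* C2′-endo deoxyribose (P = 155°, φ_m = 37°) built from the endocyclic
  torsions with standard bond lengths/angles; glycosidic χ ≈ −100°
  (anti), γ ≈ 36°, β ≈ 173° fitted;
* helical closure: the O3′(i)–P(i+1) bond of all 16 dinucleotide step
  types is closed to within 0.35 Å (bond lengths 1.44–1.57 Å) by
  optimizing the shared torsions and the pair placement, with soft
  priors keeping the placement B-form-like (x-displacement ≈ −0.7 Å)
  and steric floors holding the sugar H2′/H2″ protons ≥ 2 Å from the
  flanking base protons.  The optimized backbone lands at δ ≈ 140°,
  ε ≈ −173°, ζ ≈ −122°.

Resulting properties (all verified by tests rather than asserted): P–P
spacing 6.5–6.7 Å; every Watson–Crick hydrogen bond within 2.8–3.0 Å; all
sugars S-type; H1′–H2″ 2.34 Å vs H1′–H2′ 3.02 Å (the NOE-based
stereoassignment convention); H2″(i)···O2P(i+1) = 2.52 Å, emerging close
to the 2.4–2.6 Å range deposited NMR structures show for this contact.
The G·C C1′–C1′ distance is 10.83 Å (A·T 10.70 Å) — with rigid ideal base
fragments and H-bonds held in band, the pair cannot be made shorter, so
tests assert the generator's own 10.2–10.9 Å band rather than the
canonical 10.4 Å midpoint.  Rise and twist are parameters of the
assembly; values far from the fiber defaults degrade backbone closure
since the frozen unit was optimized at 3.38 Å / 36°.

## NOE restraints

Distances follow the isolated spin pair approximation,
d = d_ref (V_ref/V)^(1/6), calibrated on the cytosine H5–H6 distance of
2.45 Å.  Class bounds are 1.8–2.9 / 1.8–3.5 / 1.8–6.0 Å
(strong/medium/weak, non-exchangeable) and 1.8–4.0 / 1.8–5.0 / 1.8–8.0 Å
for exchangeable protons.  Where only a calibrated distance is available,
classes are assigned by thresholding at 2.9 and 3.5 Å; explicit class
labels always win.  Exchangeable classes follow the two-mixing-time
convention (intense at 50 ms / weak at 50 ms / observed only at 200 ms)
via `classify_exchangeable_series`, which needs an explicit
strong-intensity threshold because absolute volumes are
instrument-specific.  Methyl restraints get a +1.0 Å pseudoatom
correction on the upper bound (configurable).  Watson–Crick restraints:
three hydrogen bonds per G·C, two per A·T, each with heavy–heavy target
2.8–3.0 Å and H···acceptor 1.8–2.0 Å, plus one planarity group per pair.
Bookkeeping counts intra-residue, sequential (|i−j| = 1 within one
strand) and non-sequential restraints; inter-strand contacts count as
non-sequential.  The restraint-table dialect is
`assign (resid i and name A) (resid j and name B) d dminus dplus` with
d = upper, dminus = upper − lower, dplus = 0.

## Couplings, pseudorotation and backbone torsions

Karplus form ³J(θ) = A cos²θ + B cosθ + C; defaults A = 10.2, B = −0.8,
C = 0 Hz (H–H) and A = 15.3, B = −6.2, C = 1.5 Hz (H–P), both
configurable since published coefficient sets vary.  The sugar H–H
dihedrals ride on the endocyclic torsions through linear phase relations
(θ(H1′H2′) = 121.4° + 1.03 ν₁, θ(H1′H2″) = 0.9° + 1.02 ν₁,
θ(H2′H3′) = 2.4° + 1.06 ν₂, θ(H2″H3′) = 122.9° + 1.06 ν₂) — standard
deoxyribose geometry, configurable.  Pseudorotation uses
ν_j = φ_m cos(P + 144°(j−2)); the inverse is the exact harmonic
projection, so forward/inverse round trips are machine-precision.
Pucker fitting is a deterministic grid search (P step 1°, φ_m ∈ [20°,
50°] step 0.5°) minimizing Σ(J_pred − J_obs)².  Noiseless couplings are
recovered at grid resolution; at 0.5 Hz coupling noise the P estimate
wanders ~7° on average because P and φ_m trade off along a shallow
valley — the tests therefore assert the seeded mean error (≤ 10°), not
every single draw.

ε is obtained by inverting the H–P Karplus curve for the H3′–C3′–O3′–P
dihedral and applying a −120° shift (the sign is a convention choice;
both are exposed).  Candidates are filtered to the B-DNA ε region
(−210° to −120°); that branch exists only for J ≤ A + B + C (10.6 Hz
with the defaults) — larger couplings return the nearest out-of-region
candidate, and J beyond the curve maximum raises.  ζ uses the BI-form
linear correlation ζ = ε + 90° (offset configurable; the template
generator's own ε/ζ combination is independent of this default).
β is classified trans (180°) for J(P–H5′) ∈ [2, 5] Hz, otherwise left
unclassified.  All torsion restraints are centers ± width (default 30°)
normalized into (−180°, 180°].

## Ensemble geometry

Superposition is closed-form least squares (Kabsch/SVD with reflection
guard); an independent quaternion-based oracle and a numerical optimizer
cross-check it in the tests.  The backbone selection is {P, O1P/O2P (or
S1P/S2P), O5′, C5′, C4′, C3′, O3′}.  Average pairwise RMSD superposes
every unordered model pair independently.  Cross-ensemble RMSD maps
sulfurs onto the oxygens they replace (S1P↔O1P, S2P↔O2P), excludes the
terminal residue of each chain (end fraying), and offers two conventions:
`mean-structure` (default; iterative superposition onto a converged mean,
then mean-vs-mean RMSD) and `model1` (first model vs first model) — both
are reported where the choice matters.  Ensemble distances are plain
per-model Euclidean distances; symmetry-related site pairs (G2→G3 and
G16→G17) are pooled in the headline mean with per-site means retained.

Groove assignment: the helical axis is the best-fit line through the
C1′–C1′ midpoints; an atom farther from the axis than the mean
phosphorus radius + margin (default 0.5 Å) is `exterior`; otherwise the
label is `major`/`minor` by which base-edge atom set is nearer (major
edge: purine N7/O6/N6, pyrimidine N4/O4/C5; minor edge: purine N3/N2/C2,
pyrimidine O2), with the achieved separation reported as the margin.
Coordinate-based puckers compute ν₀–ν₄ from the ring dihedrals and label
S for P ∈ [90°, 270°); planar rings are rejected as degenerate.

## DSC melting

Non-self-complementary bimolecular two-state model A + B ⇌ AB with equal
strand loads: c = C_T/2, mass action K(c−x)² = x, van't Hoff
K(T) = (4/C_T) exp((ΔH/R)(1/T − 1/Tm)) anchored so the duplex fraction
α = x/c is exactly ½ at Tm (K is the formation constant; its formation
enthalpy is −ΔH).  ΔCp(T) = −ΔH dα/dT via the analytic implicit
derivative, plus an optional linear baseline and seeded Gaussian noise.
C_T defaults to 2.95 × 10⁻⁴ mol strands/L (a 0.9 mg/ml decamer duplex
load).  ΔH_cal is the trapezoidal area of ΔCp over the grid, ΔS the area
of ΔCp/T with T in kelvin; the conservation identity ∫ΔCp dT = ΔH holds
to 0.1% on a grid wide enough to contain the transition tails (tests use
0–140 °C; the default 25–95 °C instrument window clips ~1% of the area).
Fitting is nonlinear least squares over (Tm, ΔH_vH, amplitude scale,
linear baseline), initialized at the smoothed peak maximum; a trace with
two peaks above 15% relative prominence is rejected as not two-state.
One intrinsic property of this model worth knowing: the ΔCp maximum sits
*above* the anchored Tm (by ≈ 1.9 °C at ΔH = 200 kJ/mol, 1.5 °C at 300,
0.9 °C at 500, shrinking with ΔH), because the bimolecular α(T) sigmoid
is asymmetric — the fit still recovers Tm itself to < 0.05 °C noiseless.

## Synthetic data: what it does and does not emulate

The generators produce inputs with the statistical structure each stage
assumes: ISPA-consistent volumes (lognormal 10% noise; geminal pairs and
thymine methyls excluded; exchangeable peaks carry distance-derived
classes standing in for mixing-time classification), forward-Karplus
couplings (Gaussian 0.5 Hz), 20-model bundles with 0.04 Å per-coordinate
jitter (mean pairwise backbone RMSD ≈ 0.1 Å, the scale of deposited NMR
bundles), and two-state DSC traces at Tm = 76.55 / 71.99 °C,
ΔH = 300 kJ/mol, 2%-of-peak noise.  All generators are deterministic
under a fixed seed.  They do **not** emulate spin diffusion, correlated
backbone motions, conformational exchange, or baseline curvature, so
passing tests demonstrate correctness of the analysis chain under its
own assumptions — not robustness to those real-data effects.

## Known limitations

* The template is an idealized rigid-pair fiber model: no propeller
  twist, no sequence-dependent steps, residual backbone-closure error up
  to 0.35 Å.  It is a starting structure and test oracle, not a refined
  structure.
* Deposited-bundle analyses (PDB 5J3G/5J3I/5J3F, BMRB entries) require
  an explicit fetch; the bundled `.str` fixtures are synthetic stand-ins
  carrying only published modified-site ³¹P shifts.
* The NMR-STAR reader covers assigned-chemical-shift loops only.
* ISPA ignores multi-spin relaxation pathways; the pseudoatom treatment
  is a fixed upper-bound correction.
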