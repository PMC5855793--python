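# Methods

This note documents the models, conventions and numerical choices
behind `fibrilkit`, and what its synthetic ground-truth ensembles do
and do not establish about real fibril trajectories.

## Coordinate model and units

All internal coordinates are in nanometres; the PDB boundary converts
Å ↔ nm, so a round trip through a multi-model PDB is faithful to
10⁻⁴ nm (PDB files carry three decimals in Å).  Chain order along the
fibril axis is the order of first appearance in the source file, and
residue numbering is author numbering (17–42 for the Aβ17–42 window),
never re-indexed.  Alternate locations keep the first conformer;
insertion codes are rejected (fibril models do not use them).

## The synthetic fibril generator

The generator exists so that every analysis has a fixture with a known
answer.  It emulates the *geometry* of a cross-β pentamer — not its
energetics, solvent, or realistic conformational statistics.

**Chain template.**  The Cα trace is a planar polyline with exactly
0.38 nm between consecutive Cαs: straight arms and circular-arc turns
laid out as a U (arms spanning residues 17–26 and 31–42, turn 27–30)
or an S (arms 17–20, 24–33, 36–42; turns 21–23 and 34–35, with
opposite bend senses).  The arm extents cover the β-strands of the two
folds (18–26 / 31–40 for the U; 24–33 and 36–40 for the S), extended
to the window termini where the fold is geometrically straight.  On
top of the trace sits a two-residue screw period, as in a real
β-strand: the Cα carries an alternating ±0.045 nm out-of-plane pleat,
and amide N and carbonyl C are placed by fixed local-frame offsets.
The offsets were solved once (least squares over the six offset
components plus the pleat) so that arm-interior residues have backbone
dihedrals of exactly (φ, ψ) = (−139°, +135°) — ideal β — with
near-standard N–Cα / Cα–C bond lengths; the frozen constants are
`N_OFFSET`, `C_OFFSET`, `CA_PLEAT` in `synthetic.py`.  Turn residues
use the z-mirrored frame, which lands them in a clearly non-β,
non-helical dihedral region.  Residues at segment boundaries inherit
mixed dihedral quadruples and may classify either way; tests therefore
assert on segment-interior residues.

**Hydrogen-bond ladder.**  Each residue's carbonyl O and amide H are
placed on its nitrogen's stacking column (O at N + 0.19 nm·ẑ, H at
N − 0.10 nm·ẑ).  With the 0.48 nm rise this makes every in-register
inter-chain N–H···O pair have a donor–acceptor distance of exactly
0.29 nm with perfectly linear H–D–A geometry, and leaves no spurious
intra-column bonds.  This is a deliberate idealisation: with a
chemically exact carbonyl direction the same-residue donor and
acceptor columns are laterally ~0.3 nm apart and an exact in-register
ladder at 0.48 nm rise is geometrically impossible.  The cost is a
non-physical C–O bond vector; the benefit is that hydrogen-bond maps
of the ideal fibril are exactly the identity ladder, and
`plant_hbond_register` can break chosen rungs (displacing the
acceptor laterally by 0.31 nm, putting the pair at 0.42 nm) with
frame-level control, so register probabilities of 0, ½ and 1 are exact.

**Side chains** are a single Cβ pseudo-atom (absent for glycine),
alternating sides of the sheet plane.  This suffices for Cα-based
order/FMA analyses, backbone H-bonds and heavy-atom contact maps; it
under-counts side-chain surface and cannot show rotamer effects.

**Disorder dials.**  Per-coordinate Gaussian noise (σ in nm); a
per-chain tilt (each chain rotated about its own centroid — note this
leaves the A→E stacking vectors themselves unchanged and lowers the
order parameter only through the global superposition); a stacking-
axis tilt (the translation direction itself tilted by θ, which makes
the ideal ensemble's order parameter exactly cos θ); and planted
collective modes: a unit-norm displacement field over all Cαs with a
per-frame amplitude series (default: sinusoid plus Gaussian jitter),
applied rigidly to every atom of the displaced residue.  Frame 0 never
carries noise, tilt or mode displacement: it is the ideal reference
that defines the fibril axis (the laboratory z of frame 0).
`make_cterminal_mode` builds the canonical fixture — lateral fraying
of one chain's residues 36–42 — and by default projects out the
rigid-body (translation/rotation) component against the ideal
assembly, because superposition absorbs any rigid part of a
displacement field and only the internal-motion remainder is
recoverable by PCA.

**What passing tests show.**  Closed-form agreement (ordP = cos θ,
RMSF = σ√3, exact register probabilities, rank-1 PCA recovery) shows
the *estimators* are correct.  It does not show that real REMD
ensembles of the two folds behave any particular way: the generator
has no physics, and its disorder dials are chosen, not sampled.

## Order parameter

ordP averages, over residue numbers, the cosine between the
cross-fibril vector v_r (Cα of the first chain → Cα of the last
chain, same residue) and the fibril axis z.  Intermediate chains do
not enter.  Two conventions are provided because the axis definition
is otherwise ambiguous for a moving structure:

* `reference-fit` (default): every frame is Cα-superposed onto the
  reference frame and compared against a fixed axis — the laboratory z
  (the generated-data convention, and the convention under which the
  starting structure scores 1), or the reference frame's mean stacking
  vector (`axis="stacking"`, the right choice for loaded structures in
  arbitrary orientation), or an explicit vector.
* `per-frame`: no superposition; the axis is the mean stacking vector
  recomputed in each frame (this measures internal straightness only).

For the ideal and planted fixtures the conventions agree.  Values are
clipped to [−1, 1] against rounding.  The distribution helper
normalises the histogram density to integrate to 1 over [−1, 1].

## RMSF and superposition

Frames are superposed on the reference over all Cαs (configurable);
the per-atom RMSF is the RMS deviation from the time-average position,
computed from deviations relative to the reference frame so a static
trajectory gives exactly zero.  Residue values average the residue's
heavy atoms by default (`atoms="calpha"` available — the atom set is a
documented choice, not a claim about any particular prior analysis),
and the profile reports mean ± std across the five chains at each
residue number.  Kabsch superposition enforces a proper rotation and
raises a diagnostic error for degenerate (collinear) selections.

## Contact, hydrogen-bond and non-bonded maps

A residue-level "contact" means minimum heavy-atom distance within the
cutoff (0.45 nm default).  Inter-chain statistics average the two
orientations of each designated adjacent pair and default to the
interior pairs (B-C, C-D for a pentamer), excluding edge effects of
chains A and E; intra-chain statistics use the central chain with
sequence neighbours |i−j| < 2 excluded.  Hydrogen bonds are
donor(N)–acceptor(O) pairs within 0.35 nm; when explicit hydrogens
exist the H–donor–acceptor angle must be ≤ 30° unless distance-only
mode is selected (both modes are exposed; neither is claimed as the
convention of any external study — the angle term is the common
MD-analysis default).  The inter-chain map entry (i, j) is the
probability that a bond with donor residue i and acceptor residue j
exists in *either* direction of an adjacent pair; this orientation
union is what makes the ideal ladder's diagonal probability exactly 1
(each donor points only to the chain below).  All map code paths are
verified exactly against brute-force O(N²) all-pairs oracles.

## Secondary-structure classifier

A deliberately simplified stand-in for a full DSSP assignment: a
residue is structured-β in a frame iff (φ, ψ) falls in the β region
(φ ∈ [−180°, −90°], ψ ∈ [90°, 180°] ∪ [−180°, −170°]) *and* the
residue participates in at least one inter-chain backbone H-bond
(distance criterion); helical iff (φ, ψ) is within 30° of
(−60°, −45°) (circular distance); otherwise unstructured.  Chain
termini, which lack one dihedral, are classified from whichever angle
exists (helix requires both).  Probabilities average frames and
chains.  The H-bond requirement means an isolated chain never scores
β — matching the sheet-based meaning of "structured" in a fibril.

## SASA and interaction surfaces

Shrake–Rupley with a deterministic golden-spiral point set (no RNG;
default 960 points per atom, probe 0.14 nm, Bondi radii C 0.170,
N 0.155, O 0.152, S 0.180, H 0.120 nm; a united-atom table is
available).  A point on the expanded sphere (r_vdw + probe) is
accessible when outside every neighbour's expanded sphere; neighbour
candidates come from a k-d tree.  Accuracy: the isolated-atom area is
exact to machine precision (the spiral weights are uniform), overlap
cases agree with a 10⁵-point refinement to ≲0.3%, and 960 vs 3840
points differ by <1% on chain fixtures.  Translation invariance is
exact; rotation invariance holds only to quadrature accuracy (≲1%),
since the point set has a fixed orientation — an intrinsic property of
any fixed-grid Shrake–Rupley implementation.

The interaction surface of residue r in chain X w.r.t. chain Y is
SASA(r | X alone) − SASA(r | X∪Y), both with the same point set, so
buried area is non-negative point-by-point by construction.  Atom
contributions split into hydrophobic (C, S) and hydrophilic (N, O and
attached H) channels — an atom-element partition chosen here because
it needs no residue-level scale; the channels sum to the total
exactly.  Profiles average the two orientations, the designated pairs
and the frames.  The pairwise (X alone vs X∪Y) definition, rather than
chain-in-full-assembly, is what makes designated-pair averaging
well-posed.  Note the generated fibril is not up-down symmetric (the
carbonyl column points to the chain above), so the two orientations of
a pair agree only to ~10–15% individually; their average is reported.

## PCA and functional mode analysis

PCA superposes frames on the reference (Cα fit), flattens the selected
coordinates and takes the economy SVD; eigenvalues are sample
variances (ddof = 1), modes are orthonormal and descending, and the
eigenvalue sum equals the total coordinate variance (trace identity,
tested at 10⁻⁸).

FMA fits the response (typically the ordP series) by ordinary least
squares on the first m projections using only the model-building
frames; the default split is first half build / second half validation
(contiguous blocks; a seeded random split is available), and the
default m is the smallest count explaining ≥90% of coordinate
variance, capped at build_frames/10 — an over-fit guard refuses
m > build_frames − 2.  Cross-validated quality is the Pearson r
between predicted and actual response on the held-out frames.  The
ewMCM is the *eigenvalue-weighted* coefficient combination of the
retained eigenvectors, normalised to unit length and oriented so its
motion correlates positively with the response.  The eigenvalue
weighting is essential: bare OLS coefficients on near-zero-variance
modes are large and noisy, and an unweighted combination is dominated
by them; weighting by the ensemble's actual fluctuation along each
mode recovers a planted collective mode with overlap >0.99 where the
unweighted vector reaches only ~0.2.

ewMCM trajectories interpolate the mean structure along the vector
between the minimum and maximum observed projections; the filtered
RMSF replaces each frame's deviation by its projection onto the ewMCM,
giving per-atom RMSF |ewMCM_atom| · std(s).  Localisation statements
about the filtered RMSF are made in variance (RMSF²) terms, which is
the quantity a rank-1 mode actually localises.

**Benchmark design.**  The planted-mode recovery benchmark (1000
frames, noise σ = 0.01 nm, half-split) plants the C-terminal fraying
mode on a stack with a 15° baseline tilt.  The baseline tilt matters:
ordP is a cosine and is quadratic (flat) in any lateral displacement
around a perfectly aligned stack, so no linear model could see the
mode there; around a tilted baseline the response is locally linear
and the linear-FMA assumption holds by design.

## Comparison pipeline

`run_comparison` executes every stage per labelled ensemble and writes
TSVs, a JSON summary and a side-by-side table.  SASA-based stages run
on an evenly-spaced frame subsample (default 20 frames) — the
quadratic cost of surface quadrature dominates the pipeline and the
ensemble means converge quickly on the synthetic fixtures; all other
stages use every frame.  Outputs use fixed six-decimal formatting and
carry a SHA-256 config hash, making runs byte-reproducible for a fixed
config and seed.  Logs go to stderr; results never do.

The ordered-vs-disordered demonstration in `scripts/acceptance.py`
compares an ordered S-shaped stack (σ = 0.02 nm) against a disordered
U-shaped one combining σ = 0.12 nm noise, a 60° per-chain tilt and
strong C-terminal fraying of the central chain (amplitude series up to
4.0 on the unit mode field, i.e. ~1.5 nm per displaced residue — the
central chain so that the interior B-C/C-D pairs see the fraying).
These conditions produce an unmistakably disordered stack (order-
parameter peak well below the ordered ensemble's, broken C-terminal
contacts) while leaving the chains intact; only the directions of the
differences are meaningful, not their magnitudes.

## Known limitations

* The generator's backbone is geometrically idealised (carbonyl
  orientation, approximate ω and C–N bond across turns); it is
  unsuitable for force-field work or chemical realism.
* The secondary-structure classifier is not DSSP; helices and rare
  motifs (3₁₀, π, bridges) are folded into three coarse classes.
* SASA rotation invariance is limited by the fixed quadrature grid
  (≲1% at 960 points).
* FMA assumes a linear response in the principal components; strongly
  nonlinear observables need a different response model.
* Interaction surfaces are pairwise; three-chain burial effects are
  not represented.
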