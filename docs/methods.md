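# Methods

`carotenostruct` quantifies how carotenoid pigments sit inside a
carotenoprotein: the geometry of the bound chromophores, their contacts with
the protein shell, and the supporting sequence/mass/spectral bookkeeping
around a purification-and-structure study of a blue, astaxanthin- and
mytiloxanthin-binding heterodimer.  This note records the models,
parameters, numerical choices and limitations.

## Atomic model and input conventions

Structures are read from mmCIF/PDB with gemmi into a chain/residue/atom
hierarchy using **author numbering** throughout (interaction tables cite
residues the way crystallographic papers do, e.g. `Ser133(A)`).  Coordinates
are in Å, right-handed axes, as deposited.

* **Alternate locations** collapse to the highest-occupancy conformer, ties
  broken by file order.  The analyses are single-conformer by design; this
  changes atom counts only by removing duplicate-named conformers.
* **Waters** are retained but flagged, and excluded from contact, H-bond and
  SASA-partition analyses by default (a flag re-includes them in contact
  shells).
* **Hydrogens** are not expected; every geometric criterion is defined on
  heavy atoms.
* **Glycans** (NAG etc.) are kept as non-polymer residues: never counted as
  protein, reported under their own keys in SASA partitions.

**Dimer selection.** Crystals often carry several copies of the biological
unit in the asymmetric unit; the convention is to describe the copy with the
lowest average B-factor.  `select_dimer` pairs protein chains through shared
ligand contacts (a ligand within 5 Å of two chains marks them as partners)
and keeps the pair minimizing mean protein-atom B.  Candidates are sorted by
(mean B, chain ids) so the choice is independent of chain order in the file.

**Ligand templates.** A `CarotenoidTemplate` carries heavy-atom names,
formal bonds, the ordered conjugated `polyene_path`, named end-ring atom
sets and named torsion quadruples.  Shipped templates: astaxanthin (AXT,
C40H52O4, two β-end rings with 3-hydroxy-4-keto substitution) and
mytiloxanthin (MXT, C40H54O4, one β- and one κ-end ring, a C7–C8 triple
bond, a C8′ enolic hydroxyl).  The MXT template is a reconstruction from the
published chemotype using standard carotenoid numbering; depositions with a
different atom-name dialect are absorbed by name normalization (`*`/`′` →
`'`) and the matching rule (≥ 90 % of template heavy-atom names present;
residues whose code equals a template code are matched to that template
only, since the AXT/MXT skeletons share > 90 % of their atom names).

## Geometric descriptors

**Torsions.** Signed dihedrals use the IUPAC convention, range (−180°,
180°], computed by the two-normal `atan2` form; the sign flips under mirror
images, and a collinear middle bond raises rather than returning an
arbitrary value.

**End-ring conformation.** The ring–chain single-bond conformation (e.g.
the 6/6′ torsion C5–C6–C7–C8) is classified s-trans iff |angle| > 90°,
s-cis otherwise — the strict inequality puts the 90° boundary in s-cis.
This threshold is consistent with free-pigment rings near −40° (s-cis) and
protein-bound rings at 165–171° (s-trans).

**Bond length alternation (BLA).** Mean single-bond length minus mean
double-bond length along the polyene path.  Bond classes come from the
template's *formal* orders, never from observed lengths (the crystal lengths
are the measurement, not the classifier).  The path covers the conjugated
chain between the end rings; ring-internal double bonds are excluded, and a
triple bond (MXT C7–C8) enters neither mean.  Half-path scopes (β-side /
β′-side) split at the central bond; with an odd bond count the central bond
belongs to neither half, so the full-path BLA is reconstructable from the
two halves plus the central bond.

**Planes and pairs.** Polyene planes are total-least-squares fits (SVD of
the centered coordinates); the normal's sign is fixed toward +z (ties: +x,
then +y) so reports are deterministic.  For a bound carotenoid pair the
descriptors are: the acute interplanar angle; the minimum distance over
inter-ligand *polyene-chain* heavy atoms (end rings excluded — the quantity
describes the stacked chromophores, not ring splay); and a signed crossing
dihedral over a named quadruple spanning the two ligands (e.g.
C9(MXT)–C15(MXT)–C15(AXT)–C9(AXT)).

**Pseudo-twofold axes.** The dimer axis is the rotation axis of the best
subunit-onto-subunit superposition (a warning is issued if the rotation is
under 120°, i.e. no meaningful twofold).  The carotenoid-pair axis is the
rotation axis of the best rigid map of one polyene onto the other, trying
the forward and reversed path orientation and keeping the lower RMSD; paths
of unequal length are compared over a centered common subpath.  The angle
between the axes is classified coincident (< 30°), perpendicular (> 60°), or
oblique — the literature uses only the qualitative labels, so the thresholds
are this package's reproducible operationalization.

All descriptors are pure functions of heavy-atom coordinates, hence
invariant under rigid motion (verified to 1e-6 over 100 random transforms);
on noise-free synthetic polyenes the constructed BLA/torsion/min-distance
values are recovered to 1e-6.

## Interaction descriptors

**Contact shells.** A residue is in the shell when any heavy atom lies
within the cutoff (default 4.0 Å) of any ligand heavy atom; protein residues
only, partner carotenoids and glycans excluded, sorted by chain and residue
number.  Shells are monotone in the cutoff.  Whether published 4 Å shells
used all ligand atoms or the polyene only is generally unstated; the default
here is all ligand heavy atoms.

**Hydrogen bonds.** Heavy-atom N/O⋯N/O pairs within `d_max` (default
3.5 Å — the underlying study states no criterion, so this standard value is
a package choice) where a donor→acceptor assignment exists under a typing
table: backbone N donates, backbone O accepts, side-chain roles follow
standard chemistry (hydroxyls both, carboxylates accept, Lys/Arg/amide N
donate); ligand oxygens type by template bond order (single-bonded →
hydroxyl, both roles; double-bonded → keto, acceptor only).  Hydrogens being
absent, the optional geometric filter uses the donor's bonded heavy-atom
antecedent as a proxy and requires the antecedent–donor–acceptor angle
≥ 90°.  Each pair is reported once (hydroxyl–hydroxyl pairs in a single
orientation); ligand-internal bonds (e.g. an enolic hydroxyl to a nearby
keto oxygen) are reported in a separate class.

**SASA.** Shrake–Rupley with a deterministic Fibonacci-spiral lattice
(default 960 points per atom, probe 1.4 Å) — no RNG, so results are exactly
reproducible.  Van der Waals radii follow Bondi (C 1.70, N 1.55, O 1.52,
S 1.80 Å); burial fractions are mildly radii-sensitive, so the table is part
of the module contract.  The isolated-sphere closed form 4π(r+probe)² is
reproduced within the lattice tolerance (≤ 0.5 %), and a 20-atom cluster
agrees with a 10 000-point quadrature within 2 %.

**SASA partition.** For ligand L and group X (a protein chain, a glycan, or
the partner carotenoid):

    buried_X = (SASA(L alone) − SASA_L(L + X)) / SASA(L alone)
    exposed  =  SASA_L(full complex) / SASA(L alone)

Pairwise burial can double-count triple overlaps, so buried fractions plus
exposed need not sum to 1; the residual is reported as `overlap` rather than
renormalized (published per-subunit shares that sum below 100 % are
consistent with exactly this pairwise accounting).

**Fragment B-factors.** Unweighted mean and population SD of B over a
template-defined fragment (an end ring); a mobile, weakly anchored ring
shows a distinctly higher mean B than a hydrogen-bonded one.

## Superposition

Chains are matched by global pairwise sequence alignment (BLOSUM62, gap
open 10, extend 0.5 — the comparison tools used in the literature are
ClustalW-like but unparameterized, so standard values are pinned) and
superposed over matched Cα atoms with the Kabsch SVD rotation; a reflection
is never chosen.  Identity is identical columns over aligned columns
excluding terminal gaps, the conventional way "percent identity" is quoted.
Iterative trimming (default `trim_sigma` 2.0, ≤ 10 iterations) removes pairs
deviating by more than `trim_sigma`×RMSD and refits — emulating the outlier
rejection behind published "RMSD over n matched atoms" figures;
`n_matched` reports the pairs actually fitted, after trimming.  A floor of
1e-4 Å prevents "trimming" of an already-exact fit.  Dimer-level
superposition concatenates per-chain alignments, tries both chain pairings
and keeps the lower-RMSD one, fitting a single rigid transform.  The Kabsch
RMSD agrees with an independent quaternion (Horn) solution to 1e-9 on random
point sets.

## Sequence, mass and spectral utilities

* **Sequons**: every N-x-T (x ≠ P) start position; N-x-S/T by flag.
  Positions are reported on precursor numbering and, when the
  signal-peptide cleavage is known, also on mature numbering (shifted by
  exactly the cleavage offset).  Cleavage positions are user-supplied facts
  (e.g. from Edman sequencing); no signal-peptide prediction is performed.
* **Cysteine profiles**: positions and count on the mature chain are exact;
  the profile-1/2/3 label is matched against a configurable pattern table
  (counts + coarse gap classes).  The shipped table is a reconstruction —
  the defining alignments live in the cited family classification, not in
  the source study — so labels are advisory and `unclassified` is a value,
  not an error.
* **Exact masses**: monoisotopic, from pinned IUPAC values (C 12 exactly,
  H 1.0078250319, O 15.9949146221; electron 0.00054858); charged adducts are
  electron-corrected.  Mass is additive over concatenated formulas to 1e-9.
* **Spectra**: λmax is the highest interior local maximum of a centered
  moving average (default 5 nm window) within the search range, so its
  resolution is one grid step; monotone or flat input raises a no-peak
  error.  The bathochromic shift is bound-minus-free λmax, positive toward
  red.  Shoulder detection (optional) looks for renewed concavity on the
  long-wavelength flank past the peak and is reported without a precision
  claim.

## Synthetic data: what it emulates, and what it does not

The generators produce the geometric and statistical structure the analyses
assume, with the implied ground truth returned alongside: planar zig-zag
polyenes with prescribed alternating bond lengths (implied BLA =
single − double exactly) and end-ring stubs rotated to prescribed torsions;
stacked polyene pairs offset along the plane normal (implied minimum
distance = offset, interplanar angle = 0); two-chain shells of pseudo-
residues with real amino-acid atom naming whose polar atom sits at an exact
anchor distance; C2-symmetric dimers with carotenoid pairs related by a
chosen axis; sequences with planted sequons/cysteines on a motif-free
background; Gaussian spectra with seeded noise.  Structures serialize to
valid mmCIF, so file round-trips are part of the test surface.  All
randomness flows from one explicit seed.

They are *not* realistic proteins: no folds, no packing, no crystallographic
noise model, no correlated B-factors.  Passing recovery tests therefore
demonstrates the correctness of the descriptor computations and their
invariances — not robustness to real-data pathologies such as missing
density, alternate conformers of the ligand itself, or refinement-restraint
bias in bond lengths (on real crystal coordinates at moderate resolution,
bond lengths — hence BLA — carry substantial restraint influence; the
statistic is reported as measured).

Default study-like conditions: 18-atom polyene (the conjugated C7…C7′ chain
length of the shipped templates), single/double bond lengths 1.45/1.35 Å
(typical conjugated-polyene values), inter-polyene offset 7 Å and ring
torsions 170°/−35° (the bound-state geometry scale), end-ring mean
B-factors 31/56 Å² (ordered vs mobile ring), 1 nm spectral grid.

**λmax recovery conditions.** The SNR ≥ 20 recovery property is verified on
narrow bands (Gaussian σ 8 nm, 15 nm smoothing window): the prescribed
argmax estimator resolves the center at the grid resolution only when the
peak's curvature exceeds the post-smoothing noise; for broad carotenoid
bands (σ ≈ 30 nm) at the same SNR, argmax wanders several nm and a
higher SNR or sub-grid fitting would be required.  This is a documented
limitation of the deliberately simple peak caller.

## Reference depositions

The accession-based analyses (subunit RMSD ≈ 1.5 Å over ≈ 168 Cα, dimer
RMSD vs the ependymin-related fold ≈ 3.8 Å over ≈ 320 Cα, SASA shares near
48/45 % and 46/46 %, crossing dihedrals −141° / 127°, ≈ 7 Å plane
separation, end-ring B-factors ≈ 56/31 Å², the 4 Å shells and the
Ser133-κ-ring hydrogen bond, perpendicular vs coincident axis relations)
run against deposited coordinates that are **not distributed** with the
package: `scripts/fetch_reference_data.py` downloads them (network
required), `scripts/reference_analysis.py` computes the numbers, and the
corresponding acceptance test fails with a clear message when the files are
absent.  Published per-subunit SASA shares carry an unstated method and
parameters; the comparison tolerance is ±3 percentage points accordingly.
The deposited free-pigment reference geometries for relative end-ring
rotations are not available, so only absolute crystal torsions are
computed.

## Out of scope

No quantum-chemical computations of any kind (TD-DFT excitation energies
and λmax values, ring-fixing energies, optimized-geometry BLA values,
protonation-state assignment), no crystallographic data processing or
refinement, no phylogenetic tree inference, no exciton-coupling modeling,
no conjugation-length → λmax prediction, no structure-based (sequence-free)
alignment, no symmetry expansion from crystallographic operators.
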