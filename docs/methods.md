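# Methods

This note documents the models, conventions and numerical choices behind
`structkit`, and what the synthetic test fixtures do and do not demonstrate
about real macromolecular data.

## Coordinate model and file I/O

Structures are represented as an ordered hierarchy Structure > Chain >
Residue > Atom, with residues identified by *author* numbering — the pair
(number, insertion code) that appears in PDB files and in the literature
when a loop is called "19–38". Ranges are inclusive on both ends.

Parsing policy, where the community has no single convention:

* **Alternate locations** are resolved at parse time: within each residue
  and atom name the highest-occupancy conformer is kept, ties broken
  alphabetically by alt-loc identifier. This is the standard
  single-conformer convention; no occupancy-weighted averaging is done.
* **Multi-model files** (NMR ensembles) yield model 1 by default; any other
  model is available by explicit number. Models are never averaged.
* **mmCIF** identity comes from the author fields (`auth_asym_id`,
  `auth_seq_id`, …), falling back to `label_*` when absent, so an mmCIF
  parse matches a PDB-format parse of the same entry. Only the `_atom_site`
  loop is interpreted; the tokenizer honours single/double quoting so
  values containing spaces survive intact.
* **Hydrogens** are kept on parse but excluded from every downstream
  distance and contact computation.

The PDB writer emits fixed-column ATOM/HETATM records with three-decimal
coordinates, a TER after every chain and a terminal END; the round-trip
parse→write→parse is lossless on hierarchy and exact to the 10⁻³ Å printing
precision on coordinates. Chain identifiers longer than one character are
rejected (PDB column limit).

## Rigid-body geometry

Superposition uses the Kabsch algorithm: SVD of the cross-covariance of the
centred point sets, with the smallest singular vector flipped when the
candidate rotation has negative determinant, so the result is always a
proper rotation. Point sets of rank < 2 (collinear) are rejected rather
than silently returning one of the infinitely many optima. The test suite
checks the minimum RMSD against an independent quaternion-parametrized
optimum (the principal eigenvector of the Davenport K-matrix), which agrees
to ~10⁻¹⁴ Å.

SSE axes are fitted to Cα positions only (the convention of the
super-secondary-structure literature, and the most robust choice when side
chains or carbonyls are missing): the axis is the leading principal
component of the centred Cα coordinates, oriented N→C, with endpoints given
by projecting the first and last Cα onto the fitted line. Torsions follow
the IUPAC sign convention and are reported in degrees, as are all angles in
the package.

## Secondary structure

The internal assigner follows the Kabsch–Sander hydrogen-bond tradition.
Backbone amide hydrogens are imputed 1.01 Å from N along the direction
opposite the bisector of the C(prev)–N–Cα angle. A CO(i)…NH(j) bond is
declared when the electrostatic energy

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol

falls below −0.5 kcal/mol (an O…N pre-screen at 5.2 Å merely skips pairs
that cannot reach the cutoff). Two consecutive 4-turns (bonds i→i+4 and
i+1→i+4+1) mark a minimal helix run; parallel/antiparallel bridge patterns
over the bond set mark strands, with helix taking precedence. The result is
deliberately 3-state (H/E/C): 3₁₀ and π helices collapse to H, isolated
bridges to E, and turns/bends to C, both here and when classic DSSP output
files are ingested. Residues with incomplete backbones are forced to coil
and counted in the result. Segmentation keeps maximal runs of at least 4
(helix) or 3 (strand) residues — the shortest physically meaningful helix
turn and bridge-capable strand — and fits an axis per run.

## Smotif geometry

A smotif is two consecutive SSEs plus the connecting loop. With M1, M2 the
unit axis directions and Dv the vector from the first axis's C-end to the
second axis's N-start, the four descriptors are

* D = |Dv| (inter-SSE distance, Å),
* δ (hoist) = angle(M1, Dv) ∈ [0°, 180°],
* θ (packing) = angle(M1, M2) ∈ [0°, 180°],
* ρ (meridian) = right-handed rotation of M2 about M1, measured from the
  (M1, Dv) half-plane containing Dv, ∈ [0°, 360°).

The smotif literature agrees on the four names but not on one set of
endpoint/plane conventions; the definitions above were fixed once and
validated by round-trip against the scaffold generator, which places ideal
SSEs at exactly prescribed (D, θ). When Dv vanishes the motif is flagged
degenerate (δ, ρ undefined); when θ is 0° or 180° the meridian is
conventionally 0. Similarity search uses a weighted Euclidean distance over
(ΔD, Δδ, Δθ, Δρ) with the meridian difference taken circularly; the default
weights equate 1 Å with 15°, and are configurable because no published
metric exists for this space. Ties rank by library order.

## Loop grafting

Grafting superposes the donor's flanking stem residues onto the acceptor's
(default 4 residues per side, backbone N/CA/C/O — enough points for a
stable Kabsch fit while staying inside the structurally conserved stems),
applies the fitted rigid motion to the donor loop and splices it in place
of the acceptor loop. The stated range is the replaced segment, inclusive;
flanks lie outside it. Grafted residues are renumbered consecutively from
the start of the acceptor range with empty insertion codes; when the donor
loop is longer, numbering continues past the old range end and downstream
residues keep their original numbers (gap-tolerant, so author numbering of
the untouched part survives). Side chains are carried over unmodified — no
repacking, minimization or loop closure. Steric strain is *reported*, not
repaired: any grafted-loop heavy atom closer than 2.5 Å to a retained
acceptor heavy atom (flanks excluded) counts as one clash.

## Interfaces

An interface between two chains is the set of residue pairs whose minimum
inter-atomic distance is at or below a cutoff, one contact per pair
carrying that minimum. Atom modes: `heavy` (all non-hydrogen), `ca`, `cb`
(Cβ, with Cα substituted for glycine). Defaults are 5.0 Å heavy-atom and
8.0 Å Cα — common literature values. Hetero residues (waters, ligands) and
hydrogens never contribute; contacts are inter-chain only. Contact kind
(protein–protein, protein–nucleic, nucleic–nucleic) derives from residue
classification: the 20 standard amino acids + MSE are protein, the
canonical (deoxy)ribonucleotides nucleic.

## Homology hits, the Rost curve, PIR output

BLAST results are read from the standard 12-column tabular format only —
line-oriented, stable and testable without the binary. Coverage is defined
on the query, (q_end − q_start + 1)/query_length; this side is not
universal, so it is documented rather than assumed. The Rost significance
curve is the published closed form

    p(L) = n + 480 · L^(−0.32·(1 + e^(−L/1000)))

with a configurable offset n (default 5, a common conservative choice for
template selection). Note a property of this fit worth knowing: it was
fitted to the twilight-zone regime and is strictly decreasing only up to
L ≈ 400; beyond that it has a shallow artifact minimum (a rise of ~0.1
percentage points) before resuming its slow ~L^−0.32 decay toward n. The
tests therefore assert strict monotonicity on the fitted domain and the
correct long-L decay, not global strictness.

PIR output is the comparative-modeling dialect: a `structureX` template
entry whose description carries the chain and residue range, a `sequence`
query entry, 60-character line wrap, `*` terminators. A minimal PIR reader
exists solely to validate and round-trip the writer's output in tests.

## Synthetic fixtures: what they show and what they do not

All fixtures are built by sequential internal-coordinate placement from
ideal bond lengths (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å), ideal
angles (111.2°/116.2°/121.7°) and canonical torsions (helix φ=−57°,
ψ=−47°; strand φ=−120°, ψ=+120°; ω=180°), with Cβ placed tetrahedrally in
the L configuration. This yields exact, dependency-free ground truth:
generators are pure functions of their parameters and seed, and regenerate
bit-identical coordinates.

The antiparallel pairing fixture places a second ideal strand alongside the
first at fixed design constants (separation 4.0 Å, axial shift 0, roll
345°), chosen once by a deterministic grid search so the cross-strand
CO…NH pairs satisfy the assigner's energy criterion with a comfortable
margin — i.e. the fixture is hydrogen-bond-competent by construction. The
scaffold generator aligns each SSE's *fitted* axis to the prescribed
geometry, so the prescription refers to exactly the quantity the smotif
module measures; the connecting loop is an interpolated, seeded-jitter coil
whose backbone is laid out along the local chain direction (atoms present
and roughly spaced, but not at ideal internal coordinates). Dimer fixtures
place free-standing compact residues, with designed contacts solved to the
target distance by bisection (±0.005 Å) and all other pairs kept > 2 Å
beyond the cutoff.

Consequently, passing tests demonstrate algorithmic correctness —
superposition optimality, exact enumeration equivalence, parameter
recovery, format fidelity — on idealized geometry. They do not demonstrate
robustness to the pathologies of experimental structures: missing atoms
beyond the cases explicitly tested, non-ideal bond geometry, chain breaks,
unusual residues, or crystallographic artifacts. Problem sizes throughout
(12-residue helices, 30+30-residue dimers, 20-hit filter sets, 50 random
alignments, 100 superposition instances) were chosen as the smallest sizes
that exercise every code path and keep the full suite fast.

## Known limitations

* The internal assigner is 3-state and minimal; it does not reproduce full
  8-state DSSP (π-helices, β-bulges, turns, bends) and will differ from
  DSSP near SSE termini.
* Nucleic-acid support is a rigid placeholder ladder for interface typing;
  there is no realistic nucleotide geometry generator.
* Grafting performs no energetic refinement; the clash count is a
  diagnostic, not a repair mechanism.
* The smotif similarity metric is a pragmatic weighted distance, not a
  statistically calibrated one; weights should be tuned per application.
* Networked retrieval (PDB/AlphaFold), execution of external binaries
  (BLAST, DSSP, CD-HIT), SEQRES/CONECT header records and crystal symmetry
  are out of scope by design.
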