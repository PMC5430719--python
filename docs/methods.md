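# Methods

## The joint-based descriptor

A polytopic α-helical membrane protein with TM helices H₁…Hₙ is reduced
to 2n joint points: P₂ᵢ₋₁ and P₂ᵢ are the Cα atoms of the first and last
residue of helix Hᵢ. Loops are the implicit gaps between consecutive
helices. The descriptor is the ordered torsion series over sliding
joint quadruples P_k…P_{k+3}, k = 1…2n−3: odd k gives Ω-type angles
(Helix–Loop–Helix windows, relative tilt of adjacent helices), even k
gives λ-type angles (Loop–Helix–Loop windows, same-side/opposite-side
placement of next-nearest helices). The count law — n−1 Ω and n−2 λ
angles per protein — is enforced throughout and exposed as
`expected_counts`.

The descriptor is deliberately macroscopic: helices are treated as
straight P-to-P segments, so kinked or strongly bent helices produce
angles that do not reflect their internal geometry. That is a property
of the representation, not an artifact; the tool makes no attempt to
detect or correct kinks.

## Torsion computation and sign convention

With V₁ = P₁−P₂, V₂ = P₂−P₃, V₃ = P₃−P₄ and plane normals n₁ = V₁×V₂,
n₂ = V₂×V₃, the signed angle is

    angle = atan2((n₁ × V̂₂)·n₂, n₁·n₂)

in degrees, folded to (−180°, 180°] with exact −180° mapped to +180° so
the trans configuration has one representative. This equals the
geometric reading "project P₁ and P₄ onto the plane perpendicular to
P₂→P₃; clockwise rotation from the P₁ ray to the P₄ ray, viewed from P₂
toward P₃, is positive", and it agrees with the dihedral convention of
standard structural libraries (verified against Bio.PDB in the test
suite to 1e−6°, and against an independently coded projection oracle to
1e−9°). A planar cis quadruple gives 0°, planar trans +180°.

Degenerate inputs are errors, never silently patched: coincident
consecutive points ("degenerate segment") and collinear triples
("undefined normal", declared when |normal| < 1e−10 × the product of the
two arm lengths).

## Inputs and annotation policy

Cα coordinates are read from PDB text (gemmi). Alternate locations
collapse to one conformer: blank altloc wins, otherwise highest
occupancy with 'A' as the tiebreak. Residues are keyed by author number
plus insertion code; segment boundaries match on the number with an
empty insertion code unless the annotation provides one. No renumbering
is ever applied.

TM-helix boundaries are an explicit input, in precedence order: a
user-supplied segment table (columns `protein_id chain helix_index
start_residue end_residue`), then the PDB header's HELIX records as a
fallback. Secondary-structure re-assignment (DSSP-style) is deliberately
not offered — reproducible joints require fixed, citable segment
definitions, and curated databases (OPM/PDBTM-class) disagree often
enough that reconciliation must stay a human decision. A missing
boundary residue aborts that protein with a named error rather than
substituting a neighbour, since a one-residue shift moves a joint by
~1.5–3.8 Å and visibly changes the dihedrals. Chains are processed
independently; two-helix chains are accepted with a warning (one Ω, no
λ), single-helix chains rejected.

## Pattern statistics

Angles map to signs ("+" for (0°, 180°], "−" for (−180°, 0°)) and λ
additionally to quadrants A = (0°, 90°], B = (90°, 180°],
−A = [−90°, 0°), −B = (−180°, −90°). Boundary rules are fixed once and
tested: an exact 0° counts as "+"/A with a logged warning; edges close
on the side away from zero. These are measure-zero events — any fixed
rule works, but it must be stated.

Dyads and triads are overlapping windows of adjacent same-kind angles
only (Ωᵢ with Ωᵢ₊₁, never Ωᵢ with Ωᵢ₊₂), pooled across proteins, with
every possible pattern present zero-filled (4 or 8 sign patterns, 16
quadrant dyads). Quadrant patterns are defined for λ only, where the
full-circle distribution makes the 4-way partition informative; the
request is rejected for Ω. TM-size groups default to 3–6, 7–10 and
11–14 helices, overridable.

Bootstrap SDs resample the window-level observations with replacement to
the original count, B = 500 replicates by default, re-tally, and take
the SD per pattern over replicates; a zero-count pattern has SD 0.
Whether published error bars of this kind resample windows or whole
proteins is ambiguous in general, so protein-level resampling is
available as an option (`protein_groups`), window-level being the
default reading of "resampling the data". For two observations split
between two patterns the resampled count is Binomial(2, ½), SD
√0.5 ≈ 0.707 — the closed form used as the correctness check.

The Ω–λ scatter pairs Ωᵢ with λᵢ, which share three of their four
joints; the last Ω of each protein is unpaired and appears only in the
marginal histograms, which are computed from all angles regardless of
pairing, so the marginals are pairing-independent. Histogram bins
default to 20°, aligned to 0° — the resolution at which the Ω
distribution's two preferred bands (−30° to −10° and +10° to +30°)
separate — and must divide 360°.

## Symmetry screening

A protein's λ-signature is the ordered sign vector of its λ angles. Two
proteins with equal helix counts whose signatures are exact elementwise
negations are emitted as a candidate mirror pair. Exact full-length
negation is the minimal falsifiable reading of "symmetric configuration
of λ angle signs"; a palindromic variant (reverse of the negation) is
implemented but off by default. Ω signs are not constrained. The screen
is a candidate generator: confirming 3-D mirror symmetry is a human
step, supported by the per-pair signature tables the tool writes.

## Synthetic bundles

`build_chain` converts a `BundleSpec` — 2n−1 segment lengths, 2n−2
planar angles, 2n−3 torsions — to Cartesian joints by torsion-extension
(NeRF) placement: P₁ at the origin, P₂ on +x, P₃ in the xy-plane, each
later point placed from the previous three so distance, planar angle and
torsion hold exactly. Rebuilding the dihedral series from the result
reproduces the prescribed torsions to better than 1e−6° (measured
~1e−13°); this identity is the package's core oracle, because the
builder inverts torsion measurement through an entirely different code
path.

`write_bundle_pdb` renders a skeleton as ideal α-helical Cα traces:
1.5 Å rise/residue, 100° twist/residue, 2.3 Å radius — conventional
ideal-helix constants, fixture parameters rather than fitted values —
with the rise rescaled so the lattice spans each joint pair, and loop
residues linearly interpolated at ~3.8 Å spacing. Each helix lattice is
translated so its terminal Cαs straddle the joints symmetrically; with a
*closing* twist ((m−1)·100° ≡ 0 mod 360°, e.g. the default m = 19
residues/helix) the terminals coincide with the joints exactly and the
full PDB → parse → joints → dihedrals round trip reproduces the
prescribed torsions to PDB coordinate rounding (measured ≤ 0.008°).
Non-closing residue counts leave up to one helix radius of terminal
offset, which on 10–16 Å loop spans can shift torsions by ~15°; tests
therefore pin the closing default, and the 5° figure quoted for the
end-to-end example holds only there.

`generate_cohort` draws reproducible cohorts (one `numpy` Generator per
seed): helix spans U(26, 32) Å and loop spans U(10, 16) Å (≈20-residue
TM helices at 1.5 Å rise with short connecting loops), planar angles
U(70°, 110°), Ω targets from an equal mixture of U(−40°, −10°) and
U(10°, 40°) (the slanted-antiparallel packing band, giving the bimodal
Ω histogram with >90% — by construction 100% — of skeleton Ω in
[−40°, 40°]), λ targets U(−180°, 180°). A `tm_counts` override lets a
cohort reproduce an exact TM-size composition, which the acceptance
script uses to mirror the reference dataset's 103-protein group
structure. What the generator does *not* emulate: helix kinks and bends,
membrane embedding, sequence, side chains, or correlated angle
preferences between neighbouring windows. Tests passing on synthetic
cohorts therefore validate the measurement and statistics machinery, not
any biological claim about real membrane proteins.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 25–103 proteins of 3–14 helices
and 100–1500 random quadruples or specs per property — sizes at which
every stage runs in seconds while still exercising all code paths. All
randomness flows from explicit seeds (`numpy.random.default_rng`); the
CLI threads one `--seed` through bootstrap and simulation, and reruns on
identical inputs are byte-identical.

## Known limitations

- Joints at helix termini cannot represent kinked or curved helices;
  an extreme Ω near ±180° may reflect a bent segment, not parallel
  helices.
- PDB input only (no mmCIF); monomeric chains only, one chain per
  topology; no TM-segment prediction or database retrieval.
- Symmetry screening is signature-exact: one flipped sign hides a pair
  that looser, not-implemented criteria might keep.
- Statistical output is frequencies with bootstrap SDs; no significance
  testing between groups is performed.
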