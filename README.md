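# tmjoints

Joint-based macroscopic analysis of α-helical membrane protein structure.

Polytopic membrane proteins are bundles of 3–14 transmembrane (TM)
helices connected by loops. `tmjoints` reduces each protein to its
*structural joints* — the Cα atoms of the first and last residue of every
TM helix, P₁…P₂ₙ for n helices — and describes the bundle by the torsion
angles over consecutive joint quadruples:

- **Ω-type angles** (windows starting at an odd joint, a Helix–Loop–Helix
  span): Ωᵢ = torsion(P₂ᵢ₋₁, P₂ᵢ, P₂ᵢ₊₁, P₂ᵢ₊₂) measures the relative
  tilt of helices Hᵢ and Hᵢ₊₁ — 0° is antiparallel, ±180° parallel.
- **λ-type angles** (windows starting at an even joint, a
  Loop–Helix–Loop span): λᵢ = torsion(P₂ᵢ, P₂ᵢ₊₁, P₂ᵢ₊₂, P₂ᵢ₊₃) says
  whether Hᵢ₊₂ sits on the same (0°) or opposite (±180°) side as Hᵢ
  relative to Hᵢ₊₁.

An n-helix protein yields the alternating series Ω₁, λ₁, Ω₂, λ₂, … with
n−1 Ω and n−2 λ angles. Torsions are signed (clockwise positive in the
projection along the central segment, the convention of standard
structural tools), reported in degrees in (−180°, 180°].

On top of the angle series the package provides the analyses this
descriptor was designed for: Ω–λ scatter plots and histograms (a
macroscopic analogue of the Ramachandran plot), consecutive sign-pattern
(dyad/triad) frequencies with bootstrap standard deviations, the
16-pattern λ-quadrant dyad analysis (A/B/−A/−B), TM-size group
comparisons, and screening for protein pairs whose λ-sign signatures are
exact mirror images — candidates for macroscopically symmetric structure
pairs. A synthetic-bundle generator builds joint skeletons from exact
internal coordinates (NeRF chain extension) and renders them as
ideal-helix Cα PDB files, so the whole pipeline is testable with known
answers and no downloads.

## Worked example

Simulate a small cohort, compute its dihedral series, and run the
analyses:

```bash
tmjoints simulate -n 4 --tm-range 3-5 --seed 11 -o sim
tmjoints compute sim/*.pdb -a sim/segments.tsv -o angles.tsv
tmjoints analyze angles.tsv -o reports -B 500 --seed 11
```

`compute` logs one line per protein and checks the count law (n−1 Ω,
n−2 λ) as it goes:

```
INFO tmjoints: SYN001A: 3 helices -> 2 omega, 1 lambda
INFO tmjoints: SYN003A: 5 helices -> 4 omega, 3 lambda
computed 4 protein(s), 0 failure(s) -> angles.tsv
```

`angles.tsv` holds one row per dihedral with the four joint indices that
define it; a 3-helix protein contributes exactly Ω₁, λ₁, Ω₂:

```
protein_id  kind    index  angle_deg  j1  j2  j3  j4
SYN001A     omega   1      -25.3      1   2   3   4
SYN001A     lambda  1      -80.9      2   3   4   5
SYN001A     omega   2      -14.1      3   4   5   6
```

The Ω values sit in ±(10°–40°) — the slanted-antiparallel packing range
the generator's angle model prescribes — while λ ranges over the full
circle. `reports/omega_dyads.tsv` tallies consecutive Ω-sign pairs with
their bootstrap SDs (500 resamples of the window-level observations):

```
pattern  count  bootstrap_sd  group
+,+      1      0.941         all
+,-      2      1.258         all
-,+      2      1.169         all
-,-      2      1.177         all
```

The other reports cover λ dyads/triads, the 16 λ-quadrant dyads, dyad
counts per TM-size group (3–6, 7–10, 11–14 helices), the Ω–λ scatter
pairs, histograms, and `symmetry_pairs.tsv` with any mirrored λ-signature
pairs. `tmjoints analyze --plots` additionally writes PNG versions of the
scatter plot and histograms.

The same functionality is available as a library
(`tmjoints.compute_series`, `tmjoints.count_patterns`, …); see the module
docstrings.

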