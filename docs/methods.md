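# Methods

This note documents the models, conventions and numerical choices behind
`xrayval`, in the spirit of a validation-pipeline methods section. It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinate model and I/O

Structures are held as an ordered Chain → Residue → Atom hierarchy with
orthogonal Å coordinates, occupancies, isotropic B values and altloc
labels. PDB fixed-column parsing and writing are delegated to gemmi; a
light pre-pass checks the coordinate/occupancy/B columns of every
ATOM/HETATM record so that malformed records fail with the offending
line number rather than being silently coerced. The fractional ↔
orthogonal convention is the standard crystallographic one (**a** along
x, **b** in the xy-plane); `REMARK 2` supplies the nominal resolution
and `CRYST1` the cell, both optional until a stage needs them.

Residue classification is a total function of the 3-letter code:
the 20 standard amino acids, the standard (deoxy)ribonucleotides,
HOH/WAT as water, and everything else as ligand.

**Alternate conformations.** All scoring operates on a single-conformer
reduction: per atom label, the highest-occupancy altloc wins, ties going
to the alphabetically first label. Ensemble-aware scoring is a possible
extension; the single-conformer rule is the simplest defensible default
and is applied uniformly, so all per-residue scores refer to the same
reduced model.

**Hydrogens** present in the input are retained but excluded from RSR
regions and from the non-H atom count; clash analysis adds its own
idealized amide hydrogens (below).

## Covalent geometry

The restraint dictionary (`data/geometry_dict.txt`) holds Engh &
Huber-style means and sigmas for backbone bonds and angles of all 20
amino acids plus the inter-residue peptide link (C–N bond; CA–C–N,
O–C–N, C–N–CA and CA–C–O angles). Each observed feature is reported as
a z-score; `|z| > 4` (configurable) flags an outlier. Residue types or
atoms not covered simply contribute no feature — absence of a restraint
is not an error. The carbonyl angle means were chosen to satisfy
CA–C–O + CA–C–N + O–C–N = 360.0° exactly, so a planar carbonyl is
simultaneously consistent with all three restraints; this makes the
ideal-helix fixture exactly clean rather than clean only to rounding.

Two residues count as peptide-linked when the C–N distance is below
2.5 Å; chain breaks therefore suppress inter-residue features and leave
the adjacent torsions undefined.

## Torsions, Ramachandran and rotamers

Dihedrals follow the IUPAC sign convention, computed with the atan2
formulation and reported in (−180°, 180°]. φ = C(i−1)–N–CA–C and
ψ = N–CA–C–N(i+1); termini and chain breaks yield undefined values,
which propagate to an `undefined` Ramachandran class and stay out of
all percentage denominators.

Ramachandran regions are shipped as a rasterised grid
(`data/rama_grid.txt`): 10° bins over the full (φ, ψ) torus for four
categories (general, GLY, PRO, pre-PRO), every cell labelled
favored/allowed/outlier. The grid was rasterised offline from analytic
ellipse regions (α, β and left-handed-α basins, mirrored for glycine,
φ-restricted for proline). The file stores one row per (category,
φ-bin) with a 36-character label run — equivalent to one cell per line
but an order of magnitude smaller. The grid is deliberately coarse and
swappable: the classification algorithm, not the particular
distribution, is the contract, and a higher-fidelity grid in the same
format can be dropped in.

Rotamers: χ atom quadruples and canonical mode vectors live in
`data/rotamers.txt` (coarse penultimate-style values). A residue is
assigned its nearest mode under the max-over-χ circular distance; ties
keep the first library entry; deviations beyond 40° (configurable) are
outliers. Residues without χ axes (GLY, ALA) or with missing atoms are
not evaluated.

## Riding hydrogens and clashes

Backbone amide hydrogens are placed at the idealized riding position:
in the C(i−1)–N–CA plane, 1.0 Å from N, opposite the bisector of the
C–N and CA–N directions; prolines and chain-start residues are skipped.

Clashes are atom pairs with van der Waals overlap
`r₁ + r₂ − d ≥ 0.4 Å` (radii from `data/elements.txt`). The candidate
search uses a KD-tree with radius `2·r_max − cutoff`, so cost is
near-linear in atom count; the test suite checks exact agreement with an
all-pairs scan. Excluded are pairs within three bonds (1-2, 1-3, 1-4)
and hydrogen-bond pairs (a hydrogen riding on N/O against an N/O
acceptor). Bonding combines the shipped per-residue connectivity table
with a `d < 0.6·(r₁+r₂)` distance heuristic that also covers ligands.
Excluding 1-4 and donor–acceptor pairs follows standard clash-analysis
practice: an ideal α-helix contains 1-4 contacts and i→i+4 N–H···O
hydrogen bonds that are features of correct structure, not errors, and
a rule that flagged them would make the clashscore unusable. The
clashscore is 1000 × clashes / atoms, hydrogens included.

## Density synthesis, RSR and RSR-Z

Calculated density is a sum of isotropic atomic Gaussians,
ρ(r) = Σ occ·w·(2πσ²)^(−3/2)·exp(−|r−r_a|²/2σ²), with σ² =
(B + B_soften)/8π², B_soften = 10 Å² (softening keeps sharp low-B atoms
representable at practical grid spacings) and w the electron count.
Contributions are truncated beyond 5σ; the sum over the grid then still
reproduces the total electron count to well under a percent at 0.3 Å
spacing, which the tests verify. The grid spans the model bounding box
plus padding (default 3 Å), or exactly reproduces an observed grid's
raster when scoring against a map.

Residue regions: a grid point belongs to the residue owning its nearest
non-H atom, provided that distance is ≤ 2 Å (EDS-style); exact-distance
ties go to the residue earlier in file order, making regions
deterministic and disjoint.

RSR first fits k = Σρ_oρ_c / Σρ_c² on the region and then evaluates
Σ|ρ_o − kρ_c| / Σ|ρ_o + kρ_c|. The per-region least-squares scale makes
the score invariant to local scaling of the observed map and robust to
global scale drift. Degenerate regions (vanishing denominators) return
an undefined sentinel and are excluded from aggregates.

Reference tables pool (residue class, resolution shell) cells: sample
mean and n−1 sd, cells with fewer than 20 observations omitted. Shells
are 0.2 Å bins over [0.8, 4.0) Å with open-ended end bins; bins are
half-open [lo, hi), so a boundary resolution belongs to the shell it
starts. Amino acids key by name, nucleotides pool as one class, and
ligands key by group: non-H atom count bin (1–5, 6–10, 11–20, 21–40,
>40) × whether any element falls outside the common organic set
(H, C, N, O, S, P, F, Cl, Br, I). Pooling rare ligands by size and
chemistry is what makes RSR-Z feasible for them at all; the bin edges
are a working choice and live in one place
(`density_fit.LIGAND_SIZE_EDGES`).

RSR-Z = (RSR − μ)/σ from the matching cell; the outlier flag is
one-sided at z ≥ 2 — only poor fit is flagged, unusually good fit never
is. A missing cell yields "not evaluated", never a zero.

## Diffraction-data checks

All reciprocal-space work assumes P1 on a Friedel half-sphere
(l > 0, or l = 0 ∧ k > 0, or l = k = 0 ∧ h > 0); space-group symmetry
is out of scope and documented as a limitation. d-spacings come from
the reciprocal metric implied by the orthogonalization matrix; the
tests cross-check random triclinic cells against gemmi's metric tensor.

* **Wilson B.** Reflections with d < 4.5 Å are binned into ten
  equal-count shells in s² = 1/(4d²); a least-squares line of ln⟨I⟩ on
  ⟨s²⟩ gives B = −slope/2. The flat-scattering-factor convention
  (Σf² constant) matches the simulator, so recovery is exact in
  expectation; against real data the estimate inherits the usual bias
  of ignoring the form-factor falloff.
* **Shell normalisation.** The moment, L-test and outlier statistics
  divide intensities by their shell mean (equal-count shells of ~200
  reflections) first. Without this the Wilson falloff masquerades as
  intensity variation — inflating ⟨|L|⟩ and the outlier count — because
  small synthetic cells put neighbouring indices far apart in s².
* **Mislabelling.** Pooled ⟨E²⟩/⟨E⟩² is ≈2 for acentric intensities and
  ≈4/π ≈ 1.27 when amplitudes were supplied as intensities; verdict
  bands [1.8, 2.3] → consistent, [1.1, 1.45] → suspect, else
  inconclusive.
* **L-test.** Pairs (h, h+δ), δ components drawn from {0, ±1, ±2},
  δ ≠ 0, both present; L = (I₁−I₂)/(I₁+I₂). ⟨|L|⟩ is 1/2 for untwinned
  acentric data and 3/8 for a perfect twin; verdict thresholds 0.46 /
  0.40 bracket the two theory values. Pair sampling is seeded and
  deterministic.
* **Outlier reflections** exceed t× (default 10×) their shell mean,
  reported in descending order of ratio.
* **R/Rfree.** Structure factors by direct summation,
  F(h) = Σ occ·w·exp(−B s²)·exp(2πi h·x_frac) with s² = (sin θ/λ)²,
  capped at 10⁴ atoms; the scale k = Σ|F_o||F_c|/Σ|F_c|² is fitted on
  the working set only and reused for the free set.

## Percentile ranking

Archive statistics files are versioned, append-only snapshots; the
version string is embedded in every report so a rank is always
interpretable as "relative to archive X". Percentiles use the mid-rank
tie rule, which is symmetric and gives 50 when all values tie. The
relative cohort is the min(n, archive) entries minimizing
|Δ resolution|, ties broken by smaller resolution then entry id; the
query entry itself is excluded by id when it is already archived, so an
archived entry is never ranked against itself. Orientation metadata on
each metric means "higher percentile = better quality" holds for every
slider regardless of the raw score's direction.

## Aggregation and reports

Chain percentages are 100·outliers/evaluated over that chain; entry
percentages pool residues across chains rather than averaging chain
percentages, so a short bad chain cannot dominate an entry. Waters are
excluded from all denominators; ligands are excluded from
Ramachandran/rotamer statistics but participate in RSR/RSR-Z through
their group keys. Metrics with zero evaluated residues are
"not evaluated" and appear in the XML as absent attributes — never as
zeros — and in the percentile block as an explicit `ranked="false"`
marker.

The XML report validates against `data/report_schema.xsd` at render
time (a failure is an internal error, not user error). Element order is
fixed and numbers use three decimals, so identical inputs render
byte-identically; provenance carries the seed, a config hash, the tool
version and the archive version. Wall-clock timestamps are deliberately
left out of the XML (they go to the log) because report bytes are
treated as a pure function of inputs. The slider summary maps
percentile p to 1-based column round(p/100·49)+1 of a 50-character bar.

## Synthetic data

The generators define the toolkit's test conditions:

* `make_helix` builds poly-Ala from internal coordinates (natural
  extension reference frame) using the dictionary means, φ = −57°,
  ψ = −47°, ω = 180°, B = 20 Å², occupancy 1; CB is placed on the
  L-configuration branch (verified against canonical L-Ala coordinates).
  By construction it is exactly clean under every model check.
* `perturb_structure` adds i.i.d. Gaussian coordinate noise (RMSD
  σ√3 in expectation, which the tests verify via the χ distribution).
* `simulate_observed_map` adds Gaussian noise scaled by the noise-free
  map's sd, so noise levels are comparable across models.
* `simulate_wilson_set` draws I = exp(−2Bs²)·Exp(1) on the full P1
  half-sphere (default B = 40 Å², cubic 30 Å cell) and mixes disjoint
  (h,k,l)/(−h,−k,l) mate pairs for twin fraction α; l = 0 reflections
  coincide with their Friedel images under this operator and are left
  unmixed (a ~2–3 % population whose effect on ⟨|L|⟩ is far below the
  test tolerances). 5 % of reflections are flagged free.
* `sample_archive` draws each slider metric from a log-normal whose
  median worsens linearly with resolution, emulating the archive-wide
  quality/resolution trend that makes relative percentiles informative.

What the generators do **not** emulate: solvent and bulk-solvent
contributions, anisotropic displacement, crystal packing, space-group
symmetry, measurement-error models on intensities and realistic
side-chain chemistry (the helix is poly-Ala; rotamer logic is tested on
constructed fragments). Passing tests therefore demonstrate
correctness of the statistics and plumbing under these idealized
conditions, not end-to-end accuracy on real depositions.

Problem sizes used by the tests and the acceptance script — 10-residue
helices, ~2×10⁴-reflection simulations, 5000-entry archives, 10⁴-draw
standardisation checks — were chosen as the smallest sizes at which the
statistical tolerances above are comfortably resolvable.

## Known limitations

P1 only; backbone-amide-only hydrogen placement; no mmCIF input; no
FFT-based 2mFo−DFc synthesis (observed maps are supplied, or simulated
from the Gaussian model); no side-chain flip or H-bond satisfaction
analysis; coarse in-house Ramachandran/rotamer tables; no anisotropy or
missed-symmetry diagnostics.
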