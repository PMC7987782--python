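# Methods

## Structure model

Structures are reduced to single polymer chains of standard amino acids
(`ChainModel`). Waters, ligands and non-standard residues are dropped, except
selenomethionine which is mapped to methionine. Hydrogens are retained in the
atom list but excluded from all contact and surface computations: crystal
structures at the resolutions of interest rarely resolve them, and excluding
them keeps networks comparable across depositions that do and do not include
riding hydrogens. Alternate locations are resolved to the highest-occupancy
copy, first-in-file on ties. Residues are identified by author numbering
(`seq_number` + insertion code) and ordered by it; a contiguous 0-based
`sequence_index` is assigned afterwards, so sequence adjacency is defined on
*resolved* residues — two residues flanking a disordered gap count as
adjacent. Chain gaps are simply absent nodes; no model completion is
attempted.

Crystallographic quality is screened with two predicates used for dataset
assembly: resolution ≤ 3.0 Å and, when both refinement R factors are present,
R_free − R_work ≤ 0.05 (a 1e-9 epsilon keeps the inclusive boundary robust to
binary float representation). Missing resolution fails the filter; missing R
factors pass with a warning. The pipeline warns on filter failures by default
and aborts only in strict mode.

## Network construction

Two residues with sequence separation ≥ 2 form an edge when any pair of their
heavy atoms lies within 4.5 Å (closed boundary, Euclidean distance). Contact
detection uses a k-d tree but is exactly equivalent to the all-pairs
computation (asserted against a brute-force oracle in the tests). The edge
weight divides the residue pair's atom-contact count by the largest count
ever observed for that amino-acid-type pair in a reference set (the
normalization table), giving weights in (0, 1]. All tunables — cutoff (4.5 Å),
minimum separation (2), hub threshold (11 edges) — are configurable; the
defaults are the standard all-atom PSN convention.

The package's default normalization table is derived at first use from a
deterministic synthetic reference set: 60 idealized helical chains with
varied sequences plus side-chain-repacked, hinge-bent and point-mutated
variants of the ten fixture chains. Including perturbed variants matters:
they produce collapsed side-chain geometries with higher contact counts, and
a table built only from unperturbed helices would systematically clamp
weights on perturbed inputs. The set covers all 210 unordered type pairs
(pinned by a test). A ratio exceeding 1 — possible only with a user-supplied
table — is clamped to 1.0 with a warning, never silently. Users comparing
real structures should derive a table from their own high-resolution dataset
(`psn-delta normtable`); edge/hub counts and degrees are
normalization-independent, the weighted scores are not.

## Residue correspondence and RMSD

For conformer pairs of one protein, a global sequence alignment (BLOSUM62,
gap open −10, extend −0.5) recovers the topologically equivalent pairs; a
point substitution aligns rather than gaps under these parameters, so the
mutated position is always a common node (node identity is positional, not
type-based). The optional `sequence+refine` mode iteratively superposes the
mapped Cα atoms and discards pairs deviating by more than 5 Å (≤ 10 rounds),
approximating the aligned-core behaviour of structure-alignment tools —
dedicated structure alignment is deliberately out of scope, and for
near-identical sequences the sequence route is equivalent for mapping
purposes. RMSD is computed by Kabsch superposition (SVD with reflection
correction) of the mapped Cα sets.

## Network comparison

Both PSNs are restricted to the common node set before any comparison (the
dissimilarity score requires identical node counts, and the partition
semantics follow it). Edge identity is presence of the node pair: a retained
edge may change weight, and those changes are reported in a separate table
rather than moving the edge between classes. Hubs are recomputed on the
restricted graphs so both sides see the same node universe. The partition
identities (retained ∪ lost = wildtype edges; retained ∪ gained = mutant
edges; Σ ddegree = 2(gained − lost)) are asserted in the test suite.

## The dissimilarity score

Both networks use the symmetric normalized Laplacian
L = I − D^(−1/2) A D^(−1/2); its spectrum lies in [0, 2], which is what makes
the |1−λ| weighting of EWCS meaningful (eigendirections near the spectral
bulk at λ = 1 carry little weight). Rows and columns of isolated nodes are
zeroed entirely, giving them an exact (λ = 0, indicator) eigenpair, so
self-comparison of graphs with isolated nodes is still exactly zero. The
combinatorial Laplacian D − A is available as an option.

EDS divides the full-matrix Frobenius norm of A − B by the geometric mean of
the total edge weights, each undirected edge summed once (the full-matrix
summation is available behind a switch; the convention is pinned by a unit
test: one edge at weight 1.0 vs 0.5 gives EDS exactly 1). An edgeless input
raises a distinct error (zero denominator). EDS is not bounded by 1 for
pathological weight differences; values above 1 are flagged in the result,
never clamped.

Eigenvectors are paired one-to-one by maximizing the total absolute cosine
with an exact linear assignment. (A greedy descending-|cosine| pass was
evaluated first and returned measurably suboptimal assignments on small
random fixtures when checked against exhaustive enumeration, so the exact
assignment is used throughout; the exhaustive check remains as a test
oracle.) Within blocks of (near-)repeated eigenvalues — gaps below 1e-6 —
individual eigenvectors are arbitrary up to rotation of the eigenspace, so
cosines between two degenerate blocks are replaced by the basis-free mean
principal-angle cosine Σ_k cos θ_k / √(|g||h|) before assignment, and exact
ties are broken toward rank-aligned pairs using the squared rank distance
(the quantity CRS measures), scaled to ~1e-10 so it can never override a
genuine cosine difference. Degenerate spectra are flagged in the result.
Eigenvector sign is ignored (absolute cosines) throughout.

CRS is the Spearman correlation of the matched ranks; EWCS is the weighted
root-mean-square of (1 − |cos θ|) over matched pairs with weights
|1−λ^A|·|1−λ^B| (the plain weighted mean, without squaring, is available
behind a switch), defined as 0 when all weights vanish. NDS aggregates the
three components as √(EDS² + EWCS² + (1−CRS)²).

**Range.** NDS is 0 for identical networks. The √3 upper bound corresponds to
total mismatch with EDS = 1, EWCS = 1, CRS = 0; it is guaranteed only while
each component term stays within [0, 1], i.e. while CRS ≥ 0. A one-to-one
matching can in principle produce CRS < 0 (anti-correlated rank order) for
strongly uncorrelated graph pairs; with the principal-angle matching above
this did not occur anywhere in the randomized 1000-pair bound suite, but it
is a property of the score worth knowing, not an implementation bug.

**Exact identity.** When the two adjacency matrices are bitwise equal their
Laplacians and spectra are identical by definition, so `nds_score` returns
the exact identity result (EDS 0, CRS 1, EWCS 0, NDS 0) without invoking the
eigensolver; `superpose` likewise returns RMSD exactly 0 for bitwise-equal
coordinate sets, and a hinge rotation by angle 0 is the exact identity map.
This removes ~1e-15 solver noise from self-comparisons, which downstream
consumers may legitimately test against exact zero.

## Solvent accessibility

Shrake–Rupley over heavy atoms: each atom's sphere (van der Waals radius +
1.4 Å probe) is sampled on a deterministic golden-spiral lattice of 960
points; the accessible fraction scales the expanded-sphere area. Relative
accessibility divides by the residue type's theoretical maximum (Tien et al.
2013); residues are classed buried below RSA 0.10, exposed otherwise. Probe,
threshold and point count are configurable. Rotation invariance holds to
sampling tolerance (a few percent), which is why exposure classes, not raw
areas, feed the per-site reports.

## Synthetic data

The generator emulates the two perturbation regimes observed between real
wildtype/mutant crystal pairs without requiring any download:

- `make_chain` builds an idealized α-helix (rise 1.5 Å, 100° per residue,
  radius 2.3 Å) with N/CA/C/O backbone atoms; the carbonyl O of residue i
  points toward the amide N of residue i+4, as in helical hydrogen bonding,
  which realizes the i±3 and i±4 backbone contacts and gives interior nodes
  degree 4. Side chains are pseudo-atoms — the correct heavy-atom count per
  residue type, stacked 1.5 Å apart along the Cα outward normal with seeded
  jitter ≤ 0.3 Å. The contact network depends only on atom positions and
  counts, so simplified side chains exercise every code path; no rotamer
  library or sterics.
- `perturb_sidechains` displaces the side chains of a seeded residue subset
  by vectors of bounded norm, leaving backbone coordinates bitwise unchanged
  (regime a: RMSD 0, network changed). The `sidechain_repack` scenario
  compares two *independently* repacked conformers of one backbone so that
  both the lost and gained edge classes populate — a straight helix has no
  side-chain-only contacts of its own to lose.
- `hinge_bend` rigidly rotates everything past a pivot about an axis through
  the pivot Cα perpendicular to the helix axis, preserving all intra-segment
  distances (regime b: RMSD > 1 Å, segment-internal network identical).
- `mutate_residue` swaps one residue's type and regenerates its pseudo-side
  chain (point substitution with untouched backbone).

Defaults (repack fraction 0.5, displacement 3.0 Å; hinge at ¾ length, 60°;
60-residue chains) were chosen once as magnitudes typical of side-chain
rearrangement and domain hinge motions; at these settings the two regimes
separate cleanly (repack NDS ≈ 0.32–0.45 at RMSD 0; hinge NDS ≈ 0.2–0.3 at
RMSD ≈ 4.5 Å) across seeds. Everything is deterministic per seed
(numpy default_rng / PCG64).

**What passing synthetic tests does and does not show.** The synthetic chains
are helical, single-segment, and sterically unchecked; their networks are
far sparser than a folded protein's (no hubs — a tertiary-packed structure is
needed to reach degree 11), and their normalization table is not transferable
to real structures. Synthetic results validate the algebra and the
regime-level behaviour of the scores, not published per-case magnitudes;
reproducing those requires the corresponding PDB entries and a normalization
table derived from a comparable structure dataset (the published reference
table is not available, which dominates the uncertainty on weighted-score
comparisons).

## Known limitations

- Structure alignment is sequence-driven; for conformer pairs with large
  rearrangements the `sequence+refine` core is an approximation to a true
  structural alignment.
- Single chains only; no biological assemblies, no inter-chain edges.
- Dense eigendecomposition throughout — fine for protein chains (≤ a few
  thousand nodes), not intended for large generic graphs.
- The buried/exposed threshold (RSA 0.10) and SASA method are declared
  defaults; published exposure-change counts depend on unstated tool choices
  and are not an exact reproduction target.
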