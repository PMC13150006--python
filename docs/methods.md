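# Methods

## Problem setting

Catecholamine GPCRs discriminate between adrenaline, noradrenaline and
dopamine although the three agonists differ by at most two hydroxyl groups
and the orthosteric pockets of the receptors are nearly identical.  `selexp`
implements the comparative-sequence route to this problem: if the mechanism
of selectivity is conserved within a subfamily, the positions responsible
should be *conserved within* each subfamily yet *divergent between*
subfamilies.  The package turns that hypothesis into a reproducible
statistic, connects it to structure, dynamics and pharmacology, and ships
synthetic generators so every step is testable without external downloads.

## Hotspot statistic

For each alignment column carrying a generic residue number, the consensus
residue is the most frequent non-gap residue (ties broken alphabetically —
deterministic and documented) and its conservation is the consensus count
divided by the total number of sequences.  Gaps count against conservation
by default because a gap is evidence that the position is not conserved;
`gaps_in_denominator=False` switches to non-gap normalisation.  A position
is a hotspot when

- conservation ≥ θ in **both** groups (θ = 0.80 by default), and
- BLOSUM62(consensus_a, consensus_b) < 0.

The conservation comparison is inclusive (≥) by default with a strict (>)
option: published descriptions of this filter vary between "≥80%" and
">80%", and the positions of interest in practice sit near 100%
conservation where the choice is immaterial.  The BLOSUM62 table is
embedded as integer constants (standard NCBI values) so the matrix data
carries no runtime dependency; the test suite verifies all 400 entries
against Biopython's copy.  Because the BLOSUM62 diagonal is non-negative,
identical consensus residues can never be called — the statistic isolates
genuine residue-type divergence.  Candidate positions can be restricted to
a whitelist (helix segments 1–7 plus the packaged 13-position binding-site
list); the packaged list is approximate because exact helix boundaries
depend on the numbering scheme in use.

The chance-probability helper reports C(n, k) as an exact integer
(`math.comb`), e.g. C(100, 7) = 16,007,560,800 — "one in ≈16 billion" —
for selecting one specific 7-subset of 100 divergent positions at random.

## Generic numbering

Column numbering is supplied as a user table in *reference-residue
coordinates*: `position` counts the non-gap characters of a chosen
reference row (1-based).  This makes the annotation invariant to how the
alignment is gapped (property-tested by random all-gap column insertion)
and keeps the tool offline and deterministic; no live GPCRdb query is
performed.  Alignment columns are 0-based internally and 1-based in all
outputs.  `.` is accepted as a gap synonym; ambiguity codes (B, Z, X, J, O,
U) are rejected unless explicitly mapped to gaps, since curated receptor
sequence sets are expected to be clean.

## Structural annotation

*Binding site*: a receptor residue belongs to the orthosteric site when any
of its heavy (non-hydrogen) atoms is within the cutoff (default 4.0 Å) of
any ligand heavy atom.  The set is monotone in the cutoff (tested).  For
multi-conformer atoms only the highest-occupancy location is kept;
insertion codes are concatenated into residue keys.

*Regions*: hotspot calls are classified by a lookup table defaulting to the
three regions implicated in catecholamine selectivity — the orthosteric
site (the 13 binding-site positions, including 3x36, 45x52, 7x38), the
TM2-TM7 interface (2x60, 2x64, 7x35, 7x39, 1x46, 7x43) and the
TM3-TM4-TM5 interface (3x41, 3x42, 4x53, 5x46).  The table is overridable.

*Prioritization*: the triage of hotspots that are unlikely to affect ligand
binding (surface-exposed) or risky to mutate (near the G-protein interface)
was originally a manual judgement.  The package exposes it as explicit,
overridable proxies: (a) an explicit deprioritize list; (b) relative
side-chain exposure — Shrake–Rupley sampled accessible surface (480
quasi-uniform sphere points, probe 1.4 Å, standard van der Waals radii)
normalised by the same residue's surface computed in isolation, threshold
0.4.  Self-normalisation avoids a per-residue reference table and behaves
sensibly for non-standard residues; (c) Cα distance ≤ 8 Å to a user-marked
intracellular reference set, standing in for "close to the G protein
binding site", for which no published cutoff exists.

*Superposition*: Cα RMSD after least-squares rigid superposition (Kabsch,
SVD with determinant correction so the rotation is always proper).  Pairing
is by shared generic number when maps are provided, else by residue key;
unpaired residues are dropped and the matched count reported.  The
implementation is cross-checked against an independent quaternion-based
solver in the tests.  Published whole-receptor RMSD values for mutant
versus wild-type structures cannot be reproduced exactly without knowing
the residue subset used for fitting; with downloaded structures (e.g. PDB
4LDO and 7LJD plus a residue-to-generic-number map) `binding_site_residues`
and `superpose_ca` perform the corresponding analyses directly — this
optional validation needs network access and is therefore documented here
rather than exercised in the test suite.

## Trajectory networks

Edges connect residue pairs whose occupancy — the fraction of frames with
any heavy-atom distance below 4.5 Å — is at least 0.75.  Sequence-adjacent
residues (|Δseq| ≤ 1 within a chain) are excluded, the standard practice to
avoid trivial backbone contacts; both rules are configurable.  The
correlation attached to an edge is the normalized equal-time
cross-correlation of Cα displacement vectors about their means,

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

computed after superposing every frame onto frame 1 — raw lab-frame
correlation would conflate global tumbling with internal motion.  The edge
weight is w = −log |C_ij|, the convention of the dynamic-network tools this
module follows, clamped at w_max = 20 when |C| < e⁻²⁰; no published
closed-form for "weights derived from the cross-correlation matrix" exists,
so the formula is explicit and configurable.  A single-frame ensemble has
zero variance and raises a named degenerate-statistics error.

Communities are found by Girvan–Newman edge-betweenness removal with the
partition chosen at maximum modularity over the dendrogram (including the
initial connected-components partition); ties between equal-betweenness
edges are broken lexicographically so results are deterministic.  Shortest
communication paths between source and sink residues use Floyd–Warshall
over the edge weights; unreachable pairs are reported with infinite weight.
Both are verified against independent oracles (brute-force modularity
enumeration; single-source Dijkstra on 100 random graphs).

Hydrogen bonds use the geometric criterion D–A < 3.5 Å and D–H–A ≥ 120°
(inclusive), with donor hydrogens inferred from frame-1 geometry (D–H ≤
1.2 Å); occupancy is the detected-frame fraction.  χ1 is the N–Cα–Cβ–γ
torsion (γ = CG1 for Val/Ile, OG1 for Thr, OG for Ser, SG for Cys, CG
otherwise), signed per the convention shared by the standard MD analysis
libraries, range (−180°, 180°] with −180° mapped to +180°.  Welch's
unequal-variance t-test (scipy, Welch–Satterthwaite df) compares occupancy
samples; two zero-variance samples with equal means return p = 1 by
convention.

Ensemble input is a multi-model PDB or a plain-text per-frame XYZ table
against a PDB topology — no binary trajectory format is required in the
core.

## Pharmacology

The 3-parameter logistic fixes the Hill slope at 1 and fits basal, Emax and
pEC50 — matching the standard "3-parameter" model of curve-fitting
software — by bounded least squares (pEC50 ∈ [0, 14]) with multi-start over
a pEC50 grid (4–10, step 1; optional seeded jitter).  Requirements: ≥ 4
points spanning ≥ 2 log units.  A flat response returns a non-converged fit
with reason "flat-response" instead of an arbitrary optimum.  On noiseless
synthetic curves the fit recovers the generating pEC50 to < 10⁻⁴; at 5%
Gaussian noise with 3 replicates the median absolute pEC50 error is < 0.1
log units over 1,000 seeded simulations (both asserted in the tests).

Fold selectivity is 10^ΔpEC50, reported at two significant figures to match
the published convention (2500, 63, 3400, …) with full precision retained
in machine output.  Recomputing published folds from printed two-decimal
pEC50 values reproduces every quoted value at two significant figures
except one: the D1 receptor's dopamine-over-noradrenaline selectivity is
quoted as 19-fold while 10^(8.48−7.22) = 18.2 rounds to 18, presumably
because the original value was derived from unrounded potencies.  The
package reports 18 from these inputs; the discrepancy is documented here
and not patched.

## Synthetic data: what it emulates and what it does not

*Alignments*: two groups with per-position consensus residues; planted
hotspot positions carry divergent residue pairs verified negative-scoring
at construction (defaults: the five prioritized pairs G/K at 2x60, V/S at
3x36, E/L at 3x41, F/S at 45x52, N/V at 7x38, at conservation 1.0), among
identical background positions.  Group sizes default to 515 and 401
sequences, the sizes of the β-adrenergic and D1-like sets that motivated
the defaults.  Conservation is enforced *exactly by count* (⌊c·n⌋ consensus
copies) so threshold tests are sharp at θ = 0.80; minority residues are
spread over many residue types so the consensus is never ambiguous.  The
generator does not emulate phylogenetic correlation between sequences,
alignment errors, or gap structure — perfect recovery on these fixtures
demonstrates the statistic's correctness, not its robustness to tree
structure or misalignment.

*Trajectories*: point residues (single Cα pseudo-atoms) on a 3-D grid with
isotropic Gaussian noise (0.1 Å default).  Contact pairs are realised in
exactly round(occupancy · n_frames) randomly chosen frames.  Correlated
blocks share a Gaussian displacement mode; because the network's
correlation is computed after rigid-body superposition, the planted mode is
first projected onto the orthogonal complement of the rigid subspace
(translations + infinitesimal rotations over the base geometry) and its
amplitude solved in closed form so the *measured* correlation matches the
target.  A degenerate (e.g. collinear) layout would let the superposition
absorb planted modes, which is why the grid is three-dimensional.  No
physical force field or realistic protein geometry is emulated.

*Curves*: logistic truths plus seeded Gaussian noise (sd as % of Emax,
default 5%, 3 replicates, 13 half-log concentrations from 0.1 nM to
100 µM).  Default truths are the wild-type β2/D1 printed potencies so the
fitting-to-fold pipeline can be exercised end to end.

All generators are pure functions of their spec including the seed
(NumPy `default_rng`); identical specs give byte-identical output.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick, deterministic runs:
hotspot recovery on 50 background positions with 60–80 sequences per group,
networks of 8–12 residues over 200–3000 frames, 100-graph path oracles, and
1,000-curve fitting simulations.  Tolerances asserted in tests: pEC50
recovery 10⁻⁴ (noiseless) and 0.1 median (noisy), occupancy ±0.05 at 1,000
frames, correlation targets ±0.05, dihedrals 10⁻⁶ degrees on analytic
constructions.  Floating-point policy: exact integer arithmetic for
combinatorics; folds rounded only at the reporting boundary.

## Limitations

- The hotspot statistic uses raw sequence counts; no phylogenetic
  down-weighting of redundant species is performed.
- The TM whitelist and the prioritization heuristics are explicit proxies
  for judgements that were originally manual; their thresholds (exposure
  0.4, intracellular distance 8 Å) are defaults to be reviewed per use.
- The network edge-weight formula is a documented convention, not a
  published formula; alternative mappings from correlation to weight can
  change shortest paths.
- Curve fitting pools replicates into a single least-squares problem;
  replicate-level error structure is not modelled.
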