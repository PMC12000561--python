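# Methods

This note records the models implemented in `allodyn`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.
No empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and units

A complex is a `Topology` (atoms with PDB-style names, residue
annotations, partial charges in e, Lennard-Jones σ in Å and ε in
kcal/mol, plus bonds) paired with a `Trajectory` (frames × atoms × 3,
Å). Coordinates travel as multi-model PDB (fixed columns, 0.001 Å
precision) or a compact whitespace frames file; the topology lives in a
versioned YAML sidecar because PDB cannot carry charges or LJ
parameters. All unit handling is by convention — nothing is converted
implicitly. Residue numbering is 1-based (PDB convention), atom
indexing 0-based.

## Energy decomposition

For a reference fragment F, the interaction energy with the environment
is the frame-wise sum over pairs (i ∈ F, j ∉ F) of

    E_ij = k_e q_i q_j / r_ij  +  4 ε_ij [ (σ_ij/r_ij)^12 − (σ_ij/r_ij)^6 ]

with k_e = 332.0636 kcal·Å·mol⁻¹·e⁻² and Lorentz–Berthelot combining
(arithmetic σ, geometric ε), vacuum dielectric. Bonded exclusions
follow the AMBER convention: 1-2 and 1-3 pairs excluded, 1-4 pairs
scaled by 1/1.2 (electrostatics) and 1/2 (LJ); both scalings are
arguments and are logged. No distance cutoff is applied by default —
the intended systems are small and solvent-free, so the exact all-pair
sum is affordable and unambiguous; a cutoff is available as an option.
Each pair's energy is attributed to the residue owning the environment
atom j, giving the per-partner breakdown; fragment-internal pairs are
never counted. ΔE tables subtract per-partner means between two systems
(identity mapping on (chain, residue index) by default); partners
present on one side only enter with the other side as zero and are
flagged.

Solvent and ions, if present in a topology, are treated as ordinary
environment atoms; the synthetic generator emits none.

## Dynamic network

Node assignment follows the dynamic-network convention for
protein–nucleic-acid complexes: one node per amino acid anchored on Cα
(owning the residue's heavy atoms), two per nucleotide — a phosphorus
node owning phosphate + sugar heavy atoms and a base node owning the
base heavy atoms, anchored on N1 for purines and N3 for pyrimidines
(configurable per residue name) — and one node per cofactor group,
anchored at the heavy atom nearest the group centroid. An abasic
nucleotide (no base atoms) keeps its base-node slot anchored at C1′ and
flagged, so an abasic lesion is always addressable as a path endpoint.
A 5′-terminal nucleotide without P gets only the base node, with a
warning.

Two nodes are "in contact" in a frame when the minimum heavy-atom
distance between their node groups is ≤ 4.5 Å; an edge requires contact
in strictly more than 75 % of frames (both threshold and strictness are
configuration keys). Group-minimum distance was chosen over
anchor-to-anchor distance because anchor distance would miss side-chain
and base contacts that clearly couple motions. Sequence-neighbour
residues, and the two nodes of one nucleotide, are ineligible for edges
to prevent trivial backbone shortcuts. Edge weight is w = −ln|C| from
the generalized (dot-product) correlation

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)

of the node anchor displacements about their trajectory mean. Pairs
with |C| < 10⁻⁴ would carry near-infinite weight and are dropped with a
log entry rather than kept; a node with exactly zero fluctuation is an
error, not a silent C = 0. Edge betweenness counts, for every unordered
node pair, the minimum-weight path(s) between them, splitting ties
equally; optimal paths use Dijkstra on the non-negative weights with a
deterministic lexicographic tie-break on node ids. An unreachable
target is an explicit no-path result.

## Mode contributions

"Mode contribution" is computed as PCA of the trajectory covariance of
node anchor coordinates (essential dynamics): eigen-decomposition of
the 3N × 3N covariance, with a mode's contribution defined as its
eigenvalue over the trace. This matches the reported quantity —
percentage contribution of a mode to the observed motion — without
inventing spring constants; structure-based elastic-network (ANM/GNM)
Hessian modes are deliberately out of scope. Eigenvalues below zero by
round-off (> −10⁻¹⁰) are clipped to zero with a warning. Replicate
trajectories are analyzed separately; nothing is concatenated or
averaged across replicas.

## Superposition

Rigid-body fitting uses the Kabsch algorithm (proper rotations only,
det +1) on a user-chosen subset (≥ 3 non-collinear atoms; default in
the pipeline: protein Cα). RMSD is measured after superposition; RMSF
about the per-atom trajectory mean assumes an already-superposed
trajectory.

The pipeline superposes only when per-frame rigid jitter was actually
generated (`superpose: auto`; can be forced). Superposing a lab-frame
Gaussian field is not harmless: the fit removes the net rigid-body
component of each frame, which for correlated fields subtracts a
common mode and damps the observed correlations below the generator's
ground truth. A constant rigid transform of all frames, by contrast,
leaves correlations, mode fractions, energies and contacts unchanged on
either route (the acceptance suite checks this to 10⁻⁸).

## Kinetics, binding, mutation frequency

The glycosylase scheme E + S ⇌ E·S →(k₂) E·P →(k₃) E + P is fit under
the fast-binding assumption, so only k₂ and k₃ are estimated (k₁, k₋₁
are documented symbols, never fit):

* STO ([E] > [S]): P(t) = A₀(1 − e^(−k₂t)); needs ≥ 4 distinct times.
* MTO ([E] < [S]): P(t) = A₀(1 − e^(−k₂t)) + A₀k₃t, the standard
  burst-plus-linear form; A₀ estimates active enzyme and
  active fraction = A₀/[E]. Initialization: A₀ from the early-time
  plateau, k₃ from the terminal slope over A₀; bounds keep all rates
  positive. A fit whose burst never saturates inside the sampled range
  (k₂·t_max < 1) or whose amplitude error exceeds the amplitude is
  flagged degenerate; A₀ > [E] is flagged as a warning.

Fits use weighted least squares with per-time-point replicate SD when
≥ 3 replicates are present (with a floor at 10 % of the median SD to
avoid zero weights), unweighted otherwise.

One-site binding Y = B_max·X/(K_D + X) (Y in percent bound). When the
isotherm is already ≥ 90 % saturated at the smallest nonzero
concentration, K_D is not identifiable from below; the fit reports an
upper limit (K_D ≤ smallest X) and sets the `upper_limit` flag instead
of pretending precision.

Mutation frequency from the rifampicin fluctuation assay is
f = median(resistant counts) / mean(viable counts); the median
numerator makes f robust to jackpot cultures. Fold changes between
variants are ratios of these median-based f values.

## Synthetic generator

The generator emulates, at toy scale, the object of study: a small
protein (chain A, 5 heavy atoms per residue including Cα), a DNA-like
strand (chain B, phosphate + sugar plus a 3-atom base with its ring
nitrogen; optionally abasic), and an 8-atom [4Fe-4S]-like cofactor
(chain C), with charges/LJ from a small built-in table.

Geometry. Node groups are compact blobs placed on a 12 Å grid so
undesignated group pairs stay > 8 Å apart; each designated contact pair
(anchors 10.5 Å apart) is realized through one relocated non-anchor
"contact atom" placed 3.5 Å from the partner anchor. During sampling
that atom is pinned relative to the partner anchor — 3.5 Å in contact
frames, 6.5 Å in scheduled-out frames, with the leading
round(fraction·n_frames) frames assigned as contacts — so scheduled
persistence fractions are met exactly and boundary tests at
0.74/0.75/0.76 are deterministic. Anchor atoms are never pinned: they
carry the prescribed Gaussian displacement field (applied rigidly to
the rest of their group), so correlations, RMSF and mode spectra see
exactly the specified covariance.

Covariance. The node correlation matrix is background b off-diagonal
with a compound-symmetric block at the planted level c over the planted
chain. The block (all chain pairs at c, not only consecutive ones) is
what keeps the matrix positive semi-definite: consecutive-only 0.9 over
a 0.2 background has a negative leading minor, and projecting it to the
PSD cone would move the planted entries far beyond tolerance. Since
only consecutive chain pairs are placed in contact, the network still
sees exactly the intended chain. If round-off requires a nearest-PSD
projection that moves any requested entry by more than 0.01 the spec is
rejected as infeasible. The same covariance is applied independently
per Cartesian axis, which makes the dot-product correlation of the
anchors equal the specified matrix in expectation — chosen for analytic
recoverability. Default per-axis node variance is 0.09 Å² (RMSF
≈ 0.52 Å, a typical well-ordered-residue scale); it also keeps
displacement tails (≲ 2.5 Å relative at the 10⁻⁹ level) small enough
that the 10.5/12 Å anchor layout preserves scheduled contact states.

A separate mode sampler draws displacements along random orthonormal
vectors of the full 3N node-coordinate space with prescribed variances;
this is the ground truth for mode-fraction recovery, because the
per-axis node-covariance route necessarily triples every eigenvalue
(spectrum ⊗ I₃) and cannot realize a two-eigenvalue 3N spectrum.

Assays are simulated from the exact model curves with multiplicative
Gaussian noise (clipped into physical range); fluctuation-assay
resistant counts are Poisson with mean f × (design mean viable count)
and viable counts log-normal about the design mean (default CV 0.2).
Defaults mirror a realistic bench design: STO at [E] = 100 nM,
[S] = 20 nM, k₂ = 1.2 min⁻¹; MTO at [E] = 5 nM with A₀ = 4 nM,
k₃ = 0.05 min⁻¹; K_D = 2 nM with B_max = 100 %; f = 5×10⁻⁸ over 24
plates at 10⁸ viable cells.

What the generator does **not** emulate — and hence what passing tests
do not show: physical bonded geometry (bond lengths/angles are
arbitrary; toy absolute energies sit partly on the repulsive LJ wall
and only oracle agreement and system-to-system differences are
meaningful), solvent and ions, force-field realism, sequence realism,
anharmonic or time-correlated dynamics, and the magnitudes of real MD
observables. Recovery results demonstrate correctness of the
estimators under the stated generative model, not accuracy on real
trajectories.

## Problem sizes

Default validation sizes were chosen so the whole suite runs in well
under a minute while keeping sampling error far from the tolerances:
50 random systems for the energy oracle, 100 random ≤ 7-node graphs for
the graph oracle, 100 × 2000-frame replicates for planted-chain
recovery, 5000 frames for mode fractions, 100 seeds for kinetic noise
studies, 200 seeds for the fluctuation-assay fold study, and a
500-frame end-to-end fixture for determinism.

## Known limitations

* The energy engine is exact-sum only; no neighbour lists, so it scales
  as O(frames × |F| × |environment|) and is meant for desk-scale
  systems, not solvated boxes.
* The contact map is O(pairs × frames × group²) without spatial
  pruning; fine for hundreds of nodes, not thousands.
* `compare_systems` assumes identical node labelling between the two
  systems (point mutations that preserve residue numbering); indels
  would need an explicit mapping, which only the ΔE layer supports.
* The MTO burst fit assumes a clean separation of burst and linear
  phases; heavily saturating designs ([S] exhaustion) are out of model.
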