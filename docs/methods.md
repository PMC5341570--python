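# Methods

This note documents the models and procedures implemented in `rindyn`, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic validation data does and does not establish.

## Units and conventions

Lengths are nanometres everywhere in memory; Angstrom appears only at the
PDB file boundary (1 Å = 0.1 nm, so deposited coordinates are divided by
10 on read). Times are picoseconds, angles degrees, energies kcal/mol
(only in the secondary-structure hydrogen-bond score). Residue numbers are
author numbers as deposited and are never renumbered; frame indices are
0-based. Altloc conformers are resolved to the highest-occupancy copy
(ties: first encountered). Periodic boundary conditions are **not**
applied anywhere: inputs are assumed whole and clustered, as produced by
standard trajectory post-processing; all distances are plain Euclidean.

## Structure model and bond perception

A `Topology` (atoms, residues, chains, bonds) plus a `Trajectory`
(frames × atoms × 3, strictly increasing times) is the in-memory model;
PDB parsing and writing go through biotite. Intra-residue bonds come from
the chemical-component templates of the standard amino acids; residues
without a template use a distance criterion (heavy-heavy < 0.19 nm,
hydrogen to nearest heavy < 0.12 nm). Peptide bonds connect consecutive
residues of a chain when C(i)-N(i+1) < 0.19 nm; SG-SG pairs closer than
0.25 nm are recorded as disulfides. Elements missing from the file are
inferred from atom-name conventions.

## Trajectory geometry

Superposition is weighted Kabsch (proper rotations only; reflections
excluded), via the SVD-based solver. RMSF uses the iteratively refined
average structure as reference: frames are fitted to frame 0, averaged,
then re-fitted to that average (one refinement pass) before fluctuations
are measured — this makes RMSF invariant to the arbitrary choice of the
first frame. Contact counts use strict `<` at the cutoff so the result is
deterministic under floating-point ties. Profile comparison reports the
ordinary least-squares line of b on a, Pearson r, and the residual
variance s² = RSS/(n−2); s² is the residual variance around the fitted
line, not the raw data variance. Masses come from a standard atomic-mass
table; unknown elements default to 12 u with a warning.

## Hydrogen bonds

Geometric criterion: donor-acceptor distance ≤ 0.35 nm and
hydrogen-donor-acceptor angle (vertex at the donor heavy atom, **not**
donor-hydrogen-acceptor) ≤ 30°; N and O accept, NH and OH groups donate;
directly covalently bonded heavy-atom pairs are excluded. Deposited
crystal structures lack hydrogens, so a missing backbone amide H is
constructed at 0.101 nm from N opposite the bisector of the N→CA and
N→C(prev) directions; hydroxyl hydrogens cannot be placed without a
rotamer choice, so such donors are skipped and counted in a diagnostics
record. When no bond table is available, the amide-H naming convention
(H/HN) is honoured for backbone N donors only — no other donor may claim
a hydrogen by name.

## SASA

Shrake-Rupley with a deterministic golden-spiral point set (default 960
points), probe radius 0.14 nm, and a Bondi-style per-element radius table
(C 0.17, N 0.155, O 0.152, S 0.18, H 0.12 nm; default 0.152 nm with a
warning). Per-atom area = (exposed points / total points) · 4π(r+probe)².
Only atoms inside the selection occlude and are scored, so "protein-only"
and "ligand-only" areas are each computed in their own frame of reference;
occlusion by a larger environment is obtained by passing the larger
selection.

## Secondary structure

The classical electrostatic hydrogen-bond energy
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol (distances in
Å, bond iff E < −0.5) feeds the standard pattern rules: an n-turn at i iff
the NH of i+n bonds the CO of i (n = 3, 4, 5); two consecutive n-turns
make a minimal helix (class priority H > E/B > G > I on overlap);
parallel/antiparallel bridge patterns make B, with runs of two or more
consecutive bridges promoted to E; a single n-turn marks T; a bend S where
the CA(i−2)‥CA(i)‥CA(i+2) direction changes by more than 70°; otherwise
C. Chain breaks (C-N > 0.25 nm) terminate every pattern, and chains
shorter than three residues are all C. This is a re-implementation of the
published definitions; byte-compatibility with any external assigner
binary is not promised — correctness is pinned to ideal-geometry fixtures
(a 12-residue ideal helix assigns H to its interior, a two-strand
antiparallel sheet assigns E, an extended single strand assigns neither).

## Rotational correlation

NH unit vectors are taken per residue (prolines and chain N-termini
excluded; hydrogens built as above when absent). The P2 autocorrelation
averages over all time origins (stride 1) and all vectors before fitting;
it is computed through the tensor identity
P2(u·v) = (3 Σ_ab (u_a u_b)(v_a v_b) − 1)/2, which reduces the
origin average to FFT-accelerated autocorrelations of the six unique
outer-product components. The default maximum lag is half the window
length, bounding estimator noise at long lags. The model-free curve
y = a0 + (1−a0)·exp(−x/a1) is fitted by bounded least squares
(a0 ∈ [−0.5, 1], a1 > 0; initialisation a0 = last value, a1 = first lag
below a0 + (1−a0)/e; tolerance 1e-8). τ_c is the analytic integral of the
fitted curve over the fit window — a finite window is forced by the
plateau term, whose infinite integral diverges — and D_iso = 1/(6 τ_c);
both a1 and τ_c are reported. A constant series is flagged degenerate
(pure plateau; a1 unidentifiable).

For validating τ_c recovery against a known diffusion constant, a single
rigid body is one realisation of the slow global reorientation and its
windowed RCF has sampling scatter of order ±20 %; the recovery check
therefore averages the RCF over 20 independent diffusion trajectories
(50 000 frames of 1 ps each, fit window 6 000 ps ≈ 3.6 τ) before the one
fit, which brings the estimator's own error near 5 % — comfortably inside
the 15 % recovery tolerance. The fitted decay constant a1 is the sharper
estimator (the window-truncation bias of the τ_c integral over [0, T] is
1 − e^(−T/a1)); both are exercised in the tests.

## Essential dynamics

The covariance of the selected coordinates is taken after superposing all
frames onto the converged iterative mean (fit to frame 0, then two
refinement passes onto the running mean). The covariance is
mass-unweighted, matching common Cα-only practice. Eigendecomposition is
the symmetric solver; eigenvalues are clipped of numerical negatives
below 1e-14 and variance fractions are eigenvalue/trace. Projections
superpose onto the PCA mean and dot with the leading eigenvectors. The
DCCM normalises ⟨Δr_i·Δr_j⟩ by the per-atom fluctuation magnitudes;
zero-variance atoms get a zero row with unit diagonal and a warning.
Subspace similarity is reported three ways, all in [0, 1]: the per-vector
inner products |v_a,i·v_b,i| of the first k pairs, RMSIP over the first
k = 10 eigenvectors, and the normalised Hess covariance overlap
1 − √((Σ(λ_a+λ_b) − 2Σ_ij √(λ_a,i λ_b,j)(v_a,i·v_b,j)²)/Σ(λ_a+λ_b)).
Degenerate eigenvalues make individual eigenvectors arbitrary within the
eigenspace, so tests assert only subspace quantities.

## Clustering

Jarvis-Patrick on the pairwise superposed-RMSD matrix: neighbour lists are
the M = 10 nearest frames (self excluded); two frames join when each lists
the other and they share at least P = 3 common neighbours; clusters are
connected components of the join relation — deterministic and
non-iterative. Frames tied with the M-th nearest distance are all kept in
the list: with real-valued RMSDs this is exactly the M-nearest rule, and
on degenerate matrices (all frames identical) it keeps the relation
symmetric so one cluster results instead of an index-order artifact.
Fringe frames can fail the mutual condition and come out as singletons —
an inherent property of the algorithm — so a separate minimum-cluster-size
filter (default ≥ 2 members) is provided for counting states; the
representative of a cluster is its medoid (minimal summed distance, ties
to the lowest frame index). An optional RMSD-cutoff neighbour mode exists
but is not the default.

## Residue interaction networks

Nodes are standard amino-acid residues (hetero groups optional, waters
never); an edge exists when any heavy-atom pair of two residues is closer
than 0.5 nm **and** the residues are not covalently bonded — the
covalent exclusion is evaluated on the atom-level bond list, which removes
peptide-bonded neighbours and disulfide partners. The minimum heavy-atom
distance is stored per edge; DCCM strengths |C_ij| annotate edges and give
each node its correlation-weighted degree. Shortest paths are unweighted
hop counts (strengths annotate, they do not weight paths; an
inverse-strength weighted mode exists but is non-default).

Whole-network statistics: C = mean local clustering (degree < 2
contributes 0); L = mean shortest-path length over connected pairs only;
diameter/radius are the extreme eccentricities within components;
density = 2E/(N(N−1)); heterogeneity = std(degree)/mean(degree);
centralization = (N/(N−2))·(k_max/(N−1) − density). Betweenness is
normalised by (N−1)(N−2)/2; closeness is within-component:
(number of reachable nodes)/(summed distances to them), which is 1 for a
star centre and 0 for an isolate. Girvan-Newman removes the
highest-betweenness edge repeatedly (ties: lexicographically smallest
node pair, so the removal order is deterministic); the default stop is the
maximum-modularity partition over the removal sequence, including the
initial component partition (so a complete graph stays one community);
communities with ≤ 2 members are counted as isolated, larger ones as
integrated. The inter-chain pathway from a source residue is the union of
**all** shortest paths (ties retained) to every reachable residue of the
target chain, computed from the BFS predecessor DAG; its inter-chain edges
are the bridging pairs. When no target-chain residue is reachable the
union is taken to the furthest reachable frontier and flagged terminated.
All-pairs distances are available through Floyd-Warshall; pair queries may
use repeated BFS with identical results.

## Synthetic data: what it emulates and what it does not

The generators produce exactly the statistical structure each analysis
assumes: i.i.d. multivariate-normal frames with planted orthonormal modes
(PCA/DCCM ground truth), rigid-body rotational diffusion with
rotation-vector steps of per-axis variance 2·D·dt (exact exp(−6Dt) P2
limit as dt → 0), ideal backbones from textbook internal coordinates
(helix φ = −57°, ψ = −47°; strand φ = −139°, ψ = +135°; the sheet partner
strand is rigidly placed by least squares onto the antiparallel
hydrogen-bond registry), block-labelled multi-state ensembles, exact
donor-H-acceptor geometries, and bead complexes whose realized contact set
is verified against the design by a full distance scan (construction fails
loudly rather than produce an off-design fixture). All generators are
seed-deterministic.

What passing these tests shows: the estimators recover known answers from
data satisfying their assumptions. What it does not show: behaviour under
real-trajectory pathologies — anharmonic and multi-basin dynamics,
time-correlated frames, force-field artefacts, broken molecules across
periodic images, missing residues and non-standard chemistry. The
published study values that depend on the authors' 200-ns trajectories
(RMSF correlations, τ_c ≈ 28.6 ns, PCA variance fractions, pathway
node/edge counts, Table-style network statistics) are therefore not
reproduction targets; the structure-derived quantities (node count and
backbone Rg of the deposited wild-type hexamer) and the in-table density
arithmetic are.

## Problem sizes

The validation suite runs at desk scale by design: ensembles of
500-5 000 frames and 5-20 particles for geometry/PCA/DCCM/clustering,
20 × 50 000 frames for rotational-diffusion recovery, networks of up to
40 residues for the graph layer with brute-force oracles at ≤ 30 nodes,
and 12-residue ideal fixtures for the secondary-structure and
hydrogen-bond layers. The pipeline itself has no size assumptions beyond
memory; the Floyd-Warshall option is quadratic in nodes and intended for
networks of a few thousand residues.

## Known limitations

- No minimum-image handling; pre-whole-ed trajectories are required.
- Hydroxyl/amine side-chain donors without explicit hydrogens are skipped
  rather than enumerated over rotamers.
- The secondary-structure assigner omits PP-II and κ-helix extensions and
  the solvent-exposure columns of full assigner output files.
- mmCIF and compressed binary trajectory formats (XTC/DCD) are out of
  scope; convert externally.
- The model-free fit is the two-parameter plateau-exponential only; no
  two-timescale (internal + global) decomposition.
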