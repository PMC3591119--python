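# Methods

## Model and scope

All computations operate on Cα traces of single protein chains. A
*superposition* is a proper rigid motion `x → Rx + t` (det R = +1); an
*alignment* is a strictly increasing list of residue-index pairs
(sequential, order-preserving, one-to-one). Chains are treated as rigid
objects throughout: one transform per pair, no flexible or multi-fragment
fitting. Alignment indices are positional (0-based file order), never
author residue numbers; chains with unobserved interior residues are used
as-is.

## The aligners

Every aligner alternates an alignment step that is exactly optimal for its
scoring scheme given the current superposition with a least-squares
superposition of the aligned pairs, iterated until the pair set repeats or
an iteration cap of 100 is reached (a hash of the pair list detects cycles
as well as fixed points).

**STRUCTAL.** Score matrix `S(i,j) = 20/(1 + d_ij²/5)`, global DP with a
linear penalty of 10 per skipped position and a zero boundary, so a run of
skips before the first matched pair is free on the cheaper side while
interior and trailing skips are charged in full. The reported objective is
the pair-score sum minus 10 per penalized skipped position, recomputed on
the returned alignment and transform; a `convention="interior"` switch
counts only interior skips instead, for comparison with conventions that
read "number of gaps" more narrowly. The per-iteration DP and the final
objective share the constant 10.

**TM-align-style.** Score matrix `S(i,j) = 1/(1 + (d_ij/d0)²)` with
`d0 = 1.24(L−15)^⅓ − 1.8` Å, `L` the shorter chain length, floored at
0.5 Å (the raw formula is non-positive for `L ≤ 17`; short chains must not
produce a non-positive scale). Affine gaps: 0.6 per gap run opened, 0.0
per extension; switching a gap from one chain to the other opens a new
run. `d0` is fixed from the input lengths, not re-estimated per iteration.
`tmscore_align` deliberately does *not* re-fit the superposition it is
given — the two-step protocol hands each method a fixed transform — while
`tmalign_align` is the stand-alone seeded, iterated variant.

**LOCK2.** Refinement alternates mutual-nearest-neighbour pairing within
3 Å (ties to the lower index) with least-squares superposition (quaternion
solver, matching the method's lineage; the SVD solver is numerically
equivalent and cross-checked). The final alignment keeps the
maximum-cardinality sequential subset of the mutual-NN pairs —
"colinearity" is sequential-order consistency, not geometric collinearity
of vectors — breaking count ties by smaller total pair distance. The
published secondary-structure-element initial superposition requires SSE
assignment and is out of scope; seeding is the shared fragment scheme
below.

**Seeding.** Since the methods' published initial-superposition heuristics
are either unavailable or out of scope, all stand-alone runs start from a
common deterministic seed set: least-squares transforms of all length-k
fragment pairs (default k = 8, stride 4, final window always included),
deduplicated at 2° rotation / 1 Å translation, with the identity prepended.
This makes the three heuristics comparable under one protocol; it is not a
claim of bit-compatibility with the original programs.

## The deep search (CA ≤ d)

The target is the largest number of pairs a single superposition can fit
under `d` Å in sequential order — an alignment-independent ceiling for
every rigid aligner at that cutoff. `maxpairs_search` evaluates fragment
seeds at several lengths (default 4/6/8/12, stride 4), refines each by
alternating the integer threshold-counting DP with superposition of the
matched pairs (keeping the best transform *visited*, since the alternation
is not monotone in the count), then re-refines the top 10 candidates at
`d + ε` before tightening back to `d` (defaults d = 3 Å, ε = 1 Å — the
study conditions). Equal counts are tie-broken by smaller matched-pair
cRMS, then seed order; the whole search is deterministic given its
parameters. The sequential (order-preserving) reading of the measure is
adopted throughout; an unrestricted assignment variant is deliberately not
implemented.

Which subset of superposition space the original deep-search program
scanned is not published; this seed-and-refine design is a documented
reconstruction validated against the exhaustive oracle at toy scale, not a
re-implementation. Its counts are constructive lower bounds in all cases.

**Grid oracle.** For combined lengths ≤ 12 residues, an exhaustive scan
over a ZYZ-Euler grid × a translation grid anchored on the first chain's
centroid (so the centroid-aligned placement is scanned exactly) certifies
bounds: discretization displaces any atom by at most
`δ = r_max·θ_max + (√3/2)·t_step` (θ_max = 1.5 × the angular step in
radians, r_max the second chain's maximal centroid distance), so the
oracle's best count at `d + δ` is an upper bound on the true optimum at
`d`. The bound is stated in terms of this computed δ, not the search's ε,
whose published guarantee belongs to an enumeration that is not public.

## Metrics

NumPairs(d) counts *aligned* pairs within d after superposition; it never
exceeds the CA ≤ d count at the same transform (the central inequality,
asserted in tests and the acceptance script). SI = cRMS·min(L_a,L_b)/Nmat
(undefined for empty alignments — reported absent, not zero);
PSI(d) = NumPairs(d)/min(L_a,L_b). Shift agreement measures, for each test
pair (i, j) whose a-residue the reference aligns to j′, whether
|j − j′| ≤ s; the curve I_s/L_ref is reported for s = 0…s_max, measured in
the a → b direction only, and test pairs absent from the reference never
count. Benchmark aggregates are arithmetic per-pair means, overall and per
manifest label, with missing values excluded pairwise.

## Synthetic fixtures

Chains: ideal α-helices (rise 1.5 Å, 100°/residue, radius 2.3 Å —
consecutive spacing ≈ 3.83 Å), fixed-step 3.8 Å self-avoiding random walks
(rejection sampling at a 3.5 Å clash radius, relaxed gradually if a walk
dead-ends), or mixtures. Pairs: copy, delete an indel pattern, replace a
contiguous block of (1 − f) of the remainder with decoy walk geometry
branching off the native chain, apply a seeded random transform, add
isotropic Gaussian noise whose displacement norms are truncated at 2.5 σ.
The truncation makes the fixture certificate deterministic: under the
planted transform every true pair lies within max(3 σ, 0.5) Å, so the true
correspondence demonstrably places ≥ f·n pairs under that cutoff, and all
recovery tests compare against this certificate rather than an unproven
optimum.

What the fixtures do *not* emulate: real secondary-structure packing,
side chains, sequence–structure correlation, or the size distribution of
curated benchmarks. Passing recovery tests therefore shows the search
machinery finds plantable optima under realistic geometry and noise — not
that it reproduces any published benchmark figure on real structures,
which requires the corresponding PDB files and reference alignments.

## Numerical choices

* DP boundary: zero (leading skip free on the cheaper side; interior and
  trailing skips charged). The enumeration oracles score candidate
  alignments closed-form under exactly this convention, so DP and oracle
  agree to 1e-9.
* Tracebacks break ties diagonal > up > left (affine: match state > skip
  in a > skip in b) with a 1e-9 tolerance absorbing the float drift of the
  vectorized forward pass; outputs are bit-reproducible.
* "Never match" cells in the threshold DP are handled by exclusion, not
  −∞ arithmetic; the count DP is pure int64. Other DPs use a −1e18
  sentinel to avoid inf − inf.
* Superposition: SVD (Kabsch) with determinant correction by default;
  Horn's quaternion method available and cross-checked. Pairings with
  k < 3 or rank < 2 (collinear/coincident) return a best-effort transform
  with a degeneracy flag instead of failing, so iterative aligners survive
  transiently tiny pairings; all-coincident points return the identity
  rotation.
* d0 floor 0.5 Å; distance cutoffs must be positive; empty pairings are
  errors for cRMS/superposition and "absent" for SI and shift agreement.

## Problem sizes

Tests and the acceptance script use chains of 4–80 residues: enumeration
oracles cover all monotone alignments of 5×6 score matrices and ≤ 7-residue
coordinate toys; the rotation-grid RMSD oracle refines below 0.05°; the
exhaustive superposition oracle is guarded to ≤ 12 combined residues;
recovery runs 20 decoy pairs at n = 80, f = 0.6, σ = 0.5 Å; the synthetic
benchmark runs six decoy pairs at n = 60, f = 0.7, σ = 0.5 Å. These sizes
exercise every code path while keeping a full run within minutes on one
CPU; the library itself handles chains of several hundred residues (the
DPs are O(mn) per iteration with vectorized rows).

## Known limitations

* The native heuristic passes share one seeding scheme rather than each
  method's published initialization, so per-method native numbers are a
  reconstruction, not a reproduction of the original binaries.
* The deep search is a heuristic lower bound; only the toy-scale oracle
  certifies upper bounds.
* Sequential matching only; no flexible alignment, no mmCIF, first model
  of multi-model files only, no secondary-structure features.
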